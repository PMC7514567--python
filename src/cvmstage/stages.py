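"""The six ordered cervical maturation stages.

CS1 (about two years before the mandibular growth peak) through CS6 (about
two years after its end). The integer values give the total order
CS1 < CS2 < ... < CS6 used throughout the package.
"""

from __future__ import annotations

import enum


class StageLabel(enum.IntEnum):
    """Cervical vertebral maturation stage, CS1..CS6."""

    CS1 = 1
    CS2 = 2
    CS3 = 3
    CS4 = 4
    CS5 = 5
    CS6 = 6

    @classmethod
    def from_any(cls, value) -> "StageLabel":
        """Coerce an int (1..6) or a string like ``"CS3"``/``"CVS3"``/``"3"``."""
        if isinstance(value, StageLabel):
            return value
        if isinstance(value, str):
            s = value.strip().upper()
            if s.startswith("CVS"):
                s = s[3:]
            elif s.startswith("CS"):
                s = s[2:]
            value = int(s)
        return cls(int(value))


ALL_STAGES: tuple[StageLabel, ...] = tuple(StageLabel)
N_STAGES: int = len(ALL_STAGES)
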