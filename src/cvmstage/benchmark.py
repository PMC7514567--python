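"""End-to-end synthetic benchmarks: generate -> (filter) -> train -> score.

The *standard benchmark* trains the default five-block network on the easy
generator preset (100 images per class rendered at 64 x 64, split
60/20/20) for 30 epochs and reports test-set accuracy. A *small benchmark*
(32 x 32 images, narrower network, fewer images and epochs) exists for
quick comparative experiments -- the entropy-filter and network-depth
comparisons -- where many runs are needed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cvmstage import evalmetrics, model as M, preproc, synthdata


@dataclasses.dataclass
class BenchmarkResult:
    test_accuracy: float
    history: M.TrainingHistory
    confusion: np.ndarray
    report: evalmetrics.ClassReport
    probabilities: np.ndarray
    test_labels: np.ndarray
    n_train: int
    n_test: int


#: Entropy-filter settings used when a benchmark preprocesses its images:
#: 7x7 square window with a coarse 8-bin histogram, so sensor noise stays
#: mostly within one bin while structure (body rims) crosses bins.
ENTROPY_WINDOW = preproc.WindowSpec("square", 7)
ENTROPY_BINS = 8


def run_benchmark(
    seed: int,
    generator: synthdata.GeneratorConfig | None = None,
    model_config: M.ModelConfig | None = None,
    train_config: M.TrainConfig | None = None,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    entropy_filter: bool = False,
) -> BenchmarkResult:
    """One full run. ``seed`` drives both the generator and training."""
    generator = generator or synthdata.easy_preset(seed=int(seed) % (2 ** 31))
    if generator.seed != int(seed) % (2 ** 31):
        generator = dataclasses.replace(generator, seed=int(seed) % (2 ** 31))
    model_config = model_config or M.ModelConfig(
        input_side=generator.image_size)
    train_config = train_config or M.TrainConfig(seed=(int(seed) + 7919) % (2 ** 31))

    samples = synthdata.generate_samples(generator, split_fractions)
    sets = {s: synthdata.samples_to_arrays(samples, s)
            for s in synthdata.SPLIT_NAMES}
    if entropy_filter:
        sets = {
            k: (preproc.entropy_preprocess_batch(v[0], ENTROPY_WINDOW,
                                                 ENTROPY_BINS), v[1])
            for k, v in sets.items()
        }
    net = M.build_model(model_config, seed=(int(seed) + 104729) % (2 ** 31))
    net, history = M.train(net, sets["train"], sets["val"], train_config)
    x_test, y_test = sets["test"]
    probs = M.predict_proba(net, x_test)
    pred = probs.argmax(axis=1) + 1
    cm = evalmetrics.confusion_matrix(y_test, pred)
    report = evalmetrics.classification_report(cm)
    return BenchmarkResult(
        test_accuracy=float((pred == y_test).mean()),
        history=history,
        confusion=cm,
        report=report,
        probabilities=probs,
        test_labels=y_test,
        n_train=len(sets["train"][1]),
        n_test=len(y_test),
    )


def small_generator(seed: int = 0, hard: bool = False,
                    n_per_class: int = 36) -> synthdata.GeneratorConfig:
    """Reduced-count generator for quick comparative runs.

    Images stay at 64 px: the stage-defining concavities are already
    sub-pixel at that scale and coarser rasters lose the class signal."""
    make = synthdata.hard_preset if hard else synthdata.easy_preset
    return make(image_size=64, n_per_class=n_per_class, seed=seed % (2 ** 31))


def small_model_config(input_side: int = 64,
                       extra_block: bool = False) -> M.ModelConfig:
    """Narrow ladder for quick runs; ``extra_block`` appends a sixth conv
    block (pool 1, so the spatial size survives)."""
    blocks = list(M.small_conv_blocks())
    if extra_block:
        blocks.append(M.ConvBlockSpec(64, 3, 1, 0.25))
    return M.ModelConfig(input_side=input_side, conv_blocks=tuple(blocks),
                         dense_width=128)


def small_train_config(seed: int = 0, epochs: int = 12) -> M.TrainConfig:
    return M.TrainConfig(epochs=epochs, seed=seed % (2 ** 31))


def run_small_benchmark(seed: int, hard: bool = False,
                        entropy_filter: bool = False,
                        extra_block: bool = False,
                        n_per_class: int = 36,
                        epochs: int = 12) -> BenchmarkResult:
    """Scaled-down comparative run (32-px images, narrow network)."""
    return run_benchmark(
        seed,
        generator=small_generator(seed, hard=hard, n_per_class=n_per_class),
        model_config=small_model_config(extra_block=extra_block),
        train_config=small_train_config(seed, epochs=epochs),
        entropy_filter=entropy_filter,
    )
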