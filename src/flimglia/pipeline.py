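"""End-to-end detection experiments on synthetic fields of view.

Glue for the full workflow the package implements: simulate FOVs, fit
decay cubes (FBM) or take raw histograms (DBM), build labeled block
features, train the shallow network on the training FOVs, calibrate the
probability cutoff and minimum region size on those same FOVs, then score
detection on held-out FOVs.  Used by the command-line interface, the test
suite, and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import ann_core, decay_fit, detect_eval, labelprep, phantom
from .tcspc_io import RunConfig

__all__ = [
    "ExperimentResult",
    "simulate_fovs",
    "fit_fovs",
    "run_detection_experiment",
    "run_culture_benchmark",
]


@dataclasses.dataclass
class ExperimentResult:
    """Everything a detection experiment produced."""

    result: detect_eval.DetectionResult
    thresholds: detect_eval.DetectionThresholds
    net: ann_core.NetworkSpec
    report: ann_core.TrainReport
    config: RunConfig
    mode: str


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """n child seeds (< 2**31) derived deterministically from one seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_fovs(config: phantom.PhantomConfig, n_fovs: int,
                  seed: int) -> list[phantom.PhantomFOV]:
    """Generate ``n_fovs`` independent FOVs from per-FOV child seeds."""
    return [phantom.generate_phantom(config, s) for s in _spawn_seeds(seed, n_fovs)]


def fit_fovs(fovs, config: RunConfig,
             options: decay_fit.FitOptions | None = None):
    """Fit every FOV's cube with its session IRF; returns FitParamMaps list."""
    return [decay_fit.fit_cube(f.cube, f.irf, config, options) for f in fovs]


def run_detection_experiment(train_fovs, test_fovs, config: RunConfig | None = None,
                             mode: str = "fbm", seed: int = 0,
                             fit_options: decay_fit.FitOptions | None = None,
                             train_options: ann_core.TrainOptions | None = None,
                             train_maps=None, test_maps=None) -> ExperimentResult:
    """Train on ``train_fovs``, calibrate there, evaluate on ``test_fovs``.

    ``mode`` selects the fitting-based ("fbm") or decay-based ("dbm")
    feature pipeline.  Pre-computed parameter maps can be passed to avoid
    refitting when several experiments share FOVs.
    """
    if mode not in ("fbm", "dbm"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or RunConfig(rng_seed=seed)

    if mode == "fbm":
        if train_maps is None:
            train_maps = fit_fovs(train_fovs, config, fit_options)
        if test_maps is None:
            test_maps = fit_fovs(test_fovs, config, fit_options)
        train_inputs, test_inputs = train_maps, test_maps
        tables = [labelprep.extract_fbm_blocks(m, f.mask, config, fov_id=i)
                  for i, (m, f) in enumerate(zip(train_maps, train_fovs))]
    else:
        train_inputs = [f.cube for f in train_fovs]
        test_inputs = [f.cube for f in test_fovs]
        tables = [labelprep.extract_dbm_vectors(f.cube, f.mask, config, fov_id=i)
                  for i, f in enumerate(train_fovs)]

    table = labelprep.FeatureTable.concat(tables)
    table, stats = labelprep.normalize_features(table)
    split = labelprep.split_dataset(table, config.split_fractions, seed=seed)
    net = ann_core.init_network(table.n_features, config.n_hidden, seed=seed)
    train_options = train_options or ann_core.TrainOptions(seed=seed)
    net, report = ann_core.train(net, table, split, train_options)

    train_probs = [detect_eval.predict_image(net, x, config) for x in train_inputs]
    train_gt = [detect_eval.block_grid_view(f.mask, config) for f in train_fovs]
    thresholds = detect_eval.calibrate_thresholds(train_probs, train_gt)

    counts = []
    for x, fov in zip(test_inputs, test_fovs):
        prob = detect_eval.predict_image(net, x, config)
        pred = detect_eval.binarize_and_clean(prob, thresholds)
        gt = detect_eval.cell_labels_view(fov.mask, config)
        counts.append(detect_eval.match_detections(pred, gt))
    result = detect_eval.compute_metrics(counts)
    return ExperimentResult(result=result, thresholds=thresholds, net=net,
                            report=report, config=config, mode=mode)


def run_culture_benchmark(seed: int = 1, n_train: int = 20, n_test: int = 5,
                          shape: tuple[int, int] = (128, 128),
                          photons: float = 3000.0) -> ExperimentResult:
    """The headline synthetic experiment: FBM detection on the culture preset.

    Generates ``n_train + n_test`` FOVs of mixed-glia phantoms at the
    documented defaults, runs the full fit -> blocks -> train -> calibrate ->
    detect pipeline, and returns pooled detection metrics on the held-out
    FOVs.
    """
    config = RunConfig(rng_seed=seed)
    pconfig = phantom.culture_preset(shape=shape, photons=photons)
    fovs = simulate_fovs(pconfig, n_train + n_test, seed)
    return run_detection_experiment(fovs[:n_train], fovs[n_train:],
                                    config, mode="fbm", seed=seed)
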