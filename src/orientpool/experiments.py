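"""End-to-end experiment runners producing tidy results tables.

Five experiments are orchestrated:

1-3. 2AFC global-orientation discrimination against skewed comparison
     distributions — piecewise Gaussians with density-matched halves
     (experiment 1), piecewise Gaussians with equal-mass halves and unequal
     sampling intervals (experiment 2, same mode and median but different
     mean), and skewed uniforms (experiment 3, different mean and median).
     Each runs with static (spatial pooling) or dynamic (temporal pooling)
     textures.
4.   Clockwise/counter-clockwise judgements about implicit vertical as a
     function of stimulus duration (7 log-spaced durations, 0.05-3.33 s),
     for a diagnostic distribution whose VA and ML predictions straddle
     vertical.
5.   The same duration sweep at three Michelson contrasts (0.25, 0.5, 1)
     through a configurable contrast -> rate-gain hook.

Every row of a results table carries the condition, decoder, fitted PSE
(signed and magnitude), threshold, bootstrap CI, the comparison
distribution's mean/median/mode, trial counts and the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from ._angles import signed_offset
from .decoding import loglik_profile, ml_decode, va_decode
from .distributions import (
    EQUAL_MASS,
    OrientationDistribution,
    SkewedGaussianSpec,
    SkewedUniformSpec,
    build_skewed_gaussian,
    build_skewed_uniform,
    distribution_stats,
)
from .encoding import NeuronBank, mean_response, stimulus_proportions
from .psychophysics import (
    SimulatedObserver,
    StimulusParams,
    bootstrap_pse_ci,
    fit_logistic,
    run_constant_stimuli,
    simulate_vertical_judgement,
)

__all__ = [
    "ExperimentConfig",
    "experiment_conditions",
    "condition_distribution",
    "default_duration_standin",
    "noiseless_predictions",
    "run_spatial_experiments",
    "run_temporal_experiments",
    "run_duration_experiment",
    "run_contrast_experiment",
    "make_gain_function",
]

# (sigma_ccw, sigma_cw) pairs; density-matched halves, 2.5 deg grid, +/-45 deg
EXPERIMENT1_SDS = ((15.0, 15.0), (20.0, 10.0), (25.0, 5.0), (30.0, 0.0))
# (sigma_ccw, sigma_cw); equal-mass halves, ccw @2.5 / cw @0.5 deg, +/-90 deg
EXPERIMENT2_SDS = ((6.0, 15.0), (10.0, 25.0), (14.0, 35.0), (18.0, 45.0))
# (range_ccw, range_cw); equal-mass halves, 2.5 deg grid
EXPERIMENT3_RANGES = ((45.0, 45.0), (55.0, 35.0), (65.0, 25.0), (75.0, 15.0))

DURATIONS_S = tuple(float(d) for d in np.geomspace(0.05, 3.33, 7))
CONTRASTS = (0.25, 0.5, 1.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters for one experiment run.

    ``conditions`` indexes into the experiment's published condition list
    (None = all).  ``noisy_standard`` replaces the common-orientation
    standard with a symmetric Gaussian (SD 30 deg) or uniform (range 90 deg)
    standard as a control.
    """

    experiment: int = 1
    decoders: tuple = ("va",)
    mode: str = "static"
    trials_per_level: int = 80
    n_levels: int = 9
    pilot_trials: int = 50
    n_boot: int = 5000
    seed: int = 0
    conditions: tuple | None = None
    noisy_standard: str | None = None
    bandwidth: float = 22.5
    r_max: float = 60.0
    rate_floor: float = 0.01
    # duration / contrast experiments
    durations: tuple = DURATIONS_S
    contrasts: tuple = CONTRASTS
    trials_per_duration: int = 300
    gain_function: str = "identity"
    standin_ccw_range: float = 75.0
    standin_cw_range: float = 15.0
    standin_offset: float = 2.5

    def bank(self) -> NeuronBank:
        return NeuronBank(bandwidth=self.bandwidth, r_max=self.r_max, rate_floor=self.rate_floor)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        plain = {
            k: list(v) if isinstance(v, tuple) else v for k, v in self.to_dict().items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(plain, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("decoders", "durations", "contrasts", "conditions"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def experiment_conditions(experiment: int) -> tuple:
    if experiment == 1:
        return EXPERIMENT1_SDS
    if experiment == 2:
        return EXPERIMENT2_SDS
    if experiment == 3:
        return EXPERIMENT3_RANGES
    raise ValueError("experiment must be 1, 2 or 3")


def condition_distribution(experiment: int, params: tuple, reference: float = 0.0) -> OrientationDistribution:
    """Comparison distribution for one published condition."""
    a, b = params
    if experiment == 1:
        return build_skewed_gaussian(SkewedGaussianSpec(sigma_ccw=a, sigma_cw=b), reference)
    if experiment == 2:
        spec = SkewedGaussianSpec(
            sigma_ccw=a,
            sigma_cw=b,
            interval_ccw=2.5,
            interval_cw=0.5,
            truncation_ccw=90.0,
            truncation_cw=90.0,
            half_weighting=EQUAL_MASS,
        )
        return build_skewed_gaussian(spec, reference)
    if experiment == 3:
        return build_skewed_uniform(SkewedUniformSpec(range_ccw=a, range_cw=b), reference)
    raise ValueError("experiment must be 1, 2 or 3")


def _standard_distribution(noisy: str | None) -> OrientationDistribution:
    if noisy is None:
        return OrientationDistribution.point_mass(0.0)
    if noisy == "gaussian30":
        return build_skewed_gaussian(
            SkewedGaussianSpec(sigma_ccw=30.0, sigma_cw=30.0, truncation_ccw=90.0, truncation_cw=90.0)
        )
    if noisy == "uniform90":
        return build_skewed_uniform(SkewedUniformSpec(range_ccw=45.0, range_cw=45.0))
    raise ValueError(f"unknown noisy_standard {noisy!r}")


def _run_discrimination(config: ExperimentConfig, mode: str) -> pd.DataFrame:
    bank = config.bank()
    all_conditions = experiment_conditions(config.experiment)
    chosen = all_conditions if config.conditions is None else tuple(
        all_conditions[i] for i in config.conditions
    )
    standard = _standard_distribution(config.noisy_standard)
    rows = []
    for ci, params in enumerate(chosen):
        comparison = condition_distribution(config.experiment, params)
        stats = distribution_stats(comparison)
        for di, decoder in enumerate(config.decoders):
            rng = np.random.default_rng([config.seed, config.experiment, ci, di, 0 if mode == "static" else 1])
            observer = SimulatedObserver(bank, decoder, StimulusParams(mode=mode))
            data = run_constant_stimuli(
                observer,
                standard,
                comparison,
                rng,
                trials_per_level=config.trials_per_level,
                n_levels=config.n_levels,
                pilot_trials=config.pilot_trials,
            )
            fit = fit_logistic(data)
            if fit.converged and config.n_boot > 0:
                fit = bootstrap_pse_ci(data, n_boot=config.n_boot, rng=rng, base_fit=fit)
            rows.append(
                {
                    "experiment": config.experiment,
                    "mode": mode,
                    "condition": f"{params[0]:g}/{params[1]:g}",
                    "standard": config.noisy_standard or "common",
                    "decoder": decoder,
                    "pse_deg": fit.pse,
                    "pse_magnitude_deg": abs(fit.pse),
                    "threshold_deg": fit.threshold,
                    "converged": fit.converged,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "dist_mean": stats.mean,
                    "dist_median": stats.median,
                    "dist_mode": stats.mode,
                    "n_trials": int(data.n_trials.sum()),
                    "seed": config.seed,
                }
            )
    return pd.DataFrame(rows)


def run_spatial_experiments(config: ExperimentConfig) -> pd.DataFrame:
    """Experiments 1-3 with static textures (orientations pooled over space)."""
    return _run_discrimination(config, "static")


def run_temporal_experiments(config: ExperimentConfig) -> pd.DataFrame:
    """Experiments 1-3 with dynamic textures (orientations pooled over time)."""
    return _run_discrimination(config, "dynamic")


def default_duration_standin(config: ExperimentConfig | None = None) -> OrientationDistribution:
    """Diagnostic distribution for the duration/contrast experiments.

    A 75/15 skewed uniform whose median is placed a little clockwise of
    vertical, so the VA prediction (near the mean, counter-clockwise of
    vertical) and the ML prediction (at the placement, clockwise of
    vertical) straddle the implicit-vertical reference.
    """
    config = ExperimentConfig() if config is None else config
    spec = SkewedUniformSpec(range_ccw=config.standin_ccw_range, range_cw=config.standin_cw_range)
    return build_skewed_uniform(spec, 90.0 + config.standin_offset)


def noiseless_predictions(bank: NeuronBank, dist: OrientationDistribution, duration: float = 1.0) -> dict:
    """Expected-count (no Poisson noise) VA and ML estimates for a stimulus."""
    prop = stimulus_proportions(dist, bank)
    mean_counts = mean_response(bank, prop, duration)
    va = va_decode(bank, mean_counts)
    ml = ml_decode(loglik_profile(bank, mean_counts, duration, template=dist))
    return {"va": va.estimate, "ml": ml.estimate}


def run_duration_experiment(config: ExperimentConfig | None = None, gains: dict | None = None) -> pd.DataFrame:
    """Vertical-judgement proportions for each decoder across durations.

    Rejects the stand-in distribution unless the noiseless VA and ML
    predictions fall on opposite sides of vertical.  ``gains`` maps a
    contrast label to a rate gain (used by the contrast experiment); the
    default is full contrast only.
    """
    config = ExperimentConfig(decoders=("va", "ml")) if config is None else config
    bank = config.bank()
    dist = default_duration_standin(config)
    pred = noiseless_predictions(bank, dist)
    offs = {k: float(signed_offset(v, 90.0)) for k, v in pred.items()}
    if not (offs["va"] < 0.0 < offs["ml"]):
        raise ValueError(
            "stand-in distribution is not diagnostic: noiseless offsets "
            f"VA {offs['va']:+.2f} deg, ML {offs['ml']:+.2f} deg do not straddle vertical"
        )
    gains = {"1": 1.0} if gains is None else gains
    decoders = config.decoders if config.decoders else ("va", "ml")
    rows = []
    for label, gain in gains.items():
        for di, duration in enumerate(config.durations):
            for deci, decoder in enumerate(decoders):
                rng = np.random.default_rng([config.seed, 4, di, deci])
                prop = simulate_vertical_judgement(
                    dist, duration, decoder, bank, config.trials_per_duration, rng, gain=gain
                )
                n = config.trials_per_duration
                se = np.sqrt(max(prop * (1 - prop), 1e-12) / n)
                rows.append(
                    {
                        "contrast": label,
                        "gain": gain,
                        "duration_s": float(duration),
                        "decoder": decoder,
                        "n_trials": n,
                        "prop_clockwise": prop,
                        "ci_low": max(0.0, prop - 1.96 * se),
                        "ci_high": min(1.0, prop + 1.96 * se),
                        "seed": config.seed,
                    }
                )
    return pd.DataFrame(rows)


def make_gain_function(name: str):
    """Contrast -> rate-gain hook: 'identity' (g=1), 'linear' (g=c), 'power:p'."""
    if name == "identity":
        return lambda c: 1.0
    if name == "linear":
        return lambda c: float(c)
    if name.startswith("power:"):
        p = float(name.split(":", 1)[1])
        return lambda c: float(c) ** p
    raise ValueError(f"unknown gain function {name!r}")


def run_contrast_experiment(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Duration sweep at each Michelson contrast, rates scaled by the gain hook."""
    config = ExperimentConfig(decoders=("va", "ml")) if config is None else config
    g = make_gain_function(config.gain_function)
    gains = {}
    for c in config.contrasts:
        gc = g(c)
        if not (0 < gc <= 1):
            raise ValueError(f"gain function returned {gc!r} for contrast {c}, outside (0, 1]")
        gains[f"{c:g}"] = gc
    return run_duration_experiment(config, gains=gains)


def write_results(df: pd.DataFrame, out_csv, config: ExperimentConfig, manifest_path=None) -> None:
    """Write a results table plus a JSON manifest echoing the configuration."""
    df.to_csv(out_csv, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump({"config": config.to_dict(), "n_rows": len(df)}, fh, indent=2)
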