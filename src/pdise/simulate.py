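"""Synthetic stream-diatom communities along a total-phosphorus gradient.

The generator emulates the statistical structure the calibration machinery
assumes: a log-normal TP gradient spanning roughly 1–900 µg/l with a median
near 25 µg/l, taxa with Gaussian niche responses on the log10 TP axis, and
fixed-effort counts (400 valves per sample, the standard counting protocol)
drawn multinomially and converted to relative abundance.

An optional two-pool regime suppresses the carrying capacity of taxa with
intermediate TP optima, reproducing the observed scarcity of "lukewarm"
communities: site-specific community optima then distribute bimodally even
though the TP gradient itself and the taxon optima remain unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "generate_gradient",
    "generate_niches",
    "generate_community",
    "generate_bimodal_regime",
    "true_profiles",
]


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic generator.

    The TP gradient is log-normal with log10 mean 1.4 and SD 0.45: median
    10^1.4 ≈ 25 µg/l, and the central ~99.9% of 820 sites spans ≈ 1–900 µg/l,
    matching routine Swedish stream monitoring.  400 valves per sample is the
    counting standard.

    Taxon optima are always drawn from one normal (centre 1.49, SD 0.35 —
    median 31 µg/l, interquartile span ≈ 18–54 µg/l): the taxon-optimum
    distribution stays unimodal in every regime, as observed.  Taxa are
    labelled low / intermediate / high by ``intermediate_band``, and in the
    two-pool regime the intermediate pool's carrying capacity is multiplied
    by ``suppression`` — bimodality of site optima emerges from abundance
    suppression alone, not from bimodal niches.
    """

    n_sites: int = 820
    n_taxa: int = 100
    tp_mean_log10: float = 1.4
    tp_sd_log10: float = 0.45
    valve_count: int = 400
    bimodal: bool = False
    suppression: float = 0.3
    intermediate_band: tuple[float, float] = (1.25, 1.60)
    optimum_mean: float = 1.49     # taxon-optimum distribution centre
    optimum_sd: float = 0.35
    tolerance_median: float = 0.12  # true niche SD, log10 units
    tolerance_log_sd: float = 0.3
    capacity_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.valve_count < 1:
            raise ValueError("valve_count must be >= 1")
        if self.n_sites < 1 or self.n_taxa < 1:
            raise ValueError("n_sites and n_taxa must be >= 1")
        if self.tp_sd_log10 < 0:
            raise ValueError("tp_sd_log10 must be >= 0")
        if not 0 <= self.suppression:
            raise ValueError("suppression must be non-negative")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams per generator stage, all pinned by config.seed
    return np.random.default_rng([config.seed, stream])


def generate_gradient(config: SimulationConfig) -> pd.DataFrame:
    """Draw the site TP gradient: log10 TP ~ Normal(mean, sd), TP in µg/l."""
    rng = _rng(config, 1)
    log_tp = rng.normal(config.tp_mean_log10, config.tp_sd_log10, config.n_sites)
    tp = np.power(10.0, log_tp)
    index = pd.Index([f"S{i:04d}" for i in range(config.n_sites)], name="site_id")
    return pd.DataFrame({"tp_ugl": tp}, index=index)


def generate_niches(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-taxon Gaussian niche parameters on the log10 TP axis.

    Returns a frame indexed by taxon code with columns ``true_optimum``,
    ``true_tolerance`` (niche SD, log10 units), ``max_capacity`` and
    ``pool_label`` ({'low', 'intermediate', 'high'}).  Optima come from one
    unimodal normal regardless of regime; labels mark position relative to
    ``intermediate_band``.
    """
    rng = _rng(config, 2)
    n = config.n_taxa
    optima = rng.normal(config.optimum_mean, config.optimum_sd, n)
    lo, hi = config.intermediate_band
    labels = np.where(optima < lo, "low", np.where(optima > hi, "high", "intermediate"))
    tolerances = config.tolerance_median * np.exp(rng.normal(0.0, config.tolerance_log_sd, n))
    capacities = np.exp(rng.normal(0.0, config.capacity_log_sd, n))
    index = pd.Index([f"TX{i:03d}" for i in range(n)], name="code")
    return pd.DataFrame(
        {
            "true_optimum": optima,
            "true_tolerance": tolerances,
            "max_capacity": capacities,
            "pool_label": labels,
        },
        index=index,
    )


def _expected_intensity(log_tp: np.ndarray, niches: pd.DataFrame) -> np.ndarray:
    opt = niches["true_optimum"].to_numpy()
    tol = niches["true_tolerance"].to_numpy()
    cap = niches["max_capacity"].to_numpy()
    if (tol <= 0).any():
        raise ValueError("true_tolerance must be positive for every taxon")
    if (cap <= 0).any():
        raise ValueError("max_capacity must be positive for every taxon")
    z = (log_tp[:, None] - opt[None, :]) / tol[None, :]
    return cap[None, :] * np.exp(-0.5 * z * z)


def generate_community(
    chem: pd.DataFrame, niches: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Sample a site × taxon relative-abundance matrix.

    Expected abundance of taxon k at site i is proportional to
    ``capacity_k * exp(-(log10 TP_i - optimum_k)^2 / (2 tolerance_k^2))``;
    counts are multinomial with ``valve_count`` trials per site, then divided
    by the valve count, so rows sum to 1 exactly.
    """
    if niches.empty:
        raise ValueError("niche table is empty")
    log_tp = np.log10(chem["tp_ugl"].to_numpy(dtype=float))
    lam = _expected_intensity(log_tp, niches)
    row_sums = lam.sum(axis=1)
    if (row_sums <= 0).any() or not np.isfinite(row_sums).all():
        bad = chem.index[(row_sums <= 0) | ~np.isfinite(row_sums)].tolist()
        raise ValueError(
            f"all-zero expected community at sites {bad}: niches too narrow for the gradient"
        )
    probs = lam / row_sums[:, None]
    rng = _rng(config, 3)
    counts = np.empty_like(probs)
    for i in range(probs.shape[0]):
        counts[i] = rng.multinomial(config.valve_count, probs[i])
    rel = counts / config.valve_count
    return pd.DataFrame(rel, index=chem.index, columns=niches.index)


def generate_bimodal_regime(
    chem: pd.DataFrame, niches: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Sample a community with intermediate-pool capacities suppressed.

    With ``suppression`` well below 1 the distribution of site-specific
    community TP optima becomes bimodal; at 1.0 this reduces exactly to
    :func:`generate_community`.
    """
    if "pool_label" not in niches.columns:
        raise ValueError("niches must carry a 'pool_label' column for the bimodal regime")
    scaled = niches.copy()
    mask = scaled["pool_label"] == "intermediate"
    scaled.loc[mask, "max_capacity"] = scaled.loc[mask, "max_capacity"] * config.suppression
    return generate_community(chem, scaled, config)


def true_profiles(
    niches: pd.DataFrame,
    sensitivity_breakpoints=(1.1, 1.2, 1.5, 1.7),
) -> pd.DataFrame:
    """Convert true niche parameters into an index-ready profile table.

    Classes are assigned from the true optima/tolerances with the same rules
    the calibration uses, giving tests a ground-truth coefficient table.
    """
    from .calibration import assign_indicator_classes, assign_sensitivity_class

    out = pd.DataFrame(
        {
            "optimum": niches["true_optimum"],
            "tolerance": niches["true_tolerance"],
        },
        index=niches.index,
    )
    out["sensitivity_class"] = [
        assign_sensitivity_class(o, sensitivity_breakpoints) for o in out["optimum"]
    ]
    out["indicator_class"] = assign_indicator_classes(out["tolerance"].to_numpy())
    return out
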