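"""Cross-validated weighted-averaging calibration of taxon TP profiles.

The ecological optimum of a taxon is estimated as the abundance-weighted mean
of log10 TP over the samples where it occurs, and its tolerance as the
abundance-weighted standard deviation (population form, denominator Σw — the
direct analogue of the weighted mean).  Calibration repeats this over many
random 75/25 train/test splits, keeping per split only taxa that occur in at
least ``min_occurrences`` training samples, and averages each taxon's
estimates over the splits in which it passed the filter.

Optima are then binned into five sensitivity classes along fixed log10 TP
breakpoints (1.1, 1.2, 1.5, 1.7, bounded by 0 and 3) and tolerances into
three equal-width indicator classes spanning the observed tolerance range.
Class intervals are lower-inclusive, upper-exclusive, with the top class
closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationConfig",
    "make_splits",
    "occurrence_filter",
    "weighted_profile",
    "cross_validated_profiles",
    "assign_sensitivity_class",
    "assign_indicator_classes",
    "calibrate",
]

DEFAULT_BREAKPOINTS = (1.1, 1.2, 1.5, 1.7)


@dataclass
class CalibrationConfig:
    n_repeats: int = 100
    train_fraction: float = 0.75
    min_occurrences: int = 10
    sensitivity_breakpoints: tuple = DEFAULT_BREAKPOINTS
    n_indicator_classes: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        bp = tuple(self.sensitivity_breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or bp[0] <= 0 or bp[-1] >= 3:
            raise ValueError("breakpoints must be strictly increasing within (0, 3)")
        if self.n_repeats < 1 or self.min_occurrences < 1:
            raise ValueError("n_repeats and min_occurrences must be >= 1")


def make_splits(site_ids, config: CalibrationConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random unstratified train/test partitions, one per repeat.

    Repeat r uses seed ``base_seed + r``, so a plan is reproducible from the
    base seed alone.  |train| = round(train_fraction * n).
    """
    site_ids = np.asarray(site_ids)
    n = site_ids.size
    if n < 2:
        raise ValueError("need at least 2 sites to split")
    n_train = int(round(config.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    plan = []
    for r in range(config.n_repeats):
        perm = np.random.default_rng(config.base_seed + r).permutation(n)
        plan.append((site_ids[perm[:n_train]], site_ids[perm[n_train:]]))
    return plan


def occurrence_filter(matrix: pd.DataFrame, train_sites, min_occurrences: int) -> list[str]:
    """Taxa present (abundance > 0) in at least `min_occurrences` training sites."""
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    presence = (matrix.loc[train_sites] > 0).sum(axis=0)
    return presence.index[presence >= min_occurrences].tolist()


def weighted_profile(abundances, tp_ugl) -> tuple[float, float]:
    """Abundance-weighted mean and SD of log10 TP for one taxon.

    optimum = Σ w·log10(TP) / Σ w;  tolerance = sqrt(Σ w·(log10 TP − optimum)² / Σ w).
    Invariant to rescaling all weights by a positive constant.
    """
    w = np.asarray(abundances, dtype=float)
    tp = np.asarray(tp_ugl, dtype=float)
    if (tp <= 0).any():
        raise ValueError("TP must be positive everywhere")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("no occurrences: all weights are zero")
    log_tp = np.log10(tp)
    optimum = float((w * log_tp).sum() / total)
    tolerance = float(np.sqrt((w * (log_tp - optimum) ** 2).sum() / total))
    return optimum, tolerance


def _profiles_for_split(matrix: pd.DataFrame, log_tp: pd.Series, taxa: list[str]):
    """Vectorized weighted mean/SD per taxon over one training set."""
    w = matrix[taxa].to_numpy(dtype=float)
    lt = log_tp.to_numpy(dtype=float)
    totals = w.sum(axis=0)
    opt = (w * lt[:, None]).sum(axis=0) / totals
    second = (w * (lt**2)[:, None]).sum(axis=0) / totals
    tol = np.sqrt(np.maximum(second - opt**2, 0.0))
    return opt, tol


def cross_validated_profiles(
    matrix: pd.DataFrame, chem: pd.DataFrame, config: CalibrationConfig
) -> pd.DataFrame:
    """Mean optimum/tolerance per taxon over the repeats that retained it.

    Returns a frame indexed by taxon code with columns ``optimum``,
    ``tolerance``, ``n_occurrences`` (presence count in the full matrix) and
    ``n_repeats_included``.  Taxa retained in no repeat are omitted.
    """
    sites = matrix.index.intersection(chem.index)
    if len(sites) < len(matrix.index) or len(sites) < len(chem.index):
        missing = set(matrix.index).symmetric_difference(chem.index)
        raise ValueError(f"site ids differ between abundance and chemistry: {sorted(missing)[:10]}")
    chem = chem.loc[matrix.index]
    if chem["tp_ugl"].isna().any():
        bad = chem.index[chem["tp_ugl"].isna()].tolist()
        raise ValueError(f"sites with missing TP cannot be used in calibration: {bad[:10]}")
    log_tp = np.log10(chem["tp_ugl"])

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for train, _test in make_splits(matrix.index.to_numpy(), config):
        taxa = occurrence_filter(matrix, train, config.min_occurrences)
        if not taxa:
            continue
        opt, tol = _profiles_for_split(matrix.loc[train], log_tp.loc[train], taxa)
        for code, o, t in zip(taxa, opt, tol):
            if code in sums:
                sums[code] += (o, t)
                counts[code] += 1
            else:
                sums[code] = np.array([o, t])
                counts[code] = 1
    if not sums:
        warnings.warn("no taxon passed the occurrence filter in any repeat")
        return pd.DataFrame(
            columns=["optimum", "tolerance", "n_occurrences", "n_repeats_included"]
        )
    codes = [c for c in matrix.columns if c in sums]
    presence = (matrix > 0).sum(axis=0)
    out = pd.DataFrame(
        {
            "optimum": [sums[c][0] / counts[c] for c in codes],
            "tolerance": [sums[c][1] / counts[c] for c in codes],
            "n_occurrences": [int(presence[c]) for c in codes],
            "n_repeats_included": [counts[c] for c in codes],
        },
        index=pd.Index(codes, name="code"),
    )
    return out


def assign_sensitivity_class(optimum: float, breakpoints=DEFAULT_BREAKPOINTS) -> int:
    """Sensitivity class s in 1..5 from fixed log10 TP breakpoints.

    Intervals are [lower, upper); the top class is closed at 3.  Optima
    outside (0, 3] are clamped to the nearest class with a warning.
    """
    bp = np.asarray(breakpoints, dtype=float)
    if optimum <= 0 or optimum > 3:
        warnings.warn(f"optimum {optimum:.3f} outside (0, 3]; clamping to nearest class")
        return 1 if optimum <= 0 else bp.size + 1
    return int(np.searchsorted(bp, optimum, side="right")) + 1


def assign_indicator_classes(tolerances, n_classes: int = 3) -> np.ndarray:
    """Indicator class v per taxon: equal-width bins over the tolerance range.

    Class 1 holds the narrowest tolerances (strongest indicators).  Bins are
    lower-inclusive, upper-exclusive, top class closed.  A degenerate range
    (all tolerances equal) puts every taxon in class 1 with a warning.
    """
    tol = np.asarray(tolerances, dtype=float)
    if tol.size == 0:
        raise ValueError("need at least one tolerance")
    lo, hi = tol.min(), tol.max()
    if hi == lo:
        if tol.size > 1:
            warnings.warn("all tolerances equal; every taxon assigned indicator class 1")
        return np.ones(tol.size, dtype=int)
    width = (hi - lo) / n_classes
    classes = np.floor((tol - lo) / width).astype(int) + 1
    return np.clip(classes, 1, n_classes)


def calibrate(
    matrix: pd.DataFrame, chem: pd.DataFrame, config: CalibrationConfig | None = None
) -> pd.DataFrame:
    """Full calibration: cross-validated profiles plus class assignment.

    Indicator-class intervals are computed once, from the final mean
    tolerances.  The result is a complete taxon coefficient table ready for
    index scoring.
    """
    config = config or CalibrationConfig()
    profiles = cross_validated_profiles(matrix, chem, config)
    if profiles.empty:
        return profiles
    profiles["sensitivity_class"] = [
        assign_sensitivity_class(o, config.sensitivity_breakpoints)
        for o in profiles["optimum"]
    ]
    profiles["indicator_class"] = assign_indicator_classes(
        profiles["tolerance"].to_numpy(), config.n_indicator_classes
    )
    return profiles
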