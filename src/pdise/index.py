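"""PDI_SE scoring: the phosphorus diatom index and site community optima.

For a sample with relative abundances y_j, sensitivity classes s_j in 1..5
and indicator classes v_j in 1..3 over the scored taxa,

    PDI_SE = Σ_j a_j s_j v_j / Σ_j a_j v_j,    a_j = sqrt(y_j) by default.

Taxa without a profile are excluded from both sums (the ratio renormalizes
implicitly); the abundance fraction carried by scored taxa is reported as
coverage so low-coverage samples can be flagged.  The index is invariant to
rescaling a sample's abundances by any positive constant and always lies
within [min s, max s] of the scored taxa present.

The same engine scores any user-supplied (s, v) coefficient table, e.g. IPS
or TDI coefficients, which are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    assign_indicator_classes,
    assign_sensitivity_class,
    make_splits,
    occurrence_filter,
    _profiles_for_split,
)

__all__ = [
    "IndexConfig",
    "compute_index",
    "score_matrix",
    "site_specific_optimum",
    "site_optima",
    "cross_validated_index",
]

_TRANSFORMS = {"sqrt": np.sqrt, "identity": lambda a: a}


@dataclass
class IndexConfig:
    abundance_transform: str = "sqrt"

    def __post_init__(self) -> None:
        if self.abundance_transform not in _TRANSFORMS:
            raise ValueError(f"transform must be one of {sorted(_TRANSFORMS)}")


def _score_rows(values: np.ndarray, s: np.ndarray, v: np.ndarray, transform: str):
    a = _TRANSFORMS[transform](values)
    num = (a * s * v).sum(axis=1)
    den = (a * v).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def compute_index(
    sample_abundances: pd.Series, profiles: pd.DataFrame, transform: str = "sqrt"
) -> dict:
    """Score one sample; returns value, coverage and scored-taxon count.

    Raises ValueError when no profiled taxon is present with positive
    abundance (the index is undefined there).
    """
    scored = sample_abundances.index.intersection(profiles.index)
    y = sample_abundances[scored].to_numpy(dtype=float)
    if y.sum() <= 0:
        raise ValueError(
            f"no scored taxa present in sample {sample_abundances.name!r}: index undefined"
        )
    s = profiles.loc[scored, "sensitivity_class"].to_numpy(dtype=float)
    v = profiles.loc[scored, "indicator_class"].to_numpy(dtype=float)
    value = float(_score_rows(y[None, :], s, v, transform)[0])
    total = float(sample_abundances.sum())
    return {
        "value": value,
        "coverage": float(y.sum()) / total if total > 0 else np.nan,
        "n_scored_taxa": int((y > 0).sum()),
    }


def score_matrix(
    matrix: pd.DataFrame, profiles: pd.DataFrame, transform: str = "sqrt"
) -> pd.DataFrame:
    """Score every site of an abundance matrix against one profile table.

    Sites with no scored taxon get NaN (flagged, not dropped).
    """
    scored = matrix.columns.intersection(profiles.index)
    y = matrix[scored].to_numpy(dtype=float)
    s = profiles.loc[scored, "sensitivity_class"].to_numpy(dtype=float)
    v = profiles.loc[scored, "indicator_class"].to_numpy(dtype=float)
    values = _score_rows(y, s, v, transform)
    return pd.DataFrame(
        {
            "pdi": values,
            "coverage": y.sum(axis=1) / matrix.sum(axis=1).to_numpy(),
            "n_scored_taxa": (y > 0).sum(axis=1),
        },
        index=matrix.index,
    )


def site_specific_optimum(sample_abundances: pd.Series, profiles: pd.DataFrame) -> float:
    """Abundance-weighted mean of the taxon optima present at one site.

    Weights are the raw relative abundances (no square root): the community's
    TP niche centre in log10 µg/l.
    """
    scored = sample_abundances.index.intersection(profiles.index)
    y = sample_abundances[scored].to_numpy(dtype=float)
    if y.sum() <= 0:
        raise ValueError(
            f"no profiled taxa present in sample {sample_abundances.name!r}: optimum undefined"
        )
    opt = profiles.loc[scored, "optimum"].to_numpy(dtype=float)
    return float((y * opt).sum() / y.sum())


def site_optima(matrix: pd.DataFrame, profiles: pd.DataFrame) -> pd.Series:
    """Site-specific community TP optimum for every row of the matrix."""
    scored = matrix.columns.intersection(profiles.index)
    y = matrix[scored].to_numpy(dtype=float)
    opt = profiles.loc[scored, "optimum"].to_numpy(dtype=float)
    totals = y.sum(axis=1)
    with np.errstate(invalid="ignore"):
        values = np.where(totals > 0, (y * opt).sum(axis=1) / totals, np.nan)
    return pd.Series(values, index=matrix.index, name="site_optimum_log10")


def cross_validated_index(
    matrix: pd.DataFrame,
    chem: pd.DataFrame,
    index_config: IndexConfig | None = None,
    calibration_config: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated PDI_SE: per repeat, profiles fit on the training sites
    score that repeat's test sites; each site's final value is the mean over
    the repeats in which it was tested.

    Returns per site: ``pdi_mean``, ``pdi_sd`` (across repeats), and
    ``n_times_tested``.  A site never drawn into a test set (possible at very
    small repeat counts) is flagged with NaN.
    """
    index_config = index_config or IndexConfig()
    cal = calibration_config or CalibrationConfig()
    chem = chem.loc[matrix.index]
    log_tp = np.log10(chem["tp_ugl"])

    acc_sum = pd.Series(0.0, index=matrix.index)
    acc_sq = pd.Series(0.0, index=matrix.index)
    acc_n = pd.Series(0, index=matrix.index)
    for train, test in make_splits(matrix.index.to_numpy(), cal):
        taxa = occurrence_filter(matrix, train, cal.min_occurrences)
        if not taxa:
            continue
        opt, tol = _profiles_for_split(matrix.loc[train], log_tp.loc[train], taxa)
        profiles = pd.DataFrame(
            {
                "optimum": opt,
                "tolerance": tol,
                "sensitivity_class": [
                    assign_sensitivity_class(o, cal.sensitivity_breakpoints) for o in opt
                ],
                "indicator_class": assign_indicator_classes(tol, cal.n_indicator_classes),
            },
            index=pd.Index(taxa, name="code"),
        )
        scores = score_matrix(matrix.loc[test], profiles, index_config.abundance_transform)
        ok = scores["pdi"].dropna()
        acc_sum.loc[ok.index] += ok
        acc_sq.loc[ok.index] += ok**2
        acc_n.loc[ok.index] += 1

    with np.errstate(invalid="ignore"):
        mean = acc_sum / acc_n.replace(0, np.nan)
        var = acc_sq / acc_n.replace(0, np.nan) - mean**2
    sd = np.sqrt(var.clip(lower=0.0))
    sd[acc_n < 2] = np.nan
    return pd.DataFrame(
        {"pdi_mean": mean, "pdi_sd": sd, "n_times_tested": acc_n}, index=matrix.index
    )
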