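"""Bimodality analysis of site-specific TP optima and community contrasts.

Workflow: test the distribution of site-specific community optima for
unimodality with Hartigan's dip (Monte-Carlo calibrated against the uniform
null); when it is bimodal, locate the two modes of a Gaussian kernel density
estimate (Silverman bandwidth) and derive two group thresholds by quartile
reflection — the 25th percentile of the observations below the first mode is
reflected about that mode, and the 75th percentile of the observations above
the second mode about the second mode.  Sites are then assigned to low /
"lukewarm" / high TP-optimum groups, and SIMPER decomposes the between-group
Bray–Curtis dissimilarity into per-taxon contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

from ._dip import dip_statistic

__all__ = [
    "DipResult",
    "ThresholdResult",
    "dip_statistic",
    "null_dip_distribution",
    "dip_test",
    "derive_thresholds",
    "assign_groups",
    "bray_curtis",
    "simper",
]


@dataclass
class DipResult:
    statistic: float
    p_value: float
    n: int
    n_null_reps: int


@dataclass
class ThresholdResult:
    """Two KDE modes and the reflected-quartile group thresholds (log10 µg/l)."""

    mode_low: float
    mode_high: float
    q_low: float
    q_high: float
    t_low: float
    t_high: float
    bandwidth: float

    @property
    def t_low_ugl(self) -> float:
        return float(10.0**self.t_low)

    @property
    def t_high_ugl(self) -> float:
        return float(10.0**self.t_high)


def null_dip_distribution(n: int, n_reps: int, seed: int) -> np.ndarray:
    """Sorted dip statistics of `n_reps` uniform(0,1) samples of size n.

    The dip is invariant under monotone transforms of the data scale, so the
    uniform null calibrates the test for any continuous unimodal null.
    """
    rng = np.random.default_rng(seed)
    return np.sort([dip_statistic(rng.uniform(0.0, 1.0, n)) for _ in range(n_reps)])


def dip_test(values, n_null_reps: int = 1000, seed: int = 0, null: np.ndarray | None = None) -> DipResult:
    """Hartigan's dip test with a Monte-Carlo p-value.

    p = fraction of uniform null samples (same n) whose dip is >= the
    observed statistic.  A precomputed ``null`` (from
    :func:`null_dip_distribution`) may be supplied to amortize the null
    simulation over many tests at the same n.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    d = dip_statistic(values)
    if null is None:
        if n_null_reps < 500:
            raise ValueError("n_null_reps must be >= 500 for a stable p-value")
        null = null_dip_distribution(n, n_null_reps, seed)
    p = float(np.mean(null >= d))
    return DipResult(statistic=d, p_value=p, n=n, n_null_reps=int(len(null)))


def _kde_modes(values: np.ndarray, grid_size: int = 512):
    """Local maxima of a Silverman-bandwidth Gaussian KDE on a padded grid."""
    kde = gaussian_kde(values, bw_method="silverman")
    bw = float(kde.factor * values.std(ddof=1))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    return grid, dens, peaks, bw


def derive_thresholds(site_optima, grid_size: int = 512) -> ThresholdResult:
    """Group thresholds from a bimodal distribution of site optima.

    The two highest-density KDE modes separated by at least one bandwidth —
    each reaching at least 5% of the maximal density, to ignore tail
    wiggles — become m1 < m2.  q_low is the 25th percentile of observations in
    [min, m1] and t_low = m1 + (m1 − q_low); q_high is the 75th percentile of
    observations in [m2, max] and t_high = m2 − (q_high − m2).  Raises
    ValueError when fewer than two such modes exist (unimodal distribution —
    thresholds undefined).
    """
    x = np.sort(np.asarray(site_optima, dtype=float))
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("need at least 4 site optima to derive thresholds")
    grid, dens, peaks, bw = _kde_modes(x, grid_size)
    # discard spurious wiggles: a mode must reach 5% of the highest density
    peaks = peaks[dens[peaks] >= 0.05 * dens[peaks].max()]
    if peaks.size < 2:
        raise ValueError("unimodal — thresholds undefined")
    # keep the two highest-density peaks at least one bandwidth apart
    order = peaks[np.argsort(dens[peaks])[::-1]]
    m1 = grid[order[0]]
    m2 = None
    for idx in order[1:]:
        if abs(grid[idx] - m1) >= bw:
            m2 = grid[idx]
            break
    if m2 is None:
        raise ValueError("unimodal — thresholds undefined")
    if m2 < m1:
        m1, m2 = m2, m1
    low_tail = x[x <= m1]
    high_tail = x[x >= m2]
    q_low = float(np.quantile(low_tail, 0.25))
    q_high = float(np.quantile(high_tail, 0.75))
    t_low = float(m1 + (m1 - q_low))
    t_high = float(m2 - (q_high - m2))
    return ThresholdResult(
        mode_low=float(m1),
        mode_high=float(m2),
        q_low=q_low,
        q_high=q_high,
        t_low=t_low,
        t_high=t_high,
        bandwidth=bw,
    )


def assign_groups(site_optima_ugl, t_low_ugl: float, t_high_ugl: float) -> pd.Series:
    """Label each site low / lukewarm / high by its community optimum in µg/l.

    Strict inequalities: below t_low is 'low', above t_high is 'high',
    everything else — including values exactly at a threshold — 'lukewarm'.
    """
    if t_low_ugl > t_high_ugl:
        raise ValueError("thresholds must be ordered: t_low <= t_high")
    values = pd.Series(site_optima_ugl, dtype=float)
    labels = pd.Series("lukewarm", index=values.index, name="group")
    labels[values < t_low_ugl] = "low"
    labels[values > t_high_ugl] = "high"
    return labels


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Site × site Bray–Curtis dissimilarity: d(i,j) = Σ|y_i − y_j| / Σ(y_i + y_j)."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_rows = values.sum(axis=1) == 0
    if zero_rows.sum() >= 2:
        bad = matrix.index[zero_rows].tolist()
        raise ValueError(f"Bray–Curtis undefined between all-zero sites {bad}")
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _simper_pair(a: np.ndarray, b: np.ndarray, taxa) -> pd.DataFrame:
    """Per-taxon decomposition of mean Bray–Curtis over all between-group pairs."""
    # contributions[k] = mean over pairs (i in a, j in b) of |a_ik − b_jk| / Σ_m(a_im + b_jm)
    n_a, n_b = a.shape[0], b.shape[0]
    contrib = np.zeros(a.shape[1])
    for i in range(n_a):
        diff = np.abs(a[i][None, :] - b)            # n_b × taxa
        denom = (a[i].sum() + b.sum(axis=1))[:, None]
        contrib += (diff / denom).sum(axis=0)
    contrib /= n_a * n_b
    mean_bc = contrib.sum()
    if mean_bc <= 0:
        raise ValueError("groups are compositionally identical: contributions undefined")
    out = pd.DataFrame(
        {
            "mean_dissimilarity": contrib,
            "contribution_pct": 100.0 * contrib / mean_bc,
        },
        index=pd.Index(taxa, name="code"),
    )
    out = out.sort_values("contribution_pct", ascending=False, kind="stable")
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return out


def simper(matrix: pd.DataFrame, labels: pd.Series) -> dict:
    """Similarity-percentage analysis over every group pair plus the pooled contrast.

    Returns a dict keyed by (group_a, group_b) tuples — plus ``"overall"``,
    which pools every between-group site pair — of frames with per-taxon
    contribution %, cumulative %, and mean relative abundance per group.
    Contributions within each contrast sum to 100% of the mean between-group
    Bray–Curtis dissimilarity.
    """
    labels = labels.loc[matrix.index]
    groups = [g for g in pd.unique(labels) if (labels == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups for SIMPER")
    blocks = {g: matrix.loc[labels == g].to_numpy(dtype=float) for g in groups}
    means = {g: matrix.loc[labels == g].mean(axis=0) for g in groups}

    results: dict = {}
    pooled = np.zeros(matrix.shape[1])
    n_pairs = 0
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            table = _simper_pair(blocks[ga], blocks[gb], matrix.columns)
            for g in (ga, gb):
                table[f"mean_abundance_{g}"] = means[g].reindex(table.index)
            results[(ga, gb)] = table
            pairs = blocks[ga].shape[0] * blocks[gb].shape[0]
            pooled += table["mean_dissimilarity"].reindex(matrix.columns).to_numpy() * pairs
            n_pairs += pairs
    pooled /= n_pairs
    overall = pd.DataFrame(
        {
            "mean_dissimilarity": pooled,
            "contribution_pct": 100.0 * pooled / pooled.sum(),
        },
        index=matrix.columns.rename("code"),
    ).sort_values("contribution_pct", ascending=False, kind="stable")
    overall["cumulative_pct"] = overall["contribution_pct"].cumsum()
    for g in groups:
        overall[f"mean_abundance_{g}"] = means[g].reindex(overall.index)
    results["overall"] = overall
    return results
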