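"""Reading, writing and validating the tabular formats the toolkit touches.

Three table kinds circulate through the pipeline:

* **abundance matrix** — sites in rows, taxa (OMNIDIA-style short codes) in
  columns, relative abundances; rows are renormalized to sum to 1 on read.
  Percent-scaled exports (row sums near 100) are detected and rescaled.
* **chemistry table** — per-site water chemistry with total phosphorus (TP)
  as an annual mean in µg/l; optional covariates (pH, nitrate, ...).
* **taxon profile table** — per-taxon calibrated TP optimum and tolerance
  (log10 µg/l), sensitivity class s in 1..5 and indicator class v in 1..3,
  mirroring the published coefficient-table layout.

Delimiters are sniffed among comma, semicolon and tab; a decimal comma is
accepted when the delimiter is a semicolon (common in Swedish monitoring
exports).  Missing abundance cells are treated as zeros (taxon not counted),
not as missing data.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_chemistry_table",
    "write_chemistry_table",
    "read_profile_table",
    "write_profile_table",
    "merge_synonyms",
    "validate_abundance",
    "validate_profiles",
]

PROFILE_COLUMNS = ["code", "optimum", "tolerance", "sensitivity_class", "indicator_class"]


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                counts = {sep: line.count(sep) for sep in (",", ";", "\t")}
                return max(counts, key=counts.get) if max(counts.values()) else ","
    raise ValueError(f"{path}: no data lines found")


def _read_delimited(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    decimal = "," if sep == ";" else "."
    return pd.read_csv(path, sep=sep, decimal=decimal, comment="#", index_col=0)


def _write_with_header(df: pd.DataFrame, path, header_comment: str | None, **kwargs) -> None:
    buf = _io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, **kwargs)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def validate_abundance(matrix: pd.DataFrame, tol: float = 1e-6) -> None:
    """Raise ValueError unless `matrix` is a valid relative-abundance table."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate site ids: {dups}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon codes: {dups}")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance at site {matrix.index[i]!r}, taxon {matrix.columns[j]!r}"
        )
    row_sums = values.sum(axis=1)
    off = np.abs(row_sums - 1.0) > tol
    if off.any():
        bad = matrix.index[off].tolist()[:5]
        raise ValueError(f"rows do not sum to 1 (first offenders: {bad})")


def read_abundance_table(path, orientation: str = "sites", scale: str = "auto") -> pd.DataFrame:
    """Read a site × taxon relative-abundance table.

    Parameters
    ----------
    path : str or Path
        Delimited text file; first column holds site ids (or taxon codes if
        ``orientation="taxa"``).
    orientation : {"sites", "taxa"}
        Whether rows are sites or taxa; the returned frame always has sites
        in rows.
    scale : {"auto", "percent", "proportion"}
        Input scale.  ``auto`` treats a median row sum >= 50 as percent.

    Returns
    -------
    pandas.DataFrame with rows renormalized to sum to 1.
    """
    df = _read_delimited(path)
    if orientation == "taxa":
        df = df.T
    elif orientation != "sites":
        raise ValueError(f"orientation must be 'sites' or 'taxa', got {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric abundance cell ({exc})") from exc
    values = np.nan_to_num(values, nan=0.0)  # missing cell == taxon not counted
    df = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative abundance at site {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate site ids "
                         f"{df.index[df.index.duplicated()].unique().tolist()}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate taxon codes "
                         f"{df.columns[df.columns.duplicated()].unique().tolist()}")
    row_sums = values.sum(axis=1)
    if (row_sums <= 0).any():
        bad = df.index[row_sums <= 0].tolist()
        raise ValueError(f"{path}: all-zero abundance rows for sites {bad}")
    if scale == "auto":
        scale = "percent" if np.median(row_sums) >= 50 else "proportion"
    if scale not in ("percent", "proportion"):
        raise ValueError(f"scale must be 'auto', 'percent' or 'proportion', got {scale!r}")
    if scale == "percent":
        values = values / 100.0
        row_sums = row_sums / 100.0
    values = values / row_sums[:, None]
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    validate_abundance(out)
    return out


def write_abundance_table(matrix: pd.DataFrame, path, header_comment: str | None = None) -> None:
    validate_abundance(matrix)
    _write_with_header(matrix, path, header_comment, index_label="site_id")


_TP_ALIASES = ("tp_ugl", "tp", "total_phosphorus", "tp_ug_l")


def read_chemistry_table(path) -> pd.DataFrame:
    """Read a per-site chemistry table with a TP column (µg/l annual mean).

    Sites with a missing TP value are kept with NaN (flagged, not dropped);
    a TP value <= 0 or non-numeric is rejected naming the site.
    """
    df = _read_delimited(path)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate site ids {dups}")
    tp_col = next((c for c in df.columns if c.strip().lower() in _TP_ALIASES), None)
    if tp_col is None:
        raise ValueError(f"{path}: no TP column found (expected one of {_TP_ALIASES})")
    tp = pd.to_numeric(df[tp_col], errors="coerce")
    bad_numeric = tp.isna() & df[tp_col].notna()
    if bad_numeric.any():
        site = df.index[bad_numeric][0]
        raise ValueError(f"{path}: non-numeric TP for site {site!r}")
    nonpositive = tp.notna() & (tp <= 0)
    if nonpositive.any():
        site = df.index[nonpositive][0]
        raise ValueError(f"{path}: TP must be positive, got {tp[site]} for site {site!r}")
    out = df.rename(columns={tp_col: "tp_ugl"}).copy()
    out["tp_ugl"] = tp
    for col in out.columns:
        if col != "tp_ugl":
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def write_chemistry_table(chem: pd.DataFrame, path, header_comment: str | None = None) -> None:
    if "tp_ugl" not in chem.columns:
        raise ValueError("chemistry table must have a 'tp_ugl' column")
    _write_with_header(chem, path, header_comment, index_label="site_id")


def validate_profiles(profiles: pd.DataFrame) -> None:
    """Raise ValueError unless `profiles` is a valid taxon coefficient table."""
    if profiles.index.has_duplicates:
        dups = profiles.index[profiles.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon codes: {dups}")
    missing = [c for c in PROFILE_COLUMNS[1:] if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    s = profiles["sensitivity_class"]
    if ((s < 1) | (s > 5) | (s != s.round())).any():
        bad = profiles.index[(s < 1) | (s > 5) | (s != s.round())].tolist()
        raise ValueError(f"sensitivity class outside 1..5 for taxa {bad}")
    v = profiles["indicator_class"]
    if ((v < 1) | (v > 3) | (v != v.round())).any():
        bad = profiles.index[(v < 1) | (v > 3) | (v != v.round())].tolist()
        raise ValueError(f"indicator class outside 1..3 for taxa {bad}")
    if (profiles["tolerance"] < 0).any():
        bad = profiles.index[profiles["tolerance"] < 0].tolist()
        raise ValueError(f"negative tolerance for taxa {bad}")


def read_profile_table(path) -> pd.DataFrame:
    """Read a taxon profile table (code, optimum, tolerance, s, v[, n_occurrences])."""
    df = _read_delimited(path)
    df.index = df.index.astype(str)
    df.index.name = "code"
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_")
        if key in ("sensitivity_class", "s", "sensitivity"):
            rename[col] = "sensitivity_class"
        elif key in ("indicator_class", "v", "indicator"):
            rename[col] = "indicator_class"
        elif key in ("optimum", "tolerance", "n_occurrences"):
            rename[col] = key
    df = df.rename(columns=rename)
    for col in ("sensitivity_class", "indicator_class"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    validate_profiles(df)
    return df


def write_profile_table(profiles: pd.DataFrame, path, header_comment: str | None = None) -> None:
    validate_profiles(profiles)
    cols = [c for c in PROFILE_COLUMNS[1:] if c in profiles.columns]
    extras = [c for c in profiles.columns if c not in cols]
    _write_with_header(profiles[cols + extras], path, header_comment, index_label="code")


def _resolve_synonyms(mapping: Mapping[str, str]) -> dict[str, str]:
    """Resolve alias chains to their terminal accepted code; reject cycles."""
    resolved: dict[str, str] = {}
    for alias in mapping:
        seen = [alias]
        target = mapping[alias]
        while target in mapping:
            if target in seen:
                raise ValueError(f"cyclic synonym map: {' -> '.join(seen + [target])}")
            seen.append(target)
            target = mapping[target]
        for code in seen:
            resolved[code] = target
    return resolved


def merge_synonyms(matrix: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Merge synonymous taxon columns by summing their abundances per site.

    Alias chains are resolved to the terminal accepted code; cyclic maps are
    rejected.  Row sums are conserved exactly.  Target codes absent from the
    matrix are created by the merge.
    """
    if not mapping:
        return matrix.copy()
    resolved = _resolve_synonyms(mapping)
    new_names = [resolved.get(c, c) for c in matrix.columns]
    merged = matrix.T.groupby(pd.Index(new_names, name=matrix.columns.name)).sum().T
    # preserve first-appearance column order
    order = list(dict.fromkeys(new_names))
    return merged[order]
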