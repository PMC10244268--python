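"""One-command pipeline: calibration → scoring → structure analysis → assessment.

Outputs are written atomically (temp file, then rename) into the output
directory, each with a comment header carrying the toolkit version and the
seed, plus a manifest JSON listing every artifact with a SHA-256 checksum.
Identical config + seed therefore yield byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .calibration import CalibrationConfig, calibrate
from .index import IndexConfig, cross_validated_index, score_matrix, site_optima
from .structure import assign_groups, derive_thresholds, dip_test, simper
from .assessment import boundary_table, fit_linear

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("pdise")


@dataclass
class PipelineConfig:
    abundance_path: str
    chemistry_path: str
    out_dir: str
    profiles_path: str | None = None       # skip calibration if supplied
    external_index_path: str | None = None  # optional IPS/TDI values per site
    abundance_scale: str = "auto"            # auto | percent | proportion
    seed: int = 0
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    index: IndexConfig = field(default_factory=IndexConfig)
    cross_validate_index: bool = False
    dip_null_reps: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cal = CalibrationConfig(**raw.pop("calibration", {}))
        idx = IndexConfig(**raw.pop("index", {}))
        return cls(calibration=cal, index=idx, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"pdise v{__version__}\nseed={config.seed}"
    cal = dataclasses.replace(config.calibration, base_seed=config.seed)

    matrix = pio.read_abundance_table(config.abundance_path, scale=config.abundance_scale)
    chem = pio.read_chemistry_table(config.chemistry_path)
    missing = set(matrix.index).symmetric_difference(chem.index)
    if missing:
        raise ValueError(
            f"site ids differ between abundance and chemistry: {sorted(missing)[:20]}"
        )
    chem = chem.loc[matrix.index]
    logger.info("loaded %d sites × %d taxa", *matrix.shape)

    artifacts: dict[str, Path] = {}

    # --- calibration ------------------------------------------------------
    if config.profiles_path:
        profiles = pio.read_profile_table(config.profiles_path)
        logger.info("using %d supplied taxon profiles", len(profiles))
    else:
        profiles = calibrate(matrix, chem, cal)
        logger.info("calibrated %d taxon profiles", len(profiles))
    path = out_dir / "profiles.csv"
    _atomic_write(path, lambda p: pio.write_profile_table(profiles, p, header))
    artifacts["profiles"] = path

    # --- index scoring ----------------------------------------------------
    scores = score_matrix(matrix, profiles, config.index.abundance_transform)
    if config.cross_validate_index:
        cv = cross_validated_index(matrix, chem, config.index, cal)
        scores = scores.join(cv)
    path = out_dir / "index.csv"
    _atomic_write(path, lambda p: pio._write_with_header(scores, p, header, index_label="site_id"))
    artifacts["index"] = path

    # --- community structure ----------------------------------------------
    optima = site_optima(matrix, profiles).dropna()
    path = out_dir / "site_optima.csv"
    _atomic_write(
        path, lambda p: pio._write_with_header(optima.to_frame(), p, header, index_label="site_id")
    )
    artifacts["site_optima"] = path

    dip = dip_test(optima.to_numpy(), n_null_reps=config.dip_null_reps, seed=config.seed)
    structure_report: dict = {
        "dip": {
            "statistic": dip.statistic,
            "p_value": dip.p_value,
            "n": dip.n,
            "n_null_reps": dip.n_null_reps,
        }
    }
    try:
        thr = derive_thresholds(optima.to_numpy())
        structure_report["thresholds"] = {
            "mode_low_log10": thr.mode_low,
            "mode_high_log10": thr.mode_high,
            "t_low_log10": thr.t_low,
            "t_high_log10": thr.t_high,
            "t_low_ugl": thr.t_low_ugl,
            "t_high_ugl": thr.t_high_ugl,
        }
        if thr.t_low > thr.t_high:
            structure_report["groups"] = (
                "threshold reflection overlaps (modes not well separated): groups undefined"
            )
            logger.info("group assignment skipped: %s", structure_report["groups"])
        else:
            groups = assign_groups(10.0**optima, thr.t_low_ugl, thr.t_high_ugl)
            path = out_dir / "groups.csv"
            _atomic_write(
                path,
                lambda p: pio._write_with_header(groups.to_frame(), p, header,
                                                 index_label="site_id"),
            )
            artifacts["groups"] = path
            if groups.nunique() >= 2:
                overall = simper(matrix.loc[groups.index], groups)["overall"]
                path = out_dir / "simper.csv"
                _atomic_write(
                    path,
                    lambda p: pio._write_with_header(overall, p, header, index_label="code"),
                )
                artifacts["simper"] = path
    except ValueError as exc:
        structure_report["thresholds"] = str(exc)  # unimodal: graceful degradation
        logger.info("threshold derivation skipped: %s", exc)
    path = out_dir / "structure.json"
    _atomic_write(
        path,
        lambda p: Path(p).write_text(
            json.dumps({"pdise_version": __version__, "seed": config.seed, **structure_report},
                       indent=2, sort_keys=True),
            encoding="utf-8",
        ),
    )
    artifacts["structure"] = path

    # --- assessment ---------------------------------------------------------
    ok = scores["pdi"].notna() & chem["tp_ugl"].notna()
    fit = fit_linear(np.log10(chem.loc[ok, "tp_ugl"]), scores.loc[ok, "pdi"])
    fit_report = {
        "pdise_version": __version__,
        "seed": config.seed,
        "pdi_vs_log10_tp": dataclasses.asdict(fit),
    }
    if config.external_index_path:
        ext = pio._read_delimited(config.external_index_path)
        ext.index = ext.index.astype(str)
        for col in ext.columns:
            shared = scores.index.intersection(ext.index)
            sub = pd.to_numeric(ext.loc[shared, col], errors="coerce")
            good = sub.notna() & scores.loc[shared, "pdi"].notna()
            if good.sum() >= 3:
                f = fit_linear(sub[good], scores.loc[shared, "pdi"][good])
                fit_report[f"pdi_vs_{col}"] = dataclasses.asdict(f)
    path = out_dir / "fits.json"
    _atomic_write(
        path,
        lambda p: Path(p).write_text(json.dumps(fit_report, indent=2, sort_keys=True),
                                     encoding="utf-8"),
    )
    artifacts["fits"] = path

    boundaries = boundary_table()
    path = out_dir / "boundaries.csv"
    _atomic_write(
        path, lambda p: pio._write_with_header(boundaries, p, header, index_label="boundary")
    )
    artifacts["boundaries"] = path

    # --- manifest -----------------------------------------------------------
    manifest = {
        "pdise_version": __version__,
        "seed": config.seed,
        "artifacts": {
            name: {"path": p.name, "sha256": _checksum(p)} for name, p in sorted(artifacts.items())
        },
    }
    path = out_dir / "manifest.json"
    _atomic_write(
        path,
        lambda p: Path(p).write_text(json.dumps(manifest, indent=2, sort_keys=True),
                                     encoding="utf-8"),
    )
    return manifest
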