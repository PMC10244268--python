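"""Index regressions and the ecological-status boundary conversion chain.

The Swedish assessment standard expresses class boundaries on the IPS scale.
With two published linear relations —

    PDI_SE = −0.29 · IPS + 8.0536          (index against index)
    PDI_SE = 1.84322 · log10 TP + 0.6493   (index against phosphorus)

— each IPS boundary converts to a PDI_SE value and from there to a TP
concentration (µg/l), producing the boundary table: EQR (IPS boundary over
the reference IPS), IPS, PDI_SE and TP per class boundary.  The PDI_SE–TP
relation is only trusted inside its linear response range, about 4–100 µg/l;
boundaries mapping outside it carry a "no response" marker instead of a TP
value.

`fit_linear` provides the ordinary-least-squares fits (through
scipy.stats.linregress) used to re-derive such relations from scored data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "SWEDISH_PDI_IPS_FIT",
    "SWEDISH_PDI_TP_FIT",
    "SWEDISH_IPS_BOUNDARIES",
    "fit_linear",
    "pdi_from_ips",
    "tp_from_pdi",
    "boundary_table",
    "NO_RESPONSE",
]

NO_RESPONSE = "no response"


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float | None = None
    n: int | None = None

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


#: Published calibration of PDI_SE against IPS and against log10 TP for the
#: Swedish monitoring data; defaults that make the boundary chain runnable
#: without any data.
SWEDISH_PDI_IPS_FIT = RegressionFit(slope=-0.29, intercept=8.0536)
SWEDISH_PDI_TP_FIT = RegressionFit(slope=1.84322, intercept=0.6493)

#: Current Swedish standard IPS class boundaries, reference value first.
SWEDISH_IPS_BOUNDARIES = (19.6, 17.5, 14.5, 11.0, 8.0)

_BOUNDARY_NAMES = ("reference", "high/good", "good/moderate", "moderate/poor", "poor/bad")


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares y = slope·x + intercept; r² is squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def pdi_from_ips(ips, fit: RegressionFit = SWEDISH_PDI_IPS_FIT):
    """Map IPS value(s) to the PDI_SE scale through a linear fit."""
    return fit.predict(ips)


def tp_from_pdi(pdi, fit: RegressionFit = SWEDISH_PDI_TP_FIT):
    """Invert the PDI_SE–log10 TP relation: TP = 10^((PDI − intercept)/slope), µg/l."""
    if fit.slope == 0:
        raise ValueError("cannot invert a fit with zero slope")
    return np.power(10.0, (np.asarray(pdi, dtype=float) - fit.intercept) / fit.slope)


def boundary_table(
    ips_boundaries=SWEDISH_IPS_BOUNDARIES,
    reference_ips: float | None = None,
    pdi_ips_fit: RegressionFit = SWEDISH_PDI_IPS_FIT,
    pdi_tp_fit: RegressionFit = SWEDISH_PDI_TP_FIT,
    linear_range: tuple[float, float] = (4.0, 100.0),
) -> pd.DataFrame:
    """Ecological-status boundary table on the EQR / IPS / PDI_SE / TP scales.

    Per boundary: EQR = IPS / reference IPS (2 dp), PDI_SE via the IPS fit
    (2 dp), TP via the inverted TP fit (nearest integer) — replaced by the
    ``"no response"`` marker where the exact TP falls outside the linear
    response range.  Exact (unrounded) values are kept in ``*_exact``
    columns; display rounding never feeds back into the chain.
    """
    ips = np.asarray(ips_boundaries, dtype=float)
    if np.any(np.diff(ips) >= 0):
        raise ValueError("IPS boundaries must be strictly descending")
    reference = float(reference_ips if reference_ips is not None else ips[0])
    if reference <= 0:
        raise ValueError("reference IPS must be positive")
    names = (
        _BOUNDARY_NAMES if ips.size == len(_BOUNDARY_NAMES)
        else [f"boundary_{i}" for i in range(ips.size)]
    )
    eqr = ips / reference
    pdi = pdi_from_ips(ips, pdi_ips_fit)
    tp = tp_from_pdi(pdi, pdi_tp_fit)
    in_range = (tp >= linear_range[0]) & (tp <= linear_range[1])
    return pd.DataFrame(
        {
            "eqr": np.round(eqr, 2),
            "ips": ips,
            "pdi": np.round(pdi, 2),
            "tp_ugl": [int(round(t)) if ok else NO_RESPONSE for t, ok in zip(tp, in_range)],
            "pdi_exact": pdi,
            "tp_exact": tp,
            "eqr_exact": eqr,
        },
        index=pd.Index(names, name="boundary"),
    )
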