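"""Per-cell Hill fitting of concentration-response data.

Each cell contributes a full dose-response curve plus a response to a
saturating glycine concentration recorded in the same cell.  Fits are
strictly per cell (pooled fits are for display only and are never used
for parameter estimates); a partial agonist's maximum is expressed
relative to the same-cell glycine maximum (Irel), and experiments whose
saturating reference runs down by more than 30% are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "CRCCell",
    "CRCStudy",
    "HillFit",
    "HillFitError",
    "hill",
    "fit_hill",
    "relative_maximum",
    "fold_change",
    "check_rundown",
    "fit_study",
]


class HillFitError(RuntimeError):
    """Raised when a concentration-response curve cannot be fitted."""


@dataclass
class CRCCell:
    """One cell's dose-response data.

    ``reference_saturating_response`` is the same-cell response to
    saturating glycine used for Irel normalization (nA, may be absent).
    """

    cell_id: str
    agonist: str
    ph: str
    concentrations: np.ndarray  # M
    peak_responses: np.ndarray  # nA
    reference_saturating_response: float | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.peak_responses = np.asarray(self.peak_responses, dtype=float)
        if self.concentrations.shape != self.peak_responses.shape:
            raise ValueError("concentrations and responses must align")
        if self.concentrations.size < 4:
            raise ValueError("at least 4 concentration points are required")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(self.peak_responses < 0):
            raise ValueError("responses must be non-negative")


@dataclass
class CRCStudy:
    """A set of cells measured under one agonist/pH condition."""

    cells: list[CRCCell]
    truth: dict = field(default_factory=dict)


@dataclass
class HillFit:
    """Fitted Hill parameters for one cell.

    ``irel`` is the fitted maximum normalized to the same-cell saturating
    glycine response (None when no reference was recorded).
    """

    imax: float  # nA
    ec50: float  # M
    nh: float
    irel: float | None = None
    success: bool = True
    message: str = ""
    flags: list = field(default_factory=list)
    residual_ss: float = float("nan")

    def predict(self, c) -> np.ndarray:
        return hill(np.asarray(c, dtype=float), self.imax, self.ec50, self.nh)


def hill(c, imax: float, ec50: float, nh: float):
    """Hill equation r(c) = Imax * c**nH / (c**nH + EC50**nH)."""
    c = np.asarray(c, dtype=float)
    cn = c ** nh
    return imax * cn / (cn + ec50 ** nh)


def _hill_residual(params, c, r):
    imax = 10.0 ** params["log_imax"].value
    ec50 = 10.0 ** params["log_ec50"].value
    return hill(c, imax, ec50, params["nh"].value) - r


def fit_hill(cell: CRCCell) -> HillFit:
    """Least-squares Hill fit to one cell's dose-response curve.

    Imax and EC50 are log-parameterized (positivity by construction, and
    the optimizer is stable over multi-decade concentration ranges);
    starts are deterministic: Imax at the largest response, EC50 at the
    concentration nearest half-max, nH = 1.
    """
    c = cell.concentrations
    r = cell.peak_responses
    order = np.argsort(c)
    c, r = c[order], r[order]

    rmax = r.max()
    if rmax <= 0 or np.ptp(r) <= 1e-12 * max(rmax, 1.0):
        raise HillFitError("responses are flat; Hill fit cannot converge")
    slope = np.polyfit(np.log10(c), r, 1)[0]
    if slope < 0:
        raise HillFitError("responses decrease with concentration; "
                           "the Hill model is monotonically increasing")

    params = lmfit.Parameters()
    params.add("log_imax", value=np.log10(rmax), min=np.log10(rmax) - 3,
               max=np.log10(rmax) + 3)
    c_half = c[np.argmin(np.abs(r - rmax / 2))]
    params.add("log_ec50", value=np.log10(c_half), min=np.log10(c.min()) - 4,
               max=np.log10(c.max()) + 4)
    params.add("nh", value=1.0, min=0.05, max=10.0)

    out = lmfit.minimize(_hill_residual, params, args=(c, r), method="leastsq")
    if not out.success:
        raise HillFitError(f"Hill fit did not converge: {out.message}")

    imax = float(10.0 ** out.params["log_imax"].value)
    ec50 = float(10.0 ** out.params["log_ec50"].value)
    nh = float(out.params["nh"].value)
    flags = []
    if not (0.01 * c.min() <= ec50 <= 100.0 * c.max()):
        flags.append("ec50_outside_tested_range")
    fit = HillFit(imax=imax, ec50=ec50, nh=nh, success=True,
                  message=str(out.message), flags=flags,
                  residual_ss=float(np.sum(out.residual ** 2)))
    if cell.reference_saturating_response is not None:
        fit.irel = relative_maximum(fit, cell)
    return fit


def relative_maximum(fit: HillFit, cell: CRCCell, use_fitted: bool = True) -> float:
    """Irel: the cell's maximum normalized to its saturating glycine response.

    By default the fitted Imax is used in the numerator; ``use_fitted=False``
    uses the largest observed response instead.
    """
    ref = cell.reference_saturating_response
    if ref is None or ref <= 0:
        raise ValueError("cell has no positive saturating reference response")
    top = fit.imax if use_fitted else float(cell.peak_responses.max())
    return top / ref


def fold_change(value_a: float, value_b: float) -> float:
    """Ratio value_a / value_b (e.g. EC50 at pH 6.4 over pH 7.4).

    Display layers round to one decimal to report e.g. "3.6-fold".
    """
    if value_a <= 0 or value_b <= 0:
        raise ValueError("fold changes require positive values")
    return value_a / value_b


@dataclass
class RundownResult:
    passed: bool
    max_drop: float  # largest fractional fall below the first reference


def check_rundown(reference_series, threshold: float = 0.30) -> RundownResult:
    """Discard rule for whole-cell experiments: fail when any later
    saturating reference falls more than ``threshold`` below the first."""
    refs = np.asarray(list(reference_series), dtype=float)
    if refs.size < 2:
        raise ValueError("need at least two reference responses")
    drops = 1.0 - refs[1:] / refs[0]
    max_drop = float(max(drops.max(), 0.0))
    return RundownResult(passed=max_drop <= threshold, max_drop=max_drop)


def fit_study(study: CRCStudy) -> tuple[pd.DataFrame, dict]:
    """Fit every cell of a study; return per-cell table and mean +/- SD summary."""
    rows = []
    for cell in study.cells:
        fit = fit_hill(cell)
        rows.append({
            "cell_id": cell.cell_id,
            "agonist": cell.agonist,
            "ph": cell.ph,
            "imax_na": fit.imax,
            "ec50_m": fit.ec50,
            "nh": fit.nh,
            "irel": fit.irel,
            "flags": ";".join(fit.flags),
        })
    table = pd.DataFrame(rows)
    summary = {}
    for col in ("imax_na", "ec50_m", "nh", "irel"):
        vals = table[col].dropna()
        if len(vals):
            summary[col] = {"mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                            "n": int(len(vals))}
    return table, summary
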