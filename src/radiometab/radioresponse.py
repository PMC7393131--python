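"""Radiosensitivity quantification from clonogenic and viability assays.

The clonogenic survival assay plates a known number of cells, irradiates
at graded doses, and counts the colonies that grow out. Surviving
fractions are normalized by the unirradiated plating efficiency and
summarized two ways:

* a linear-quadratic (LQ) fit, SF(d) = exp(-(alpha*d + beta*d^2)), the
  standard parameterization of radiation cell-survival curves; and
* the mean inactivating dose Dmid, the area under the survival curve on
  a linear SF axis — larger Dmid means more radioresistant.

Enhancement ratios (ER = Dmid_control / Dmid_treatment; > 1 means the
treatment radiosensitizes, < 1 radioprotects) quantify modifiers such as
IMPDH inhibitors or nucleoside supplementation. For neurosphere lines
not amenable to clonogenic assays, the same ratio is formed from GI50
values of a long-term viability dose-response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .errors import (
    AssayError,
    FitError,
    NotReachedError,
    ValidationError,
)

__all__ = [
    "SurvivalCurve",
    "EnhancementResult",
    "surviving_fractions",
    "fit_lq",
    "dmid",
    "enhancement_ratio",
    "gi50",
    "er_from_gi50",
]

ER_NEUTRAL_TOL = 1e-6


@dataclass
class SurvivalCurve:
    """A fitted clonogenic survival curve.

    ``doses`` in Gy with SF(0) = 1 by construction; ``alpha`` (1/Gy) and
    ``beta`` (1/Gy^2) are the LQ coefficients, NaN until fitted.
    """

    doses: np.ndarray
    sf: np.ndarray
    se: np.ndarray | None = None
    alpha: float = np.nan
    beta: float = np.nan
    rss: float = np.nan

    def predicted_sf(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d * d))


@dataclass
class EnhancementResult:
    er: float
    dmid_control: float
    dmid_treatment: float
    basis: str = "dmid"

    @property
    def classification(self) -> str:
        if abs(self.er - 1.0) <= ER_NEUTRAL_TOL:
            return "neutral"
        return "radiosensitization" if self.er > 1.0 else "radioprotection"


def surviving_fractions(assay: pd.DataFrame) -> SurvivalCurve:
    """Plating-efficiency-normalized surviving fractions.

    ``assay`` has columns (dose_gy, cells_plated, colonies, replicate).
    PE = mean over dose-0 replicates of colonies/cells_plated;
    SF(d) = mean(colonies/cells_plated at d) / PE. Doses with zero
    colonies in every replicate are reported missing (the log-scale fit
    cannot use them).
    """
    required = {"dose_gy", "cells_plated", "colonies"}
    if not required.issubset(assay.columns):
        raise ValidationError(f"clonogenic table needs columns {sorted(required)}")
    if (assay["colonies"] > assay["cells_plated"]).any():
        raise ValidationError("colonies cannot exceed cells plated")
    if (assay[["colonies", "cells_plated", "dose_gy"]] < 0).any().any():
        raise ValidationError("doses and counts must be non-negative")
    zero = assay[assay["dose_gy"] == 0]
    if zero.empty:
        raise AssayError("dose-0 (unirradiated) records are required")
    pe = float((zero["colonies"] / zero["cells_plated"]).mean())
    if pe <= 0:
        raise AssayError("plating efficiency is zero: no colonies at dose 0")
    ratios = assay["colonies"] / assay["cells_plated"]
    grouped = ratios.groupby(assay["dose_gy"])
    mean_ratio = grouped.mean()
    n_rep = grouped.count()
    se_ratio = grouped.std(ddof=1) / np.sqrt(n_rep)
    sf = (mean_ratio / pe).to_numpy()
    doses = mean_ratio.index.to_numpy(dtype=float)
    sf[0] = 1.0  # dose 0 defines PE, so SF(0) = 1 by construction
    sf = np.where(sf == 0.0, np.nan, sf)
    return SurvivalCurve(doses=doses, sf=sf, se=(se_ratio / pe).to_numpy())


def fit_lq(doses, sf, weights=None) -> tuple[float, float]:
    """Constrained linear-quadratic fit on the log-survival scale.

    Minimizes the squared error of ln SF against -(alpha*d + beta*d^2)
    subject to alpha, beta >= 0 (non-negative least squares). Dose-0 /
    missing points are excluded; at least three distinct positive doses
    are required. Returns (alpha, beta).
    """
    d = np.asarray(doses, dtype=float)
    s = np.asarray(sf, dtype=float)
    keep = (d > 0) & np.isfinite(s)
    d, s = d[keep], s[keep]
    if np.unique(d).size < 3:
        raise FitError("need >= 3 distinct positive doses for the LQ fit")
    if np.any(s <= 0) or np.any(s > 1.0 + 1e-9):
        raise ValidationError("surviving fractions must lie in (0, 1]")
    y = -np.log(s)
    a = np.column_stack([d, d * d])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[keep])
        a, y = a * w[:, None], y * w
    coef, _ = optimize.nnls(a, y)
    return float(coef[0]), float(coef[1])


def fit_curve(assay: pd.DataFrame) -> SurvivalCurve:
    """surviving_fractions + fit_lq in one step."""
    curve = surviving_fractions(assay)
    curve.alpha, curve.beta = fit_lq(curve.doses, curve.sf)
    resid = np.log(curve.sf[curve.doses > 0]) + (
        curve.alpha * curve.doses[curve.doses > 0]
        + curve.beta * curve.doses[curve.doses > 0] ** 2
    )
    curve.rss = float(np.nansum(resid**2))
    return curve


def dmid(curve: SurvivalCurve, dose_max: float, method: str = "fitted") -> float:
    """Mean inactivating dose: area under the survival curve (linear SF axis).

    ``fitted`` integrates exp(-(alpha*d + beta*d^2)) over [0, dose_max]
    by adaptive quadrature (abs. tolerance 1e-8); ``trapezoid``
    integrates the measured SF points over the assayed dose range and
    requires dose_max not to exceed the largest assayed dose.
    """
    if dose_max <= 0:
        raise ValidationError("dose_max must be positive")
    if method == "fitted":
        if not (np.isfinite(curve.alpha) and np.isfinite(curve.beta)):
            raise FitError("fitted Dmid requires LQ coefficients; call fit_lq first")
        a, b = curve.alpha, curve.beta
        val, _ = integrate.quad(lambda d: np.exp(-(a * d + b * d * d)),
                                0.0, dose_max, epsabs=1e-8, limit=200)
        return float(val)
    if method == "trapezoid":
        d = np.asarray(curve.doses, dtype=float)
        s = np.asarray(curve.sf, dtype=float)
        keep = np.isfinite(s)
        d, s = d[keep], s[keep]
        if d.size < 2 or d.min() > 0:
            raise ValidationError("trapezoid Dmid needs measured SF including dose 0")
        if dose_max > d.max() + 1e-12:
            raise ValidationError(
                f"dose_max {dose_max} exceeds largest assayed dose {d.max()}")
        mask = d <= dose_max + 1e-12
        return float(np.trapezoid(s[mask], d[mask]))
    raise ValidationError(f"unknown Dmid method {method!r}")


def enhancement_ratio(dmid_control: float, dmid_treatment: float,
                      basis: str = "dmid") -> EnhancementResult:
    """ER = Dmid(control) / Dmid(treatment); > 1 means radiosensitization."""
    if dmid_control <= 0 or dmid_treatment <= 0:
        raise ValidationError("Dmid (or GI50) values must be positive")
    return EnhancementResult(er=dmid_control / dmid_treatment,
                             dmid_control=float(dmid_control),
                             dmid_treatment=float(dmid_treatment),
                             basis=basis)


def gi50(doses, viability) -> float:
    """Dose at which viability crosses 50% of the unirradiated value.

    ``viability`` is in percent of unirradiated (100 at dose 0). The
    crossing is located by linear interpolation between the bracketing
    measured doses; no extrapolation beyond the assayed range.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.size != v.size or d.size < 2:
        raise ValidationError("need >= 2 (dose, viability) pairs of equal length")
    order = np.argsort(d)
    d, v = d[order], v[order]
    if np.any(v <= 0):
        raise ValidationError("viability values must be positive")
    target = 50.0
    if v[0] <= target:
        return float(d[0])
    for i in range(1, d.size):
        if v[i] <= target:
            lo, hi = i - 1, i
            frac = (v[lo] - target) / (v[lo] - v[hi])
            return float(d[lo] + frac * (d[hi] - d[lo]))
    raise NotReachedError("viability never falls to 50% within the assayed range")


def er_from_gi50(doses_control, viability_control,
                 doses_treated, viability_treated) -> EnhancementResult:
    """Enhancement ratio from viability curves: GI50(control)/GI50(treated)."""
    g_control = gi50(doses_control, viability_control)
    g_treated = gi50(doses_treated, viability_treated)
    return enhancement_ratio(g_control, g_treated, basis="gi50")
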