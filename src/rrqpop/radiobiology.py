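"""Clonogenic survival analysis and small in-vivo tumor metrics.

Clonogenic assays quantify reproductive cell death after irradiation:
plating efficiency PE = colonies / cells plated, surviving fraction
SF(D) = PE_irradiated / PE_control, modelled with the linear-quadratic (LQ)
form SF(D) = exp(-(b1*D + b2*D^2)) with b1 (per Gy) the single-track and
b2 (per Gy^2) the two-track killing component.  The radiosensitization
ratio of a drug is the fold-reduction in clonogenic survival it causes at a
reference radiation dose (4 Gy by default): SF_control / SF_treated > 1
means the drug radiosensitizes.

Also provided: the ellipsoid tumor-volume formula V = pi/6 * L * B * H and
the endpoint-difference growth rate used for caliper time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize

__all__ = [
    "ClonogenicCurve",
    "plating_efficiency",
    "surviving_fraction",
    "fit_lq",
    "fit_lq_counts",
    "fit_lq_linearized",
    "sensitization_ratio",
    "mean_inactivation_dose",
    "tumor_volume",
    "growth_rate",
    "cumulative_dose",
]


@dataclass(frozen=True)
class ClonogenicCurve:
    """Fitted LQ survival curve; SF(0) = 1 by construction."""

    doses: np.ndarray
    sf: np.ndarray
    b1: float  # Gy^-1
    b2: float  # Gy^-2
    rss: float

    def surviving_fraction(self, dose):
        d = np.asarray(dose, dtype=float)
        out = np.exp(-(self.b1 * d + self.b2 * d**2))
        return float(out) if out.ndim == 0 else out


def plating_efficiency(colonies, plated):
    """Colonies counted / cells plated."""
    if plated < 1:
        raise ValueError("plated must be >= 1")
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    if colonies > plated:
        raise ValueError(f"{colonies} colonies from {plated} plated cells "
                         "is impossible")
    return colonies / plated


def surviving_fraction(pe_irradiated, pe_control):
    """PE of irradiated cells / PE of unirradiated cells."""
    if pe_control <= 0:
        raise ValueError("control plating efficiency must be positive")
    sf = pe_irradiated / pe_control
    if sf > 1:
        warnings.warn(f"surviving fraction {sf:.3f} > 1 (irradiated PE above "
                      "control); passed through", stacklevel=2)
    return sf


def _lq(d, b1, b2):
    return np.exp(-(b1 * d + b2 * d**2))


def fit_lq(doses, sf):
    """Nonlinear least squares of SF = exp(-(b1*D + b2*D^2)), b1, b2 >= 0.

    Fitted on the SF scale (not log scale).  Requires dose 0 in the ladder
    and at least 3 distinct doses; any SF <= 0 is rejected (the model never
    reaches zero).
    """
    doses = np.asarray(doses, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if doses.shape != sf.shape:
        raise ValueError("doses and sf must have equal length")
    if 0 not in doses:
        raise ValueError("dose ladder must include 0 Gy")
    if len(np.unique(doses)) < 3:
        raise ValueError("need at least 3 distinct doses")
    if np.any(sf <= 0):
        raise ValueError("surviving fractions must be positive under the LQ "
                         "model")
    x0 = fit_lq_linearized(doses, sf)
    (b1, b2), _ = curve_fit(_lq, doses, sf, p0=x0,
                            bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
    rss = float(np.sum((sf - _lq(doses, b1, b2)) ** 2))
    return ClonogenicCurve(doses=doses, sf=sf, b1=float(b1), b2=float(b2),
                           rss=rss)


def fit_lq_counts(doses, colonies, plated):
    """Binomial-likelihood LQ fit directly from colony counts.

    Models colonies ~ Binomial(plated, pe0 * SF(dose)) with the plating
    efficiency pe0 a jointly estimated nuisance parameter.  This weights
    each dose by its actual counting noise and is markedly more efficient
    than normalizing to SF and least-squares fitting, especially for the
    quadratic coefficient; parameter uncertainty from 3-4 dose levels at a
    few hundred cells per dish remains substantial for b2 regardless of
    estimator (the information bound, not the fit, is limiting).

    Accepts replicate rows (repeated doses).  Returns a ClonogenicCurve
    whose ``sf`` field holds the per-dose pooled SF estimates.
    """
    doses = np.asarray(doses, dtype=float)
    col = np.asarray(colonies, dtype=float)
    n = np.asarray(plated, dtype=float)
    if not (doses.shape == col.shape == n.shape):
        raise ValueError("doses, colonies and plated must align")
    if 0 not in doses:
        raise ValueError("dose ladder must include 0 Gy")
    if np.any(col > n) or np.any(col < 0):
        raise ValueError("colony counts must lie in [0, plated]")

    def nll(theta):
        logit_pe0, b1, b2 = theta
        pe0 = 1.0 / (1.0 + np.exp(-logit_pe0))
        p = np.clip(pe0 * np.exp(-(np.maximum(b1, 0) * doses
                                   + np.maximum(b2, 0) * doses**2)),
                    1e-12, 1 - 1e-12)
        return -np.sum(col * np.log(p) + (n - col) * np.log1p(-p))

    pe0_hat = max(col[doses == 0].sum() / n[doses == 0].sum(), 1e-6)
    x0 = np.array([np.log(pe0_hat / (1 - pe0_hat + 1e-12)), 0.2, 0.02])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 10000})
    b1, b2 = max(float(res.x[1]), 0.0), max(float(res.x[2]), 0.0)
    # pooled per-dose SF for the curve record
    uniq = np.unique(doses)
    pe = np.array([col[doses == d].sum() / n[doses == d].sum()
                   for d in uniq])
    sf = pe / pe[uniq == 0][0]
    rss = float(np.sum((sf - _lq(uniq, b1, b2)) ** 2))
    return ClonogenicCurve(doses=uniq, sf=sf, b1=b1, b2=b2, rss=rss)


def fit_lq_linearized(doses, sf):
    """Cross-check fit: least squares of -ln SF on (D, D^2), no intercept.

    Returns (b1, b2) clipped at 0.  Used as the initializer and as an
    independent oracle for :func:`fit_lq`.
    """
    doses = np.asarray(doses, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("surviving fractions must be positive")
    y = -np.log(sf)
    X = np.column_stack([doses, doses**2])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return np.maximum(coef, 0.0)


def sensitization_ratio(ctrl, treated, at_dose=4.0):
    """SF_control(D) / SF_treated(D) at the reference dose (default 4 Gy).

    A ratio above 1 means the drug lowered clonogenic survival at that
    radiation dose, i.e. radiosensitized.
    """
    sf_t = treated.surviving_fraction(at_dose)
    if sf_t == 0:
        raise ValueError("treated surviving fraction is 0 at this dose")
    return ctrl.surviving_fraction(at_dose) / sf_t


def mean_inactivation_dose(curve, d_max=20.0, n=2001):
    """Area under SF(D), an alternative radiosensitization summary."""
    d = np.linspace(0.0, d_max, n)
    return float(np.trapezoid(curve.surviving_fraction(d), d))


def tumor_volume(l, b, h):
    """Ellipsoid approximation V = pi/6 * L * B * H (mm^3)."""
    if l <= 0 or b <= 0 or h <= 0:
        raise ValueError("all tumor dimensions must be positive")
    return np.pi / 6.0 * l * b * h


def growth_rate(volumes, days):
    """(V_last - V_first) / (day_last - day_first), in mm^3/day."""
    volumes = np.asarray(volumes, dtype=float)
    days = np.asarray(days, dtype=float)
    if volumes.shape != days.shape or len(volumes) < 2:
        raise ValueError("need >= 2 paired (volume, day) measurements")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    return float((volumes[-1] - volumes[0]) / (days[-1] - days[0]))


def cumulative_dose(n_fractions, dose_per_fraction):
    """Total physical dose of a fractionated schedule (Gy)."""
    if n_fractions < 1 or dose_per_fraction <= 0:
        raise ValueError("need n_fractions >= 1 and a positive fraction dose")
    return n_fractions * dose_per_fraction
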