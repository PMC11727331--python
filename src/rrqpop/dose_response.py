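"""Single-agent dose-response fitting and ICx interpolation.

Raw plate signals are normalized to vehicle/blank controls, fitted with a
four-parameter log-logistic (Hill) curve

    v(d) = bottom + (top - bottom) / (1 + (d / ic50) ** hill),

and drug concentrations producing a given percent inhibition (IC15, IC30,
IC50) are interpolated from the fitted curve.  These ICx doses define the
coded levels of the combination screen: level -1 is no drug (IC0), level 0
is IC15 and level +1 is IC30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "DoseResponseFit",
    "normalize_viability",
    "fit_loglogistic",
    "intrapolate_icx",
]

#: viability range below which a curve is declared flat (non-responder)
FLAT_SPAN = 0.1
#: number of Latin-hypercube starts for the nonlinear fit
N_STARTS = 8
HILL_RANGE = (0.3, 5.0)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted log-logistic parameters for one drug.

    ``converged=False`` marks degenerate inputs (flat curves, failed
    optimization); downstream ICx queries refuse such fits.
    """

    top: float
    bottom: float
    hill: float
    ic50: float
    rss: float
    converged: bool

    def viability(self, dose):
        """Predicted viability fraction at ``dose`` (uM); vectorized."""
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(d > 0, (d / self.ic50) ** self.hill, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)


def normalize_viability(raw, vehicle_mean, blank_mean):
    """Normalize a raw luminescence signal to the [0, 1] viability scale.

    viability = (raw - blank) / (vehicle - blank).  Values above 1
    (stimulation) pass through; negative values are clipped to 0 with a
    warning rather than silently.
    """
    if vehicle_mean <= blank_mean:
        raise ValueError(
            f"vehicle_mean ({vehicle_mean}) must exceed blank_mean "
            f"({blank_mean}): unusable plate"
        )
    v = (np.asarray(raw, dtype=float) - blank_mean) / (vehicle_mean - blank_mean)
    if np.any(v < 0):
        warnings.warn("negative normalized viability clipped to 0", stacklevel=2)
        v = np.clip(v, 0.0, None)
    if np.ndim(raw) == 0:
        return float(v)
    return v


def _residuals(params, doses, viability, constrain):
    log_ic50, log_hill = params[:2]
    hill = np.exp(log_hill)
    ic50 = np.exp(log_ic50)
    if constrain:
        top, bottom = 1.0, 0.0
    else:
        top, bottom = params[2], params[3]
    with np.errstate(over="ignore"):  # huge (d/ic50)^hill -> pred = bottom
        pred = bottom + (top - bottom) / (1.0 + (doses / ic50) ** hill)
    return pred - viability


def fit_loglogistic(doses, viability, constrain=True):
    """Least-squares log-logistic fit with multi-start initialization.

    Parameters
    ----------
    doses, viability : array-like
        Paired observations; doses in uM, strictly positive, >= 4 distinct.
    constrain : bool
        If True (default) fix top = 1 and bottom = 0, matching viability
        normalized to vehicle.  Otherwise all four parameters are free.

    Starts are drawn from a Latin hypercube over (hill in [0.3, 5],
    ic50 in the observed dose range), both on log scale; the lowest-RSS
    solution wins, ties broken by the smallest hill slope.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (dose 0 is off-curve)")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")

    if np.ptp(viability) < FLAT_SPAN:
        # flat curve: ICx undefined
        return DoseResponseFit(
            top=float(np.mean(viability)), bottom=float(np.mean(viability)),
            hill=np.nan, ic50=np.nan,
            rss=float(np.sum((viability - viability.mean()) ** 2)),
            converged=False,
        )

    sampler = qmc.LatinHypercube(d=2, seed=0)
    unit = sampler.random(N_STARTS)
    log_hill_lo, log_hill_hi = np.log(HILL_RANGE)
    log_d_lo, log_d_hi = np.log(doses.min()), np.log(doses.max())
    starts = np.column_stack([
        log_d_lo + unit[:, 0] * (log_d_hi - log_d_lo),
        log_hill_lo + unit[:, 1] * (log_hill_hi - log_hill_lo),
    ])

    best = None
    for s in starts:
        if constrain:
            x0 = s
        else:
            x0 = np.concatenate([s, [viability.max(), viability.min()]])
        try:
            res = least_squares(
                _residuals, x0, args=(doses, viability, constrain),
                method="lm" if len(doses) >= len(x0) else "trf",
            )
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        rss = float(np.sum(res.fun**2))
        hill = float(np.exp(res.x[1]))
        key = (round(rss, 12), hill)
        if res.success and (best is None or key < best[0]):
            best = (key, res.x, rss)

    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.inf, False)

    x = best[1]
    ic50, hill = float(np.exp(x[0])), float(np.exp(x[1]))
    if constrain:
        top, bottom = 1.0, 0.0
    else:
        top, bottom = float(x[2]), float(x[3])
        if bottom > top:
            top, bottom = bottom, top
            hill = -hill
    return DoseResponseFit(top=top, bottom=bottom, hill=hill, ic50=ic50,
                           rss=best[2], converged=True)


def intrapolate_icx(fit, x):
    """Dose (uM) producing ``x`` percent inhibition on a fitted curve.

    Inhibition is on the normalized viability scale: the target viability is
    1 - x/100.  Closed form inversion of the log-logistic; IC0 is by
    convention dose 0 and is handled by the design layer, not here.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; ICx undefined")
    if not 0 < x < 100:
        raise ValueError("x must be strictly between 0 and 100")
    target = 1.0 - x / 100.0
    if not fit.bottom < target < fit.top:
        span_lo = (1.0 - fit.top) * 100.0
        span_hi = (1.0 - fit.bottom) * 100.0
        raise ValueError(
            f"{x}% inhibition is outside the achievable span "
            f"({span_lo:.1f}%, {span_hi:.1f}%) of this curve"
        )
    ratio = (fit.top - target) / (target - fit.bottom)
    return float(fit.ic50 * ratio ** (1.0 / fit.hill))
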