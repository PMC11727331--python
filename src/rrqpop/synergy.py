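"""Synergy quantification: Chou-Talalay combination index and Bliss excess.

Two complementary nulls are implemented.  The median-effect (Chou-Talalay)
model linearizes each dose-response as

    log10(fa / (1 - fa)) = m * (log10 D - log10 Dm),

where fa is the fraction affected (1 - viability), Dm the median-effect
dose and m the slope; the combination index at effect level fa for a
fixed-ratio combination is the two-term (mutually exclusive) form

    CI = d1 / Dx1 + d2 / Dx2,

with (d1, d2) the combination doses achieving fa and Dx_i the iso-effective
single-agent doses.  CI < 1 indicates synergy, CI = 1 additivity.

Bliss independence expects combined inhibition EA + EB - EA*EB/100 (percent
scale); the mean excess of observed over expected across the combination
cells of a dose matrix is the synergy score, classified synergistic when
> 10 and antagonistic when < -10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

__all__ = [
    "MedianEffectFit",
    "CIResult",
    "BlissResult",
    "fit_median_effect",
    "combination_index",
    "bliss_expected",
    "bliss_score",
    "DEFAULT_FA_GRID",
]

#: fa values outside (EPS, 1-EPS) are excluded from the median-effect fit
EPS = 1e-4
#: Bliss classification thresholds on the mean-excess score (percent)
BLISS_SYNERGY_THRESHOLD = 10.0
BLISS_ANTAGONISM_THRESHOLD = -10.0
DEFAULT_FA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters: Dm (uM), slope m, fit correlation r."""

    dm: float
    m: float
    r: float
    n_points: int
    monotone: bool = True

    def dose_for_fa(self, fa):
        """Iso-effective dose D = Dm * (fa/(1-fa))^(1/m)."""
        fa = np.asarray(fa, dtype=float)
        if np.any((fa <= 0) | (fa >= 1)):
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass(frozen=True)
class CIResult:
    """Combination-index curve over an fa grid at a fixed d1:d2 ratio."""

    fa: np.ndarray
    ci: np.ndarray
    ratio: float

    @property
    def log10_ci(self):
        return np.log10(self.ci)


@dataclass(frozen=True)
class BlissResult:
    """Observed/expected/excess inhibition matrices and the mean-excess score."""

    observed: np.ndarray
    expected: np.ndarray
    excess: np.ndarray
    score: float
    label: str


def fit_median_effect(doses, fa):
    """OLS of log10(fa/(1-fa)) on log10(dose).

    Points with fa outside (EPS, 1-EPS) are excluded (the logit transform is
    undefined at 0 and 1); at least 3 usable points are required.  A
    non-positive slope is flagged (``monotone=False``) rather than rejected.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have equal length")
    usable = (fa > EPS) & (fa < 1 - EPS) & (doses > 0)
    if usable.sum() < 3:
        raise ValueError(
            f"only {int(usable.sum())} points with fa strictly inside "
            f"({EPS}, {1 - EPS}); need >= 3"
        )
    x = np.log10(doses[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    res = linregress(x, y)
    m = float(res.slope)
    monotone = m > 0
    if not monotone:
        warnings.warn("median-effect slope m <= 0: non-monotone response",
                      stacklevel=2)
    dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(dm=dm, m=m, r=float(res.rvalue),
                           n_points=int(usable.sum()), monotone=monotone)


def combination_index(fit1, fit2, combo_fit, ratio, fa_grid=None):
    """Chou-Talalay CI across an fa grid for a fixed-ratio combination.

    ``ratio`` is d1:d2, the constant dose ratio of drug 1 to drug 2 in the
    combination series; ``combo_fit`` is the median-effect fit of the
    combination treated as a single agent with dose = d1 + d2.
    """
    if ratio <= 0:
        raise ValueError("dose ratio must be positive")
    if fa_grid is None:
        fa_grid = DEFAULT_FA_GRID
    fa = np.asarray(fa_grid, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise ValueError("fa grid must lie strictly in (0, 1)")
    D = combo_fit.dose_for_fa(fa)
    d1 = D * ratio / (1.0 + ratio)
    d2 = D / (1.0 + ratio)
    ci = d1 / fit1.dose_for_fa(fa) + d2 / fit2.dose_for_fa(fa)
    return CIResult(fa=fa, ci=ci, ratio=float(ratio))


def bliss_expected(ea, eb):
    """Bliss-independent combined inhibition (percent): EA + EB - EA*EB/100."""
    ea = np.asarray(ea, dtype=float)
    eb = np.asarray(eb, dtype=float)
    if np.any(ea < 0) or np.any(ea > 100) or np.any(eb < 0) or np.any(eb > 100):
        warnings.warn("inhibition outside [0, 100] clipped", stacklevel=2)
        ea = np.clip(ea, 0, 100)
        eb = np.clip(eb, 0, 100)
    out = ea + eb - ea * eb / 100.0
    return float(out) if out.ndim == 0 else out


def bliss_score(matrix):
    """Excess-over-Bliss score of an inhibition matrix.

    ``matrix`` is (n+1) x (m+1) percent inhibition: cell [0, 0] is the
    untreated control, the first row and first column hold the single-agent
    inhibitions of the column and row drugs, and the remaining cells are
    combinations.  Excess = observed - expected on combination cells only
    (the margins have zero excess by definition); the score is the mean
    excess, labelled synergistic (> 10), antagonistic (< -10) or additive.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("matrix must be at least 2x2 (margins + combinations)")
    if np.any(np.isnan(M[0, :])) or np.any(np.isnan(M[:, 0])):
        raise ValueError("single-agent margins (first row/column) are missing")
    ea = M[1:, 0][:, None]  # row drug single-agent inhibition
    eb = M[0, 1:][None, :]  # column drug single-agent inhibition
    expected = np.full_like(M, np.nan)
    expected[0, :] = M[0, :]
    expected[:, 0] = M[:, 0]
    expected[1:, 1:] = bliss_expected(
        np.broadcast_to(ea, M[1:, 1:].shape),
        np.broadcast_to(eb, M[1:, 1:].shape),
    )
    excess = M - expected
    score = float(np.mean(excess[1:, 1:]))
    if score > BLISS_SYNERGY_THRESHOLD:
        label = "synergistic"
    elif score < BLISS_ANTAGONISM_THRESHOLD:
        label = "antagonistic"
    else:
        label = "additive"
    return BlissResult(observed=M, expected=expected, excess=excess,
                       score=score, label=label)
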