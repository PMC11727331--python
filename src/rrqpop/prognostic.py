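"""Directional Cox screening and Kaplan-Meier signature evaluation.

Candidate genes from the selection cascade are screened one at a time: the
cohort is split at the median expression of each gene and a univariate Cox
proportional-hazards model of the binary group indicator is fitted (Efron
tie handling).  The directional hypothesis filter keeps genes whose hazard
orientation matches their dysregulation direction in the radioresistant
cells: genes overexpressed in RR should carry risk in the high-expression
group (HR Higher/Lower > 1), underexpressed genes the opposite
(HR Lower/Higher > 1), at p < alpha.  Surviving genes form a signature
scored as the equal-weight mean of per-gene z-scores of log expression,
median-dichotomized and evaluated with Kaplan-Meier curves, the log-rank
test and a group Cox HR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "CoxRecord",
    "SignatureModel",
    "median_dichotomize",
    "cox_univariate",
    "direction_filter",
    "signature_score",
    "km_logrank",
]

ALPHA_DIRECTION = 0.05


@dataclass(frozen=True)
class CoxRecord:
    """Univariate Cox result for one gene's median-split group indicator.

    ``orientation`` names the numerator group: 'Higher/Lower' reports the
    hazard of the high-expression group relative to low, 'Lower/Higher'
    the reverse.
    """

    gene: str
    hr: float
    ci95: tuple
    pvalue: float
    orientation: str

    def reoriented(self, orientation):
        """The same fit expressed in the other orientation (hr -> 1/hr)."""
        if orientation == self.orientation:
            return self
        if orientation not in ("Higher/Lower", "Lower/Higher"):
            raise ValueError(f"unknown orientation {orientation!r}")
        lo, hi = self.ci95
        return CoxRecord(gene=self.gene, hr=1.0 / self.hr,
                         ci95=(1.0 / hi, 1.0 / lo), pvalue=self.pvalue,
                         orientation=orientation)


@dataclass
class SignatureModel:
    """A gene panel with its scoring rule.

    Scores are equal-weight (or ``weights``-weighted) means of within-cohort
    z-scores of log2(expression + 1); the cohort median of the score
    dichotomizes patients into 'high'/'low' signature groups.  The cutoff
    is always computed on the evaluation cohort.
    """

    genes: list[str]
    weights: np.ndarray | None = None
    description: str = "mean of per-gene z-scores of log2 expression"
    _resolved: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("signature panel is empty")
        w = (np.ones(len(self.genes)) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if w.shape != (len(self.genes),):
            raise ValueError("weights must match panel length")
        self._resolved = w / w.sum()


def median_dichotomize(values):
    """Split at the median: 'high' strictly above, ties and below 'low'."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need >= 4 patients to dichotomize")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: degenerate median split")
    med = np.median(v)
    return np.where(v > med, "high", "low")


def cox_univariate(time, event, groups, orientation="Higher/Lower",
                   gene="gene"):
    """Cox PH fit of a binary high/low group indicator.

    Ties in event times are handled by Efron's method (lifelines default).
    Requires at least one event in each group.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if orientation not in ("Higher/Lower", "Lower/Higher"):
        raise ValueError(f"unknown orientation {orientation!r}")
    for g in ("high", "low"):
        n_ev = event[groups == g].sum()
        if n_ev < 1:
            raise ValueError(
                f"group {g!r} has no events ({np.sum(groups == g)} patients); "
                "the partial likelihood is uninformative")
    numerator = "high" if orientation == "Higher/Lower" else "low"
    df = pd.DataFrame({
        "time": time, "event": event,
        "x": (groups == numerator).astype(float),
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).values
    return CoxRecord(gene=gene, hr=hr, ci95=(float(lo), float(hi)),
                     pvalue=float(cph.summary.loc["x", "p"]),
                     orientation=orientation)


def direction_filter(records, rr_directions, alpha=ALPHA_DIRECTION):
    """Directional hypothesis filter on per-gene Cox records.

    Keep genes where (RR-up and HR Higher/Lower > 1 and p < alpha) or
    (RR-down and HR Lower/Higher > 1 and p < alpha).  ``rr_directions``
    maps gene -> 'up'/'down' (dysregulation direction in RR cells).
    """
    kept = []
    for rec in records:
        if rec.gene not in rr_directions:
            raise ValueError(f"no RR direction supplied for {rec.gene}")
        want = ("Higher/Lower" if rr_directions[rec.gene] == "up"
                else "Lower/Higher")
        oriented = rec.reoriented(want)
        if oriented.hr > 1 and oriented.pvalue < alpha:
            kept.append(rec.gene)
    return kept


def signature_score(expression, model):
    """Per-patient signature scores and median-split groups.

    ``expression`` is a DataFrame patients x genes (raw positive scale);
    each panel gene is log2(x+1)-transformed and z-scored within the
    cohort, then averaged with the panel weights.
    """
    missing = [g for g in model.genes if g not in expression.columns]
    if missing:
        raise ValueError(f"expression matrix lacks panel genes: {missing}")
    logx = np.log2(expression[model.genes].to_numpy(dtype=float) + 1.0)
    sd = logx.std(axis=0, ddof=0)
    if np.any(sd == 0):
        flat = [g for g, s in zip(model.genes, sd) if s == 0]
        raise ValueError(f"constant expression for panel genes: {flat}")
    z = (logx - logx.mean(axis=0)) / sd
    scores = z @ model._resolved
    return pd.Series(scores, index=expression.index, name="score"), \
        median_dichotomize(scores)


def km_logrank(time, event, groups):
    """Kaplan-Meier curves, two-sided log-rank test and group Cox HR.

    Returns a dict with per-group product-limit curve tables, the log-rank
    p-value and the Cox HR of the low vs high group (low as numerator, the
    reporting convention for protective signatures).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected 2 groups, got {list(labels)}")
    curves = {}
    for g in labels:
        m = groups == g
        if m.sum() == 0 or event[m].sum() == 0:
            raise ValueError(f"group {g!r} is empty or has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(g))
        curves[str(g)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(g): "survival"})
    lr = logrank_test(time[groups == labels[0]], time[groups == labels[1]],
                      event[groups == labels[0]], event[groups == labels[1]])
    cox = cox_univariate(time, event, groups, orientation="Lower/Higher",
                         gene="signature")
    return {"curves": curves, "logrank_p": float(lr.p_value),
            "hr_low_vs_high": cox.hr, "hr_ci95": cox.ci95,
            "cox_p": cox.pvalue}
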