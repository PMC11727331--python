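"""Quadratic response-surface (QPOP) regression and combination ranking.

Normalized viability from the OACD screen is regressed on coded drug levels
with a full second-order polynomial

    v(x) = b0 + sum_i bi xi + sum_i bii xi^2 + sum_{i<j} bij xi xj,

then every two-drug combination (the other drugs at level -1, i.e. absent)
is scored by its predicted viability over the four (IC15/IC30)^2 level
assignments and ranked ascending: lower predicted viability = stronger
combination.  Parabolic response surfaces over any drug pair are emitted as
gridded tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceModel",
    "PairRanking",
    "build_model_matrix",
    "coefficient_names",
    "fit_quadratic",
    "predict_viability",
    "enumerate_pairs",
    "response_surface",
]


def n_coefficients(k):
    """1 intercept + k linear + k quadratic + k(k-1)/2 interactions."""
    return 1 + 2 * k + k * (k - 1) // 2


def build_model_matrix(levels):
    """Second-order model matrix with pinned column order.

    Columns: [1, x_1..x_k, x_1^2..x_k^2, x_i x_j for i<j lexicographic].
    """
    X = np.asarray(levels, dtype=float)
    n, k = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, i] for i in range(k))
    cols.extend(X[:, i] ** 2 for i in range(k))
    cols.extend(X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k))
    return np.column_stack(cols)


def coefficient_names(drugs):
    names = ["intercept"]
    names += [f"lin:{d}" for d in drugs]
    names += [f"quad:{d}" for d in drugs]
    names += [f"int:{a}*{b}" for a, b in itertools.combinations(drugs, 2)]
    return names


@dataclass
class SurfaceModel:
    """Fitted (or ground-truth) second-order viability surface.

    ``beta_int`` is stored in lexicographic (i<j) order matching
    :func:`build_model_matrix`.
    """

    drugs: list[str]
    beta0: float
    beta_lin: np.ndarray
    beta_quad: np.ndarray
    beta_int: np.ndarray
    rss: float = np.nan
    df: int = 0
    cov: np.ndarray | None = None

    def __post_init__(self):
        k = len(self.drugs)
        self.beta_lin = np.asarray(self.beta_lin, dtype=float)
        self.beta_quad = np.asarray(self.beta_quad, dtype=float)
        self.beta_int = np.asarray(self.beta_int, dtype=float)
        if self.beta_lin.shape != (k,) or self.beta_quad.shape != (k,):
            raise ValueError("linear/quadratic coefficient length must equal k")
        if self.beta_int.shape != (k * (k - 1) // 2,):
            raise ValueError("interaction coefficient length must be k(k-1)/2")

    @property
    def k(self):
        return len(self.drugs)

    @property
    def coef(self):
        return np.concatenate([[self.beta0], self.beta_lin, self.beta_quad,
                               self.beta_int])

    def interaction(self, i, j):
        """Pairwise coefficient b_ij for drug indices i != j."""
        if i == j:
            raise ValueError("interaction requires two distinct drugs")
        i, j = min(i, j), max(i, j)
        k = self.k
        idx = i * k - i * (i + 1) // 2 + (j - i - 1)
        return float(self.beta_int[idx])

    @classmethod
    def from_coef(cls, drugs, coef, **kw):
        k = len(drugs)
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (n_coefficients(k),):
            raise ValueError(f"expected {n_coefficients(k)} coefficients")
        return cls(drugs=list(drugs), beta0=float(coef[0]),
                   beta_lin=coef[1:1 + k], beta_quad=coef[1 + k:1 + 2 * k],
                   beta_int=coef[1 + 2 * k:], **kw)


@dataclass
class PairRanking:
    """All-pair scoring output.

    ``records``: one row per (pair, level assignment), 4 per pair.
    ``headline``: one row per pair at its best (minimum-viability) level
    assignment, sorted ascending so rank 1 is the strongest combination.
    """

    records: pd.DataFrame
    headline: pd.DataFrame


def fit_quadratic(design, viability):
    """Ordinary least squares of viability on the second-order expansion.

    Refuses rank-deficient model matrices rather than silently
    regularizing.  ``viability`` is replicate-averaged, one value per run;
    fitting stacked replicates with repeated design rows gives the same
    estimate (OLS equivalence).
    """
    y = np.asarray(viability, dtype=float)
    if y.shape[0] != design.n_runs:
        raise ValueError("viability length must equal number of runs")
    X = build_model_matrix(design.levels)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"model matrix rank {rank} < {X.shape[1]}: the design cannot "
            "estimate the full second-order model; use an OACD"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = xtx_inv * (rss / df if df > 0 else np.nan)
    return SurfaceModel.from_coef(design.drugs, coef, rss=rss, df=df, cov=cov)


def predict_viability(model, levels):
    """Evaluate the polynomial at coded ``levels`` (vector or matrix).

    Output is the raw model prediction, not clipped to [0, 1].
    """
    x = np.atleast_2d(np.asarray(levels, dtype=float))
    if x.shape[1] != model.k:
        raise ValueError(f"levels must have length {model.k}")
    pred = build_model_matrix(x) @ model.coef
    return float(pred[0]) if np.ndim(levels) == 1 else pred


#: coded levels enumerated for each drug of a candidate pair
PAIR_LEVELS = (0, 1)  # IC15, IC30
BACKGROUND_LEVEL = -1  # all other drugs absent


def enumerate_pairs(model):
    """Score and rank every unordered two-drug combination.

    For each pair, predicted viability is computed at the four
    (IC15/IC30)^2 level assignments with every other drug at level -1
    (absent); the pair's headline score is the minimum over the four.
    """
    k = model.k
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for li, lj in itertools.product(PAIR_LEVELS, repeat=2):
            x = np.full(k, BACKGROUND_LEVEL, dtype=float)
            x[i], x[j] = li, lj
            rows.append({
                "drug_i": model.drugs[i], "level_i": li,
                "drug_j": model.drugs[j], "level_j": lj,
                "predicted_viability": predict_viability(model, x),
            })
    records = pd.DataFrame(rows).sort_values(
        "predicted_viability", kind="mergesort").reset_index(drop=True)
    headline = (
        records.loc[records.groupby(["drug_i", "drug_j"], sort=False)
                    ["predicted_viability"].idxmin()]
        .sort_values("predicted_viability", kind="mergesort")
        .reset_index(drop=True)
    )
    headline.insert(0, "rank", np.arange(1, len(headline) + 1))
    return PairRanking(records=records, headline=headline)


def response_surface(model, drug_i, drug_j, grid=None):
    """Predicted-viability grid over [-1, +1]^2 for one drug pair.

    All other drugs are held at level -1 (absent).  Returns a tidy
    DataFrame (level_i, level_j, predicted_viability) suitable for
    contour/surface plotting; default grid 21 x 21.
    """
    if drug_i == drug_j:
        raise ValueError("response surface requires two distinct drugs")
    i = model.drugs.index(drug_i)
    j = model.drugs.index(drug_j)
    if grid is None:
        grid = np.linspace(-1, 1, 21)
    grid = np.asarray(grid, dtype=float)
    pts = []
    for gi in grid:
        for gj in grid:
            x = np.full(model.k, float(BACKGROUND_LEVEL))
            x[i], x[j] = gi, gj
            pts.append((gi, gj, predict_viability(model, x)))
    return pd.DataFrame(pts, columns=["level_i", "level_j",
                                      "predicted_viability"])
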