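"""Orthogonal-array composite design (OACD) construction.

The combination screen uses an OACD: the row-concatenation of a two-level
fractional factorial 2^(12-5) (128 runs, factor screening) and the
three-level orthogonal array OA(27, 3^13) restricted to 12 columns (27 runs,
curvature and model fitting), for 155 runs total.  Coded levels -1/0/+1 map
to per-drug doses 0 (IC0, drug absent), IC15 and IC30.

The 155-run design supports the full second-order polynomial in 12 factors
(91 coefficients): the pinned default generators yield a resolution-IV
two-level block whose two-factor-interaction aliasing is broken by the
three-level block, so the expanded model matrix has full column rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import intrapolate_icx

__all__ = [
    "DesignMatrix",
    "DoseMap",
    "DEFAULT_GENERATORS_12_5",
    "build_two_level_ff",
    "build_oa27",
    "build_oacd",
    "map_levels_to_doses",
]

#: Pinned generator words for the 2^(12-5) block, as tuples of 1-based base
#: factors: factor 8 = 2*3*4*5, 9 = 3*4*7, 10 = 1*2*4*7, 11 = 1*2*4*5*6,
#: 12 = 2*6*7.  Resolution IV; chosen so that, combined with OA(27, 3^12),
#: the quadratic model matrix has full rank 91.
DEFAULT_GENERATORS_12_5 = (
    (2, 3, 4, 5),
    (3, 4, 7),
    (1, 2, 4, 7),
    (1, 2, 4, 5, 6),
    (2, 6, 7),
)

#: GF(3) exponent vectors defining the 13 columns of OA(27, 3^13), in pinned
#: order: each column is (a*x1 + b*x2 + c*x3) mod 3 over the 27 base triples.
_OA27_VECTORS = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 2, 0), (1, 0, 1), (1, 0, 2),
    (0, 1, 1), (0, 1, 2),
    (1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
)


@dataclass
class DesignMatrix:
    """Coded run-by-drug level matrix with provenance.

    ``levels`` holds integers in {-1, 0, +1}; ``provenance`` tags each run
    as belonging to the two-level ('ff') or three-level ('oa') block.
    """

    levels: np.ndarray
    drugs: list[str]
    provenance: np.ndarray
    resolution: int | None = None

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        if not np.isin(self.levels, (-1, 0, 1)).all():
            raise ValueError("coded levels must be in {-1, 0, +1}")
        if self.levels.shape[1] != len(self.drugs):
            raise ValueError("drug names must match design columns")

    @property
    def n_runs(self):
        return self.levels.shape[0]

    @property
    def n_drugs(self):
        return self.levels.shape[1]

    def to_frame(self):
        df = pd.DataFrame(self.levels, columns=self.drugs)
        df.insert(0, "block", self.provenance)
        return df


@dataclass
class DoseMap:
    """Per-drug mapping of coded level to dose: {-1: 0, 0: IC15, +1: IC30}."""

    doses: dict = field(default_factory=dict)  # drug -> {-1,0,1} -> uM

    def add(self, drug, ic15, ic30):
        if not 0 < ic15 < ic30:
            raise ValueError(f"{drug}: require 0 < IC15 ({ic15}) < IC30 ({ic30})")
        self.doses[drug] = {-1: 0.0, 0: float(ic15), 1: float(ic30)}


def _default_names(k):
    return [f"drug{i + 1:02d}" for i in range(k)]


def _defining_words(base, generators):
    """All 2^p - 1 nonzero defining words (as frozensets of 0-based factors)."""
    gen_words = [
        frozenset(f - 1 for f in g) ^ frozenset([base + i])
        for i, g in enumerate(generators)
    ]
    words = []
    for r in range(1, len(gen_words) + 1):
        for combo in itertools.combinations(gen_words, r):
            w = frozenset()
            for gw in combo:
                w ^= gw
            words.append(w)
    return words


def build_two_level_ff(k=12, p=5, generators=None):
    """Two-level fractional factorial 2^(k-p) at coded levels +/-1.

    ``generators`` is a sequence of p tuples of 1-based base-factor indices;
    generated factor k-p+i+1 is the product of the named base columns.  The
    design's resolution (shortest defining word) is computed and stored;
    generators aliasing a main effect (resolution < 3) are rejected.
    """
    if generators is None:
        if (k, p) == (12, 5):
            generators = DEFAULT_GENERATORS_12_5
        elif p == 0:
            generators = ()
        else:
            raise ValueError(
                f"no default generators for 2^({k}-{p}); supply them explicitly"
            )
    if len(generators) != p:
        raise ValueError(f"expected {p} generator words, got {len(generators)}")
    base = k - p
    for g in generators:
        if any(not 1 <= f <= base for f in g):
            raise ValueError(f"generator {g} references non-base factors")

    runs = np.array(list(itertools.product((-1, 1), repeat=base)), dtype=int)
    cols = [runs[:, i] for i in range(base)]
    for g in generators:
        cols.append(np.prod(runs[:, [f - 1 for f in g]], axis=1))
    levels = np.column_stack(cols)

    if p > 0:
        resolution = min(len(w) for w in _defining_words(base, generators))
        if resolution < 3:
            raise ValueError(
                f"generators alias a main effect (resolution {resolution} < III)"
            )
    else:
        resolution = None

    return DesignMatrix(
        levels=levels,
        drugs=_default_names(k),
        provenance=np.array(["ff"] * len(levels)),
        resolution=resolution,
    )


def build_oa27(columns=12):
    """The 27-run three-level orthogonal array OA(27, 3^13), first ``columns``
    columns, coded -1/0/+1.

    Constructed from GF(3) linear combinations of three base columns; any
    single column carries each level 9 times, any column pair each of the 9
    level combinations exactly 3 times (strength 2).
    """
    if not 1 <= columns <= 13:
        raise ValueError(f"columns must be in 1..13, got {columns}")
    base = np.array(list(itertools.product(range(3), repeat=3)), dtype=int)
    cols = [(base @ np.array(v)) % 3 for v in _OA27_VECTORS[:columns]]
    levels = np.column_stack(cols) - 1
    return DesignMatrix(
        levels=levels,
        drugs=_default_names(columns),
        provenance=np.array(["oa"] * 27),
    )


def build_oacd(k=12, drugs=None):
    """The composite design: 2^(12-5) stacked on OA(27, 3^12), 155 runs.

    Only k = 12 is catalogued; the quadratic model matrix of the result has
    full column rank (91 coefficients), which is the 'sufficient for factor
    screening and model fitting' property the screen relies on.
    """
    if k != 12:
        raise ValueError(f"unsupported factor count {k}; supported sizes: [12]")
    if drugs is None:
        drugs = _default_names(k)
    if len(drugs) != k:
        raise ValueError("drug name list must have length k")
    ff = build_two_level_ff(12, 5)
    oa = build_oa27(12)
    return DesignMatrix(
        levels=np.vstack([ff.levels, oa.levels]),
        drugs=list(drugs),
        provenance=np.concatenate([ff.provenance, oa.provenance]),
        resolution=ff.resolution,
    )


def map_levels_to_doses(design, fits):
    """Translate coded levels to a per-run dosing plan in uM.

    ``fits`` maps each drug name to a converged DoseResponseFit; IC15 and
    IC30 are interpolated from the curve, level -1 maps to exactly 0.
    Returns a DataFrame of shape (runs, drugs).
    """
    dm = DoseMap()
    for drug in design.drugs:
        if drug not in fits:
            raise ValueError(f"no dose-response fit supplied for {drug}")
        fit = fits[drug]
        if not fit.converged:
            raise ValueError(f"dose-response fit for {drug} did not converge")
        dm.add(drug, intrapolate_icx(fit, 15), intrapolate_icx(fit, 30))

    plan = np.empty(design.levels.shape, dtype=float)
    for j, drug in enumerate(design.drugs):
        lut = dm.doses[drug]
        for lvl in (-1, 0, 1):
            plan[design.levels[:, j] == lvl, j] = lut[lvl]
    return pd.DataFrame(plan, columns=design.drugs)
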