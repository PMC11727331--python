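"""Synthetic pipeline inputs with known ground truth.

The study's raw screen, count and cohort data are not deposited, so every
downstream stage is exercised on generated data that emulates the study's
structure: a 12-drug, 3-level OACD screen in technical duplicate;
log-logistic single-agent dose responses over 0.0001-100 uM; Bliss-null and
synergy-planted 5x5 dose matrices; linear-quadratic clonogenic survival at
0/1/2/4 Gy; negative-binomial counts over 2 cell lines x 2 phenotypes x
2 knockdowns x 3 replicates (24 samples) with planted RR-dysregulated genes
reversed by siHDAC6; and right-censored survival cohorts (n = 261 and 158)
with expression-linked hazards.

Every generator is deterministic given its seed, and each truth object can
be serialized to JSON so recovery tests can compare against the planted
parameters and labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpop import SurfaceModel, build_model_matrix

__all__ = [
    "TruthSpec",
    "CountTruth",
    "SurvivalTruth",
    "default_truth",
    "default_count_truth",
    "default_survival_truth",
    "gen_dose_response",
    "gen_screen_viability",
    "gen_bliss_matrix",
    "gen_clonogenic",
    "gen_counts",
    "gen_survival",
    "DEFAULT_DOSE_LADDER",
]

#: default single-agent dose ladder: log steps over 0.0001-100 uM
DEFAULT_DOSE_LADDER = np.logspace(-4, 2, 10)
#: plate-reader signal scale for raw luminescence emulation
VEHICLE_SIGNAL = 1.0e6
BLANK_SIGNAL = 5.0e4
#: viability clip ceiling (plate readers report mild stimulation)
VIABILITY_CEILING = 1.2


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class TruthSpec:
    """Ground truth for the dose-response and screen generators."""

    seed: int
    n_drugs: int
    surface_truth: SurfaceModel
    dr_params: pd.DataFrame  # per-drug: top, bottom, hill, ic50_uM
    noise_sd: float
    planted_pairs: list  # (i, j, sign): sign -1 synergistic, +1 antagonistic

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for i, j, _ in self.planted_pairs:
            if not (0 <= i < self.n_drugs and 0 <= j < self.n_drugs and i != j):
                raise ValueError(f"planted pair ({i}, {j}) out of range")

    def to_json(self):
        return json.dumps({
            "seed": self.seed,
            "n_drugs": self.n_drugs,
            "surface_coef": self.surface_truth.coef.tolist(),
            "dr_params": self.dr_params.to_dict(orient="list"),
            "noise_sd": self.noise_sd,
            "planted_pairs": [list(p) for p in self.planted_pairs],
        }, indent=2)


@dataclass
class CountTruth:
    """Ground truth for the RNA-count generator.

    ``rr_lfc`` is the planted log2FC of RR-siNC vs WT-siNC per (gene, line);
    ``kd_lfc`` the log2FC of RR-siHDAC6 vs RR-siNC.  siHDAC6-responsive
    genes have kd_lfc of the opposite sign to rr_lfc; consensus genes are
    planted identically in both cell lines.
    """

    seed: int
    genes: list
    cell_lines: tuple
    baseline: np.ndarray  # per-gene mean
    dispersion: np.ndarray  # per-gene NB dispersion (alpha)
    rr_lfc: dict  # line -> per-gene array
    kd_lfc: dict  # line -> per-gene array
    rr_up: set = field(default_factory=set)
    rr_down: set = field(default_factory=set)
    sihdac6_responsive: set = field(default_factory=set)
    consensus: set = field(default_factory=set)

    def __post_init__(self):
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersions must be positive")
        if self.rr_up & self.rr_down:
            raise ValueError("rr_up and rr_down must be disjoint")
        if not self.consensus <= self.sihdac6_responsive:
            raise ValueError("consensus genes must be siHDAC6-responsive")

    def truth_sets(self):
        return {
            "rr_up": sorted(self.rr_up),
            "rr_down": sorted(self.rr_down),
            "sihdac6_responsive": sorted(self.sihdac6_responsive),
            "consensus": sorted(self.consensus),
        }

    def to_json(self):
        return json.dumps({"seed": self.seed, **self.truth_sets()}, indent=2)


@dataclass
class SurvivalTruth:
    """Ground truth for the survival-cohort generator.

    With ``dichotomous=True`` the hazard acts on the median-split group of
    the signature score (log-HR ``beta`` for the low group), so the "true
    dichotomized HR" is exactly exp(beta).  Otherwise hazards are linear in
    the continuous per-gene expression (coefficients ``beta_per_gene``).
    """

    seed: int
    n_patients: int
    baseline_hazard: float
    beta: float  # log-HR of low vs high group (dichotomous mode)
    beta_per_gene: dict = field(default_factory=dict)
    censor_max: float = 1.5  # administrative uniform censoring horizon
    dichotomous: bool = True

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censor_max <= 0:
            raise ValueError("censoring horizon must be positive")


# ---------------------------------------------------------------------------
# default truth factories (the study conditions)


def default_truth(seed=0, n_drugs=12, noise_sd=0.05,
                  planted_pair=(0, 1), planted_sign=-1):
    """Screen ground truth with one planted strongly interacting pair.

    Linear coefficients are drawn in [-0.030, -0.015] per coded unit (all
    drugs kill, mildly, so that the polynomial stays within the plate's
    [0, 1.2] viability range over the whole design); the planted pair gets
    the strongest linear effects (-0.085) and an interaction of magnitude
    0.15 (negative = synergistic), making it the unambiguous top-ranked
    combination of the truth surface with a margin well above the
    viability noise.  The intercept is set so the no-drug corner (all
    levels -1) sits at viability 0.95.
    """
    rng = np.random.default_rng(seed)
    p, q = planted_pair
    drugs = [f"drug{i + 1:02d}" for i in range(n_drugs)]
    beta_lin = rng.uniform(-0.030, -0.015, n_drugs)
    beta_lin[[p, q]] = -0.085
    beta_quad = rng.uniform(-0.015, 0.015, n_drugs)
    beta_int = np.zeros(n_drugs * (n_drugs - 1) // 2)
    idx = 0
    pos = {}
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            pos[(i, j)] = idx
            idx += 1
    beta_int[pos[(min(p, q), max(p, q))]] = planted_sign * 0.15
    # anchor: viability at the all-absent corner
    corner = np.full(n_drugs, -1.0)
    partial = SurfaceModel(drugs=drugs, beta0=0.0, beta_lin=beta_lin,
                           beta_quad=beta_quad, beta_int=beta_int)
    beta0 = 0.95 - float((build_model_matrix(corner[None, :]) @ partial.coef)[0])
    surface = SurfaceModel(drugs=drugs, beta0=beta0, beta_lin=beta_lin,
                           beta_quad=beta_quad, beta_int=beta_int)
    dr = pd.DataFrame({
        "drug": drugs,
        "top": 1.0,
        "bottom": 0.0,
        "hill": rng.uniform(0.7, 2.5, n_drugs),
        "ic50_uM": 10.0 ** rng.uniform(-2, 1, n_drugs),
    }).set_index("drug")
    return TruthSpec(seed=seed, n_drugs=n_drugs, surface_truth=surface,
                     dr_params=dr, noise_sd=noise_sd,
                     planted_pairs=[(p, q, planted_sign)])


def default_count_truth(seed=0, n_genes=20000, n_consensus=24,
                        n_line_specific=(76, 30), n_rr_only=200,
                        n_same_direction=50, lfc_range=(1.5, 2.5),
                        cell_lines=("FaDu", "HK1")):
    """Count ground truth mirroring the study's selection structure.

    24 consensus genes (4 up / 20 down in RR, fully reversed by siHDAC6 in
    both lines) are planted among 20,000, alongside line-specific
    responsive genes, RR-dysregulated genes that ignore the knockdown, and
    genes responding in the same (not opposite) direction, so every
    cascade stage has something to reject.  Effect magnitudes are drawn in
    [1.5, 2.5] log2 units; planted genes get comfortably detectable
    baselines; dispersions are log-normal around 0.05.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    baseline = np.exp(rng.normal(np.log(100.0), 1.5, n_genes))
    dispersion = np.exp(rng.normal(np.log(0.05), 0.3, n_genes))

    n_planted = (n_consensus + sum(n_line_specific) + n_rr_only
                 + n_same_direction)
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    baseline[planted_idx] = np.exp(
        rng.uniform(np.log(50.0), np.log(1000.0), n_planted))
    cursor = 0

    def take(n):
        nonlocal cursor
        out = planted_idx[cursor:cursor + n]
        cursor += n
        return out

    cons_idx = take(n_consensus)
    line_idx = {line: take(n) for line, n in zip(cell_lines, n_line_specific)}
    rr_only_idx = take(n_rr_only)
    same_idx = take(n_same_direction)

    def signed_lfc(n, frac_up):
        mag = rng.uniform(*lfc_range, n)
        sign = np.where(np.arange(n) < round(frac_up * n), 1.0, -1.0)
        return mag * sign

    rr_lfc = {line: np.zeros(n_genes) for line in cell_lines}
    kd_lfc = {line: np.zeros(n_genes) for line in cell_lines}

    # consensus: identical effects in both lines, 4 up / 20 down as in the
    # study's final panel, siHDAC6 fully reverses
    cons_eff = signed_lfc(n_consensus, 4 / 24)
    for line in cell_lines:
        rr_lfc[line][cons_idx] = cons_eff
        kd_lfc[line][cons_idx] = -cons_eff
    # line-specific responsive genes
    for line in cell_lines:
        eff = signed_lfc(len(line_idx[line]), 0.4)
        rr_lfc[line][line_idx[line]] = eff
        kd_lfc[line][line_idx[line]] = -eff
    # RR-dysregulated but knockdown-inert
    rr_eff = signed_lfc(n_rr_only, 0.35)
    for line in cell_lines:
        rr_lfc[line][rr_only_idx] = rr_eff
    # responds in the same direction (excluded by interaction analysis)
    same_eff = signed_lfc(n_same_direction, 0.5)
    for line in cell_lines:
        rr_lfc[line][same_idx] = same_eff
        kd_lfc[line][same_idx] = 0.8 * same_eff

    g = np.array(genes)
    rr_all = np.concatenate([cons_idx, *line_idx.values(), rr_only_idx,
                             same_idx])
    up = {gi for gi in rr_all if rr_lfc[cell_lines[0]][gi] > 0
          or rr_lfc[cell_lines[1]][gi] > 0}
    responsive = set(cons_idx) | set().union(*[set(v) for v in
                                               line_idx.values()])
    return CountTruth(
        seed=seed, genes=genes, cell_lines=tuple(cell_lines),
        baseline=baseline, dispersion=dispersion,
        rr_lfc=rr_lfc, kd_lfc=kd_lfc,
        rr_up=set(g[sorted(i for i in rr_all if i in up)]),
        rr_down=set(g[sorted(i for i in rr_all if i not in up)]),
        sihdac6_responsive=set(g[sorted(responsive)]),
        consensus=set(g[sorted(cons_idx)]),
    )


def default_survival_truth(seed=0, n_patients=261, hr=1.8,
                           baseline_hazard=1.0, censor_max=1.5):
    """Cohort truth: low-signature patients at exp(beta) = hr excess hazard.

    Cohort sizes 261 (discovery) and 158 (validation) match the study's RT
    cohorts; the uniform censoring horizon yields roughly half the cohort
    with events.
    """
    return SurvivalTruth(seed=seed, n_patients=n_patients,
                         baseline_hazard=baseline_hazard,
                         beta=float(np.log(hr)), censor_max=censor_max,
                         dichotomous=True)


# ---------------------------------------------------------------------------
# generators


def _loglogistic(dose, top, bottom, hill, ic50):
    d = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


def gen_dose_response(spec, doses=None, replicates=4):
    """Single-agent viability plate table for every drug in the truth.

    Columns: drug, dose_uM, replicate, raw, viability.  Noiseless
    generation lies exactly on the planted log-logistic curves; the raw
    signal emulates a luminescence readout between blank and vehicle.
    """
    if doses is None:
        doses = DEFAULT_DOSE_LADDER
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list is empty")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and sorted ascending")
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for drug, p in spec.dr_params.iterrows():
        truth = _loglogistic(doses, p.top, p.bottom, p.hill, p.ic50_uM)
        for rep in range(1, replicates + 1):
            noisy = truth + rng.normal(0.0, spec.noise_sd, len(doses))
            noisy = np.clip(noisy, 0.0, VIABILITY_CEILING)
            raw = BLANK_SIGNAL + noisy * (VEHICLE_SIGNAL - BLANK_SIGNAL)
            rows.append(pd.DataFrame({
                "drug": drug, "dose_uM": doses, "replicate": rep,
                "raw": raw, "viability": noisy,
            }))
    return pd.concat(rows, ignore_index=True)


def gen_screen_viability(spec, design, replicates=2):
    """OACD screen viability table: truth surface + Gaussian plate noise.

    One row per run x replicate; viability clipped to [0, 1.2].  Technical
    duplicates (replicates=2) match the screen protocol.
    """
    if design.n_drugs != spec.n_drugs:
        raise ValueError("design columns must match the truth's drug count")
    rng = np.random.default_rng(spec.seed + 1)
    X = build_model_matrix(design.levels)
    truth = X @ spec.surface_truth.coef
    rows = []
    for rep in range(1, replicates + 1):
        v = truth + rng.normal(0.0, spec.noise_sd, len(truth))
        rows.append(pd.DataFrame({
            "run": np.arange(len(truth)), "replicate": rep,
            "viability": np.clip(v, 0.0, VIABILITY_CEILING),
        }))
    return pd.concat(rows, ignore_index=True)


def gen_bliss_matrix(mode="null", ea_row=None, eb_col=None, excess=20.0,
                     noise_sd=1.0, seed=0, shape=(5, 5)):
    """Synthetic (n x m) percent-inhibition dose matrix with margins.

    Cell [0, 0] is the untreated control (0); the first column holds the
    row drug's single-agent inhibitions, the first row the column drug's.
    Under ``mode='null'`` combination cells follow the Bliss expectation
    exactly (plus noise); under ``mode='planted'`` a constant ``excess`` is
    added to every combination cell.
    """
    if mode not in ("null", "planted"):
        raise ValueError(f"unknown mode {mode!r}")
    n, m = shape
    if n < 2 or m < 2:
        raise ValueError("matrix must be at least 2x2")
    if ea_row is None:
        ea_row = np.linspace(15, 70, n - 1)
    if eb_col is None:
        eb_col = np.linspace(10, 60, m - 1)
    ea_row = np.asarray(ea_row, dtype=float)
    eb_col = np.asarray(eb_col, dtype=float)
    if np.any((ea_row < 0) | (ea_row > 100) | (eb_col < 0) | (eb_col > 100)):
        raise ValueError("single-agent inhibitions must be in [0, 100]")
    M = np.zeros((n, m))
    M[1:, 0] = ea_row
    M[0, 1:] = eb_col
    expected = ea_row[:, None] + eb_col[None, :] - ea_row[:, None] * \
        eb_col[None, :] / 100.0
    M[1:, 1:] = expected + (excess if mode == "planted" else 0.0)
    rng = np.random.default_rng(seed)
    M[1:, 1:] += rng.normal(0.0, noise_sd, (n - 1, m - 1))
    return M


def gen_clonogenic(b1=0.3, b2=0.03, doses=(0, 1, 2, 4), plated=500,
                   pe0=0.5, seed=0, replicates=3):
    """Colony-count table: colonies ~ Binomial(plated, pe0 * SF_LQ(dose)).

    The default 0/1/2/4 Gy ladder matches the clonogenic protocol; pe0 is
    the unirradiated plating efficiency.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if plated < 1:
        raise ValueError("must plate at least one cell")
    if not 0 < pe0 <= 1:
        raise ValueError("pe0 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sf = np.exp(-(b1 * doses + b2 * doses**2))
    rows = []
    for rep in range(1, replicates + 1):
        colonies = rng.binomial(plated, pe0 * sf)
        rows.append(pd.DataFrame({
            "dose_Gy": doses, "plated": plated, "colonies": colonies,
            "replicate": rep,
        }))
    return pd.concat(rows, ignore_index=True)


def gen_counts(truth, n_per_group=3):
    """NB count matrix and sample sheet for the factorial knockdown study.

    2 cell lines x 2 phenotypes (WT/RR) x 2 knockdowns (siNC/siHDAC6) x
    ``n_per_group`` replicates (24 samples at the default triplicate).
    Per-sample library-size factors are log-normal(0, 0.2); planted
    log2FCs act multiplicatively on the per-gene baseline.
    """
    if n_per_group < 2:
        raise ValueError("need >= 2 replicates per group (dispersion is "
                         "unidentifiable otherwise)")
    rng = np.random.default_rng(truth.seed)
    n_genes = len(truth.genes)
    names, meta, cols = [], [], []
    for line in truth.cell_lines:
        for phen in ("WT", "RR"):
            for kd in ("siNC", "siHDAC6"):
                log2_shift = np.zeros(n_genes)
                if phen == "RR":
                    log2_shift = log2_shift + truth.rr_lfc[line]
                    if kd == "siHDAC6":
                        log2_shift = log2_shift + truth.kd_lfc[line]
                mu_group = truth.baseline * 2.0 ** log2_shift
                for rep in range(1, n_per_group + 1):
                    sf = np.exp(rng.normal(0.0, 0.2))
                    mu = np.maximum(mu_group * sf, 1e-8)
                    nbn = 1.0 / truth.dispersion
                    counts = rng.negative_binomial(nbn, nbn / (nbn + mu))
                    cols.append(counts)
                    name = f"{line}_{phen}_{kd}_r{rep}"
                    names.append(name)
                    meta.append({"sample": name, "cell_line": line,
                                 "phenotype": phen, "knockdown": kd,
                                 "replicate": rep})
    counts = pd.DataFrame(np.column_stack(cols), index=truth.genes,
                          columns=names)
    samples = pd.DataFrame(meta).set_index("sample")
    return counts, samples


def gen_survival(truth, panel=("TMEM229B", "SMPDL3B", "HIVEP3", "SEMA3D"),
                 seed=None):
    """Right-censored cohort with per-gene expression columns.

    In dichotomous mode (default) the hazard is baseline * exp(beta) for
    patients whose panel mean-z score falls at or below the cohort median,
    so the true dichotomized HR (low vs high) is exactly exp(beta).  In
    continuous mode hazards are exp(sum beta_g * z_g).  Event times are
    exponential; censoring is administrative uniform on (0, censor_max).

    Returns a DataFrame with time, event and one log-scale expression
    column per panel gene.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_patients
    panel = list(panel)
    z = rng.normal(0.0, 1.0, (n, len(panel)))
    expr = pd.DataFrame(2.0 ** (8.0 + z), columns=panel)  # positive scale
    score = z.mean(axis=1)
    if truth.dichotomous:
        low = score <= np.median(score)
        log_hr = truth.beta * low.astype(float)
    else:
        beta = np.array([truth.beta_per_gene.get(g, 0.0) for g in panel])
        log_hr = z @ beta
    lam = truth.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, truth.censor_max, n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    out = pd.DataFrame({"time": time, "event": event})
    return pd.concat([out, expr], axis=1)
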