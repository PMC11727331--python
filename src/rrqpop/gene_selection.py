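"""Multi-stage selection of RR-dysregulated, siHDAC6-responsive genes.

The cascade mirrors the transcriptomic analysis of paired radioresistant
(RR) / parental (WT) cell lines with and without HDAC6 knockdown:

1. differential expression for two contrasts — RR vs WT (control
   knockdown) and siHDAC6 vs control within RR cells — thresholded at
   |log2FC| > 0.5 and BH-adjusted p < 0.1;
2. interaction analysis keeping genes whose fold-change direction is
   opposite between the two contrasts (dysregulated in RR and reversed by
   HDAC6 knockdown);
3. magnitude refinement, per cell line, keeping genes whose
   siHDAC6-induced relative change in RR exceeds that in WT by more than
   2-fold (log2 ratio > 1, sign-aligned to the response direction);
4. consensus across cell lines.

The DE stage is a deliberately simple stand-in for a full NB GLM tool: a
vectorized negative-binomial Wald test on median-of-ratios-normalized
counts with a trimmed-moment common dispersion, stratified by cell line and
combined with Stouffer's method.  Externally produced DE tables (gene,
log2fc, padj) can be supplied instead and bypass this stage entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm

__all__ = [
    "size_factors",
    "differential_expression",
    "threshold_de",
    "de_summary",
    "interaction_genes",
    "refine_by_magnitude",
    "consensus",
    "run_cascade",
]

#: default stage thresholds
LFC_MIN = 0.5
ALPHA = 0.1
REFINE_MIN_LOG2_RATIO = 1.0
#: pseudocount on normalized group means in the refinement ratios
REFINE_PSEUDOCOUNT = 1.0

CONTRASTS = ("RRvsWT", "siHDAC6vsControl-in-RR")


def size_factors(counts):
    """DESeq-style median-of-ratios normalization factors, one per sample.

    Factors are rescaled to geometric mean 1; equal-depth libraries get
    factors near 1.
    """
    mat = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.where(mat > 0, np.log(mat, where=mat > 0, out=np.full_like(mat, np.nan)), np.nan)
    ref = np.nanmean(logc, axis=1)
    ok = np.isfinite(ref)
    if ok.sum() == 0:
        raise ValueError("no gene is expressed in every sample")
    sf = np.exp(np.nanmedian(logc[ok] - ref[ok, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _common_dispersion(normed, groups):
    """Trimmed-mean NB dispersion from per-gene pooled moment estimates."""
    means, varis, ns = [], [], []
    for g in np.unique(groups):
        sub = normed[:, groups == g]
        means.append(sub.mean(axis=1))
        varis.append(sub.var(axis=1, ddof=1))
        ns.append(sub.shape[1])
    m = np.average(np.column_stack(means), axis=1, weights=ns)
    v = np.average(np.column_stack(varis), axis=1,
                   weights=[n - 1 for n in ns])
    a = (v - m) / np.maximum(m, 1e-8) ** 2
    use = m > 5
    if use.sum() < 10:
        return 0.05  # too few informative genes; plausible RNA-seq default
    lo, hi = np.quantile(a[use], [0.05, 0.95])
    return float(max(np.clip(a[use], lo, hi).mean(), 1e-8))


def _two_group_wald(normed1, normed2, alpha_nb):
    """Vectorized NB Wald test on normalized counts (genes x replicates)."""
    n1, n2 = normed1.shape[1], normed2.shape[1]
    m1 = normed1.mean(axis=1)
    m2 = normed2.mean(axis=1)
    eps = 0.5
    lfc_ln = np.log(m1 + eps) - np.log(m2 + eps)
    se = np.sqrt((1.0 / np.maximum(m1, eps) + alpha_nb) / n1
                 + (1.0 / np.maximum(m2, eps) + alpha_nb) / n2)
    return lfc_ln / np.log(2), lfc_ln / se


def _select(samples, **conditions):
    mask = pd.Series(True, index=samples.index)
    for col, val in conditions.items():
        mask &= samples[col] == val
    return samples.index[mask]


def differential_expression(counts, samples, contrast, cell_line=None):
    """Per-gene DE table for one contrast.

    Parameters
    ----------
    counts : DataFrame, genes x samples (integer counts)
    samples : DataFrame indexed by sample with columns ``cell_line``,
        ``phenotype`` (WT/RR) and ``knockdown`` (siNC/siHDAC6)
    contrast : "RRvsWT" (RR-siNC vs WT-siNC) or "siHDAC6vsControl-in-RR"
    cell_line : restrict to one line; by default both lines are analysed
        as strata and combined (mean log2FC, Stouffer z), which adjusts the
        contrast for the cell-line factor.

    Returns a DataFrame with columns gene, log2fc, pvalue, padj, direction.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {CONTRASTS}")
    for col in ("cell_line", "phenotype", "knockdown"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    if not np.issubdtype(np.asarray(counts).dtype, np.number) or np.any(
            np.asarray(counts) != np.asarray(counts).astype(int)):
        raise ValueError("counts must be integers")

    sf = size_factors(counts)
    normed_all = np.asarray(counts, dtype=float) / sf.values

    lines = [cell_line] if cell_line is not None else sorted(
        samples["cell_line"].unique())
    lfcs, zs = [], []
    for line in lines:
        if contrast == "RRvsWT":
            g1 = _select(samples, cell_line=line, phenotype="RR",
                         knockdown="siNC")
            g2 = _select(samples, cell_line=line, phenotype="WT",
                         knockdown="siNC")
        else:
            g1 = _select(samples, cell_line=line, phenotype="RR",
                         knockdown="siHDAC6")
            g2 = _select(samples, cell_line=line, phenotype="RR",
                         knockdown="siNC")
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(
                f"contrast {contrast} in line {line}: need >= 2 replicates "
                f"per group (got {len(g1)} vs {len(g2)})"
            )
        i1 = [counts.columns.get_loc(s) for s in g1]
        i2 = [counts.columns.get_loc(s) for s in g2]
        groups = np.array([0] * len(i1) + [1] * len(i2))
        sub = normed_all[:, i1 + i2]
        alpha_nb = _common_dispersion(sub, groups)
        lfc, z = _two_group_wald(normed_all[:, i1], normed_all[:, i2],
                                 alpha_nb)
        lfcs.append(lfc)
        zs.append(z)

    lfc = np.mean(lfcs, axis=0)
    z = np.sum(zs, axis=0) / np.sqrt(len(zs))
    pvalue = 2 * norm.sf(np.abs(z))
    padj = false_discovery_control(pvalue, method="bh")
    return pd.DataFrame({
        "gene": counts.index,
        "log2fc": lfc,
        "pvalue": pvalue,
        "padj": padj,
        "direction": np.where(lfc >= 0, "up", "down"),
        "contrast": contrast,
    })


def threshold_de(records, lfc_min=LFC_MIN, alpha=ALPHA):
    """Keep |log2fc| > lfc_min AND padj < alpha (both strict)."""
    keep = (records["log2fc"].abs() > lfc_min) & (records["padj"] < alpha)
    return records.loc[keep].reset_index(drop=True)


def de_summary(records):
    """(n_up, n_down, total) bookkeeping for a thresholded DE table."""
    n_up = int((records["direction"] == "up").sum())
    n_down = int((records["direction"] == "down").sum())
    return n_up, n_down, n_up + n_down


def interaction_genes(de_rr, de_sihdac6):
    """Genes DE in both contrasts with opposite fold-change direction.

    Both inputs must already be thresholded.  Returns the gene set of
    candidates dysregulated in RR and reversed by HDAC6 knockdown.
    """
    rr_dir = de_rr.set_index("gene")["direction"]
    kd_dir = de_sihdac6.set_index("gene")["direction"]
    shared = rr_dir.index.intersection(kd_dir.index)
    opposite = shared[rr_dir.loc[shared].values != kd_dir.loc[shared].values]
    return set(opposite)


def refine_by_magnitude(counts, samples, genes, cell_line,
                        response_direction, min_log2_ratio=REFINE_MIN_LOG2_RATIO,
                        signed=True):
    """Keep genes whose siHDAC6 response is > 2-fold stronger in RR than WT.

    For each gene, delta_wt = mean(WT-siHDAC6) / mean(WT-control) and
    delta_rr likewise within RR, on size-factor-normalized means with a
    pseudocount of 1.  The log2 ratio log2(delta_rr / delta_wt) is
    sign-aligned to the gene's siHDAC6 response direction in RR
    (``response_direction``: gene -> 'up'/'down'), so that a value above
    ``min_log2_ratio`` always means a stronger response in the RR cells.
    With ``signed=False`` the absolute ratio is used instead.

    Returns (retained gene set, per-gene trace DataFrame).
    """
    groups = {}
    for phen in ("WT", "RR"):
        for kd in ("siNC", "siHDAC6"):
            sel = _select(samples, cell_line=cell_line, phenotype=phen,
                          knockdown=kd)
            if len(sel) == 0:
                raise ValueError(
                    f"cell line {cell_line}: missing group {phen}/{kd}")
            groups[(phen, kd)] = sel

    sf = size_factors(counts)
    normed = counts.div(sf, axis=1)
    genes = sorted(genes)
    sub = normed.loc[genes]
    mean = {k: sub[v].mean(axis=1) + REFINE_PSEUDOCOUNT
            for k, v in groups.items()}
    delta_wt = mean[("WT", "siHDAC6")] / mean[("WT", "siNC")]
    delta_rr = mean[("RR", "siHDAC6")] / mean[("RR", "siNC")]
    log2_ratio = np.log2(delta_rr / delta_wt)
    sign = pd.Series(
        [1.0 if response_direction[g] == "up" else -1.0 for g in genes],
        index=genes,
    )
    aligned = np.abs(log2_ratio) if not signed else sign * log2_ratio
    retained = set(np.array(genes)[aligned > min_log2_ratio])
    trace = pd.DataFrame({
        "gene": genes,
        "delta_wt": delta_wt.values,
        "delta_rr": delta_rr.values,
        "log2_ratio": aligned.values,
        "retained": [g in retained for g in genes],
        "cell_line": cell_line,
    })
    return retained, trace


def consensus(retained_per_line, n_input):
    """Intersect per-line retained sets; report counts and percentages.

    ``n_input`` is the size of the gene set entering refinement; all
    percentages are of that set, rounded to one decimal.
    """
    if len(retained_per_line) < 2:
        raise ValueError("consensus requires >= 2 cell lines")
    panel = set.intersection(*map(set, retained_per_line.values()))
    rows = [
        {"stage": f"retained_{line}", "n": len(s),
         "pct": round(100.0 * len(s) / n_input, 1)}
        for line, s in sorted(retained_per_line.items())
    ]
    rows.append({"stage": "consensus", "n": len(panel),
                 "pct": round(100.0 * len(panel) / n_input, 1)})
    return panel, pd.DataFrame(rows)


def run_cascade(counts, samples, lfc_min=LFC_MIN, alpha=ALPHA,
                min_log2_ratio=REFINE_MIN_LOG2_RATIO,
                de_rr=None, de_sihdac6=None):
    """Run the full selection cascade; returns a result dict.

    ``de_rr`` / ``de_sihdac6`` allow supplying externally produced DE
    tables (columns gene, log2fc, padj and optionally direction), bypassing
    the built-in DE stage.

    The result holds the thresholded DE tables, the opposite-direction
    candidate set, per-line refinement traces, the consensus panel, the
    summary table and a per-gene SelectionTrace with the implication chain
    consensus => refined in both lines => opposite_direction => both DE.
    """
    def _prep(tab):
        tab = tab.copy()
        if "direction" not in tab.columns:
            tab["direction"] = np.where(tab["log2fc"] >= 0, "up", "down")
        return tab

    if de_rr is None:
        de_rr = differential_expression(counts, samples, "RRvsWT")
    if de_sihdac6 is None:
        de_sihdac6 = differential_expression(counts, samples,
                                             "siHDAC6vsControl-in-RR")
    de_rr, de_sihdac6 = _prep(de_rr), _prep(de_sihdac6)

    de_rr_hits = threshold_de(de_rr, lfc_min, alpha)
    de_kd_hits = threshold_de(de_sihdac6, lfc_min, alpha)
    candidates = interaction_genes(de_rr_hits, de_kd_hits)

    response_dir = de_kd_hits.set_index("gene")["direction"].to_dict()
    retained, traces = {}, {}
    for line in sorted(samples["cell_line"].unique()):
        retained[line], traces[line] = refine_by_magnitude(
            counts, samples, candidates, line, response_dir,
            min_log2_ratio=min_log2_ratio)
    panel, summary = consensus(retained, n_input=max(len(candidates), 1))

    rr_set = set(de_rr_hits["gene"])
    kd_set = set(de_kd_hits["gene"])
    lines = sorted(retained)
    trace = pd.DataFrame({"gene": counts.index})
    trace["de_rr"] = trace["gene"].isin(rr_set)
    trace["de_sihdac6"] = trace["gene"].isin(kd_set)
    trace["opposite_direction"] = trace["gene"].isin(candidates)
    for line in lines:
        trace[f"refined_{line}"] = trace["gene"].isin(retained[line])
    trace["consensus"] = trace["gene"].isin(panel)

    return {
        "de_rr": de_rr, "de_sihdac6": de_sihdac6,
        "de_rr_hits": de_rr_hits, "de_sihdac6_hits": de_kd_hits,
        "candidates": candidates, "retained": retained,
        "refine_traces": traces, "panel": panel,
        "summary": summary, "trace": trace,
    }
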