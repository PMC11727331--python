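"""End-to-end pipeline driver chaining all stages on synthetic inputs.

Each stage writes its artifacts into the run directory; a resolved config,
a structured log, a version stamp and input checksums accompany every run.
All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np

from . import design as design_mod
from . import dose_response as dr
from . import gene_selection as gs
from . import prognostic as prog
from . import qpop, radiobiology, synergy, synthetic
from .config import PipelineConfig
from .io import write_json, write_table

__all__ = ["run_pipeline"]

STAGE_ORDER = ("design", "dose_response", "qpop", "synergy", "radio",
               "select", "prognostic")


def _checksum(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig):
    """Execute the requested stages in dependency order.

    Returns the run directory (Path).  Deterministic given the config
    seed; raises on any stage error.
    """
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in config.stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=logging.INFO, format="%(message)s")
    log = logging.getLogger("rrqpop")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)

    config.dump(out / "config.yaml")
    write_json({"version": config.version}, out / "version.json")
    artifacts = {}
    truth = synthetic.default_truth(seed=config.seed,
                                    n_drugs=config.n_drugs,
                                    noise_sd=config.screen_noise_sd)
    (out / "truth.json").write_text(truth.to_json())

    oacd = None
    model = None
    try:
        for stage in stages:
            t0 = time.time()
            if stage == "design":
                oacd = design_mod.build_oacd(config.n_drugs)
                artifacts["design"] = write_table(
                    oacd.to_frame(), out / "design.csv")
            elif stage == "dose_response":
                plate = synthetic.gen_dose_response(truth)
                artifacts["plate"] = write_table(plate, out / "plate.csv",
                                                 schema="plate")
                fits = {}
                for drug, sub in plate.groupby("drug"):
                    fit = dr.fit_loglogistic(sub["dose_uM"], sub["viability"])
                    fits[drug] = {
                        "top": fit.top, "bottom": fit.bottom,
                        "hill": fit.hill, "ic50_uM": fit.ic50,
                        "converged": fit.converged,
                        "ic15_uM": dr.intrapolate_icx(fit, 15),
                        "ic30_uM": dr.intrapolate_icx(fit, 30),
                    }
                artifacts["fits"] = write_json(fits, out / "fits.json")
            elif stage == "qpop":
                if oacd is None:
                    raise RuntimeError("qpop requires the design stage first")
                screen = synthetic.gen_screen_viability(
                    truth, oacd, replicates=config.screen_replicates)
                write_table(screen, out / "screen.csv", schema="screen")
                avg = screen.groupby("run")["viability"].mean().values
                model = qpop.fit_quadratic(oacd, avg)
                ranking = qpop.enumerate_pairs(model)
                write_table(ranking.headline, out / "ranking.tsv")
                write_json({"drugs": model.drugs,
                            "coef": model.coef.tolist(),
                            "rss": model.rss, "df": model.df},
                           out / "surface_model.json")
                p, q, _ = truth.planted_pairs[0]
                surf = qpop.response_surface(model, model.drugs[p],
                                             model.drugs[q])
                write_table(surf, out / "response_surface.csv")
            elif stage == "synergy":
                planted = synthetic.gen_bliss_matrix(
                    "planted", excess=20.0, noise_sd=1.0, seed=config.seed)
                null = synthetic.gen_bliss_matrix(
                    "null", noise_sd=1.0, seed=config.seed + 1)
                rep = {}
                for name, M in (("planted", planted), ("null", null)):
                    res = synergy.bliss_score(M)
                    rep[name] = {"score": res.score, "label": res.label}
                write_json(rep, out / "bliss.json")
            elif stage == "radio":
                rng = np.random.default_rng(config.seed)
                curves = {}
                for arm, (b1, b2) in (("control", (0.20, 0.02)),
                                      ("treated", (0.35, 0.03))):
                    tab = synthetic.gen_clonogenic(
                        b1, b2, seed=int(rng.integers(2**31)))
                    grp = tab.groupby("dose_Gy")[["colonies", "plated"]].sum()
                    pe = grp["colonies"] / grp["plated"]
                    sf = pe / pe.loc[0.0]
                    curves[arm] = radiobiology.fit_lq(grp.index.values,
                                                      sf.values)
                ratio = radiobiology.sensitization_ratio(
                    curves["control"], curves["treated"],
                    at_dose=config.sensitization_dose_Gy)
                write_json({
                    arm: {"b1": c.b1, "b2": c.b2} for arm, c in
                    curves.items()} | {"sensitization_ratio": ratio,
                                       "at_dose_Gy":
                                       config.sensitization_dose_Gy},
                    out / "clonogenic.json")
            elif stage == "select":
                ct = synthetic.default_count_truth(seed=config.seed,
                                                   n_genes=config.n_genes)
                counts, samples = synthetic.gen_counts(
                    ct, n_per_group=config.n_per_group)
                (out / "count_truth.json").write_text(ct.to_json())
                result = gs.run_cascade(
                    counts, samples, lfc_min=config.de_lfc_min,
                    alpha=config.de_alpha,
                    min_log2_ratio=config.refine_min_log2_ratio)
                write_table(result["de_rr"], out / "de_rr.tsv", schema="de")
                write_table(result["trace"], out / "selection_trace.tsv")
                write_json({"panel": sorted(result["panel"])},
                           out / "panel.json")
                artifacts["select"] = result
            elif stage == "prognostic":
                st = synthetic.default_survival_truth(
                    seed=config.seed, n_patients=config.cohort_n,
                    hr=config.cohort_hr)
                cohort = synthetic.gen_survival(st)
                write_table(cohort, out / "cohort.tsv", schema="survival")
                panel = [c for c in cohort.columns
                         if c not in ("time", "event")]
                sig = prog.SignatureModel(genes=panel)
                scores, groups = prog.signature_score(
                    cohort[panel], sig)
                km = prog.km_logrank(cohort["time"], cohort["event"], groups)
                write_json({"hr_low_vs_high": km["hr_low_vs_high"],
                            "hr_ci95": list(km["hr_ci95"]),
                            "logrank_p": km["logrank_p"]},
                           out / "signature_km.json")
            log.info("stage %s done in %.2fs", stage, time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()

    checks = {p.name: _checksum(p) for p in sorted(out.iterdir())
              if p.is_file() and p.name != "checksums.json"}
    write_json(checks, out / "checksums.json")
    return out
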