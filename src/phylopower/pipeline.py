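"""End-to-end orchestration: data -> regressions -> ASR -> ancestral power.

``run_pipeline`` executes the full comparative analysis from a
:class:`RunConfig` and writes its tables and JSON bundles to the output
directory.  Every stage logs to stderr with timing; identical config +
seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asr_continuous import (fit_evolution_models, reconstruct_continuous,
                             select_and_rescale)
from .asr_discrete import fit_mk, marginal_node_likelihoods
from .dataset import (DEFAULT_BMR_THRESHOLD, align_to_tree,
                      exclude_extreme_dimorphism, load_species_table,
                      log10_standardize)
from .phyloglm import fit_phylogistic, parametric_bootstrap, significance_stars
from .power_prediction import build_ancestral_power_table
from .treeio import (graft_taxon, load_fossil_records, prune_to_taxa,
                     read_newick_file, vcv_matrix)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("phylopower")

#: predictors with a continuous ASR (estrous overlap is regression-only)
ASR_PREDICTORS = ("bmr", "cr", "sr")
ALL_PREDICTORS = ("bmr", "cr", "eo", "sr")

CLADE_ORDER = [
    "Primates", "Strepsirrhini", "Haplorhini", "Lemuriformes", "Lorisiformes",
    "Anthropoidea", "Platyrrhini", "Catarrhini", "Cercopithecoidea", "Hominoidea",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    tree: str = None                  # Newick path
    traits: str = None                # species CSV path
    clades: str = None                # clade map (YAML / JSON) path
    fossils: str = None               # optional fossil CSV path
    out: str = "results"
    predictors: tuple = ALL_PREDICTORS
    reps: int = 2000
    alpha: float = 0.05
    exclude_bmr_over: float = DEFAULT_BMR_THRESHOLD
    mk_structure: str = "ER"
    seed: int = 0

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def digest(self) -> str:
        # the output path is not analysis-relevant: identical analyses into
        # different directories must produce identical result files
        payload = {k: v for k, v in asdict(self).items() if k != "out"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_clade_map(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        return {k: list(v) for k, v in yaml.safe_load(text).items()}
    return {k: list(v) for k, v in json.loads(text).items()}


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("glm")
def _run_glm(tree, table, predictor, reps, alpha, seed):
    sub = table.predictor(predictor)
    keep = list(sub["species"])
    ptree = prune_to_taxa(tree, keep)
    order = ptree.tip_labels
    sub = sub.set_index("species").loc[order].reset_index()
    y = (sub["power"] == "MD").astype(float).to_numpy()
    z, std = log10_standardize(sub[predictor].to_numpy())
    labels, V = vcv_matrix(ptree)
    fit = fit_phylogistic(y, z, V)
    boot = parametric_bootstrap(fit, ptree, z, reps=reps, alpha=alpha, seed=seed)
    return {"tree": ptree, "fit": fit, "boot": boot, "standardization": std,
            "n": len(y)}


@_stage("asr-continuous")
def _run_asr_continuous(tree, table, predictor, alpha):
    sub = table.predictor(predictor, require_power=False)
    ptree = prune_to_taxa(tree, list(sub["species"]))
    order = ptree.tip_labels
    vals = np.log10(sub.set_index("species").loc[order, predictor].to_numpy())
    fits = fit_evolution_models(ptree, vals)
    rescaled = select_and_rescale(fits, ptree, alpha=alpha)
    est = reconstruct_continuous(rescaled, vals)
    return {"tree": ptree, "fits": fits, "estimates": est}


@_stage("asr-discrete")
def _run_asr_discrete(tree, table, structure):
    lab = table.frame.dropna(subset=["power"])
    ptree = prune_to_taxa(tree, list(lab["species"]))
    states = dict(zip(lab["species"], lab["power"]))
    fit = fit_mk(ptree, states, structure=structure,
                 state_set=("MD", "CD", "FD"))
    lik = marginal_node_likelihoods(fit, ptree, states)
    return {"tree": ptree, "fit": fit, "likelihoods": lik}


def _table2_rows(results, dataset_label):
    rows = []
    names = {"bmr": "Body mass dimorphism", "cr": "Canine length dimorphism",
             "eo": "Expected estrous overlap", "sr": "Sex ratio"}
    for pred, res in results.items():
        fit, boot = res["fit"], res["boot"]
        rows.append({
            "dataset": dataset_label,
            "predictor": names[pred],
            "estimate": fit.b1,
            "se": fit.se_b1,
            "t": abs(fit.t1),
            "p_boot": boot.p_b1,
            "stars": significance_stars(boot.p_b1),
            "b0_boot_mean": boot.mean_b0,
            "b1_boot_mean": boot.mean_b1,
            "n": res["n"],
        })
    return rows


def run_pipeline(config: RunConfig, tree=None, table=None, clade_map=None):
    """Run the whole analysis; returns the results bundle and writes files.

    ``tree``/``table``/``clade_map`` may be passed in memory (e.g. from the
    synthetic fixture); otherwise they are loaded from the configured paths.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    if tree is None:
        tree = read_newick_file(config.tree)
    if table is None:
        table = load_species_table(config.traits)
    if clade_map is None:
        clade_map = load_clade_map(config.clades)
    if config.fossils:
        for rec in load_fossil_records(config.fossils):
            tree = graft_taxon(tree, rec)
    table, report = align_to_tree(table, tree.tip_labels)
    if report["table_only"] or report["tree_only"]:
        log.warning("species only in table: %s; only in tree: %s",
                    report["table_only"], report["tree_only"])
    tree = prune_to_taxa(tree, [s for s in table.species])

    seeds = np.random.SeedSequence(config.seed).generate_state(16) % (2**31)
    # per-predictor phylogenetic logistic regression + bootstrap
    glm = {}
    for i, pred in enumerate(config.predictors):
        glm[pred] = _run_glm(tree, table, pred, config.reps, config.alpha,
                             int(seeds[i]))
    # reduced analysis mirroring the extreme-dimorphism exclusion (EO, SR)
    reduced_table = exclude_extreme_dimorphism(table, config.exclude_bmr_over)
    glm_reduced = {}
    for j, pred in enumerate(p for p in ("eo", "sr") if p in config.predictors):
        glm_reduced[pred] = _run_glm(tree, reduced_table, pred, config.reps,
                                     config.alpha, int(seeds[8 + j]))

    disc = _run_asr_discrete(tree, table, config.mk_structure)
    cont = {}
    for pred in (p for p in ASR_PREDICTORS if p in config.predictors):
        cont[pred] = _run_asr_continuous(tree, table, pred, config.alpha)

    coeffs = {p: (glm[p]["boot"].mean_b0, glm[p]["boot"].mean_b1) for p in cont}
    power_table = build_ancestral_power_table(
        discrete=(disc["tree"], disc["likelihoods"]),
        continuous={p: (cont[p]["tree"], cont[p]["estimates"]) for p in cont},
        coefficients=coeffs,
        clade_map=clade_map,
        clade_order=[c for c in CLADE_ORDER if c in clade_map] or None,
    )

    meta = {"config_hash": config.digest(), "seed": config.seed,
            "version": __version__}
    t2 = pd.DataFrame(_table2_rows(glm, "All primates")
                      + _table2_rows(glm_reduced, "Excluding extremely dimorphic taxa"))
    t2.round(4).to_csv(outdir / "regression_table.csv", index=False)
    power_table.round(4).to_csv(outdir / "ancestral_power_table.csv", index=False)
    bundle = {
        **meta,
        "glm": {p: {"fit": r["fit"].to_dict(), "bootstrap": r["boot"].to_dict()}
                for p, r in glm.items()},
        "glm_reduced": {p: {"fit": r["fit"].to_dict(),
                            "bootstrap": r["boot"].to_dict()}
                        for p, r in glm_reduced.items()},
        "mk": {"lnL": disc["fit"].lnL, "structure": disc["fit"].structure,
               "Q": disc["fit"].Q.tolist()},
        "model_selection": {
            p: [{"model": f.model, "lnL": f.lnL, "aic": f.aic,
                 "shape": f.shape, "lrt_p": f.lrt_p}
                for f in cont[p]["fits"]] for p in cont
        },
    }
    (outdir / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return {"meta": meta, "glm": glm, "glm_reduced": glm_reduced,
            "discrete": disc, "continuous": cont, "power_table": power_table}
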