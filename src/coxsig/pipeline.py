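"""End-to-end pipeline: deregulation filter -> OS screen -> resampling
selection -> signature build -> validation, with every intermediate table
persisted and a deterministic manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__, io as cio
from .deg import consistent_deg, per_cohort_deg
from .exceptions import CoxsigError
from .resample import ResamplePlan, build_signature, concordance_saturation, select_frequency
from .scoring import validate_cohort
from .screen import univariate_screen
from .simulate import GenerativeSpec, gen_study

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "fc_threshold": 5.0,
    "alpha": 0.05,
    "n_splits": 100,
    "train_fraction": 2.0 / 3.0,
    "saturation_tol": 0.005,
    "saturation_patience": 3,
    "max_k": None,
    "stages": ["deg", "screen", "select", "build", "validate"],
    "simulate": {},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> Path:
    """Run the configured stages in order, writing all artifacts plus a
    manifest (versions, seeds, thresholds, artifact hashes) to ``out_dir``.

    The run is a pure function of the config: re-running with the same
    config reproduces bit-identical artifacts and manifest.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    plan = ResamplePlan(cfg["n_splits"], cfg["train_fraction"], cfg["seed"])

    # ---- inputs: simulate or load ----
    if "inputs" in cfg and cfg["inputs"]:
        paths = cfg["inputs"]
        de_cohorts = [
            cio.load_expression(e, c)
            for e, c in zip(paths.get("deg_expr", []), paths.get("deg_class", []))
        ]
        disc_expr = cio.load_expression(paths["discovery_expr"], paths.get("discovery_class"))
        disc_surv = cio.load_clinical(paths["discovery_clinical"])
        validation = [
            (cio.load_expression(e, c2), cio.load_clinical(c))
            for e, c2, c in zip(
                paths.get("validation_expr", []),
                paths.get("validation_class", [None] * 9),
                paths.get("validation_clinical", []),
            )
        ]
    else:
        spec = GenerativeSpec(**{**cfg["simulate"], "seed": cfg["seed"]})
        bundle = gen_study(spec)
        de_cohorts = bundle.de_cohorts
        disc_expr, disc_surv = bundle.discovery_expr, bundle.discovery_surv
        validation = bundle.validation

    artifacts: dict[str, Path] = {}

    # ---- stage 1: multi-cohort deregulation filter ----
    genes = list(disc_expr.gene_ids)
    if "deg" in stages:
        tables = [per_cohort_deg(c, cfg["fc_threshold"], cfg["alpha"]) for c in de_cohorts]
        for t in tables:
            p = out / f"deg_{t.cohort_name}.tsv"
            t.table.to_csv(p, sep="\t")
            artifacts[p.name] = p
        consistent = consistent_deg(tables)
        p = out / "consistent_genes.tsv"
        consistent.to_csv(p, sep="\t")
        artifacts[p.name] = p
        genes = list(consistent.index)
        log.info("deg: %d consistent genes", len(genes))

    # ---- stage 2: univariate OS screen ----
    if "screen" in stages:
        screen = univariate_screen(disc_expr, disc_surv, genes, cfg["alpha"])
        p = out / "screen.tsv"
        screen.table.to_csv(p, sep="\t")
        artifacts[p.name] = p
        genes = list(screen.passed_genes)
        log.info("screen: %d genes pass", len(genes))

    model = None
    if "select" in stages or "build" in stages:
        if len(genes) == 0:
            raise CoxsigError("no candidate genes survive the screen")
        sel = select_frequency(genes, disc_expr, disc_surv, plan, cfg["alpha"])
        p = out / "selection_counts.tsv"
        pd.DataFrame(
            {"selection_count": sel.counts, "mean_abs_coef": sel.mean_abs_coef}
        ).loc[sel.ranked_genes].to_csv(p, sep="\t", index_label="gene_id")
        artifacts[p.name] = p
        profile = concordance_saturation(
            sel.ranked_genes, disc_expr, disc_surv, plan,
            tol=cfg["saturation_tol"], patience=cfg["saturation_patience"],
            max_k=cfg["max_k"],
        )
        p = out / "concordance_profile.tsv"
        pd.DataFrame({"k": profile.k, "mean_c": profile.mean_c}).to_csv(p, sep="\t", index=False)
        artifacts[p.name] = p
        top = sel.ranked_genes[: profile.k_star]

        if "build" in stages:
            model = build_signature(top, disc_expr, disc_surv, plan)
            p = out / "signature.json"
            model.to_json(p)
            artifacts[p.name] = p

    if "validate" in stages and model is not None:
        reports = {}
        for name, (e, s) in [("discovery", (disc_expr, disc_surv))] + [
            (f"validation{i}", v) for i, v in enumerate(validation)
        ]:
            rep = validate_cohort(model, e, s)
            reports[name] = rep.to_dict()
            pd.DataFrame({"score": rep.scores, "group": rep.groups}).to_csv(
                out / f"scores_{name}.tsv", sep="\t", index_label="sample_id"
            )
            artifacts[f"scores_{name}.tsv"] = out / f"scores_{name}.tsv"
        p = out / "validation.json"
        with open(p, "w") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts[p.name] = p

    manifest = {
        "software": {"coxsig": __version__},
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "artifacts": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out
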