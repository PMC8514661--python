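"""End-to-end orchestration: one YAML config drives both study arms.

The human arm runs simulate (or load) -> per-region score construction ->
random-SNP control score -> association battery.  The mouse arm runs
simulate (or load) -> behavioral composites and group statistics ->
2^-ddCt quantification -> permutation ANOVA, pairwise tests and the
behavior-expression correlogram.  A run manifest records seeds, input
digests and output paths so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rriscore import __version__
from rriscore.association import derive_cm, derive_sdq, run_battery
from rriscore.io_formats import read_genotypes, read_table, write_genotypes, write_table
from rriscore.mouse import derive_behavior, group_stats, sex_ratio_fisher
from rriscore.qpcr import (
    build_correlogram,
    pairwise_permutation_tests,
    permutation_factorial_anova,
    quantify_expression,
)
from rriscore.scores import build_control_score, build_rri, combine_scores
from rriscore.synthetic import (
    HumanSimSpec,
    LDBlock,
    MouseSimSpec,
    OutcomeSpec,
    simulate_human_cohort,
    simulate_mouse_cohort,
    truth_to_yaml_dict,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def human_spec_from_dict(d: dict) -> HumanSimSpec:
    d = dict(d)
    if "ld_blocks" in d:
        d["ld_blocks"] = tuple(LDBlock(**b) for b in d["ld_blocks"])
    if "outcome_specs" in d:
        d["outcome_specs"] = {k: OutcomeSpec(**v) for k, v in d["outcome_specs"].items()}
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    if "cm_probs" in d:
        d["cm_probs"] = tuple(d["cm_probs"])
    return HumanSimSpec(**d)


def mouse_spec_from_dict(d: dict) -> MouseSimSpec:
    d = dict(d)
    for key in ("genes", "ms_sex", "ns_sex"):
        if key in d:
            d[key] = tuple(d[key])
    return MouseSimSpec(**d)


def _load_or_simulate_human(cfg: dict, out: Path, manifest: dict):
    if ("sim" in cfg) == ("paths" in cfg):
        raise ValueError("human arm needs exactly one of 'sim' or 'paths'")
    if "sim" in cfg:
        spec = human_spec_from_dict(cfg["sim"])
        genotypes, covariates, phenotypes, truth = simulate_human_cohort(spec)
        write_genotypes(genotypes, out / "genotypes.tsv")
        write_table(covariates, out / "covariates.tsv")
        write_table(phenotypes, out / "phenotypes.tsv")
        with open(out / "human_truth.yaml", "w") as fh:
            yaml.safe_dump(truth_to_yaml_dict(truth), fh, default_flow_style=None)
        manifest["human_inputs"] = {"simulated": True, "seed": spec.seed}
    else:
        p = cfg["paths"]
        genotypes = read_genotypes(p["genotypes"], p.get("genotype_format", "plink_raw_tsv"))
        covariates = read_table(p["covariates"], "covariates")
        phenotypes = read_table(p["phenotypes"], "phenotypes")
        manifest["human_inputs"] = {k: _sha256(Path(v)) for k, v in p.items() if Path(str(v)).exists()}
    return genotypes, covariates, phenotypes


def run_human_arm(cfg: dict, out: Path, manifest: dict) -> None:
    stage = "load-human"
    try:
        genotypes, covariates, phenotypes = _load_or_simulate_human(cfg, out, manifest)
        cov = covariates.set_index("subject_id").loc[genotypes.subject_ids].reset_index()
        phe = phenotypes.set_index("subject_id").loc[genotypes.subject_ids].reset_index()

        stage = "build-score"
        alpha = cfg.get("alpha", 0.1)
        r2 = cfg.get("r2_cutoff", 0.5)
        cand = [s for s in genotypes.snp_ids if genotypes.snp_meta.loc[s, "category"] == "candidate"]
        cand = cand or None
        regions = {"hippocampus": "hippocampus_ml", "mpfc": "mpfc_ml"}
        score_frames = {}
        for region, col in regions.items():
            defn, scores, _ = build_rri(
                genotypes, phe[col], cov, region, snp_ids=cand, alpha=alpha, r2_cutoff=r2
            )
            with open(out / f"score_{region}.yaml", "w") as fh:
                yaml.safe_dump(defn.to_dict(), fh)
            write_table(scores, out / f"scores_{region}.tsv")
            score_frames[region] = scores
        hm = combine_scores(score_frames["hippocampus"], score_frames["mpfc"])
        write_table(hm, out / "scores_combined.tsv")

        stage = "control-score"
        ctrl_cfg = cfg.get("control", {})
        pool = [s for s in genotypes.snp_ids if genotypes.snp_meta.loc[s, "category"] != "candidate"]
        pool = pool or None
        control_scores = None
        try:
            c_defn, control_scores, _, _ = build_control_score(
                genotypes,
                phe["hippocampus_ml"],
                cov,
                "hippocampus",
                pool=pool,
                n_snps=ctrl_cfg.get("n_snps", min(674, len(pool or genotypes.snp_ids))),
                seed=ctrl_cfg.get("seed", 0),
                alpha=alpha,
                r2_cutoff=r2,
            )
            with open(out / "score_control.yaml", "w") as fh:
                yaml.safe_dump(c_defn.to_dict(), fh)
            write_table(control_scores, out / "scores_control.tsv")
        except Exception as exc:  # a null panel may legitimately yield no score
            log.warning("control score could not be built: %s", exc)
            manifest["control_score"] = f"not built: {exc}"

        stage = "associate"
        cm = derive_cm(phe[[f"ctq{i}" for i in range(1, 7)]])
        es, is_ = derive_sdq(
            phe["sdq_conduct"], phe["sdq_hyperactivity"], phe["sdq_emotional"], phe["sdq_peer"]
        )
        outcomes = pd.DataFrame(
            {
                "depband": phe["depband"],
                "es": es,
                "is": is_,
                "cape_pds": phe["cape_pds"],
                "cape_nds": phe["cape_nds"],
                "cape_dds": phe["cape_dds"],
            }
        )
        scores = {
            "HRRI": score_frames["hippocampus"]["score"],
            "MRRI": score_frames["mpfc"]["score"],
            "HMRRI": hm["score"],
        }
        battery = run_battery(scores, outcomes, cov["sex"].to_numpy(), cm, cfg.get("fdr_families"))
        write_table(battery, out / "battery.tsv")
        if control_scores is not None:
            ctrl_battery = run_battery(
                {"CONTROL": control_scores["score"]}, outcomes, cov["sex"].to_numpy(), cm
            )
            write_table(ctrl_battery, out / "battery_control.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def run_mouse_arm(cfg: dict, out: Path, manifest: dict) -> None:
    stage = "load-mouse"
    try:
        if ("sim" in cfg) == ("paths" in cfg):
            raise ValueError("mouse arm needs exactly one of 'sim' or 'paths'")
        if "sim" in cfg:
            spec = mouse_spec_from_dict(cfg["sim"])
            behavior, ct_table, truth = simulate_mouse_cohort(spec)
            write_table(behavior, out / "mouse_behavior.tsv")
            write_table(ct_table, out / "mouse_qpcr_ct.tsv")
            with open(out / "mouse_truth.yaml", "w") as fh:
                yaml.safe_dump(truth_to_yaml_dict(truth), fh, default_flow_style=None)
            manifest["mouse_inputs"] = {"simulated": True, "seed": spec.seed}
        else:
            p = cfg["paths"]
            behavior = read_table(p["behavior"], "mouse_behavior")
            ct_table = read_table(p["qpcr_ct"], "qpcr_ct")
            manifest["mouse_inputs"] = {k: _sha256(Path(v)) for k, v in p.items()}

        stage = "mouse-behavior"
        derived = derive_behavior(behavior)
        write_table(derived, out / "mouse_zscores.tsv")
        stats = group_stats(derived)
        stats["sex_ratio_fisher_p"] = sex_ratio_fisher(behavior)
        write_table(stats, out / "mouse_behavior_stats.tsv")

        stage = "qpcr"
        expr = quantify_expression(
            ct_table,
            behavior[["animal_id", "group"]],
            reference_gene=cfg.get("reference_gene", "Rab5a"),
        )
        write_table(expr, out / "expression.tsv")
        n_perm = cfg.get("n_perm", 999)
        seed = cfg.get("seed", 0)
        anova = permutation_factorial_anova(expr, n_perm=n_perm, seed=seed)
        with open(out / "expression_anova.json", "w") as fh:
            json.dump(
                {k: anova[k] for k in ("gene", "group", "interaction")}, fh, indent=2
            )
        pairwise = pairwise_permutation_tests(expr, n_perm=n_perm, seed=seed)
        write_table(pairwise, out / "expression_pairwise.tsv")

        stage = "correlogram"
        wide = expr.pivot(index="animal_id", columns="gene", values="rel_level")
        wide["Z_Behavior"] = derived.set_index("animal_id").loc[wide.index, "depression_index"]
        cg = build_correlogram(wide)
        cg.r.to_csv(out / "correlogram_r.tsv", sep="\t")
        cg.p.to_csv(out / "correlogram_p.tsv", sep="\t")
        cg.mask.to_csv(out / "correlogram_mask.tsv", sep="\t")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured arms end to end; returns the run manifest.

    ``config`` is a dict or a YAML path with optional ``human`` and
    ``mouse`` sections (each with ``sim`` or ``paths``) and an
    ``out_dir``.  Outputs and ``manifest.json`` are written under
    ``out_dir``; any stage error aborts with the stage name, leaving
    earlier outputs in place.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir or config.get("out_dir", "rri_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config}
    if "human" in config:
        run_human_arm(config["human"], out, manifest)
    if "mouse" in config:
        run_mouse_arm(config["mouse"], out, manifest)
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
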