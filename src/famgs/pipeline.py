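"""End-to-end driver: simulate (optional) -> QC -> family GWAS -> sibling
association -> candidate selection -> prioritization -> GS build (discovery)
-> GS evaluation (validation) -> bootstrap reports.

Each stage writes a TSV artifact (header plus a comment line carrying the
config hash) into the output directory and appends a count line to
``pipeline.log``; rerunning with the same config is byte-identical.  Stages
are exposed individually so any of them can be re-run from its
predecessor's files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fileio
from .bootstrap import bootstrap_statistic
from .cohort import FamilyCohort
from .gee import gee_logistic, run_sibling_tests, select_candidates
from .liability import LiabilityParams
from .prioritize import GeneMappingRules, prioritize
from .qc import QCThresholds, apply_qc
from .score import compute_gs, evaluate_gs, select_best_model
from .simulate import CausalSNP, SimulationParams, simulate_evidence, simulate_families, simulate_annotation
from .transmission import run_family_gwas

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "genome_wide_threshold"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def genome_wide_threshold(base: float = 5e-8, n_analyses: int = 4) -> float:
    """Genome-wide significance threshold Bonferroni-corrected for running
    several GWA analyses (four in the discovery design): base / n."""
    if n_analyses < 1:
        raise ValueError("n_analyses must be >= 1")
    return base / n_analyses


_DEFAULTS = {
    "output_dir": "famgs_out",
    "seed": 0,
    "qc": {"hwe_p_min": 1e-3, "call_rate_min": 0.90, "maf_min": 0.05},
    "selection": {"p_family_max": 1e-3, "p_sibling_max": 0.05},
    "scoring": {"cutoff": 4.0, "proximal_bp": 5000, "extended_bp": 50000},
    "liability": {
        "male": {"K": 1.0 / 54, "K_R": 0.259},
        "female": {"K": 1.0 / 252, "K_R": 0.096},
    },
    "bootstrap": {"B": 1000, "enabled": True},
    "evidence": {"p_true": 0.9, "p_false": 0.05},
    "evaluation": {"ascertainment_correction": True, "min_affected": 2,
                   "mc_target_children": 30_000},
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in (over or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated view over the YAML config mapping."""

    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(_merge(_DEFAULTS, d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(fileio.load_config(path))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.raw["qc"])

    @property
    def mapping_rules(self) -> GeneMappingRules:
        s = self.raw["scoring"]
        return GeneMappingRules(int(s["proximal_bp"]), int(s["extended_bp"]))

    @property
    def liability_params(self) -> dict[str, LiabilityParams]:
        return {
            sex: LiabilityParams(float(d["K"]), float(d["K_R"]))
            for sex, d in self.raw["liability"].items()
        }

    def simulation_params(self, which: str) -> SimulationParams:
        sim = self.raw["simulate"]
        causal = tuple(
            CausalSNP(
                int(c["index"]), str(c["model"]), float(c["beta"]),
                maf=(None if c.get("maf") is None else float(c["maf"])),
            )
            for c in sim.get("causal", [])
        )
        cpf = sim.get("children_per_family", (2, 4))
        if isinstance(cpf, list):
            cpf = tuple(cpf)
        return SimulationParams(
            n_families=int(sim[f"n_families_{which}"]),
            children_per_family=cpf,
            n_snps=int(sim.get("n_snps", 500)),
            maf_range=tuple(sim.get("maf_range", (0.05, 0.5))),
            causal=causal,
            shared_sib_var=float(sim.get("shared_sib_var", 0.0)),
            male_prevalence=float(sim.get("male_prevalence", 1.0 / 54)),
            female_prevalence=float(sim.get("female_prevalence", 1.0 / 252)),
            ascertainment_min_affected=int(sim.get("ascertainment_min_affected", 2)),
            missing_rate=float(sim.get("missing_rate", 0.0)),
            genotype_error_rate=float(sim.get("genotype_error_rate", 0.0)),
            seed=self.seed + (0 if which == "discovery" else 1),
        )

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _grr_statistic(gs_models: dict, sex: str):
    """Statistic closure for the bootstrap: GRR of the frozen GS in one sex."""
    from .cohort import AFFECTED, FEMALE, MALE, UNAFFECTED

    model = gs_models[sex]

    def stat(cohort: FamilyCohort) -> float:
        ind = cohort.individuals
        ch = cohort.child_rows
        status = ind["status"].to_numpy()[ch]
        sexes = ind["sex"].to_numpy()[ch]
        want = {"male": sexes == MALE, "female": sexes == FEMALE}.get(
            sex, np.ones(len(ch), bool)
        )
        keep = want & np.isin(status, (AFFECTED, UNAFFECTED))
        rows = ch[keep]
        y = (status[keep] == AFFECTED).astype(float)
        scores, _ = compute_gs(cohort, model, rows)
        X = np.column_stack([np.ones_like(scores), scores])
        fit = gee_logistic(y, X, ind["fid"].to_numpy()[rows], ["intercept", "score"])
        if fit.non_estimable:
            return np.nan
        return fit.odds_ratio

    return stat


def run_pipeline(config: PipelineConfig | dict) -> Path:
    """Execute every stage in order; returns the output directory.

    The config must contain either a ``simulate`` block (cohorts generated
    in-process) or a ``paths`` block pointing at existing PED/MAP,
    annotation and evidence files.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    tag = f"famgs config={config.config_hash}"
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r}: {exc}") from exc

        return _Ctx()

    # ---------------------------------------------------------------- inputs
    with stage("simulate"):
        if "simulate" in config.raw:
            disc = simulate_families(config.simulation_params("discovery"))
            valid = simulate_families(config.simulation_params("validation"))
            sim = config.raw["simulate"]
            causal_ids = [
                disc.snps["snp"].iloc[int(c["index"])] for c in sim.get("causal", [])
            ]
            annotation = simulate_annotation(disc)
            ev = config.raw["evidence"]
            evidence = simulate_evidence(
                disc, set(causal_ids), float(ev["p_true"]), float(ev["p_false"]),
                seed=config.seed + 2, annotation=annotation,
            )
            fileio.write_ped_map(disc, out / "discovery.ped", out / "discovery.map")
            fileio.write_ped_map(valid, out / "validation.ped", out / "validation.map")
            fileio.write_results_table(annotation, out / "annotation.tsv", tag)
            fileio.write_results_table(evidence, out / "evidence.tsv", tag)
            log(f"simulate: discovery {disc.n_families} families, "
                f"validation {valid.n_families}, {disc.n_snps} SNPs, "
                f"{len(causal_ids)} causal")
        else:
            paths = config.raw["paths"]
            disc = fileio.read_ped_map(paths["discovery_ped"], paths["discovery_map"])
            valid = fileio.read_ped_map(paths["validation_ped"], paths["validation_map"])
            annotation = fileio.read_annotation(paths["annotation"])
            evidence = fileio.read_evidence(paths["evidence"])
            log(f"load: discovery {disc.n_families} families, "
                f"validation {valid.n_families}, {disc.n_snps} SNPs")

    with stage("qc"):
        disc, qc_report, mendel_log = apply_qc(disc, config.qc_thresholds)
        fileio.write_results_table(qc_report, out / "qc_report.tsv", tag)
        fileio.write_results_table(mendel_log, out / "mendel_log.tsv", tag)
        keep = set(disc.snps["snp"])
        valid = valid.subset_snps(valid.snps["snp"].isin(keep).to_numpy())
        log(f"qc: {int(qc_report['pass'].sum())}/{len(qc_report)} SNPs pass; "
            f"{len(mendel_log)} Mendel errors masked")

    with stage("family_gwas"):
        fam = run_family_gwas(disc)
        fileio.write_results_table(fam, out / "family_assoc.tsv", tag)
        log(f"family_gwas: {len(fam)} tests over {disc.n_snps} SNPs")

    with stage("sibling_assoc"):
        p_fam = float(config.raw["selection"]["p_family_max"])
        sib = run_sibling_tests(disc, fam, p_fam)
        fileio.write_results_table(sib, out / "sibling_assoc.tsv", tag)
        log(f"sibling_assoc: {len(sib)} fits for family hits at p<{p_fam:g}")

    with stage("select"):
        cand = select_candidates(
            fam, sib, p_fam, float(config.raw["selection"]["p_sibling_max"])
        )
        fileio.write_results_table(cand, out / "candidates.tsv", tag)
        log(f"select: {cand['snp'].nunique() if len(cand) else 0} candidate SNPs")

    with stage("prioritize"):
        cards = prioritize(
            cand, evidence, annotation, disc.snps,
            float(config.raw["scoring"]["cutoff"]), config.mapping_rules,
        )
        fileio.write_results_table(cards, out / "scorecards.tsv", tag)
        selected = sorted(set(cards.loc[cards["snp_selected"], "snp"])) if len(cards) else []
        log(f"prioritize: {len(selected)} SNPs at score >= "
            f"{config.raw['scoring']['cutoff']}")

    with stage("gs_build"):
        if not selected:
            raise ValueError("no SNPs survived prioritization")
        best = cand[cand["is_best"] & cand["snp"].isin(selected)]
        entries = [(r["snp"], r["risk_allele"] == "a1") for _, r in best.iterrows()]
        gs_models = {}
        for sex in ("male", "female"):
            m = select_best_model(disc, entries, sex, direction_filter=True)
            gs_models[sex] = m
            fileio.write_results_table(
                pd.DataFrame(
                    [
                        {"snp": e.snp, "risk_allele": "a1" if e.risk_is_a1 else "a2",
                         "model": e.model, "sex": sex}
                        for e in m.entries
                    ],
                    columns=["snp", "risk_allele", "model", "sex"],
                ),
                out / f"gs_model_{sex}.tsv", tag,
            )
            log(f"gs_build[{sex}]: {len(m.entries)} SNPs retained")

    with stage("gs_eval"):
        if valid.n_families == 0:
            raise ValueError("validation cohort is empty")
        usable = {s: m for s, m in gs_models.items() if m.entries}
        ev_cfg = config.raw["evaluation"]
        results = evaluate_gs(
            valid, usable, config.liability_params,
            correct_ascertainment=bool(ev_cfg["ascertainment_correction"]),
            min_affected=int(ev_cfg["min_affected"]),
            mc_seed=config.seed + 20,
            mc_target_children=int(ev_cfg["mc_target_children"]),
        )
        fileio.write_results_table(
            pd.DataFrame([r.__dict__ for r in results.values()]),
            out / "gs_evaluation.tsv", tag,
        )
        for sex, r in results.items():
            log(
                f"gs_eval[{sex}]: AUC={r.auc:.3f} v={r.v:.4f} h2={r.h2:.3f} "
                f"gve={r.genetic_variance_explained:.4f} GRR={r.grr:.3f} p={r.p:.3g}"
            )

    if config.raw["bootstrap"].get("enabled", True):
        with stage("bootstrap"):
            B = int(config.raw["bootstrap"]["B"])
            rows = []
            for k, sex in enumerate(usable):
                res = bootstrap_statistic(
                    valid, _grr_statistic(gs_models, sex), B=B,
                    seed=config.seed + 10 + k,
                )
                rows.append(
                    {
                        "sex": sex, "B": B, "grr_observed": res.observed,
                        "grr_boot_mean": res.mean, "inflation": res.inflation,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "n_redrawn": res.n_redrawn,
                    }
                )
            fileio.write_results_table(
                pd.DataFrame(rows), out / "bootstrap_grr.tsv", tag
            )
            log(f"bootstrap: B={B} per sex")

    (out / "pipeline.log").write_text(
        "\n".join([f"# {tag}"] + log_lines) + "\n"
    )
    return out
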