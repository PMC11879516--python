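"""End-to-end orchestration of the daily-life G×E sensitivity analysis.

The full sequence: generate (or load) genotypes, summary statistics and ESM
data → ancestry principal components → clumping + thresholding polygenic
scores → momentary indices → per (outcome × context × threshold) time-lagged
random-intercept screening models → Benjamini–Hochberg FDR within each
(outcome × context) family across the score thresholds → for FDR-significant
interactions, covariate trimming followed by the six-model crossover
competition.  The report enumerates every planned cell exactly once, with
either estimates or a logged failure reason, and is byte-identical under a
fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import esm as esm_mod
from . import synth as synth_mod
from .gxe import classify
from .lmm import DesignSpec, fit_ml, trim_covariates, wald_tests
from .prs import GenotypeDosageMatrix, clump, score

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisPlan",
    "StudyConfig",
    "fdr_adjust",
    "ancestry_pcs",
    "run",
    "validate_report",
    "write_report",
    "load_config",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisPlan:
    """Which cells the screening phase enumerates and how it is corrected."""

    outcomes: tuple[str, ...] = ("paranoia", "ple", "negative_like", "na", "pa")
    contexts: tuple[str, ...] = ("positive", "stressful")
    prs_thresholds: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)
    alpha: float = 0.05


@dataclass(frozen=True)
class StudyConfig:
    synth: synth_mod.SynthConfig = field(default_factory=synth_mod.SynthConfig)
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    clump_r2: float = 0.1
    clump_window_kb: float = 1000.0
    n_ancestry_pcs: int = 2
    n_boot: int = 500


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ancestry_pcs(geno: GenotypeDosageMatrix, k: int = 2) -> pd.DataFrame:
    """Top-k principal components of the column-standardized dosage matrix.

    Signs are fixed by making each component's largest-magnitude SNP loading
    positive, so the output does not depend on SVD sign conventions.
    """
    if k == 0:
        return pd.DataFrame(index=pd.Index(geno.subject_ids, name="subject_id"))
    if geno.n_subjects < k + 1:
        raise ValueError(f"need at least {k + 1} subjects for {k} components")
    d = geno.imputed()
    sd = d.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all SNPs monomorphic; ancestry components undefined")
    z = (d[:, keep] - d[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(min(k, vt.shape[0])):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(
        scores, index=pd.Index(geno.subject_ids, name="subject_id"), columns=cols
    )


def _screen_cell(pairs: pd.DataFrame, pc_cols: tuple[str, ...]) -> dict:
    spec = DesignSpec(outcome="y", fixed=("G", "E", "GxE", *pc_cols))
    fit = fit_ml(pairs, spec)
    tests = wald_tests(fit)
    return {
        "n_pairs": int(fit.n_obs),
        "n_subjects": int(fit.n_groups),
        "estimate_g": float(fit.params["G"]),
        "se_g": float(fit.bse["G"]),
        "estimate_e": float(fit.params["E"]),
        "se_e": float(fit.bse["E"]),
        "estimate_gxe": float(fit.params["GxE"]),
        "se_gxe": float(fit.bse["GxE"]),
        "z_gxe": float(tests.loc["GxE", "z"]),
        "p_gxe": float(tests.loc["GxE", "p"]),
    }


def run(config: StudyConfig) -> dict:
    """Execute the full study analogue; returns the report bundle."""
    plan = config.plan
    scfg = config.synth

    logger.info("stage: synthetic genotypes")
    geno = synth_mod.simulate_genotypes(scfg)
    stats = synth_mod.simulate_summary_stats(geno.snp_map, scfg)

    logger.info("stage: ancestry components")
    pcs = ancestry_pcs(geno, k=config.n_ancestry_pcs)
    pc_cols = tuple(pcs.columns)

    logger.info("stage: polygenic scores")
    retained = clump(stats, geno, r2_max=config.clump_r2, window_kb=config.clump_window_kb)
    profile = score(geno, stats, retained, list(plan.prs_thresholds))

    logger.info("stage: experience sampling")
    esm_df, truth = synth_mod.simulate_esm(profile, scfg)
    data = esm_mod.build_indices(esm_df)
    data = data.merge(pcs.reset_index(), on="subject_id", how="left")

    logger.info("stage: screening models")
    cells: list[dict] = []
    pair_cache: dict[tuple[str, str, float], pd.DataFrame] = {}
    for outcome in plan.outcomes:
        for context in plan.contexts:
            for tau in plan.prs_thresholds:
                cell = {"outcome": outcome, "context": context, "threshold": tau}
                try:
                    g = profile.zscores(tau)
                    pairs = esm_mod.make_lagged_pairs(
                        data, predictor=context, outcome=outcome,
                        covariates=pc_cols, g=g,
                    )
                    pairs["GxE"] = pairs["G"] * pairs["E"]
                    pair_cache[(outcome, context, tau)] = pairs
                    cell["screening"] = _screen_cell(pairs, pc_cols)
                    cell["error"] = None
                except Exception as exc:  # noqa: BLE001 - logged per contract
                    logger.warning(
                        "screening failed for %s/%s/%s: %s", outcome, context, tau, exc
                    )
                    cell["screening"] = None
                    cell["error"] = f"screening: {exc}"
                cells.append(cell)

    logger.info("stage: FDR correction")
    for outcome in plan.outcomes:
        for context in plan.contexts:
            fam = [
                c for c in cells
                if c["outcome"] == outcome and c["context"] == context
                and c["screening"] is not None
            ]
            if not fam:
                continue
            adj = fdr_adjust([c["screening"]["p_gxe"] for c in fam])
            for c, q in zip(fam, adj):
                c["p_fdr"] = float(q)
                c["significant"] = bool(q < plan.alpha)

    logger.info("stage: competitive-confirmatory classification")
    for i, cell in enumerate(cells):
        if not cell.get("significant"):
            cell["classification"] = None
            continue
        key = (cell["outcome"], cell["context"], cell["threshold"])
        pairs = pair_cache[key]
        try:
            spec = DesignSpec(outcome="y", fixed=("G", "E", "GxE", *pc_cols))
            trimmed = trim_covariates(pairs, spec, candidates=pc_cols, alpha=plan.alpha)
            covs = tuple(c for c in trimmed.fixed if c in pc_cols)
            cls = classify(
                pairs,
                covariates=covs,
                n_boot=config.n_boot,
                seed=(scfg.seed * 1009 + i) % 2**31,
            )
            cell["classification"] = {
                "label": cls.label,
                "best_model": cls.best.label,
                "c_hat": float(cls.c_hat),
                "c_ci": list(cls.c_ci) if cls.c_ci is not None else None,
                "e_bounds": list(cls.e_bounds),
                "within_bounds": cls.within_bounds,
                "covariates_kept": list(covs),
                "aic_table": {
                    m: float(a) for m, a in cls.aic_table["aic"].items()
                },
            }
        except Exception as exc:  # noqa: BLE001
            logger.warning("classification failed for %s: %s", key, exc)
            cell["classification"] = None
            cell["error"] = f"classification: {exc}"

    obs = esm_df[esm_df["observed"].astype(bool)]
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": scfg.seed,
        "config": dataclasses.asdict(config),
        "prs": {
            "n_snps_retained": len(retained),
            "n_snps_used": {f"{t:g}": n for t, n in profile.n_snps_used.items()},
        },
        "esm": {
            "n_subjects": int(esm_df["subject_id"].nunique()),
            "n_issued": int(len(esm_df)),
            "n_completed": int(len(obs)),
            "mean_completed_per_subject": float(
                obs.groupby("subject_id").size().mean()
            ),
        },
        "cells": cells,
    }
    return report


def validate_report(report: dict) -> None:
    """Raise ValueError when the report bundle violates the schema."""
    for key in ("schema_version", "seed", "config", "prs", "esm", "cells"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    plan_cfg = report["config"]["plan"]
    expected = {
        (o, c, t)
        for o in plan_cfg["outcomes"]
        for c in plan_cfg["contexts"]
        for t in plan_cfg["prs_thresholds"]
    }
    seen = [(c["outcome"], c["context"], c["threshold"]) for c in report["cells"]]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate cells in report")
    if set(seen) != expected:
        raise ValueError("report cells do not enumerate the plan exactly once")
    for c in report["cells"]:
        if c["screening"] is None and not c.get("error"):
            raise ValueError("cell without estimates must log a failure reason")


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the JSON report plus a TSV mirror of the screening table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(_to_jsonable(report), indent=2, sort_keys=True))
    rows = []
    for c in report["cells"]:
        s = c["screening"] or {}
        cls = c["classification"] or {}
        rows.append(
            {
                "outcome": c["outcome"],
                "context": c["context"],
                "threshold": c["threshold"],
                "estimate_gxe": s.get("estimate_gxe"),
                "se_gxe": s.get("se_gxe"),
                "p_gxe": s.get("p_gxe"),
                "p_fdr": c.get("p_fdr"),
                "best_gxe_model": cls.get("label"),
            }
        )
    pd.DataFrame(rows).to_csv(out / "screening.tsv", sep="\t", index=False)
    return path


def load_config(path: str | Path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file."""
    import yaml

    from .gxe import GxeModelSpec

    raw = yaml.safe_load(Path(path).read_text()) or {}
    s = dict(raw.get("synth", {}))
    if "true_model" in s:
        tm = s["true_model"]
        s["true_model"] = GxeModelSpec.make(tm["framework"], tm["strength"])
    if "true_params" in s:
        s["true_params"] = synth_mod.CrossoverParams(**s["true_params"])
    for key in ("maf_range", "window_minutes"):
        if key in s:
            s[key] = tuple(s[key])
    kwargs: dict = {"synth": synth_mod.SynthConfig(**s)}
    if "plan" in raw:
        p = dict(raw["plan"])
        for key in ("outcomes", "contexts", "prs_thresholds"):
            if key in p:
                p[key] = tuple(p[key])
        kwargs["plan"] = AnalysisPlan(**p)
    for key in ("clump_r2", "clump_window_kb", "n_ancestry_pcs", "n_boot"):
        if key in raw:
            kwargs[key] = raw[key]
    return StudyConfig(**kwargs)
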