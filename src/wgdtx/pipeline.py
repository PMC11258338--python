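"""End-to-end orchestration: simulate/load -> WGD calls -> normalization ->
differential expression -> cross-cohort enrichment -> survival.

Every stage writes its artifact under the output directory and contributes a
section to a machine-readable run report; a failure aborts with the failing
stage named, keeping partial outputs.  With a fixed seed and config the
report is byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path


import pandas as pd

from . import __version__
from .dge import DGEThresholds, WGDExpressionModel, intersect_cohorts
from .enrichment import read_gmt, run_enrichment
from .normalize import drop_unexpressed, log_cpm, tmm_factors
from .segments import call_wgd
from .simulate import (
    Cohort,
    SimulationConfig,
    load_cohort,
    simulate_cohort,
    simulate_gene_sets,
    write_cohort,
)
from .survival import compare_groups

log = logging.getLogger("wgdtx")

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    With no ``discovery_path`` a discovery cohort is simulated from
    ``simulation`` (and, when ``with_validation``, a validation cohort from
    a shifted seed).  Thresholds default to the asymmetric
    discovery/validation scheme: significance at |coef| >= 1.5, enrichment
    candidates at |coef| >= 1.0 (discovery) / 0.5 (validation).
    """

    outdir: str = "wgdtx_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    with_validation: bool = True
    discovery_path: str | None = None
    validation_path: str | None = None
    gmt_path: str | None = None
    coef_threshold: float = 1.5
    disc_coef: float = 1.0
    valid_coef: float = 0.5
    alpha: float = 0.05
    purity_min: float = 0.3
    include_cn: bool = True

    def __post_init__(self) -> None:
        if min(self.coef_threshold, self.disc_coef, self.valid_coef) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for p in (self.discovery_path, self.validation_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def config_hash(self) -> str:
        blob = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [
        h for h in log.handlers if not isinstance(h, logging.FileHandler)
    ]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)


def _analyse_cohort(
    cohort: Cohort, cfg: PipelineConfig, outdir: Path, label: str
):
    """WGD calls, normalization and the per-gene GLM for one cohort."""
    profiles = {
        s: p for s, p in cohort.profiles.items() if p.purity >= cfg.purity_min
    }
    if not profiles:
        raise StageError(f"call-wgd[{label}]: all samples below purity cutoff")
    calls = {s: call_wgd(p) for s, p in profiles.items()}
    call_df = pd.DataFrame(
        {
            "sample": list(calls),
            "mcn_ge2_fraction": [c.mcn_ge2_fraction for c in calls.values()],
            "is_wgd": [c.is_wgd for c in calls.values()],
            "timing": [c.timing for c in calls.values()],
            "het_cn2_len": [c.het_cn2_len for c in calls.values()],
            "hom_cn2_len": [c.hom_cn2_len for c in calls.values()],
        }
    )
    call_df.to_csv(outdir / f"wgd_calls_{label}.tsv", sep="\t", index=False)

    counts = cohort.counts[[s for s in cohort.counts.columns if s in profiles]]
    counts = drop_unexpressed(counts)
    if counts.empty:
        raise StageError(f"normalize[{label}]: no expressed genes")
    factors = tmm_factors(counts)
    norm = log_cpm(counts, factors)
    norm.to_csv(outdir / f"normalized_{label}.tsv", sep="\t")

    from .plotting import plot_volcano

    model = WGDExpressionModel.from_profiles(
        norm,
        profiles,
        cohort.meta,
        cohort.genes,
        include_cn=cfg.include_cn,
        thresholds=DGEThresholds(coef=cfg.coef_threshold, alpha=cfg.alpha),
    )
    results = model.fit()
    results.to_tsv(outdir / f"dge_{label}.tsv")
    plot_volcano(
        results.records, outdir / f"volcano_{label}.png",
        coef=cfg.coef_threshold, alpha=cfg.alpha,
    )
    diag = results.residual_diagnostics()
    diag.to_csv(outdir / f"dge_diagnostics_{label}.tsv", sep="\t", index=False)
    return calls, results


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the machine-readable run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
    }

    stage = "simulate"
    try:
        if cfg.discovery_path:
            discovery = load_cohort(cfg.discovery_path)
            validation = (
                load_cohort(cfg.validation_path) if cfg.validation_path else None
            )
        else:
            sim_cfg = cfg.simulation or SimulationConfig(seed=cfg.seed)
            discovery = simulate_cohort(sim_cfg, seed=cfg.seed)
            write_cohort(discovery, outdir / "discovery")
            validation = None
            if cfg.with_validation:
                # same gene universe and planted module, fresh samples
                validation = simulate_cohort(
                    sim_cfg,
                    seed=cfg.seed + 1000,
                    genes=discovery.genes,
                    module_genes=discovery.truth["module_genes"],
                )
                write_cohort(validation, outdir / "validation")
        log.info("simulate: discovery n=%d%s", len(discovery.meta),
                 f", validation n={len(validation.meta)}" if validation else "")

        stage = "call-wgd/normalize/dge"
        calls_d, res_d = _analyse_cohort(discovery, cfg, outdir, "discovery")
        res_v = None
        if validation is not None:
            calls_v, res_v = _analyse_cohort(validation, cfg, outdir, "validation")

        timing_counts = pd.Series(
            [c.timing for c in calls_d.values()]
        ).value_counts()
        report["wgd"] = {
            "n_samples": len(calls_d),
            "n_wgd": int(sum(c.is_wgd for c in calls_d.values())),
            "by_timing": {k: int(v) for k, v in sorted(timing_counts.items())},
        }
        report["dge"] = {
            "genes_tested": res_d.n_genes - res_d.n_failed,
            "genes_failed": res_d.n_failed,
            "significant_up": len(res_d.significant_genes("up")),
            "significant_down": len(res_d.significant_genes("down")),
        }
        log.info("dge: %s up / %s down significant",
                 report["dge"]["significant_up"], report["dge"]["significant_down"])

        stage = "intersect"
        if res_v is not None:
            inter = intersect_cohorts(
                res_d.records, res_v.records, alpha=cfg.alpha
            )
            inter.to_csv(outdir / "intersect.tsv", sep="\t", index=False)
            report["intersect"] = {
                "n_genes": len(inter),
                "n_down": int((inter["direction"] == "down").sum()),
                "n_up": int((inter["direction"] == "up").sum()),
            }

        stage = "enrichment"
        if cfg.gmt_path:
            gene_sets = read_gmt(cfg.gmt_path)
        else:
            gene_sets = simulate_gene_sets(discovery)
            with open(outdir / "pathways.gmt", "w") as fh:
                for name, genes in sorted(gene_sets.items()):
                    fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
        enr = run_enrichment(
            res_d.records,
            res_v.records if res_v is not None else None,
            gene_sets,
            disc_coef=cfg.disc_coef,
            valid_coef=cfg.valid_coef,
            alpha=cfg.alpha,
        )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        top = {}
        for direction in ("down", "up"):
            sub = enr[enr["direction"] == direction]
            if len(sub):
                best = sub.iloc[0]
                top[direction] = {
                    "pathway": best["pathway_id"],
                    "p_adj": float(best["p_adj"]),
                    "significant": bool(best["significant"]),
                }
        report["enrichment"] = {
            "n_pathways": int(enr["pathway_id"].nunique()),
            "n_significant": int(enr["significant"].sum()),
            "top": top,
        }

        stage = "survival"
        surv = discovery.meta.loc[list(calls_d)].copy()
        surv["group"] = [calls_d[s].timing for s in surv.index]
        if surv["group"].nunique() >= 2 and {"time", "event"} <= set(surv.columns):
            curves, lr = compare_groups(surv, "group")
            for g, curve in curves.items():
                curve.to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
            from .plotting import plot_km

            plot_km(curves, outdir / "km.png")
            report["survival"] = {
                "logrank_statistic": round(lr.statistic, 10),
                "df": lr.df,
                "p": float(f"{lr.p:.10g}"),
                "groups": {g: int((surv["group"] == g).sum()) for g in curves},
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", outdir / "report.json")
    return report
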