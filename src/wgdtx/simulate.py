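"""Synthetic tumour cohorts with known WGD ground truth.

The generator produces everything the analysis chain consumes — allele-
specific copy-number segments, raw counts, sample metadata, gene intervals,
pathway sets — with planted truth, so every stage is testable without
access-controlled data.

Copy-number histories start from diploid autosomes (approximate human
chromosome-arm scaffold) and apply whole-arm or half-arm single-copy loss
events ordered around an optional whole-genome duplication:

* ``early``: duplication first, then losses remove both doubled copies of
  one parental allele, leaving heterozygous 1+1 regions among a 2+2
  background;
* ``late``: losses first (1+0), then duplication doubles them into
  homozygous 2+0 regions among a 2+2 background;
* ``none``: losses on a diploid background, no duplication.

Expression is negative-binomial with a copy-number dose effect on log2
means, a planted group effect on a designated gene module in early-WGD
samples, purity dilution by a fixed stromal profile, and log-normal library
depths.  Survival is exponential with per-group hazards and independent
exponential censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .segments import Segment, SegmentProfile, assign_gene_cnlr

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_cn_history",
    "simulate_expression",
    "simulate_survival",
    "simulate_cohort",
    "simulate_gene_sets",
    "write_cohort",
    "load_cohort",
]

# Approximate human autosome scaffold: (chrom, length, centromere), Mb.
_CHROMS = [
    ("1", 249, 125), ("2", 243, 93), ("3", 198, 91), ("4", 191, 50),
    ("5", 181, 48), ("6", 171, 61), ("7", 159, 60), ("8", 146, 45),
    ("9", 141, 49), ("10", 136, 40), ("11", 135, 53), ("12", 134, 36),
    ("13", 115, 18), ("14", 107, 17), ("15", 103, 19), ("16", 90, 37),
    ("17", 81, 24), ("18", 78, 17), ("19", 59, 26), ("20", 63, 28),
    ("21", 48, 13), ("22", 51, 15),
]
_MB = 1_000_000


def _half_arm_units() -> list[tuple[str, int, int]]:
    """Atomic loss units: each chromosome arm split into two halves.

    1-based closed coordinates.
    """
    units = []
    for chrom, length, cen in _CHROMS:
        for lo, hi in ((1, cen * _MB), (cen * _MB + 1, length * _MB)):
            mid = (lo + hi) // 2
            units.append((chrom, lo, mid))
            units.append((chrom, mid + 1, hi))
    return units


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a serous ovarian cancer cohort: an early/late/no-WGD
    mix, moderately high purity (Beta(8,3), mean 0.73), a copy-number dose
    effect of one log2 unit per cnlr unit, a -2 log2-unit planted effect on
    a small gene module in early-WGD samples, and a twofold hazard for the
    early-WGD group.
    """

    n_early: int = 30
    n_late: int = 20
    n_none: int = 30
    n_genes: int = 2000
    n_module_genes: int = 20
    beta_wgd: float = -2.0
    beta_cn: float = 1.0
    loss_rate: float = 0.3
    purity_alpha: float = 8.0
    purity_beta: float = 3.0
    nb_dispersion: float = 0.1
    loss_bias: float = 2.5
    hazard_early: float = 0.2
    hazard_late: float = 0.1
    hazard_none: float = 0.1
    censor_rate: float = 0.05
    contradictory_rate: float = 0.05
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    gene_length: int = 10_000
    depth_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_early, self.n_late, self.n_none) < 0 or (
            self.n_early + self.n_late + self.n_none
        ) <= 0:
            raise ValueError("need a non-negative arm size and >= 1 sample")
        if self.n_genes <= 0 or self.n_module_genes < 0:
            raise ValueError("need positive gene counts")
        if self.n_module_genes > self.n_genes:
            raise ValueError("module larger than gene universe")
        if not (0.0 <= self.loss_rate < 1.0):
            raise ValueError("loss_rate must lie in [0, 1)")
        for h in (self.hazard_early, self.hazard_late, self.hazard_none):
            if h <= 0:
                raise ValueError("hazards must be positive")
        if self.nb_dispersion < 0 or self.censor_rate < 0:
            raise ValueError("dispersion and censor_rate must be >= 0")

    @property
    def hazards(self) -> dict[str, float]:
        return {
            "early": self.hazard_early,
            "late": self.hazard_late,
            "none": self.hazard_none,
        }


@dataclass
class Cohort:
    """A simulated cohort plus its ground truth."""

    config: SimulationConfig
    profiles: dict[str, SegmentProfile]
    counts: pd.DataFrame  # genes x samples, raw
    genes: pd.DataFrame  # chrom, start, end, gene_id
    meta: pd.DataFrame  # indexed by sample: purity, hr, group, time, event
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta.index)


def simulate_cn_history(
    config: SimulationConfig,
    arm: str,
    rng: np.random.Generator,
    sample_id: str,
    loss_affinity: np.ndarray | None = None,
) -> tuple[SegmentProfile, dict]:
    """One sample's allele-specific segment profile and its truth record.

    ``arm`` is the cohort arm: ``early``, ``late`` or ``none``.

    ``loss_affinity`` is a cohort-level per-unit recurrent-loss landscape
    (one value per half-arm unit): WGD samples preferentially lose
    high-affinity units (logit weight ``loss_bias * affinity``), non-WGD
    samples lose uniformly.  This creates the systematic gene-level
    association between copy number and WGD status that motivates the
    copy-number covariate in the expression model.
    """
    if arm not in ("early", "late", "none"):
        raise ValueError(f"unknown arm {arm!r}")
    units = _half_arm_units()
    lengths = np.array([hi - lo + 1 for _, lo, hi in units], dtype=float)
    total = lengths.sum()
    logits = np.zeros(len(units))
    if loss_affinity is not None and arm != "none":
        if len(loss_affinity) != len(units):
            raise ValueError("loss_affinity must have one value per unit")
        logits = config.loss_bias * np.asarray(loss_affinity, dtype=float)
    # Gumbel-perturbed logits = weighted sampling without replacement
    keys = logits + rng.gumbel(size=len(units))
    order = np.argsort(-keys)
    lost: set[int] = set()
    acc = 0.0
    for idx in order:
        if acc >= config.loss_rate * total:
            break
        lost.add(int(idx))
        acc += lengths[idx]

    segments = []
    for i, (chrom, lo, hi) in enumerate(units):
        is_lost = i in lost
        if arm == "none":
            major, minor = (1, 0) if is_lost else (1, 1)
        elif is_lost:
            # lost regions carry the timing signal; a small contradictory
            # fraction flips zygosity to exercise robustness paths
            flip = rng.random() < config.contradictory_rate
            if arm == "early":
                major, minor = (2, 0) if flip else (1, 1)
            else:
                major, minor = (1, 1) if flip else (2, 0)
        else:
            major, minor = (2, 2) if arm in ("early", "late") else (1, 1)
        segments.append(Segment(chrom, lo, hi, major, minor))

    purity = float(rng.beta(config.purity_alpha, config.purity_beta))
    purity = max(purity, 1e-3)
    profile = SegmentProfile(sample_id, tuple(segments), purity)
    truth = {
        "sample_id": sample_id,
        "group": arm,
        "is_wgd": arm != "none",
        "timing": arm,
        "purity": purity,
        "lost_fraction": acc / total,
    }
    return profile, truth


def _draw_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom_len = {c: l * _MB for c, l, _ in _CHROMS}
    chroms = list(chrom_len)
    lens = np.array([chrom_len[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    rows = []
    picks = rng.choice(len(chroms), size=config.n_genes, p=probs)
    for i, ci in enumerate(picks):
        chrom = chroms[ci]
        start = int(rng.integers(1, chrom_len[chrom] - config.gene_length))
        rows.append((chrom, start, start + config.gene_length - 1, f"G{i:05d}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return df.sort_values(["chrom", "start"], key=lambda s: (
        s.astype(int) if s.name == "chrom" else s
    )).reset_index(drop=True)


def simulate_expression(
    cohort_truth: dict,
    profiles: dict[str, SegmentProfile],
    genes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    module_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial counts with CN dose, module effect and purity dilution.

    ``module_genes`` pins the planted module to a given gene set (used to
    share the module between a discovery and a validation cohort); by
    default the module is drawn at random from the gene universe.
    """
    n_genes = len(genes)
    gene_ids = genes["gene_id"].to_numpy()
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    stroma = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    if module_genes is None:
        module_idx = rng.choice(n_genes, size=config.n_module_genes, replace=False)
        module = np.zeros(n_genes, dtype=bool)
        module[module_idx] = True
    else:
        module = np.isin(gene_ids, list(module_genes))

    samples = list(profiles)
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        prof = profiles[s]
        p = prof.purity
        cnlr = assign_gene_cnlr(prof, genes).to_numpy()
        cnlr = np.nan_to_num(cnlr, nan=0.0)
        # purity dilution: the per-gene baseline is a purity-weighted mixture
        # of the tumour and stromal profiles; the copy-number dose enters
        # through the cnlr, whose definition already mixes the tumour CN with
        # the diploid stromal fraction at this purity
        mixed_base = p * 2.0**baseline + (1.0 - p) * 2.0**stroma
        log2_mu = np.log2(mixed_base) + config.beta_cn * cnlr
        if cohort_truth[s]["timing"] == "early":
            log2_mu = log2_mu + config.beta_wgd * module
        depth = rng.lognormal(0.0, config.depth_sigma)
        mu = np.maximum(2.0**log2_mu * depth, 1e-8)
        if config.nb_dispersion > 0:
            lam = rng.gamma(
                1.0 / config.nb_dispersion, mu * config.nb_dispersion
            )
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    expr_truth = {
        "module_genes": sorted(gene_ids[module].tolist()),
        "beta_wgd": config.beta_wgd,
        "beta_cn": config.beta_cn,
        "baseline_log2": {g: float(b) for g, b in zip(gene_ids, baseline)},
    }
    return df, expr_truth


def simulate_survival(
    cohort_truth: dict, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential event times with per-group hazards, exponential censoring."""
    rows = []
    for s, rec in cohort_truth.items():
        hazard = config.hazards[rec["timing"]]
        t_event = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate)
        else:
            t_cens = np.inf
        rows.append(
            {
                "sample": s,
                "time": float(min(t_event, t_cens)),
                "event": int(t_event <= t_cens),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    *,
    genes: pd.DataFrame | None = None,
    module_genes: list[str] | None = None,
) -> Cohort:
    """Generate a full cohort (segments, counts, metadata, truth).

    ``seed`` overrides ``config.seed``; one generator drives every draw, so
    a fixed seed fixes the whole cohort.  ``genes`` and ``module_genes``
    pin the gene annotation and planted module, so a validation cohort can
    share them with its discovery cohort (samples, baselines and noise are
    still drawn fresh).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arms = (
        ["early"] * config.n_early
        + ["late"] * config.n_late
        + ["none"] * config.n_none
    )
    # recurrent-loss landscape shared by every sample in the cohort
    loss_affinity = rng.uniform(0.0, 1.0, size=len(_half_arm_units()))
    profiles: dict[str, SegmentProfile] = {}
    truth_samples: dict[str, dict] = {}
    for i, arm in enumerate(arms):
        sid = f"S{i:03d}"
        prof, t = simulate_cn_history(config, arm, rng, sid, loss_affinity)
        profiles[sid] = prof
        truth_samples[sid] = t

    if genes is None:
        genes = _draw_genes(config, rng)
    counts, expr_truth = simulate_expression(
        truth_samples, profiles, genes, config, rng, module_genes=module_genes
    )
    surv = simulate_survival(truth_samples, config, rng)

    # HR-deficiency exposure: nuisance covariate, gamma-distributed
    hr = rng.gamma(2.0, 0.25, size=len(arms))
    meta = pd.DataFrame(
        {
            "purity": [profiles[s].purity for s in profiles],
            "hr": hr,
            "group": [truth_samples[s]["timing"] for s in profiles],
        },
        index=pd.Index(list(profiles), name="sample"),
    ).join(surv)

    truth = {
        "samples": truth_samples,
        "module_genes": expr_truth["module_genes"],
        "beta_wgd": expr_truth["beta_wgd"],
        "beta_cn": expr_truth["beta_cn"],
        "config": asdict(config),
    }
    return Cohort(
        config=config,
        profiles=profiles,
        counts=counts,
        genes=genes,
        meta=meta,
        truth=truth,
    )


def simulate_gene_sets(
    cohort: Cohort,
    rng: np.random.Generator | None = None,
    *,
    n_null_pathways: int = 20,
    pathway_size: int = 50,
) -> dict[str, list[str]]:
    """Pathway collection containing the planted module plus null pathways.

    The module's pathway carries the module genes plus random fillers up to
    ``pathway_size`` (annotation is never exact); null pathways are random
    draws from the gene universe.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 1)
    universe = cohort.genes["gene_id"].to_numpy()
    module = list(cohort.truth["module_genes"])
    non_module = np.setdiff1d(universe, module)
    fill = rng.choice(
        non_module, size=max(pathway_size - len(module), 0), replace=False
    )
    sets = {"MODULE_PATHWAY": sorted(module + fill.tolist())}
    for i in range(n_null_pathways):
        sets[f"NULL_PATHWAY_{i:02d}"] = sorted(
            rng.choice(universe, size=pathway_size, replace=False).tolist()
        )
    return sets


# ---------------------------------------------------------------------------
# round-trippable file emission


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write segments.tsv, counts.tsv, genes.tsv, meta.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    seg = pd.concat(
        [p.to_frame() for p in cohort.profiles.values()], ignore_index=True
    )
    paths["segments"] = outdir / "segments.tsv"
    seg.to_csv(paths["segments"], sep="\t", index=False)
    paths["counts"] = outdir / "counts.tsv"
    cohort.counts.to_csv(paths["counts"], sep="\t")
    paths["genes"] = outdir / "genes.tsv"
    cohort.genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["meta"] = outdir / "meta.tsv"
    # %.17g keeps float round-trips exact
    cohort.meta.to_csv(paths["meta"], sep="\t", float_format="%.17g")
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths


def load_cohort(outdir) -> Cohort:
    """Re-load a written cohort; inverse of :func:`write_cohort`."""
    from .segments import profiles_from_table, read_segment_table, read_gene_table

    outdir = Path(outdir)
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    config = SimulationConfig(**truth["config"])
    meta = pd.read_csv(
        outdir / "meta.tsv", sep="\t", index_col="sample",
        float_precision="round_trip",
    )
    seg = read_segment_table(outdir / "segments.tsv")
    profiles = profiles_from_table(
        seg, meta["purity"].to_dict(), min_purity=0.0
    )
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="gene_id")
    genes = read_gene_table(outdir / "genes.tsv")
    return Cohort(
        config=config,
        profiles=profiles,
        counts=counts,
        genes=genes,
        meta=meta,
        truth=truth,
    )
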