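"""Cross-cohort pathway over-representation.

Per-gene evidence from a discovery and a validation cohort is merged with
Brown's method (Fisher's combined statistic moment-matched to a scaled
chi-square using the empirical dependence between cohorts), genes are ranked
by merged p-value, and each pathway is scored with a ranked hypergeometric
test: the minimum over prefixes of the ranked list of the hypergeometric
upper-tail probability of the pathway overlap in that prefix.  Up- and
down-regulated candidate lists are built and tested separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "browns_merge",
    "ranked_hypergeometric",
    "run_enrichment",
    "PathwayResult",
    "read_gmt",
]

_TINY = np.finfo(float).tiny


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT pathway file (name, description, genes...)."""
    from gseapy import read_gmt as _read_gmt

    gene_sets = _read_gmt(str(path))
    if not gene_sets:
        raise ValueError(f"no pathways parsed from {path}")
    return gene_sets


def browns_merge(
    p_matrix: pd.DataFrame | np.ndarray,
    dependence: np.ndarray | None = None,
) -> np.ndarray:
    """Merge per-gene p-values across cohorts with Brown's method.

    Parameters
    ----------
    p_matrix : genes x cohorts, values in (0, 1]
        Zeros are clamped to the smallest positive float with a warning.
    dependence : cohorts x cohorts covariance of the -2 ln p columns, optional
        Estimated from the empirical covariance across genes when omitted.
        Passing ``4 * I`` (independent cohorts) reduces the method to
        Fisher's.

    Returns
    -------
    merged p per gene.  A single cohort is returned unchanged.
    """
    P = np.asarray(p_matrix, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if np.any((P < 0) | (P > 1) | ~np.isfinite(P)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(P == 0):
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        P = np.maximum(P, _TINY)
    n_genes, k = P.shape
    if k == 1:
        return P[:, 0].copy()
    logs = -2.0 * np.log(P)  # each column ~ chi2(2) under the null
    psi = logs.sum(axis=1)
    if dependence is None:
        if n_genes < 2:
            raise ValueError("need >= 2 genes to estimate cohort dependence")
        dependence = np.cov(logs, rowvar=False)
    dependence = np.asarray(dependence, dtype=float)
    mean = 2.0 * k
    # variance of the sum: per-column chi2(2) variance is 4; covariances from
    # the supplied/estimated dependence matrix
    offdiag = dependence[~np.eye(k, dtype=bool)].sum()
    var = 4.0 * k + offdiag
    var = max(var, 1e-12)
    scale = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    return stats.chi2.sf(psi / scale, df)


@dataclass(frozen=True)
class PathwayResult:
    """Ranked hypergeometric result for one pathway."""

    pathway_id: str
    p_raw: float
    best_prefix_size: int
    overlap_genes: tuple[str, ...]
    p_adj: float = np.nan


def ranked_hypergeometric(
    ranked_genes,
    pathway,
    background,
) -> PathwayResult:
    """Minimum hypergeometric tail probability over prefixes of a ranked list.

    For each prefix of ``ranked_genes`` (ordered best evidence first) the
    upper-tail P(X >= overlap) is computed with population N = |background|,
    K = |pathway & background| successes and n = prefix size draws; the
    minimum over prefixes is returned with its prefix and overlap.  The
    minimum is reported unpenalized for the prefix selection, as is usual
    for this statistic, and is therefore anti-conservative as a standalone
    p-value.
    """
    background = set(background)
    K_set = set(pathway) & background
    if not K_set:
        raise ValueError("pathway shares no genes with the background")
    ranked = [g for g in ranked_genes if g in background]
    if not ranked:
        warnings.warn("empty ranked list; returning p = 1")
        return PathwayResult("", 1.0, 0, ())
    N = len(background)
    K = len(K_set)
    member = np.fromiter((g in K_set for g in ranked), bool, len(ranked))
    overlap = np.cumsum(member)
    n = np.arange(1, len(ranked) + 1)
    # P(X >= overlap) for hypergeom(N, K, n)
    pvals = stats.hypergeom.sf(overlap - 1, N, K, n)
    best = int(np.argmin(pvals))
    genes = tuple(g for g in ranked[: best + 1] if g in K_set)
    return PathwayResult("", float(pvals[best]), best + 1, genes)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p
    key = {"holm": "holm", "bh": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


def _candidate_table(
    discovery: pd.DataFrame,
    validation: pd.DataFrame | None,
    sign: int,
    disc_coef: float,
    valid_coef: float,
) -> pd.DataFrame:
    d = discovery[discovery["fit_status"] == "ok"].set_index("gene_id")
    keep = sign * d["coef_wgd"] >= disc_coef
    if validation is not None:
        v = validation[validation["fit_status"] == "ok"].set_index("gene_id")
        common = d.index.intersection(v.index)
        d, v = d.loc[common], v.loc[common]
        keep = (sign * d["coef_wgd"] >= disc_coef) & (
            sign * v["coef_wgd"] >= valid_coef
        )
        out = pd.DataFrame(
            {"p_discovery": d.loc[keep, "p_raw"], "p_validation": v.loc[keep, "p_raw"]}
        )
    else:
        out = pd.DataFrame({"p_discovery": d.loc[keep, "p_raw"]})
    return out


def run_enrichment(
    discovery: pd.DataFrame,
    validation: pd.DataFrame | None,
    gene_sets: dict[str, list[str]],
    *,
    disc_coef: float = 1.0,
    valid_coef: float = 0.5,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Directional pathway over-representation from one or two DGE tables.

    Candidate genes pass the per-cohort coefficient filters (defaults
    mirror a stricter discovery than validation cutoff); their p-values are
    merged across cohorts with :func:`browns_merge`, ranked ascending (ties
    broken by gene id for determinism), and every pathway is scored with
    :func:`ranked_hypergeometric` against the full fitted-gene background.
    Pathway p-values are adjusted per direction (Holm by default).
    """
    if not gene_sets:
        raise ValueError("empty pathway collection")
    background = set(discovery.loc[discovery["fit_status"] == "ok", "gene_id"])
    if validation is not None:
        background &= set(
            validation.loc[validation["fit_status"] == "ok", "gene_id"]
        )
    if not background:
        raise ValueError("no gene overlap between cohorts")
    covered = set().union(*gene_sets.values())
    if not covered & background:
        raise ValueError("no overlap between pathway genes and the background")

    rows = []
    for direction, sign in (("down", -1), ("up", +1)):
        cand = _candidate_table(
            discovery, validation, sign, disc_coef, valid_coef
        )
        if len(cand):
            # too few genes to estimate dependence -> assume independence
            dep = None if len(cand) >= 2 else 4.0 * np.eye(cand.shape[1])
            merged = browns_merge(cand.to_numpy(), dep)
        else:
            merged = np.array([])
        order = sorted(
            range(len(cand)), key=lambda i: (merged[i], cand.index[i])
        )
        ranked = [cand.index[i] for i in order]
        empty = PathwayResult("", 1.0, 0, ())
        dir_rows = []
        for name, genes in sorted(gene_sets.items()):
            if not set(genes) & background:
                continue
            res = (
                ranked_hypergeometric(ranked, genes, background)
                if ranked
                else empty  # no candidate genes in this direction
            )
            dir_rows.append(
                {
                    "pathway_id": name,
                    "direction": direction,
                    "p_raw": res.p_raw,
                    "best_prefix_size": res.best_prefix_size,
                    "n_overlap": len(res.overlap_genes),
                    "overlap_genes": ",".join(res.overlap_genes),
                }
            )
        sub = pd.DataFrame(dir_rows)
        if len(sub):
            sub["p_adj"] = _adjust(sub["p_raw"].to_numpy(), adjust)
            sub["significant"] = sub["p_adj"] < alpha
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["direction", "p_adj", "pathway_id"], ignore_index=True
    )
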