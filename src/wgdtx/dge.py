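"""Copy-number-aware differential expression between WGD groups.

Standard count-based DGE tools cannot carry a covariate that varies per gene
*and* per sample, which is exactly what gene-level copy number is.  Each
gene is therefore fitted with its own gaussian GLM (identity link, i.e.
ordinary least squares) of normalized log expression on a WGD indicator
plus per-sample covariates:

    log2 expr ~ WGD + HR covariate + purity + copy-number log-ratio

The WGD coefficient estimate is the effect size (in log2-expression units,
in place of a fold change), with a two-sided t-test per gene and
Benjamini-Hochberg adjustment across genes.

The module is organised as a model/results pair: build a
:class:`WGDExpressionModel` from a normalized matrix and a design, call
``fit()``, and read estimates, calls and diagnostics off the returned
:class:`WGDExpressionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .segments import SegmentProfile, assign_gene_cnlr, call_wgd

__all__ = [
    "DGEThresholds",
    "WGDExpressionModel",
    "WGDExpressionResults",
    "fit_gene_glm",
    "bh_adjust",
    "intersect_cohorts",
    "filter_expressed",
]

_RESULT_COLUMNS = [
    "gene_id",
    "coef_wgd",
    "se",
    "p_raw",
    "p_adj",
    "direction",
    "significant",
    "n_used",
    "fit_status",
]


@dataclass(frozen=True)
class DGEThresholds:
    """Significance thresholds for per-gene calls.

    ``coef`` is the minimum absolute WGD coefficient; ``alpha`` the p-value
    cutoff, applied to BH-adjusted p-values unless ``use_adjusted`` is
    False (raw-p mode).
    """

    coef: float = 1.5
    alpha: float = 0.05
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.coef < 0 or not (0 < self.alpha < 1):
            raise ValueError("coef must be >= 0 and alpha in (0, 1)")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_gene_glm(
    y: np.ndarray, X: np.ndarray, coef_index: int = 1
) -> tuple[float, float, float]:
    """OLS fit of one gene; returns (coef, se, p) for column ``coef_index``.

    The gaussian identity-link GLM is fitted in closed form via the normal
    equations; the p-value is the two-sided t-test with n - p degrees of
    freedom.  A rank-deficient design raises ValueError.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than parameters ({k})")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    coef = float(beta[coef_index])
    if sigma2 <= 1e-20 * max(1.0, float(np.mean(y * y))):
        # degenerate (e.g. constant response): no evidence either way
        return coef, 0.0, 1.0
    se = float(np.sqrt(sigma2 * xtx_inv[coef_index, coef_index]))
    t = coef / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return coef, se, float(p)


def filter_expressed(
    counts: pd.DataFrame, *, min_count: int = 10, min_prop: float = 0.5
) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` reads in ``min_prop`` of samples.

    Low-count genes have skewed log-CPM values that a gaussian model fits
    poorly; filtering them before linear modelling is standard practice.
    """
    ok = (counts >= min_count).mean(axis=1) >= min_prop
    return counts.loc[ok]


def _minmax(x: pd.Series) -> pd.Series:
    rng = x.max() - x.min()
    if rng == 0:
        return pd.Series(0.0, index=x.index)
    return (x - x.min()) / rng


class WGDExpressionModel:
    """Per-gene gaussian GLM of normalized expression on WGD status.

    Parameters
    ----------
    norm : DataFrame, genes x samples
        Normalized log2 expression (e.g. TMM log-CPM).
    design : DataFrame, samples x covariates
        Must contain column ``wgd`` (0/1); optional ``hr`` (HR-deficiency
        exposure, min-max scaled here) and ``purity``.
    cnlr : DataFrame, genes x samples, optional
        Per-gene, per-sample copy-number log-ratio; enables the copy-number
        covariate.  Pass None (or ``include_cn=False``) for the
        no-CN-covariate sensitivity mode.
    """

    def __init__(
        self,
        norm: pd.DataFrame,
        design: pd.DataFrame,
        cnlr: pd.DataFrame | None = None,
        *,
        include_cn: bool = True,
        thresholds: DGEThresholds = DGEThresholds(),
    ) -> None:
        if "wgd" not in design.columns:
            raise ValueError("design must contain a 'wgd' column")
        samples = list(norm.columns)
        if set(samples) - set(design.index):
            missing = sorted(set(samples) - set(design.index))
            raise ValueError(f"samples missing from design: {missing}")
        design = design.loc[samples]
        if not design["wgd"].isin([0, 1]).all():
            raise ValueError("wgd indicator must be 0/1")
        if design.drop(columns=[c for c in ("cohort",) if c in design], errors="ignore").isna().any().any():
            raise ValueError("design contains missing values")
        self.norm = norm
        self.design = design
        self.include_cn = include_cn and cnlr is not None
        if self.include_cn:
            cnlr = cnlr.reindex(index=norm.index, columns=samples)
        self.cnlr = cnlr if self.include_cn else None
        self.thresholds = thresholds
        covs = [c for c in ("hr", "purity") if c in design.columns]
        self._sample_cols = ["wgd"] + covs
        self.exog_names = ["intercept", "wgd"] + covs + (
            ["cnlr"] if self.include_cn else []
        )

    @classmethod
    def from_profiles(
        cls,
        norm: pd.DataFrame,
        profiles: Mapping[str, SegmentProfile],
        meta: pd.DataFrame,
        genes: pd.DataFrame | None = None,
        *,
        include_cn: bool = True,
        thresholds: DGEThresholds = DGEThresholds(),
    ) -> "WGDExpressionModel":
        """Assemble the design from segment profiles and sample metadata.

        Samples are restricted to those with a profile (the purity filter is
        applied when profiles are built).  ``meta`` may carry an ``hr``
        column (scaled min-max to [0, 1]); purity is taken from the
        profiles.  ``genes`` (chrom/start/end/gene_id) enables the per-gene
        copy-number log-ratio covariate.
        """
        samples = [s for s in norm.columns if s in profiles]
        if not samples:
            raise ValueError("no overlap between expression samples and profiles")
        norm = norm[samples]
        calls = {s: call_wgd(profiles[s]) for s in samples}
        design = pd.DataFrame(
            {
                "wgd": [int(calls[s].is_wgd) for s in samples],
                "purity": [profiles[s].purity for s in samples],
            },
            index=pd.Index(samples, name="sample"),
        )
        if meta is not None and "hr" in meta.columns:
            design["hr"] = _minmax(meta["hr"].reindex(samples))
            design = design[["wgd", "hr", "purity"]]
        cnlr = None
        if include_cn:
            if genes is None:
                raise ValueError("gene annotation required for the CN covariate")
            cnlr = pd.DataFrame(
                {s: assign_gene_cnlr(profiles[s], genes) for s in samples}
            )
            cnlr = cnlr.reindex(norm.index)
        return cls(
            norm, design, cnlr, include_cn=include_cn, thresholds=thresholds
        )

    # -- fitting ----------------------------------------------------------

    def _design_for_gene(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """(samples mask, design matrix) for one gene."""
        base = self.design[self._sample_cols].to_numpy(dtype=float)
        n = base.shape[0]
        if self.include_cn:
            cn = self.cnlr.loc[gene].to_numpy(dtype=float)
            ok = np.isfinite(cn)
            X = np.column_stack(
                [np.ones(ok.sum()), base[ok], cn[ok]]
            )
        else:
            ok = np.ones(n, dtype=bool)
            X = np.column_stack([np.ones(n), base])
        return ok, X

    def fit(self, *, max_failure_fraction: float = 0.5) -> "WGDExpressionResults":
        """Fit every gene; BH-adjust across successful fits; call significance.

        Per-gene failures (rank deficiency, too few usable samples) are
        flagged and excluded from the adjustment; if more than
        ``max_failure_fraction`` of genes fail, the run aborts.
        """
        rows = []
        y_all = self.norm.to_numpy(dtype=float)
        for i, gene in enumerate(self.norm.index):
            ok, X = self._design_for_gene(gene)
            y = y_all[i][ok]
            try:
                coef, se, p = fit_gene_glm(y, X, coef_index=1)
                status = "ok"
            except (ValueError, np.linalg.LinAlgError) as exc:
                coef, se, p = np.nan, np.nan, np.nan
                status = f"failed: {exc}"
            rows.append((gene, coef, se, p, int(ok.sum()), status))
        rec = pd.DataFrame(
            rows, columns=["gene_id", "coef_wgd", "se", "p_raw", "n_used", "fit_status"]
        )
        n_failed = (rec["fit_status"] != "ok").sum()
        if len(rec) and n_failed / len(rec) > max_failure_fraction:
            raise RuntimeError(
                f"{n_failed}/{len(rec)} gene fits failed; aborting "
                "(check design collinearity)"
            )
        rec["p_adj"] = np.nan
        okm = rec["fit_status"] == "ok"
        rec.loc[okm, "p_adj"] = bh_adjust(rec.loc[okm, "p_raw"].to_numpy())
        rec["direction"] = np.where(rec["coef_wgd"] >= 0, "up", "down")
        rec.loc[~okm, "direction"] = "na"
        th = self.thresholds
        p_used = rec["p_adj"] if th.use_adjusted else rec["p_raw"]
        rec["significant"] = (
            okm & (rec["coef_wgd"].abs() >= th.coef) & (p_used < th.alpha)
        )
        return WGDExpressionResults(self, rec[_RESULT_COLUMNS])


class WGDExpressionResults:
    """Fitted per-gene estimates, calls and diagnostics."""

    def __init__(self, model: WGDExpressionModel, records: pd.DataFrame) -> None:
        self.model = model
        self.records = records.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return len(self.records)

    @property
    def n_failed(self) -> int:
        return int((self.records["fit_status"] != "ok").sum())

    def significant_genes(self, direction: str | None = None) -> pd.DataFrame:
        sig = self.records[self.records["significant"]]
        if direction is not None:
            sig = sig[sig["direction"] == direction]
        return sig

    def summary(self) -> str:
        th = self.model.thresholds
        up = len(self.significant_genes("up"))
        down = len(self.significant_genes("down"))
        pmode = "BH-adjusted" if th.use_adjusted else "raw"
        lines = [
            "WGD differential expression (per-gene gaussian GLM)",
            "=" * 55,
            f"genes fitted:          {self.n_genes - self.n_failed}",
            f"genes failed:          {self.n_failed}",
            f"samples:               {self.model.norm.shape[1]}",
            f"covariates:            {', '.join(self.model.exog_names[1:])}",
            f"thresholds:            |coef| >= {th.coef}, {pmode} p < {th.alpha}",
            f"significant up:        {up}",
            f"significant down:      {down}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    # -- diagnostics ------------------------------------------------------

    def residual_diagnostics(self) -> pd.DataFrame:
        """Model-fit diagnostics at the expression tertiles.

        For the genes closest to the 1/3, 2/3 and 3/3 quantiles of mean
        normalized expression, refit and report: Kolmogorov-Smirnov p of
        standardized residuals against N(0,1), the number of standardized
        residuals beyond |3|, and the residual-variance ratio between WGD
        groups.
        """
        okm = self.records["fit_status"] == "ok"
        ok_genes = self.records.loc[okm, "gene_id"]
        mean_expr = self.model.norm.loc[ok_genes].mean(axis=1)
        rows = []
        for q in (1 / 3, 2 / 3, 1.0):
            target = mean_expr.quantile(q)
            gene = (mean_expr - target).abs().idxmin()
            mask, X = self.model._design_for_gene(gene)
            y = self.model.norm.loc[gene].to_numpy(dtype=float)[mask]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = max(len(y) - X.shape[1], 1)
            sd = np.sqrt(resid @ resid / df)
            z = resid / sd if sd > 0 else resid
            ks = stats.kstest(z, "norm")
            wgd = self.model.design["wgd"].to_numpy(dtype=float)[mask]
            v1 = float(np.var(resid[wgd == 1])) if (wgd == 1).any() else np.nan
            v0 = float(np.var(resid[wgd == 0])) if (wgd == 0).any() else np.nan
            ratio = v1 / v0 if v0 and np.isfinite(v0) and v0 > 0 else np.nan
            rows.append(
                {
                    "quantile": q,
                    "gene_id": gene,
                    "mean_expr": float(mean_expr[gene]),
                    "ks_stat": float(ks.statistic),
                    "ks_p": float(ks.pvalue),
                    "n_outliers": int((np.abs(z) > 3).sum()),
                    "wgd_var_ratio": ratio,
                }
            )
        return pd.DataFrame(rows)


def intersect_cohorts(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes differentially expressed in both cohorts with concordant sign.

    Requires BH-adjusted p < ``alpha`` in both cohorts and the same
    coefficient sign; no magnitude requirement is placed on the validation
    side, so small concordant validation effects are retained.
    """
    d = discovery.set_index("gene_id") if "gene_id" in discovery else discovery
    v = validation.set_index("gene_id") if "gene_id" in validation else validation
    common = d.index.intersection(v.index)
    if common.empty:
        raise ValueError("no gene overlap between cohorts")
    d, v = d.loc[common], v.loc[common]
    keep = (
        (d["p_adj"] < alpha)
        & (v["p_adj"] < alpha)
        & (np.sign(d["coef_wgd"]) == np.sign(v["coef_wgd"]))
        & (d["fit_status"] == "ok")
        & (v["fit_status"] == "ok")
    )
    out = pd.DataFrame(
        {
            "coef_discovery": d.loc[keep, "coef_wgd"],
            "coef_validation": v.loc[keep, "coef_wgd"],
            "p_adj_discovery": d.loc[keep, "p_adj"],
            "p_adj_validation": v.loc[keep, "p_adj"],
            "direction": np.where(d.loc[keep, "coef_wgd"] >= 0, "up", "down"),
        }
    )
    out.index.name = "gene_id"
    return out.reset_index()
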