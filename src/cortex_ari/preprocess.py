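"""Expression filtering, normalisation, outlier QC, and covariate regression.

The attenuation statistics operate on a *regressed* expression matrix that
retains only the subject random intercept, the fixed effects of diagnosis
and region, and the residual; everything upstream of that matrix lives here:

* CPM computation and the count-level feature filter (CPM > 0.1 in at least
  30% of samples; effective length >= 15 bp);
* log2(CPM + prior) normalisation (prior 0.5);
* sample outlier detection within (sequencing batch x cortical lobe) groups,
  flagging samples that are extreme on both the top expression principal
  components (|z| > 3) and a connectivity score (z < -2) built from the
  signed adjacency (soft power 2) of the sample biweight midcorrelation;
* per-gene mixed-model regression removing nuisance covariates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import REGION_LOBE

log = logging.getLogger(__name__)

META_CORE = ("sample_id", "subject_id", "region", "diagnosis")


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts with per-gene effective lengths."""

    counts: pd.DataFrame
    effective_length: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if self.effective_length.reindex(self.counts.index).isna().any():
            raise ValueError("effective_length must be defined for every gene")
        self.effective_length = self.effective_length.reindex(self.counts.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class RegressedExpr:
    """Regressed log2 expression with provenance of the removed covariates."""

    values: pd.DataFrame
    removed_covariates: tuple[str, ...]
    ols_fallback_genes: tuple[str, ...] = ()


def validate_metadata(meta: pd.DataFrame, expr_columns: pd.Index | None = None) -> None:
    """Check the sample-table invariants the downstream statistics rely on."""
    missing = [c for c in META_CORE if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    dup = meta.duplicated(subset=["subject_id", "region"])
    if dup.any():
        raise ValueError(
            "at most one sample per (subject, region) is allowed; duplicates: "
            f"{meta.loc[dup, ['subject_id', 'region']].to_dict('records')}"
        )
    if expr_columns is not None:
        a, b = set(meta["sample_id"]), set(expr_columns)
        if a != b:
            raise ValueError(
                f"metadata and matrix samples differ: {sorted(a ^ b)[:10]} ..."
            )


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts / library size * 1e6, library = column sum."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        empty = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero library size: {empty}")
    return mat / lib * 1e6


def filter_features(
    counts: CountMatrix,
    cpm_threshold: float = 0.1,
    sample_fraction: float = 0.30,
    min_length_bp: float = 15.0,
) -> CountMatrix:
    """Retain genes expressed above threshold in enough samples and long enough.

    A gene is kept iff CPM > ``cpm_threshold`` (strict) in at least
    ``ceil(sample_fraction * n_samples)`` samples and its effective length is
    at least ``min_length_bp``. Gene order is preserved; an empty result is
    allowed with a warning.
    """
    if cpm_threshold <= 0 or sample_fraction <= 0 or min_length_bp <= 0:
        raise ValueError("filter thresholds must be positive")
    c = cpm(counts)
    n_required = math.ceil(sample_fraction * counts.counts.shape[1])
    expressed = (c > cpm_threshold).sum(axis=1) >= n_required
    long_enough = counts.effective_length >= min_length_bp
    keep = expressed & long_enough
    if not keep.any():
        warnings.warn("filter_features removed every gene", stacklevel=2)
    return CountMatrix(
        counts=counts.counts.loc[keep],
        effective_length=counts.effective_length.loc[keep],
    )


def log_normalize(counts: CountMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2(CPM + prior) expression matrix (prior 0.5 keeps zeros finite at -1)."""
    if prior <= 0:
        raise ValueError("prior must be positive")
    return np.log2(cpm(counts) + prior)


def biweight_midcorrelation(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biweight midcorrelation between columns of X (genes x samples).

    Returns (corr, degenerate) where degenerate marks columns with zero MAD,
    for which the correlation is undefined (left NaN).
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    degenerate = mad == 0
    safe_mad = np.where(degenerate, 1.0, mad)
    u = (X - med) / (9.0 * safe_mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1)
    a = (X - med) * w
    norm = np.sqrt((a**2).sum(axis=0))
    norm = np.where(norm == 0, np.nan, norm)
    corr = (a.T @ a) / np.outer(norm, norm)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    return corr, degenerate


def detect_outliers(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    group_by: tuple[str, ...] = ("batch", "lobe"),
    z_pc: float = 3.0,
    z_k: float = -2.0,
    n_pcs: int = 10,
    soft_power: int = 2,
    lobe_map: dict[str, str] | None = None,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Flag outlier samples within (batch x lobe) groups.

    Within each group a sample is flagged iff it exceeds |z| > ``z_pc`` on at
    least one of the top ``min(n_pcs, rank)`` principal components of the
    gene-centred expression matrix AND its standardised connectivity
    (row sum of the signed adjacency ((1+bicor)/2)^soft_power, z-scored
    within the group) falls below ``z_k``. Both criteria are required.

    Groups smaller than ``min_group_size`` are skipped with a warning.
    Samples with undefined correlation (constant expression) are marked
    ``degenerate`` for manual review and never silently dropped. If every
    sample in a group is identical the connectivity SD is zero, the z-score
    is undefined, and nothing is flagged.
    """
    meta = meta.copy()
    if "lobe" in group_by and "lobe" not in meta.columns:
        lm = lobe_map or REGION_LOBE
        meta["lobe"] = meta["region"].map(lm)
        if meta["lobe"].isna().any():
            raise ValueError("no lobe assignment for some regions; pass lobe_map")
    keys = [k for k in group_by if k in meta.columns]
    if not keys:
        keys = ["lobe"] if "lobe" in meta.columns else []
    report = pd.DataFrame(
        {
            "sample_id": meta["sample_id"],
            "group": "",
            "max_abs_pc_z": np.nan,
            "zk": np.nan,
            "outlier": False,
            "degenerate": False,
        }
    ).set_index("sample_id")

    grouped = meta.groupby(list(keys)) if keys else [((), meta)]
    for name, g in grouped:
        label = "/".join(map(str, name)) if isinstance(name, tuple) else str(name)
        samples = list(g["sample_id"])
        report.loc[samples, "group"] = label
        if len(samples) < min_group_size:
            warnings.warn(
                f"outlier group {label!r} has {len(samples)} samples (<{min_group_size}); skipped",
                stacklevel=2,
            )
            continue
        X = expr[samples].to_numpy(dtype=float)
        # PC scores of samples from the gene-centred matrix
        M = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes
        U, s, _ = np.linalg.svd(M - M.mean(axis=0), full_matrices=False)
        rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
        k_use = min(n_pcs, rank)
        if k_use > 0:
            scores = U[:, :k_use] * s[:k_use]
            sd = scores.std(axis=0, ddof=1)
            sd = np.where(sd == 0, np.nan, sd)
            z = (scores - scores.mean(axis=0)) / sd
            max_abs_z = np.nanmax(np.abs(z), axis=1)
        else:
            max_abs_z = np.zeros(len(samples))
        report.loc[samples, "max_abs_pc_z"] = max_abs_z

        corr, degenerate = biweight_midcorrelation(X)
        report.loc[np.asarray(samples)[degenerate], "degenerate"] = True
        adj = ((1.0 + corr) / 2.0) ** soft_power
        np.fill_diagonal(adj, 0.0)
        k = np.nansum(adj, axis=1)
        ksd = np.nanstd(k, ddof=1)
        if ksd > 0:
            zk = (k - np.nanmean(k)) / ksd
        else:
            zk = np.full(len(samples), np.nan)
        report.loc[samples, "zk"] = zk
        flag = (max_abs_z > z_pc) & (zk < z_k) & ~degenerate & ~np.isnan(zk)
        report.loc[samples, "outlier"] = flag
    return report.reset_index()


def _design_matrices(
    meta: pd.DataFrame, keep: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Kept and nuisance fixed-effect design blocks (intercept in kept)."""
    kept_cols: list[pd.Series] = [pd.Series(1.0, index=meta.index, name="intercept")]
    for col in ("diagnosis", "region"):
        dummies = pd.get_dummies(meta[col], prefix=col, drop_first=True, dtype=float)
        kept_cols.extend(dummies[c] for c in dummies)
    nuis_cols: list[pd.Series] = []
    nuisance_names: list[str] = []
    skipped = []
    for col in meta.columns:
        if col in META_CORE or col in keep:
            continue
        v = meta[col]
        if v.isna().any():
            raise ValueError(f"covariate {col!r} has missing values")
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, prefix=col, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                skipped.append(col)
                continue
            nuis_cols.extend(dummies[c] for c in dummies)
        else:
            vv = v.astype(float)
            if vv.nunique() <= 1:
                skipped.append(col)
                continue
            nuis_cols.append(vv.rename(col))
        nuisance_names.append(col)
    if skipped:
        log.info("constant/empty covariates skipped: %s", skipped)
    X_keep = pd.concat(kept_cols, axis=1)
    X_nuis = (
        pd.concat(nuis_cols, axis=1)
        if nuis_cols
        else pd.DataFrame(index=meta.index)
    )
    X = pd.concat([X_keep, X_nuis], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    return (
        X_keep.to_numpy(),
        X_nuis.to_numpy(),
        list(X_nuis.columns),
        nuisance_names,
    )


def regress_covariates(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    keep: tuple[str, ...] = ("subject_id", "diagnosis", "region"),
) -> RegressedExpr:
    """Remove nuisance covariate effects, keeping subject, diagnosis, region.

    Per gene a linear mixed model with a subject random intercept and fixed
    effects for diagnosis, region, and every remaining metadata column is
    fitted by REML; the regressed value is the observation minus the summed
    nuisance fixed-effect contributions, so the kept effects and the residual
    are untouched. Genes whose mixed model fails to converge fall back to an
    ordinary least squares fit and are recorded.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    validate_metadata(meta, expr.columns)
    meta = (
        meta.set_index("sample_id")
        .loc[expr.columns]
        .rename_axis("sample_id")
        .reset_index()
    )
    if meta.groupby("diagnosis")["subject_id"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per diagnosis")

    X_keep, X_nuis, nuis_colnames, nuisance_names = _design_matrices(meta, keep)
    if X_nuis.shape[1] == 0:
        log.info("no nuisance covariates present; returning the input matrix")
        return RegressedExpr(expr.copy(), removed_covariates=())

    X = np.hstack([X_keep, X_nuis])
    n_keep = X_keep.shape[1]
    groups = meta["subject_id"].to_numpy()
    Y = expr.to_numpy(dtype=float)
    out = np.empty_like(Y)
    fallback: list[str] = []
    for gi, gene in enumerate(expr.index):
        y = Y[gi]
        beta_nuis = None
        try:
            with warnings.catch_warnings():
                # a boundary (zero) subject variance is fine; non-convergence is not
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("error", ConvergenceWarning)
                fit = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
            params = np.asarray(fit.fe_params)
            if np.isfinite(params).all():
                beta_nuis = params[n_keep:]
        except Exception:
            beta_nuis = None
        if beta_nuis is None:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            beta_nuis = beta[n_keep:]
            fallback.append(str(gene))
        out[gi] = y - X_nuis @ beta_nuis
    if fallback:
        log.info("%d genes fell back to OLS: %s ...", len(fallback), fallback[:5])
    return RegressedExpr(
        values=pd.DataFrame(out, index=expr.index, columns=expr.columns),
        removed_covariates=tuple(nuisance_names),
        ols_fallback_genes=tuple(fallback),
    )
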