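"""Orthogonal (total least squares) regression of DE effect sizes.

Comparing the per-gene case-control log2 fold change of one region against
the whole-cortex log2 fold change asks how regional effect sizes scale with
the global signature. Ordinary least squares is unsuitable because both
vectors are estimated with error and the fitted slope depends on which one
is called the response; total least squares (principal-components
regression on the two-column cloud) minimises perpendicular distances and
is invariant to swapping the axes. The slope is tested against unity by a
gene-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairwise import group_mask


class DegenerateCloudError(ValueError):
    """Raised when the principal axis of the effect-size cloud is vertical
    or undefined, so no finite slope exists."""


def compute_log2fc(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    scope: str = "whole_cortex",
    gene_subset: list[str] | None = None,
) -> pd.Series:
    """Case-vs-control log2 fold change per gene within a scope.

    ``scope`` is a region label or ``"whole_cortex"``. Each subject is first
    averaged across its in-scope samples (so subjects with more regions do
    not dominate), then the mean over case subjects minus the mean over
    control subjects is taken per gene. Input is assumed to be log2 scale,
    so the difference is a log2 fold change.
    """
    sub = meta if scope == "whole_cortex" else meta[meta["region"] == scope]
    if sub.empty:
        raise ValueError(f"no samples in scope {scope!r}")
    case = group_mask(sub, "case")
    if case.all() or (~case).all():
        raise ValueError(f"scope {scope!r} is missing a diagnosis group")
    means = {}
    for diag, g in sub.groupby(case.map({True: "case", False: "control"})):
        per_subject = {
            s: expr[list(gg["sample_id"])].mean(axis=1)
            for s, gg in g.groupby("subject_id")
        }
        means[diag] = pd.DataFrame(per_subject).mean(axis=1)
    fc = means["case"] - means["control"]
    fc.name = scope
    if gene_subset is not None:
        fc = fc.loc[[g for g in gene_subset if g in fc.index]]
    return fc


def tls_slope(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> tuple[float, float]:
    """Total-least-squares slope and intercept of y against x.

    Both vectors are centred on their shared genes; the slope is the
    component ratio of the leading eigenvector of the 2x2 covariance matrix,
    which makes swapping x and y return the exact reciprocal. A vertical
    principal axis (zero x-component) or an isotropic cloud raises
    :class:`DegenerateCloudError` rather than reporting a number.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        shared = x.index.intersection(y.index)
        xv = x.loc[shared].to_numpy(dtype=float)
        yv = y.loc[shared].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValueError("x and y must align")
    if xv.size < 3:
        raise ValueError("need at least 3 shared genes")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("effect vectors must be finite")
    C = np.cov(xv, yv)
    if not (C[0, 0] > 0 or C[1, 1] > 0):
        raise DegenerateCloudError("zero variance in both coordinates")
    evals, evecs = np.linalg.eigh(C)
    if np.isclose(evals[0], evals[1]) and np.isclose(C[0, 1], 0.0):
        raise DegenerateCloudError("isotropic cloud: principal axis undefined")
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise DegenerateCloudError("vertical principal axis: infinite slope")
    slope = float(v[1] / v[0])
    intercept = float(yv.mean() - slope * xv.mean())
    return slope, intercept


@dataclass
class SlopeFit:
    """TLS slope with bootstrap confidence interval and test against unity."""

    slope: float
    intercept: float
    boot_ci: tuple[float, float]
    p_vs_unity: float
    n_boot: int
    seed: int
    n_genes: int
    n_degenerate_skipped: int = 0
    boot_samples: np.ndarray | None = None  # raw bootstrap slopes, for audit

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.boot_ci[0],
            "ci_high": self.boot_ci[1],
            "p_vs_unity": self.p_vs_unity,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_genes": self.n_genes,
        }


def slope_bootstrap(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> SlopeFit:
    """Gene-resampling bootstrap of the TLS slope.

    Genes are resampled with replacement ``n_boot`` times; the 95% CI is the
    2.5/97.5 percentile interval and the two-sided p-value against slope 1
    is twice the smaller bootstrap tail, floored at 2/(n_boot+1). Degenerate
    resamples are skipped and counted; more than 10% skipped aborts.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        shared = x.index.intersection(y.index)
        xv, yv = x.loc[shared].to_numpy(dtype=float), y.loc[shared].to_numpy(dtype=float)
    else:
        xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    slope, intercept = tls_slope(xv, yv)
    rng = np.random.default_rng(seed)
    n = xv.size
    boots = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            s, _ = tls_slope(xv[idx], yv[idx])
        except (DegenerateCloudError, ValueError):
            skipped += 1
            continue
        boots.append(s)
    if skipped > 0.1 * n_boot:
        raise DegenerateCloudError(
            f"{skipped}/{n_boot} bootstrap resamples were degenerate"
        )
    b = np.array(boots)
    lo, hi = np.percentile(b, [2.5, 97.5])
    p = 2.0 * min(float((b <= 1.0).mean()), float((b >= 1.0).mean()))
    p = min(1.0, max(p, 2.0 / (n_boot + 1)))
    return SlopeFit(
        slope=slope,
        intercept=intercept,
        boot_ci=(float(lo), float(hi)),
        p_vs_unity=p,
        n_boot=n_boot,
        seed=seed,
        n_genes=n,
        n_degenerate_skipped=skipped,
        boot_samples=b,
    )
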