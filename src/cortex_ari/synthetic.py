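"""Synthetic multi-region cortical expression cohorts with known ground truth.

The generator emulates the statistical structure the attenuation analysis
assumes: ~11 cortical regions sampled per subject with region-level
missingness, subject random intercepts, a subset of genes whose log2
expression follows an anterior-posterior gradient, and a diagnosis-dependent
multiplicative attenuation of those gradients in cases. Log-scale expression
for gene g, subject s, region r is

    x = b_g + u_s + slope_g * rank(r) * (lambda if case else 1)
        + covariate terms + eps,   eps ~ N(0, noise_sd)

where b_g ~ N(mean_log_expr, gene_mean_sd) is the per-gene baseline
abundance, u_s the subject random intercept, and lambda in [0, 1] the
attenuation factor (1 = null, 0 = gradients fully erased in cases). Counts can optionally be materialised from the
log-scale matrix with a negative-binomial read model for exercising the
count-level filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import CountMatrix
from .regions import REGIONS_AP, region_ranks, sanitize_region


class InfeasibleDesignError(ValueError):
    """Raised when missingness leaves a region with <2 subjects in a group."""


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    Defaults mirror a realistic multi-region post-mortem cohort: ~50 subjects
    per group, 11 regions with roughly a third of (subject, region) samples
    missing, subject intercept and residual SDs of a few tenths of a log2
    unit, and 30% of genes carrying an anterior-posterior gradient whose
    per-rank-step slope has SD 0.05 log2 (about half a log2 unit across the
    full 11-region axis).
    """

    n_control: int = 54
    n_case: int = 49
    regions: tuple[str, ...] = REGIONS_AP
    missing_rate: float = 0.35
    n_genes: int = 2000
    gradient_fraction: float = 0.3
    gradient_effect_sd: float = 0.05
    gradient_min_slope: float = 0.0  # lower bound on |slope| of gradient genes
    subject_sd: float = 0.3
    noise_sd: float = 0.25
    attenuation: float = 0.7
    covariate_effects: dict[str, float] | None = None
    emit_counts: bool = False
    nb_dispersion: float = 10.0
    mean_log_expr: float = 4.0
    gene_mean_sd: float = 2.0  # spread of per-gene baseline abundance (log2)
    library_size: float = 3.0e7
    effective_length_bp: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.gradient_fraction <= 1):
            raise ValueError("gradient_fraction must be in [0, 1]")
        if not (0 <= self.attenuation <= 1):
            raise ValueError("attenuation must be in [0, 1]")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("regions must be unique")
        for name in (
            "gradient_effect_sd",
            "subject_sd",
            "noise_sd",
            "gradient_min_slope",
            "gene_mean_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery benchmarking."""

    gradient_gene_ids: frozenset
    per_gene_slope: dict[str, float]
    subject_intercepts: dict[str, float]
    expected_attenuated_pairs: frozenset = field(default_factory=frozenset)


def _subject_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_control + config.n_case
    width = len(str(n))
    ids = [f"ctrl{str(i + 1).zfill(width)}" for i in range(config.n_control)] + [
        f"case{str(i + 1).zfill(width)}" for i in range(config.n_case)
    ]
    diagnosis = ["control"] * config.n_control + ["case"] * config.n_case
    return pd.DataFrame(
        {
            "subject_id": ids,
            "diagnosis": diagnosis,
            "age": np.round(rng.uniform(2.0, 68.0, size=n), 1),
            "sex": rng.choice(["M", "F"], size=n),
            "batch": rng.choice(["batch1", "batch2"], size=n),
            "intercept": rng.normal(0.0, config.subject_sd, size=n),
        }
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, sample metadata, ground truth).

    Returns a log2-scale genes x samples DataFrame whose columns align 1:1
    with the metadata rows; output is a pure function of the config
    (identical seed implies bit-identical matrices).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ranks = region_ranks(config.regions)
    genes = [f"g{str(i).zfill(len(str(config.n_genes)))}" for i in range(config.n_genes)]

    n_grad = int(round(config.gradient_fraction * config.n_genes))
    grad_idx = rng.choice(config.n_genes, size=n_grad, replace=False)
    slopes = np.zeros(config.n_genes)
    z = rng.normal(0.0, config.gradient_effect_sd or 1.0, size=n_grad)
    if config.gradient_effect_sd == 0:
        z = np.zeros(n_grad)
    mag = config.gradient_min_slope + np.abs(z)
    slopes[grad_idx] = np.where(z >= 0, mag, -mag)

    # per-gene baseline abundance; cancels in all within-gene contrasts but
    # gives samples the strong mutual correlation real expression data show
    baseline = rng.normal(config.mean_log_expr, config.gene_mean_sd, size=config.n_genes)

    subjects = _subject_frame(config, rng)

    # region-level missingness: independent Bernoulli per (subject, region)
    present = rng.random((len(subjects), len(config.regions))) >= config.missing_rate
    for j, region in enumerate(config.regions):
        for diag in ("control", "case"):
            n_here = int(present[(subjects["diagnosis"] == diag).to_numpy(), j].sum())
            if n_here < 2:
                raise InfeasibleDesignError(
                    f"region {region} has {n_here} {diag} subjects after missingness; "
                    "lower missing_rate or raise the group size"
                )

    # nuisance covariate machinery (optional)
    cov_effects: dict[str, np.ndarray] = {}
    cov_values: dict[str, pd.Series] = {}
    if config.covariate_effects:
        for name, sd in config.covariate_effects.items():
            if sd < 0:
                raise ValueError("covariate effect SDs must be >= 0")
            cov_effects[name] = rng.normal(0.0, sd, size=config.n_genes)
            if name == "age":
                v = subjects["age"].astype(float)
                cov_values[name] = (v - v.mean()) / v.std()
            elif name == "sex":
                cov_values[name] = subjects["sex"].map({"M": -0.5, "F": 0.5}).astype(float)
            elif name == "batch":
                cov_values[name] = subjects["batch"].map(
                    {"batch1": -0.5, "batch2": 0.5}
                ).astype(float)
            else:  # generic numeric subject-level covariate, added to metadata
                vals = rng.normal(0.0, 1.0, size=len(subjects))
                cov_values[name] = pd.Series(vals, index=subjects.index)
                subjects[name] = np.round(vals, 4)

    rows = []
    columns = []
    sample_ids = []
    for i, subj in subjects.iterrows():
        lam = config.attenuation if subj["diagnosis"] == "case" else 1.0
        for j, region in enumerate(config.regions):
            if not present[i, j]:
                continue
            mean = baseline + subj["intercept"] + slopes * ranks[region] * lam
            for name, eff in cov_effects.items():
                mean = mean + eff * cov_values[name].iloc[i]
            sid = f"{subj['subject_id']}_{sanitize_region(region)}"
            sample_ids.append(sid)
            columns.append(mean)
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subj["subject_id"],
                    "region": region,
                    "diagnosis": subj["diagnosis"],
                    "age": subj["age"],
                    "sex": subj["sex"],
                    "batch": subj["batch"],
                    **{
                        name: subjects.loc[i, name]
                        for name in (config.covariate_effects or {})
                        if name in subjects.columns
                        and name not in ("age", "sex", "batch")
                    },
                }
            )

    means = np.column_stack(columns)
    noise = rng.normal(0.0, config.noise_sd, size=means.shape)
    expr = pd.DataFrame(
        means + noise, index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    meta = pd.DataFrame(rows)

    grad_ids = frozenset(genes[i] for i in grad_idx)
    if config.attenuation < 1 and n_grad > 0:
        from .pairwise import all_region_pairs

        expected = frozenset(all_region_pairs(config.regions))
    else:
        expected = frozenset()
    truth = SyntheticTruth(
        gradient_gene_ids=grad_ids,
        per_gene_slope={g: float(s) for g, s in zip(genes, slopes)},
        subject_intercepts=dict(
            zip(subjects["subject_id"], subjects["intercept"].astype(float))
        ),
        expected_attenuated_pairs=expected,
    )
    return expr, meta, truth


def emit_counts(
    expr: pd.DataFrame,
    config: SimulationConfig,
    effective_lengths: pd.Series | None = None,
) -> CountMatrix:
    """Materialise negative-binomial counts from a log2 expression matrix.

    Per sample, expected counts are proportional to 2^expr rescaled to the
    configured library size; counts are gamma-Poisson draws with dispersion
    ``nb_dispersion`` (variance mu + mu^2/dispersion). A -inf expression
    entry is the structural-zero sentinel and yields count 0; any other
    non-finite value is rejected.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    vals = expr.to_numpy(dtype=float)
    bad = np.isnan(vals) | (vals == np.inf)
    if bad.any():
        raise ValueError("expression matrix contains NaN or +inf entries")
    rng = np.random.default_rng([int(config.seed), 0xC0DE])
    mu = np.where(vals == -np.inf, 0.0, np.exp2(np.where(vals == -np.inf, 0.0, vals)))
    colsum = mu.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("a sample has zero total expression")
    mean = mu / colsum * config.library_size
    shape = config.nb_dispersion
    lam = np.where(mean > 0, rng.gamma(shape, 1.0, size=mean.shape) * mean / shape, 0.0)
    counts = rng.poisson(lam)
    if effective_lengths is None:
        effective_lengths = pd.Series(
            config.effective_length_bp, index=expr.index, name="effective_length"
        )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=expr.index, columns=expr.columns),
        effective_length=effective_lengths.reindex(expr.index),
    )
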