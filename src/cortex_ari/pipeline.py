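"""End-to-end orchestration: simulate -> preprocess -> pairwise DE ->
permutation ARI -> bootstrap ARI -> ARI genes -> effect-size slope.

A run is driven by a :class:`RunConfig` (typically loaded from YAML), writes
plain-text TSV/JSON artifacts per stage into the output directory, and
records a manifest with per-stage seeds, wall times, and artifact SHA-256
hashes. Stage seeds are derived from the master seed by a keyed hash of the
stage name, so enabling or disabling one stage never perturbs another's
random stream; two runs with the same config produce bit-identical seeded
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .bootstrap import bootstrap_ari, bootstrap_table, pair_seed
from .genes import (
    build_ari_groups,
    control_region_medians,
    filter_ari_genes,
    records_table,
)
from .pairwise import all_region_pairs, count_de
from .permutation import ATTENUATED, ari_test, outcomes_table
from .preprocess import (
    detect_outliers,
    filter_features,
    log_normalize,
    regress_covariates,
    validate_metadata,
)
from .regions import REGIONS_AP, region_ranks
from .slope import compute_log2fc, slope_bootstrap
from .synthetic import SimulationConfig, emit_counts, generate_dataset

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "pairwise_de", "ari_perm", "ari_boot", "ari_genes", "slope")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Keyed, stable derivation of a per-stage seed below 2^31."""
    return (int(master_seed) * 2654435761 + crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    # input: either a simulation or paths to existing artifacts
    simulate: SimulationConfig | None = None
    counts_path: str | None = None
    lengths_path: str | None = None
    expr_path: str | None = None
    meta_path: str | None = None
    # stage parameters
    alpha: float = 0.05
    prior: float = 0.5
    regress: bool = True
    outlier_filter: bool = True
    B_perm: int = 10_000
    B_boot: int = 10_000
    k_boot: int = 10
    occurrence_threshold: float = 0.95
    p_threshold: float = 0.05
    fdr_boot: float = 0.05
    n_boot_slope: int = 1000
    slope_region: str = "BA17"
    write_gene_tables: bool = False
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; valid: {STAGES}")
        self.stages = {s: self.stages.get(s, True) for s in STAGES}
        if self.simulate is None and self.expr_path is None and self.counts_path is None:
            raise ConfigError("provide a simulate block or expr/counts paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        sim = raw.pop("simulate", None)
        try:
            if sim is not None:
                sim = SimulationConfig(**sim)
                sim.validate()
            return cls(simulate=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if d.get("simulate") is not None:
            d["simulate"]["regions"] = list(d["simulate"]["regions"])
        return yaml.safe_dump(d, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(config.to_yaml())
    manifest: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "seconds": round(time.time() - t0, 3),
            "artifacts": {str(p.relative_to(out)): _sha256(p) for p in paths},
        }

    def run_stage(stage, fn):
        if not config.stages.get(stage, False):
            return
        t0 = time.time()
        try:
            paths = fn()
        except Exception as exc:
            _write_manifest(out, manifest)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, t0, paths)

    state: dict = {}

    # ---- simulate
    def do_simulate() -> list[Path]:
        sim = dataclasses.replace(
            config.simulate, seed=stage_seed(config.seed, "simulate")
        )
        expr, meta, truth = generate_dataset(sim)
        d = out / "sim"
        d.mkdir(exist_ok=True)
        cio.write_matrix_tsv(expr, d / "expr.tsv")
        cio.write_metadata(meta, d / "meta.tsv")
        cio.write_truth(truth, d / "truth.tsv")
        paths = [d / "expr.tsv", d / "meta.tsv", d / "truth.tsv"]
        state.update(expr=expr, meta=meta, truth=truth, regions=sim.regions)
        if sim.emit_counts:
            cm = emit_counts(expr, sim)
            cio.write_counts(cm, d / "counts.tsv", d / "lengths.tsv")
            paths += [d / "counts.tsv", d / "lengths.tsv"]
            state["counts"] = cm
        return paths

    if config.simulate is not None:
        run_stage("simulate", do_simulate)
    else:
        if config.counts_path:
            state["counts"] = cio.read_counts(config.counts_path, config.lengths_path)
        if config.expr_path:
            state["expr"] = cio.read_matrix_tsv(config.expr_path)
        state["meta"] = cio.read_metadata(config.meta_path)
        state["regions"] = tuple(
            r for r in REGIONS_AP if r in set(state["meta"]["region"])
        ) or tuple(sorted(set(state["meta"]["region"])))

    # ---- preprocess
    def do_preprocess() -> list[Path]:
        d = out / "preprocess"
        d.mkdir(exist_ok=True)
        paths: list[Path] = []
        meta = state["meta"]
        if "counts" in state and "expr" not in state:
            cm = filter_features(state["counts"])
            expr = log_normalize(cm, prior=config.prior)
        else:
            expr = state["expr"]
        validate_metadata(meta, expr.columns)
        report = detect_outliers(expr, meta)
        report.to_csv(d / "outliers.tsv", sep="\t", index=False)
        paths.append(d / "outliers.tsv")
        if config.outlier_filter and report["outlier"].any():
            keep = set(report.loc[~report["outlier"], "sample_id"])
            expr = expr[[c for c in expr.columns if c in keep]]
            meta = meta[meta["sample_id"].isin(keep)].reset_index(drop=True)
        if config.regress:
            reg = regress_covariates(expr, meta)
            expr = reg.values
            (d / "regression_provenance.json").write_text(
                json.dumps(
                    {
                        "removed_covariates": list(reg.removed_covariates),
                        "ols_fallback_genes": list(reg.ols_fallback_genes),
                    },
                    indent=2,
                )
            )
            paths.append(d / "regression_provenance.json")
        cio.write_matrix_tsv(expr, d / "regressed.tsv")
        paths.append(d / "regressed.tsv")
        state["expr"] = expr
        state["meta"] = meta
        return paths

    run_stage("preprocess", do_preprocess)
    expr, meta = state["expr"], state["meta"]
    pairs = all_region_pairs(state["regions"])

    # ---- pairwise DE on true labels
    def do_pairwise() -> list[Path]:
        d = out / "pairwise"
        d.mkdir(exist_ok=True)
        rows = []
        for pair in pairs:
            for group in ("control", "case"):
                res = count_de(expr, meta, pair, group, alpha=config.alpha)
                rows.append(
                    {
                        "pair": str(pair),
                        "group": group,
                        "n_subjects": res.n_subjects,
                        "n_de": res.n_de if res.feasible else np.nan,
                        "feasible": res.feasible,
                    }
                )
                if config.write_gene_tables and res.feasible:
                    fn = d / f"de_{str(pair).replace('/', '-').replace('|', '_vs_')}_{group}.tsv"
                    res.table.to_csv(fn, sep="\t")
        pd.DataFrame(rows).to_csv(d / "summary.tsv", sep="\t", index=False)
        return [d / "summary.tsv"]

    run_stage("pairwise_de", do_pairwise)

    # ---- permutation ARI (tracks occurrence for the gene stage)
    def do_perm() -> list[Path]:
        d = out / "perm"
        d.mkdir(exist_ok=True)
        base = stage_seed(config.seed, "ari_perm")
        outcomes = []
        for pair in pairs:
            s = int(np.random.SeedSequence(pair_seed(base, pair)).generate_state(1)[0] % 2**31)
            outcomes.append(
                ari_test(
                    expr,
                    meta,
                    pair,
                    B=config.B_perm,
                    alpha=config.alpha,
                    seed=s,
                    p_threshold=config.p_threshold,
                    track_occurrence=True,
                )
            )
        outcomes_table(outcomes).to_csv(d / "outcomes.tsv", sep="\t", index=False)
        state["perm_outcomes"] = outcomes
        return [d / "outcomes.tsv"]

    run_stage("ari_perm", do_perm)

    # ---- bootstrap ARI
    def do_boot() -> list[Path]:
        d = out / "boot"
        d.mkdir(exist_ok=True)
        outcomes = bootstrap_ari(
            expr,
            meta,
            pairs,
            B=config.B_boot,
            k=config.k_boot,
            alpha=config.alpha,
            fdr=config.fdr_boot,
            seed=stage_seed(config.seed, "ari_boot"),
        )
        bootstrap_table(outcomes).to_csv(d / "outcomes.tsv", sep="\t", index=False)
        state["boot_outcomes"] = outcomes
        return [d / "outcomes.tsv"]

    run_stage("ari_boot", do_boot)

    # ---- ARI gene extraction from permutation-attenuated pairs
    def do_genes() -> list[Path]:
        if "perm_outcomes" not in state:
            raise ConfigError("ari_genes requires the ari_perm stage")
        d = out / "genes"
        d.mkdir(exist_ok=True)
        records_by_pair = {}
        for o in state["perm_outcomes"]:
            if o.classification != ATTENUATED:
                continue
            records_by_pair[o.pair] = filter_ari_genes(
                o.control_de, o.occurrence, o.B, threshold=config.occurrence_threshold
            )
        paths = []
        if any(records_by_pair.values()):
            groups = build_ari_groups(
                records_by_pair,
                region_ranks(state["regions"]),
                control_region_medians(expr, meta),
            )
            (d / "ari_down.txt").write_text("\n".join(sorted(groups.ari_down)) + "\n")
            (d / "ari_up.txt").write_text("\n".join(sorted(groups.ari_up)) + "\n")
            paths += [d / "ari_down.txt", d / "ari_up.txt"]
            state["ari_groups"] = groups
        records = [r for recs in records_by_pair.values() for r in recs]
        records_table(records).to_csv(d / "ari_genes.tsv", sep="\t", index=False)
        paths.append(d / "ari_genes.tsv")
        return paths

    run_stage("ari_genes", do_genes)

    # ---- regional vs whole-cortex effect-size slope
    def do_slope() -> list[Path]:
        d = out / "slope"
        d.mkdir(exist_ok=True)
        x = compute_log2fc(expr, meta, scope=config.slope_region)
        y = compute_log2fc(expr, meta, scope="whole_cortex")
        fit = slope_bootstrap(
            x, y, n_boot=config.n_boot_slope, seed=stage_seed(config.seed, "slope")
        )
        pd.DataFrame({"gene_id": x.index, "region_log2fc": x.to_numpy(),
                      "cortex_log2fc": y.loc[x.index].to_numpy()}).to_csv(
            d / "effects.tsv", sep="\t", index=False
        )
        (d / "slope.json").write_text(json.dumps(fit.to_dict(), indent=2))
        return [d / "effects.tsv", d / "slope.json"]

    run_stage("slope", do_slope)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
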