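"""ARI gene extraction: occurrence filter, region assignment, grouping."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import cortex_ari as ca
from cortex_ari.genes import control_region_medians, filter_ari_genes, records_table
from cortex_ari.pairwise import PairKey, paired_differences


class TestPermutationOccurrence:
    def test_constant_gene_never_occurs(self, tiny_perm_dataset):
        _, expr, meta, _ = tiny_perm_dataset
        expr = expr.copy()
        expr.iloc[0, :] = 3.14
        occ = ca.permutation_occurrence(expr, meta, PairKey.make("BA9", "BA17"),
                                        B=40, seed=0)
        assert occ.iloc[0] == 0

    def test_matches_exhaustive_enumeration(self, tiny_perm_dataset):
        """Occurrence counts from the exhaustive stream equal an independent
        scipy/statsmodels recomputation over all 20 label assignments."""
        _, expr, meta, _ = tiny_perm_dataset
        pair = PairKey.make("BA9", "BA17")
        out = ca.ari_test(expr, meta, pair, exhaustive=True, track_occurrence=True)

        case = ca.paired_subjects(meta, pair, "case")
        ctrl = ca.paired_subjects(meta, pair, "control")
        pool = sorted(set(case) | set(ctrl))
        counts = pd.Series(0.0, index=expr.index)
        for combo in itertools.combinations(range(len(pool)), len(case)):
            pseudo_ctrl = [pool[i] for i in range(len(pool)) if i not in combo]
            D = paired_differences(expr, meta, pair, sorted(pseudo_ctrl))
            ps = []
            for row in D:
                nz = row[row != 0]
                ps.append(1.0 if nz.size == 0 else sps.wilcoxon(nz, mode="exact").pvalue)
            q = multipletests(ps, method="fdr_bh")[1]
            counts[q < 0.05] += 1
        assert out.occurrence.equals(counts)

    def test_same_seed_same_stream_as_ari_test(self, tiny_perm_dataset):
        _, expr, meta, _ = tiny_perm_dataset
        pair = PairKey.make("BA9", "BA17")
        a = ca.ari_test(expr, meta, pair, B=30, seed=8, track_occurrence=True)
        occ = ca.permutation_occurrence(expr, meta, pair, B=30, seed=8)
        assert a.occurrence.equals(occ)
        b = ca.ari_test(expr, meta, pair, B=30, seed=8, track_occurrence=False)
        assert np.array_equal(a.perm_diffs, b.perm_diffs)


class TestFilterAriGenes:
    def make_de_result(self):
        pair = PairKey.make("BA9", "BA17")
        table = pd.DataFrame(
            {
                "p": [0.001, 0.002, 0.003, 0.004, 0.5],
                "q": [0.01, 0.01, 0.01, 0.01, 0.5],
                "direction": [1, -1, 1, 1, 0],
                "de_flag": [True, True, True, True, False],
                "median_diff": [0.5, -0.4, 0.3, 0.2, 0.0],
                "mean_diff": [0.5, -0.4, 0.3, 0.2, 0.0],
            },
            index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
        )
        return ca.DEResult(pair=pair, group="control", n_subjects=10, alpha=0.05,
                           table=table, n_de=4,
                           de_genes=frozenset(["g0", "g1", "g2", "g3"]))

    def test_boundary_semantics_strictly_less_than(self):
        de = self.make_de_result()
        B = 1000
        occ = pd.Series({"g0": 0, "g1": B, "g2": int(0.95 * B), "g3": int(0.95 * B) - 1,
                         "g4": 0})
        records = filter_ari_genes(de, occ, B, threshold=0.95)
        kept = {r.gene_id for r in records}
        assert kept == {"g0", "g3"}  # occurrence B and exactly 0.95B excluded

    def test_region_assignment_follows_higher_control_expression(self):
        de = self.make_de_result()
        occ = pd.Series(0.0, index=de.table.index)
        records = {r.gene_id: r for r in filter_ari_genes(de, occ, 100)}
        # paired difference is BA17 - BA9: positive median -> higher in BA17
        assert records["g0"].assigned_region == "BA17"
        assert records["g1"].assigned_region == "BA9"

    def test_only_true_control_de_genes_considered(self):
        de = self.make_de_result()
        occ = pd.Series(0.0, index=de.table.index)
        kept = {r.gene_id for r in filter_ari_genes(de, occ, 100)}
        assert "g4" not in kept

    def test_threshold_monotonicity(self):
        de = self.make_de_result()
        rng = np.random.default_rng(0)
        occ = pd.Series(rng.integers(0, 100, size=5).astype(float), index=de.table.index)
        sizes = [len(filter_ari_genes(de, occ, 100, threshold=t))
                 for t in (0.2, 0.5, 0.8, 1.0)]
        assert sizes == sorted(sizes)

    def test_missing_occurrence_rejected(self):
        de = self.make_de_result()
        with pytest.raises(ValueError, match="occurrence undefined"):
            filter_ari_genes(de, pd.Series({"g0": 0.0}), 100)


class TestBuildGroups:
    def test_monotone_posterior_increase_is_ari_down(self):
        regions = ("BA9", "BA7", "BA17")
        ranks = ca.region_ranks(regions)
        summary = pd.DataFrame(
            {"BA9": [1.0, 3.0], "BA7": [2.0, 2.0], "BA17": [3.0, 1.0]},
            index=["up_gene", "down_gene"],
        )
        rec = lambda g: ca.ARIGeneRecord(g, PairKey.make("BA9", "BA17"), 0.1, "BA17", 0.01)
        groups = ca.build_ari_groups([[rec("up_gene"), rec("down_gene")]], ranks, summary)
        assert groups.ari_down == {"up_gene"}   # rises along the A-P axis
        assert groups.ari_up == {"down_gene"}   # falls along the A-P axis

    def test_union_without_duplicates(self):
        regions = ("BA9", "BA7", "BA17")
        ranks = ca.region_ranks(regions)
        summary = pd.DataFrame(
            {"BA9": [1.0], "BA7": [2.0], "BA17": [3.0]}, index=["g"]
        )
        r1 = ca.ARIGeneRecord("g", PairKey.make("BA9", "BA17"), 0.1, "BA17", 0.01)
        r2 = ca.ARIGeneRecord("g", PairKey.make("BA9", "BA7"), 0.2, "BA7", 0.02)
        r3 = ca.ARIGeneRecord("g", PairKey.make("BA7", "BA17"), 0.3, "BA17", 0.03)
        groups = ca.build_ari_groups([[r1], [r2], [r3]], ranks, summary)
        assert groups.ari_down == {"g"} and groups.ari_up == frozenset()
        assert r1.group == r2.group == r3.group == "ari_down"

    def test_flat_profile_left_unassigned(self):
        regions = ("BA9", "BA7", "BA17")
        summary = pd.DataFrame({"BA9": [1.0], "BA7": [1.0], "BA17": [1.0]}, index=["g"])
        rec = ca.ARIGeneRecord("g", PairKey.make("BA9", "BA17"), 0.1, "BA17", 0.01)
        groups = ca.build_ari_groups([[rec]], ca.region_ranks(regions), summary)
        assert groups.unassigned == {"g"}
        assert not groups.ari_down and not groups.ari_up

    def test_end_to_end_recovery_on_full_attenuation(self, strong_attenuation_dataset):
        """lambda = 0 run: the union ARI set recovers planted gradient genes
        with little contamination, and directions match the planted slopes."""
        cfg, expr, meta, truth = strong_attenuation_dataset
        pairs = ca.all_region_pairs(cfg.regions)
        outs = [ca.ari_test(expr, meta, p, B=200, seed=31, track_occurrence=True)
                for p in pairs]
        recs = {o.pair: filter_ari_genes(o.control_de, o.occurrence, o.B)
                for o in outs if o.classification == "attenuated"}
        assert recs, "no attenuated pairs on a full-attenuation fixture"
        groups = ca.build_ari_groups(
            recs, ca.region_ranks(cfg.regions), control_region_medians(expr, meta)
        )
        union = groups.ari_down | groups.ari_up
        grad = truth.gradient_gene_ids
        assert len(union & grad) / len(grad) >= 0.9
        assert len(union - grad) / len(union) <= 0.1
        # orientation: positive planted slope means posterior-high -> ari_down
        for g in sorted(union & grad):
            expected = "ari_down" if truth.per_gene_slope[g] > 0 else "ari_up"
            got = "ari_down" if g in groups.ari_down else "ari_up"
            assert got == expected

    def test_records_table_roundtrip(self):
        rec = ca.ARIGeneRecord("g1", PairKey.make("BA9", "BA17"), 0.25, "BA17", 0.01,
                               group="ari_down")
        tab = records_table([rec])
        assert tab.loc[0, "gene_id"] == "g1"
        assert tab.loc[0, "source_pair"] == "BA9|BA17"
        assert tab.loc[0, "group"] == "ari_down"
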