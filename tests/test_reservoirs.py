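import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from promscape import reservoirs as res
from promscape.consensus import build_consensus
from promscape.expression import quantify_window, tpm_from_counts
from promscape.genomic_io import (
    GeneModel,
    GenomicInterval,
    GenomeAssembly,
    PromoterWindow,
)
from promscape.occupancy import OccupancyMatrix, build_occupancy_matrix

from oracles import neighbor_class_oracle


def matrix_from_counts(n_dbps_per_gene, n_cols=40):
    """Binary matrix whose row sums equal the requested per-gene counts."""
    rows = {}
    for gid, n in n_dbps_per_gene.items():
        row = np.zeros(n_cols, dtype=np.int8)
        row[:n] = 1
        rows[gid] = row
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"D{i}" for i in range(n_cols)])
    return OccupancyMatrix(df)


def gene(gid, tss, strand="+", chrom="chr1", length=100):
    if strand == "+":
        span = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        span = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
    return GeneModel(gid, "mRNA", span)


class TestCountThreshold:
    def test_fixed_mode_returns_configured_default(self):
        assert res.find_count_threshold([1, 2, 3], mode="fixed") == 7

    def test_valley_mode_lands_between_two_gaussian_modes(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([
            rng.normal(2, 1, 3000).clip(0), rng.normal(40, 4, 2000)
        ]).round().astype(int)
        t = res.find_count_threshold(values, mode="valley")
        assert 5 < t < 35

    def test_unimodal_falls_back_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        values = rng.normal(10, 2, 2000).round().astype(int).clip(0)
        with caplog.at_level(logging.WARNING):
            t = res.find_count_threshold(values, mode="valley", fixed=7)
        assert t == 7
        assert any("unimodal" in r.message for r in caplog.records)


class TestCallReservoirs:
    def test_strict_threshold_semantics(self):
        m = matrix_from_counts({"a": 8, "b": 7, "c": 20})
        tpm = {"a": 0.0, "b": 0.0, "c": 0.5}
        calls = res.call_reservoirs(m, tpm)
        assert calls.loc["a", "is_reservoir"]          # 8 > 7, silent
        assert not calls.loc["b", "is_reservoir"]      # exactly 7 is NOT enough
        assert not calls.loc["c", "is_reservoir"]      # expressed

    def test_tpm_boundary_is_strict(self):
        m = matrix_from_counts({"a": 10, "b": 10})
        calls = res.call_reservoirs(m, {"a": 0.001, "b": 0.0009})
        assert not calls.loc["a", "is_reservoir"]
        assert calls.loc["b", "is_reservoir"]

    def test_missing_expression_is_an_error(self):
        m = matrix_from_counts({"a": 10})
        with pytest.raises(ValueError):
            res.call_reservoirs(m, {})


class TestSuperenhancerOverlap:
    def test_toy_flags_match_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        wins = [
            PromoterWindow(f"g{i}", GenomicInterval("chr1", int(s), int(s) + 6000),
                           3000, int(s) + 3000, "+")
            for i, s in enumerate(rng.integers(0, 90_000, 5))
        ]
        ses = [GenomicInterval("chr1", int(s), int(s) + 8000)
               for s in rng.integers(0, 90_000, 3)]
        ses.append(GenomicInterval("chr2", 0, 1000))
        m = matrix_from_counts({w.gene_id: 10 for w in wins})
        calls = res.call_reservoirs(m, {w.gene_id: 0.0 for w in wins})
        calls, n = res.flag_superenhancer_overlap(calls, wins, ses)
        for w in wins:
            expected = any(
                s.chrom == w.chrom and s.start < w.end and w.start < s.end
                for s in ses
            )
            assert calls.loc[w.gene_id, "se_overlap"] == expected
        assert n == int(calls["se_overlap"].sum())  # all rows are reservoirs here

    def test_se_on_other_chromosome_not_flagged(self):
        w = PromoterWindow("g", GenomicInterval("chr1", 0, 6000), 3000, 3000, "+")
        m = matrix_from_counts({"g": 10})
        calls = res.call_reservoirs(m, {"g": 0.0})
        calls, n = res.flag_superenhancer_overlap(
            calls, [w], [GenomicInterval("chr2", 0, 10_000)]
        )
        assert not calls.loc["g", "se_overlap"] and n == 0


class TestNeighborClassification:
    OFFSETS = [250, 999, 1000, 1001]

    def test_truth_table_exhaustive(self):
        """All <=3-neighbor configurations x strands x offsets {250, 999,
        1000, 1001} bp up/downstream agree with the rule-table oracle."""
        signed = [o for d in self.OFFSETS for o in (d, -d)]
        n_checked = 0
        for q_strand in "+-":
            for k in range(0, 4):
                for offs in itertools.combinations(signed, k):
                    for strands in itertools.product("+-", repeat=k):
                        genes = [gene("q", 50_000, q_strand)]
                        for i, (o, s) in enumerate(zip(offs, strands)):
                            genes.append(gene(f"n{i}", 50_000 + o, s))
                        got = res.classify_neighbor(genes, "q", distance=1000)
                        want = neighbor_class_oracle(q_strand, list(zip(offs, strands)))
                        assert got == want, (q_strand, offs, strands)
                        n_checked += 1
        assert n_checked > 1000

    def test_vectorised_classifier_agrees_with_single_query(self):
        rng = np.random.default_rng(3)
        genes = [
            gene(f"g{i}", int(t), "+" if rng.random() < 0.5 else "-")
            for i, t in enumerate(np.cumsum(rng.integers(100, 2000, 40)) + 10_000)
        ]
        all_classes = res.classify_neighbors(genes, 1000)
        for g in genes:
            assert all_classes[g.gene_id] == res.classify_neighbor(genes, g.gene_id)

    def test_isolated_gene_is_none(self):
        assert res.classify_neighbor([gene("q", 5000)], "q") == "none"

    def test_opposite_strand_upstream_is_bidirectional(self):
        genes = [gene("q", 5000, "+"), gene("n", 4500, "-")]
        assert res.classify_neighbor(genes, "q") == "bidirectional"

    def test_two_neighbors_trump_bidirectional(self):
        genes = [gene("q", 5000, "+"), gene("n1", 4500, "-"), gene("n2", 5400, "+")]
        assert res.classify_neighbor(genes, "q") == "multiple_nearby"

    def test_absent_query_raises(self):
        with pytest.raises(KeyError):
            res.classify_neighbor([gene("a", 100)], "zzz")


class TestNeighborExpression:
    def test_fraction_zero_and_one(self):
        genes = [gene("q", 5000, "+"), gene("n", 4500, "-"),
                 gene("far", 50_000, "+")]
        m = matrix_from_counts({"q": 10, "n": 1, "far": 1})
        calls = res.call_reservoirs(m, {"q": 0.0, "n": 0.0, "far": 5.0})
        frac, _, _, status = res.neighbor_expression_status(
            calls, genes, {"q": 0.0, "n": 0.0, "far": 5.0}
        )
        assert frac == 0.0
        frac2, _, _, _ = res.neighbor_expression_status(
            calls, genes, {"q": 0.0, "n": 3.0, "far": 5.0}
        )
        assert frac2 == 1.0

    def test_chi2_matches_hand_computation(self):
        # 20 reservoirs + 80 non, all with one neighbor; expressed-neighbor
        # counts planted as [[5, 15], [60, 20]]
        genes, tpm, nd = [], {}, {}
        flags = {}
        i = 0
        for group, n_exp, n_tot in (("r", 5, 20), ("n", 60, 80)):
            for j in range(n_tot):
                q = f"{group}{j}"
                nb = f"{group}{j}_nb"
                genes += [gene(q, 100_000 * i + 5000, "+"),
                          gene(nb, 100_000 * i + 5600, "-")]
                tpm[q] = 0.0
                tpm[nb] = 5.0 if j < n_exp else 0.0
                nd[q] = 10 if group == "r" else 1
                nd[nb] = 1
                i += 1
        m = matrix_from_counts(nd)
        calls = res.call_reservoirs(m, {g: tpm.get(g, 0.0) if g in tpm else 0.0
                                        for g in nd})
        calls.loc[[f"n{j}" for j in range(80)], "is_reservoir"] = False
        calls.loc[[f"n{j}_nb" for j in range(80)], "is_reservoir"] = False
        frac, chi2, p, status = res.neighbor_expression_status(calls, genes, tpm)
        obs = None  # hand-check on the reservoir-query cells only
        # every *_nb gene also has a neighbor (its partner), so restrict the
        # hand computation to the same population the function used
        sub = status.dropna().astype(bool)
        is_res = calls.loc[sub.index, "is_reservoir"].astype(bool)
        table = np.array([
            [(sub & is_res).sum(), (~sub & is_res).sum()],
            [(sub & ~is_res).sum(), (~sub & ~is_res).sum()],
        ], float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert chi2 == pytest.approx(((table - exp) ** 2 / exp).sum())


class TestWindowNeighborhood:
    def _calls(self, gene_ids, reservoir=(), se=()):
        df = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
        df["is_reservoir"] = [g in reservoir for g in gene_ids]
        df["se_overlap"] = [g in se for g in gene_ids]
        return df

    def test_printed_toy_window_mean(self):
        genes = [gene(f"g{i}", 10_000 * (i + 1)) for i in range(5)]
        tpm = {f"g{i}": float(i + 1) for i in range(5)}  # 1..5
        calls = self._calls([g.gene_id for g in genes])
        df, _ = res.window_neighborhood_expression(genes, tpm, calls, k=5)
        assert list(df.index) == ["g2"]  # only the full window's center
        assert df.loc["g2", "neighbor_mean_tpm"] == pytest.approx((1 + 2 + 4 + 5) / 4)

    def test_constant_expression_flat_and_nonsignificant(self):
        genes = [gene(f"g{i}", 10_000 * (i + 1)) for i in range(20)]
        tpm = {g.gene_id: 1.0 for g in genes}
        calls = self._calls([g.gene_id for g in genes], reservoir={"g5", "g9"})
        df, tests = res.window_neighborhood_expression(genes, tpm, calls, k=5)
        assert np.allclose(df["neighbor_mean_tpm"], 1.0)
        assert tests["reservoir_vs_non"][1] == pytest.approx(1.0)

    def test_planted_low_expression_neighborhoods_detected(self):
        rng = np.random.default_rng(6)
        genes = [gene(f"g{i}", 10_000 * (i + 1)) for i in range(200)]
        reservoir = {f"g{i}" for i in range(10, 200, 20)}
        tpm = {}
        for i, g in enumerate(genes):
            near_res = any(abs(i - j) <= 2 for j in range(10, 200, 20))
            base = 0.5 if near_res else 20.0
            tpm[g.gene_id] = float(base * rng.uniform(0.5, 1.5))
        calls = self._calls([g.gene_id for g in genes], reservoir=reservoir)
        df, tests = res.window_neighborhood_expression(genes, tpm, calls, k=5)
        stat, p = tests["reservoir_vs_non"]
        res_mean = df.loc[df["is_reservoir"], "neighbor_mean_tpm"].mean()
        non_mean = df.loc[~df["is_reservoir"], "neighbor_mean_tpm"].mean()
        assert res_mean < non_mean and p < 0.05

    def test_short_chromosome_contributes_nothing(self):
        genes = [gene("a", 1000), gene("b", 5000), gene("c", 9000)]
        calls = self._calls(["a", "b", "c"])
        df, _ = res.window_neighborhood_expression(
            genes, {g.gene_id: 1.0 for g in genes}, calls, k=5
        )
        assert df.empty


class TestGhostZombieAndConservative:
    def _calls(self):
        m = matrix_from_counts({"r1": 10, "r2": 12, "n1": 2})
        return res.call_reservoirs(m, {"r1": 0.0, "r2": 0.0, "n1": 5.0})

    def test_forced_examples(self):
        calls = res.classify_ghost_zombie(
            self._calls(), {"r1": 0.0, "r2": 2.0, "n1": 0.0}
        )
        assert calls.loc["r1", "subclass"] == "ghost"
        assert calls.loc["r2", "subclass"] == "zombie"
        assert calls.loc["n1", "subclass"] == "none"

    def test_partition_invariant(self):
        calls = res.classify_ghost_zombie(
            self._calls(), {"r1": 0.0005, "r2": 0.001, "n1": 7.0}
        )
        is_res = calls["is_reservoir"]
        assert ((calls.loc[is_res, "subclass"] != "none").all())
        assert (calls.loc[~is_res, "subclass"] == "none").all()

    def test_missing_proseq_for_reservoir_raises(self):
        with pytest.raises(ValueError):
            res.classify_ghost_zombie(self._calls(), {"r1": 0.0, "n1": 0.0})

    def test_conservative_truth_table(self):
        calls = self._calls()
        wt = pd.DataFrame(
            {
                "total_1": {"r1": 0.0, "r2": 0.0, "n1": 0.0},
                "polya_1": {"r1": 0.0, "r2": 0.5, "n1": 0.0},
            }
        )
        calls = res.conservative_set(calls, wt)
        assert calls.loc["r1", "conservative"]        # silent in every sample
        assert not calls.loc["r2", "conservative"]    # one polyA sample expressed
        assert not calls.loc["n1", "conservative"]    # not a reservoir at all


class TestChromatinAssociation:
    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(7)
        flags = {f"g{i}": i < 100 for i in range(200)}
        tpm = {f"g{i}": float((4.0 if i < 100 else 1.0) * rng.uniform(0.8, 1.2))
               for i in range(200)}
        out = res.chromatin_association(flags, tpm)
        assert out["ratio"] == pytest.approx(4.0, rel=0.15)
        assert out["p"] < 1e-6

    def test_identical_distributions_ratio_one(self):
        flags = {f"g{i}": i % 2 == 0 for i in range(40)}
        tpm = {f"g{i}": 2.0 for i in range(40)}
        out = res.chromatin_association(flags, tpm)
        assert out["ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_empty_complement_gives_nan(self):
        out = res.chromatin_association({"a": True, "b": True}, {"a": 1.0, "b": 2.0})
        assert np.isnan(out["ratio"]) and out["n_without"] == 0


class TestPlantedRecovery:
    def test_reservoir_and_subtype_labels_recovered_exactly(self, default_dataset):
        """Module chain on the default synthetic study: consensus (all DBPs)
        -> occupancy -> reservoir calls -> ghost/zombie split recovers every
        planted label (precision = recall = 1) under the planting margins."""
        ds = default_dataset
        sets = [build_consensus(ds.peaksets[d], d) for d in ds.dbp_names]
        matrix = build_occupancy_matrix(sets, ds.promoters)
        total_cols = [s for s, a in ds.gene_tpm.assays.items() if a == "total_rna"]
        tpm_total = ds.gene_tpm.tpm[total_cols].mean(axis=1)
        calls = res.call_reservoirs(matrix, tpm_total)

        pro_samples = {s: ds.reads[s] for s, a in ds.read_assays.items()
                       if a == "pro_seq"}
        counts = quantify_window(pro_samples, ds.promoters,
                                 {s: "pro_seq" for s in pro_samples})
        pro_tpm = tpm_from_counts(counts).tpm.mean(axis=1)
        calls = res.classify_ghost_zombie(calls, pro_tpm)

        truth = ds.manifest["planted_class"]
        planted_res = truth.str.startswith("reservoir")
        assert (calls["is_reservoir"].reindex(truth.index) == planted_res).all()
        got_ghost = (calls["subclass"] == "ghost").reindex(truth.index)
        assert (got_ghost == (truth == "reservoir_ghost")).all()
        got_zombie = (calls["subclass"] == "zombie").reindex(truth.index)
        assert (got_zombie == (truth == "reservoir_zombie")).all()
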