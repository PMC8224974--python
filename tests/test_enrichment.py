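import numpy as np
import pytest
from scipy import stats

from promscape import enrichment as enr
from promscape._rng import substream
from promscape.consensus import ConsensusPeakSet
from promscape.genomic_io import GenomeAssembly, GenomicInterval, RepeatElement
from promscape.occupancy import OccupancyMatrix, build_occupancy_matrix

import pandas as pd


@pytest.fixture
def genome():
    return GenomeAssembly({"chr1": 1_000_000, "chr2": 500_000},
                          canonical=frozenset({"chr1", "chr2"}))


def cset(dbp, triples):
    return ConsensusPeakSet(dbp, [GenomicInterval(c, s, e) for c, s, e in triples], 2)


class TestShuffle:
    def test_width_multiset_and_counts_preserved_per_chromosome(self, genome):
        rng = np.random.default_rng(0)
        triples = [("chr1", int(s), int(s + w))
                   for s, w in zip(rng.integers(0, 900_000, 40),
                                   rng.integers(50, 5000, 40))]
        triples += [("chr2", int(s), int(s + w))
                    for s, w in zip(rng.integers(0, 400_000, 25),
                                    rng.integers(50, 5000, 25))]
        cs = cset("X", triples)
        shuffled = enr.shuffle_peaks(cs, genome, seed=3)
        for chrom in ("chr1", "chr2"):
            orig = sorted(e - s for c, s, e in triples if c == chrom)
            new = sorted(iv.end - iv.start for iv in shuffled if iv.chrom == chrom)
            assert new == orig
        assert all(0 <= iv.start and iv.end <= genome.length(iv.chrom)
                   for iv in shuffled)

    def test_deterministic_given_seed(self, genome):
        cs = cset("X", [("chr1", 100, 500), ("chr2", 1000, 1500)])
        a = enr.shuffle_peaks(cs, genome, seed=9)
        b = enr.shuffle_peaks(cs, genome, seed=9)
        assert a == b
        assert a != enr.shuffle_peaks(cs, genome, seed=10)

    def test_peak_wider_than_chromosome_rejected(self):
        g = GenomeAssembly({"chr1": 100})
        cs = ConsensusPeakSet("X", [GenomicInterval("chr1", 0, 100)], 2)
        enr.shuffle_peaks(cs, g, 0)  # width == length is allowed
        g2 = GenomeAssembly({"chr1": 99})
        with pytest.raises(ValueError):
            enr.shuffle_peaks(cs, g2, 0)


class TestPermutationEnrichment:
    def test_features_tiling_genome_degenerate(self, genome):
        feats = [GenomicInterval(c, 0, genome.length(c)) for c in genome.names]
        res = enr.permutation_enrichment(
            cset("X", [("chr1", 10, 20), ("chr2", 30, 40)]), feats, genome,
            n_perm=50, seed=1,
        )
        assert res.null_sd == 0 and res.z is None
        assert res.direction == "undefined"
        assert res.observed == 2

    def test_empty_feature_set(self, genome):
        res = enr.permutation_enrichment(
            cset("X", [("chr1", 10, 20)]), [], genome, n_perm=20, seed=1
        )
        assert res.observed == 0 and (res.null_draws == 0).all()

    def test_planted_toy_enriched_and_dual_implementation_z(self, genome):
        """Peaks copied onto features: significant, and z matches an
        independent re-implementation of the shuffle-count loop run with
        the same named substream."""
        rng = np.random.default_rng(42)
        starts = np.sort(rng.choice(990_000, size=60, replace=False))
        feats = [GenomicInterval("chr1", int(s), int(s) + 400) for s in starts]
        cs = ConsensusPeakSet("TFX", list(feats), 2)
        res = enr.permutation_enrichment(
            cs, feats, genome, n_perm=200, seed=5, feature_set="toy"
        )
        assert res.p_empirical < 0.01
        assert res.direction == "enriched"
        assert res.observed == 60

        # independent oracle: same generator contract, naive python counting
        rng2 = substream(5, "perm", "TFX", "toy")
        widths = np.full(60, 400)
        fs = starts
        fe = starts + 400
        draws = []
        mat = rng2.integers(0, genome.length("chr1") - widths + 1, size=(200, 60))
        for row in mat:
            count = 0
            for s in row:
                e = s + 400
                if any(fs[k] < e and s < fe[k] for k in range(len(fs))):
                    count += 1
            draws.append(count)
        draws = np.asarray(draws)
        z_expected = (60 - draws.mean()) / draws.std(ddof=1)
        assert res.z == pytest.approx(z_expected, rel=1e-12)

    def test_adding_features_never_decreases_observed(self, genome):
        rng = np.random.default_rng(7)
        peaks = [("chr1", int(s), int(s + 300)) for s in rng.integers(0, 900_000, 50)]
        cs = cset("X", peaks)
        feats = [GenomicInterval("chr1", int(s), int(s) + 500)
                 for s in rng.integers(0, 900_000, 30)]
        prev = -1
        for k in (0, 5, 10, 20, 30):
            res = enr.permutation_enrichment(cs, feats[:k], genome, n_perm=1, seed=0)
            assert res.observed >= prev
            prev = res.observed

    def test_fisher_table_rows_sum_to_peak_count(self, genome):
        cs = cset("X", [("chr1", i * 1000, i * 1000 + 100) for i in range(30)])
        feats = [GenomicInterval("chr1", 0, 15_000)]
        res = enr.permutation_enrichment(cs, feats, genome, n_perm=50, seed=2)
        assert 0 <= res.observed <= cs.n_peaks
        assert res.p_fisher is not None and 0 <= res.p_fisher <= 1


class TestRepeatMatrix:
    def _repeats(self, genome, rng):
        out = []
        for fam, cls, n in (("FamA", "C1", 40), ("FamB", "C2", 40)):
            for s in rng.integers(0, 900_000, n):
                out.append(RepeatElement(
                    GenomicInterval("chr1", int(s), int(s) + 800), f"{fam}_x", fam, cls
                ))
        return out

    def test_planted_family_binder_has_max_positive_z(self, genome):
        rng = np.random.default_rng(11)
        repeats = self._repeats(genome, rng)
        fam_a = [r.interval for r in repeats if r.family == "FamA"]
        binder = ConsensusPeakSet("BND", fam_a, 2)  # peaks copied onto FamA
        other = cset("OTH", [("chr1", int(s), int(s) + 300)
                             for s in rng.integers(0, 900_000, 50)])
        z, p, nulls = enr.repeat_enrichment_matrix(
            [binder, other], repeats, genome, by="family", n_perm=100, seed=3
        )
        assert z.loc["BND", "FamA"] == z.to_numpy().max()
        assert z.loc["BND", "FamA"] > 3

    def test_avoided_half_genome_family_depleted(self, genome):
        # FamG covers the left half of chr1; peaks confined to the right half
        repeats = [
            RepeatElement(GenomicInterval("chr1", s, s + 10_000), "G", "FamG", "CG")
            for s in range(0, 500_000, 10_000)
        ]
        rng = np.random.default_rng(13)
        cs = cset("X", [("chr1", int(s), int(s) + 200)
                        for s in rng.integers(600_000, 990_000, 60)])
        z, _, _ = enr.repeat_enrichment_matrix(
            [cs], repeats, genome, by="family", n_perm=100, seed=4
        )
        assert z.loc["X", "FamG"] < 0

    def test_absent_group_is_an_error(self, genome):
        rng = np.random.default_rng(1)
        repeats = self._repeats(genome, rng)
        with pytest.raises(ValueError):
            enr.repeat_enrichment_matrix(
                [cset("X", [("chr1", 0, 10)])], repeats, genome,
                by="family", groups=["NoSuchFam"], n_perm=2, seed=0,
            )


class TestBiotypeBias:
    def _matrix(self, bound_lnc, n_lnc, bound_m, n_m):
        genes = [f"l{i}" for i in range(n_lnc)] + [f"m{i}" for i in range(n_m)]
        col = [1] * bound_lnc + [0] * (n_lnc - bound_lnc) \
            + [1] * bound_m + [0] * (n_m - bound_m)
        df = pd.DataFrame({"D": col}, index=genes).astype(np.int8)
        bt = {g: ("lncRNA" if g.startswith("l") else "mRNA") for g in genes}
        return OccupancyMatrix(df), bt

    def test_proportional_binding_gives_zero_log_ratio(self):
        m, bt = self._matrix(10, 100, 10, 100)
        (res,) = enr.biotype_bias_test(m, bt)
        assert res.log2_obs_exp == pytest.approx(0.0)

    def test_statistic_matches_hand_computed_2x2(self):
        m, bt = self._matrix(60, 100, 20, 100)
        (res,) = enr.biotype_bias_test(m, bt)
        # textbook chi-squared of [[60,20],[40,80]] computed by hand
        obs = np.array([[60, 20], [40, 80]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert res.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_unbound_dbp_flagged_invalid(self):
        m, bt = self._matrix(0, 50, 0, 50)
        (res,) = enr.biotype_bias_test(m, bt)
        assert not res.valid


class TestHypergeometric:
    def test_zero_successes_certain(self):
        assert enr.hypergeometric_overrepresentation(0, 5, 3, 20) == 1.0

    def test_small_case_matches_enumeration(self):
        # N=5, K=2, n=2, k=2: C(2,2)*C(3,0)/C(5,2) = 1/10
        assert enr.hypergeometric_overrepresentation(2, 2, 2, 5) == pytest.approx(0.1)

    def test_full_draw_certain(self):
        assert enr.hypergeometric_overrepresentation(4, 4, 4, 4) == pytest.approx(1.0)

    def test_matches_bruteforce_enumeration(self):
        from itertools import combinations

        N, K, n, k = 8, 3, 4, 2
        pop = [1] * K + [0] * (N - K)
        hits = sum(1 for c in combinations(range(N), n)
                   if sum(pop[i] for i in c) >= k)
        total = sum(1 for _ in combinations(range(N), n))
        assert enr.hypergeometric_overrepresentation(k, K, n, N) == pytest.approx(
            hits / total
        )

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            enr.hypergeometric_overrepresentation(5, 3, 4, 8)


class TestReservoirDbpBias:
    def _toy(self, frac_res, frac_non, n_res=200, n_non=800, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"r{i}" for i in range(n_res)] + [f"n{i}" for i in range(n_non)]
        col = np.concatenate([
            (rng.random(n_res) < frac_res), (rng.random(n_non) < frac_non)
        ]).astype(np.int8)
        m = OccupancyMatrix(pd.DataFrame({"D": col}, index=genes))
        flags = {g: g.startswith("r") for g in genes}
        return m, flags

    def test_equal_representation_in_neither_list(self):
        m, flags = self._toy(0.3, 0.3)
        enriched, depleted, _ = enr.reservoir_dbp_bias(m, flags)
        assert enriched == [] and depleted == []

    def test_planted_denser_binding_detected_as_enriched(self):
        m, flags = self._toy(0.8, 0.2, seed=3)
        enriched, depleted, df = enr.reservoir_dbp_bias(m, flags)
        assert enriched == ["D"] and depleted == []

    def test_infinite_fold_threshold_empties_both_lists(self):
        m, flags = self._toy(0.8, 0.2, seed=3)
        enriched, depleted, _ = enr.reservoir_dbp_bias(m, flags, fold=np.inf)
        assert enriched == [] and depleted == []
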