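"""Diversity statistics against independent oracles and constructions."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

from zsd import diversity
from zsd._codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from zsd.errors import UndefinedStatisticError, ValidationError


# ---------------------------------------------------------------------------
# independent brute-force pathway oracle (recursive, distinct from the
# implementation's permutation walk)


def _oracle_pathways(c1: str, c2: str):
    """Enumerate all substitution orders recursively, yielding (syn, nonsyn)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        yield (0.0, 0.0)
        return

    def rec(cur, remaining, syn, nonsyn, blocked):
        if not remaining:
            yield (syn, nonsyn, blocked)
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            step_syn = CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt)
            yield from rec(
                nxt,
                remaining[:i] + remaining[i + 1 :],
                syn + (1.0 if step_syn else 0.0),
                nonsyn + (0.0 if step_syn else 1.0),
                blocked or (nxt in STOP_CODONS and nxt != c2),
            )

    results = list(rec(c1, diffs, 0.0, 0.0, False))
    open_paths = [(s, n) for s, n, b in results if not b]
    yield from open_paths if open_paths else [(s, n) for s, n, _ in results]


def _oracle_diffs(c1: str, c2: str):
    paths = list(_oracle_pathways(c1, c2))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def _oracle_sites(codon: str) -> float:
    aa = CODON_TO_AA[codon]
    syn = sum(
        CODON_TO_AA.get(codon[:p] + b + codon[p + 1 :]) == aa
        for p in range(3)
        for b in "ACGT"
        if b != codon[p]
    )
    return syn / 3.0


class TestNeiGojobori:
    def test_matches_oracle_on_all_sense_codon_pairs(self):
        """Pathway counts equal recursive enumeration over all 61x61 pairs."""
        for c1, c2 in product(SENSE_CODONS, SENSE_CODONS):
            got = diversity.nei_gojobori_pair([c1], [c2])
            syn_d, nonsyn_d = _oracle_diffs(c1, c2)
            assert got.syn_diffs == pytest.approx(syn_d), (c1, c2)
            assert got.nonsyn_diffs == pytest.approx(nonsyn_d), (c1, c2)
            sites = (_oracle_sites(c1) + _oracle_sites(c2)) / 2.0
            assert got.syn_sites == pytest.approx(sites)
            assert got.syn_sites + got.nonsyn_sites == pytest.approx(3.0)

    def test_identical_sequences(self):
        got = diversity.nei_gojobori_pair(["ATG", "AAA"], ["ATG", "AAA"])
        assert got.syn_diffs == 0 and got.nonsyn_diffs == 0
        assert got.syn_sites + got.nonsyn_sites == pytest.approx(6.0)

    def test_symmetry(self):
        a = diversity.nei_gojobori_pair(["TTT", "GGA"], ["GTA", "GGG"])
        b = diversity.nei_gojobori_pair(["GTA", "GGG"], ["TTT", "GGA"])
        assert a == b

    def test_gapped_codons_skipped(self):
        got = diversity.nei_gojobori_pair(["TTT", "---"], ["TTC", "AAA"])
        assert got.syn_diffs == 1.0
        assert got.syn_sites + got.nonsyn_sites == pytest.approx(3.0)

    def test_all_gapped_raises(self):
        with pytest.raises(UndefinedStatisticError):
            diversity.nei_gojobori_pair(["---"], ["AAA"])


class TestTripletIndel:
    def test_no_gaps(self):
        assert diversity.triplet_indel_pair("TTTAAA", "TTTAAA") == 0

    def test_six_nt_gap_counts_two_triplets(self):
        assert diversity.triplet_indel_pair("TTTAAACCC", "TTT------") == 2
        assert (
            diversity.triplet_indel_pair("TTTAAACCC", "TTT------", count_events=True)
            == 1
        )

    def test_shared_gap_not_a_difference(self):
        assert diversity.triplet_indel_pair("TTT---CCC", "TTT---CCC") == 0


class TestAlignmentValidation:
    def test_valid_trivial(self):
        aln = diversity.validate_alignment([("a", "TTTAAACCC"), ("b", "TTTAAACCC")])
        assert aln.n_seqs == 2 and aln.n_codons == 3

    def test_ragged_rejected(self):
        with pytest.raises(ValidationError, match="ragged"):
            diversity.validate_alignment([("a", "TTTAAA"), ("b", "TTT")])

    def test_non_triplet_gap_cites_column(self):
        with pytest.raises(ValidationError, match="column 3"):
            diversity.validate_alignment([("a", "TTT--ACCC"), ("b", "TTTAAACCC")])

    def test_offset_gap_rejected(self):
        with pytest.raises(ValidationError):
            diversity.validate_alignment([("a", "TT---TCCC"), ("b", "TTTAAACCC")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            diversity.validate_alignment([("a", "TTT"), ("a", "TTT")])

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            diversity.validate_alignment([("a", "TAAAAA"), ("b", "TTTAAA")])

    def test_terminal_stop_allowed(self):
        aln = diversity.validate_alignment([("a", "AAATAA"), ("b", "AAATAA")])
        assert aln.n_codons == 2

    def test_simulated_haplotypes_always_valid(self, founder_haplotypes):
        aln = diversity.align_simulated_haplotypes(founder_haplotypes)
        assert aln.n_seqs == 11
        assert set(aln.regions) == {"E8", "HVR", "E9"}


class TestSlidingWindows:
    def test_identical_rows_all_zero(self, rng):
        rows = [("a", "AAATTTGGGCCC" * 12), ("b", "AAATTTGGGCCC" * 12)]
        aln = diversity.validate_alignment(rows)
        for w in diversity.sliding_window_diversity(aln, boot_reps=5, rng=rng):
            assert w.pi_syn == 0 and w.pi_nonsyn == 0 and w.indel_per_triplet == 0

    def test_window_tiling(self, founder_haplotypes, rng):
        aln = diversity.align_simulated_haplotypes(founder_haplotypes)
        windows = diversity.sliding_window_diversity(aln, boot_reps=2, rng=rng)
        for w1, w2 in zip(windows[:-2], windows[1:-1]):
            assert w2.start - w1.start == 24
            assert w1.end - w2.start == 75  # consecutive windows share 75 nt
        assert windows[-1].end == aln.length  # final window truncated, not dropped

    def test_single_syn_snp_localised(self, rng):
        """A lone synonymous SNP contributes pi_s only to windows covering it."""
        base = "AAATTTGGGCCC" * 15  # 180 nt, 60 codons
        snp = base[:30] + "GGA" + base[33:]  # codon 10: GGG -> GGA (Gly, syn)
        aln = diversity.validate_alignment([("a", base), ("b", snp)])
        windows = diversity.sliding_window_diversity(aln, boot_reps=2, rng=rng)
        for w in windows:
            covers = w.start <= 30 < w.end
            assert (w.pi_syn > 0) == covers
            assert w.pi_nonsyn == 0

    def test_diversity_peaks_in_variable_region(self, founder_haplotypes, rng):
        """Simulated haplotypes vary only in HVR/E9: peak windows lie there."""
        aln = diversity.align_simulated_haplotypes(founder_haplotypes)
        windows = diversity.sliding_window_diversity(aln, boot_reps=2, rng=rng)
        hvr_start = aln.regions["HVR"][0]
        flat = [w for w in windows if w.end <= hvr_start]
        variable = [w for w in windows if w.start >= hvr_start]
        assert all(w.pi_nonsyn == 0 and w.indel_per_triplet == 0 for w in flat)
        assert max(w.pi_nonsyn for w in variable) > 0
        assert max(w.indel_per_triplet for w in variable) > 0

    def test_short_alignment_rejected(self, rng):
        aln = diversity.validate_alignment([("a", "TTTAAA"), ("b", "TTTAAA")])
        with pytest.raises(ValidationError, match="shorter"):
            diversity.sliding_window_diversity(aln, rng=rng)

    def test_row_order_invariance(self, founder_haplotypes, rng):
        aln = diversity.align_simulated_haplotypes(founder_haplotypes)
        rev = diversity.validate_alignment(
            list(zip(reversed(aln.ids), reversed(aln.rows))), regions=aln.regions
        )
        w1 = diversity.sliding_window_diversity(aln, boot_reps=1, rng=np.random.default_rng(0))
        w2 = diversity.sliding_window_diversity(rev, boot_reps=1, rng=np.random.default_rng(0))
        a = np.array([(w.pi_syn, w.pi_nonsyn) for w in w1])
        b = np.array([(w.pi_syn, w.pi_nonsyn) for w in w2])
        assert np.allclose(a, b)


class TestExonDiversity:
    def test_identical_rows_zero(self, rng):
        aln = diversity.validate_alignment([("a", "AAATTT"), ("b", "AAATTT")])
        res = diversity.exon_diversity(aln, boot_reps=5, rng=rng)
        assert (res.pi, res.pi_syn, res.pi_nonsyn) == (0, 0, 0)

    def test_hand_computed_single_codon(self, rng):
        """TTT vs TTC: 1 syn diff over 1/3 syn sites; pi = 1/3 p-distance."""
        aln = diversity.validate_alignment([("a", "TTT"), ("b", "TTC")])
        res = diversity.exon_diversity(aln, boot_reps=2, rng=rng)
        assert res.pi == pytest.approx(1 / 3)
        assert res.pi_syn == pytest.approx(3.0)  # 1 diff / (1/3 sites)
        assert res.pi_nonsyn == 0.0

    def test_empty_region_rejected(self, rng):
        aln = diversity.validate_alignment([("a", "AAATTT"), ("b", "AAATTT")])
        with pytest.raises(ValidationError):
            diversity.exon_diversity(aln, region=(3, 3), rng=rng)

    def test_bootstrap_se_shrinks_with_region_size(self):
        """SE ~ 1/sqrt(codon count) on a homogeneous random alignment."""
        rng = np.random.default_rng(1)
        n_codons = 240
        rows = []
        for sid in "abcd":
            codons = []
            for _ in range(n_codons):
                codons.append(["AAA", "AAG", "GGG", "GGC"][rng.integers(4)])
            rows.append((sid, "".join(codons)))
        aln = diversity.validate_alignment(rows)
        se_small = diversity.exon_diversity(
            aln, region=(0, 60), boot_reps=80, rng=np.random.default_rng(2)
        ).se_syn
        se_large = diversity.exon_diversity(
            aln, region=(0, 720), boot_reps=80, rng=np.random.default_rng(3)
        ).se_syn
        ratio = se_small / se_large  # expect ~ sqrt(12) = 3.46
        assert 2.0 < ratio < 6.0


class TestCodonUsageAndLengths:
    def test_hand_counted_hvr_proportions(self):
        from zsd.simcore import HaplotypeRecord

        # HVR "AATAATCAT" -> N,N,H; flank: 7 codons before to satisfy bounds
        nt = "AAT" * 7 + "AATAATCAT" + "ATG"
        h = HaplotypeRecord("h1", nt, (7, 10))
        table = diversity.codon_usage_profile([h])
        props = table.proportions[("h1", "HVR")]
        assert props["AAT"] == pytest.approx(2 / 3)
        assert props["CAT"] == pytest.approx(1 / 3)
        assert table.hvr_ant_nat

    def test_empty_hvr_flagged(self):
        from zsd.simcore import HaplotypeRecord

        h = HaplotypeRecord("h1", "ATGAAA", (1, 1))
        table = diversity.codon_usage_profile([h])
        assert ("h1", "HVR") in table.empty_regions

    def test_simulated_hvr_flag_true(self, founder_haplotypes):
        assert diversity.codon_usage_profile(founder_haplotypes).hvr_ant_nat

    def test_hvr_length_histogram(self, founder_haplotypes):
        hist = diversity.hvr_length_distribution(founder_haplotypes)
        assert sum(hist.values()) == len(founder_haplotypes)
        assert min(hist) >= 7 and max(hist) <= 24

    def test_single_haplotype_histogram(self):
        from zsd.simcore import HaplotypeRecord

        h = HaplotypeRecord("h1", "AAT" * 10, (0, 10))
        assert diversity.hvr_length_distribution([h]) == {10: 1}


class TestHaplotypeDiversity:
    def test_single_allele_zero(self):
        assert diversity.haplotype_diversity({"a": 5}) == 0.0

    def test_two_singletons_is_one(self):
        assert diversity.haplotype_diversity({"a": 1, "b": 1}) == pytest.approx(1.0)

    def test_all_singletons_exactly_one(self):
        counts = {f"h{i}": 1 for i in range(37)}
        assert diversity.haplotype_diversity(counts) == pytest.approx(1.0)

    def test_requires_two_observations(self):
        with pytest.raises(UndefinedStatisticError):
            diversity.haplotype_diversity({"a": 1})


class TestPhiSt:
    def _matrix(self, rng, n):
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return d

    def test_exchangeable_labels_near_zero(self, rng):
        # every pair of distinct individuals equidistant: groups carry no signal
        d = np.ones((20, 20)) - np.eye(20)
        labels = ["p1"] * 10 + ["p2"] * 10
        res = diversity.amova_phi_st(d, labels, n_perm=500, rng=rng)
        assert abs(res.average) < 0.05
        assert res.pairwise_p[("p1", "p2")] > 0.5

    def test_perfect_separation_is_one(self):
        d = np.zeros((8, 8))
        d[:4, 4:] = 1.0
        d[4:, :4] = 1.0
        labels = ["a"] * 4 + ["b"] * 4
        res = diversity.amova_phi_st(d, labels, n_perm=200, rng=np.random.default_rng(0))
        assert res.pairwise[("a", "b")] == pytest.approx(1.0)
        assert res.pairwise_p[("a", "b")] < 0.05

    def test_singleton_population_excluded(self, rng):
        d = self._matrix(rng, 9)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"]
        with pytest.warns(UserWarning, match="singleton"):
            res = diversity.amova_phi_st(d, labels, n_perm=50, rng=rng)
        assert res.excluded == ("c",)

    def test_permutation_p_uniform_under_null(self):
        """Label-exchangeable data give uniform permutation p-values."""
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            d = self._matrix(rng, 16)
            labels = ["x"] * 8 + ["y"] * 8
            res = diversity.amova_phi_st(d, labels, n_perm=199, rng=rng)
            ps.append(res.pairwise_p[("x", "y")])
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01
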