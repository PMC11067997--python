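"""Simulator invariants: haplotype structure, mutation, selection, broods."""

import numpy as np
import pytest

from zsd import (
    Individual,
    InvalidConfigError,
    InvalidCrossError,
    SimConfig,
    ValidationError,
    generate_founder_alleles,
    mutate_haplotype,
    simulate_brood,
    simulate_expression_matrix,
    simulate_population,
)
from zsd.simcore import HVR_CODONS, _is_ant_or_nat


class TestFounderAlleles:
    def test_distinct_and_valid(self, rng):
        cfg = SimConfig(k=2)
        haps = generate_founder_alleles(2, cfg, rng)
        assert len({h.aa_seq for h in haps}) == 2
        for h in haps:
            h.validate(cfg.hvr_len_bounds)
            for i in range(*h.hvr_span):
                assert _is_ant_or_nat(h.nt_seq[i * 3 : i * 3 + 3])

    def test_leiden_like_richness(self, rng):
        haps = generate_founder_alleles(18, SimConfig(k=18), rng)
        assert len({h.aa_seq for h in haps}) == 18

    def test_seed_determinism(self):
        cfg = SimConfig(k=6, seed=42)
        a = generate_founder_alleles(6, cfg, np.random.default_rng(42))
        b = generate_founder_alleles(6, cfg, np.random.default_rng(42))
        assert [h.nt_seq for h in a] == [h.nt_seq for h in b]

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            generate_founder_alleles(1, SimConfig(k=2), rng)


class TestMutation:
    def test_zero_rates_identity(self, rng, founder_haplotypes):
        cfg = SimConfig(mu_point=0.0, mu_slip=0.0, mu_e9=0.0)
        h = founder_haplotypes[0]
        assert mutate_haplotype(h, cfg, rng) is h

    def test_slippage_respects_bounds(self, rng):
        cfg = SimConfig(mu_slip=1.0, mu_point=0.0, mu_e9=0.0)
        h = generate_founder_alleles(2, SimConfig(k=2, hvr_len_bounds=(24, 24)), rng)[0]
        assert h.hvr_len == 24
        cur = h
        for _ in range(200):
            cur = mutate_haplotype(cur, cfg, rng)
            assert 7 <= cur.hvr_len <= 24

    def test_hvr_point_mutations_stay_ant_nat(self, rng, founder_haplotypes):
        cfg = SimConfig(mu_point=0.5, mu_slip=0.2, mu_e9=0.01)
        h = founder_haplotypes[0]
        for _ in range(10_000 // 10):
            m = mutate_haplotype(h, cfg, rng)
            m.validate(cfg.hvr_len_bounds)
            for i in range(*m.hvr_span):
                assert m.nt_seq[i * 3 : i * 3 + 3] in HVR_CODONS

    def test_e9_mutation_outside_hvr(self, rng, founder_haplotypes):
        cfg = SimConfig(mu_point=0.0, mu_slip=0.0, mu_e9=1.0)
        h = founder_haplotypes[0]
        m = mutate_haplotype(h, cfg, rng)
        assert m.hvr_nt == h.hvr_nt
        assert m.nt_seq[: h.hvr_span[0] * 3] == h.nt_seq[: h.hvr_span[0] * 3]
        assert m.aa_seq != h.aa_seq  # nonsynonymous by construction


class TestPopulation:
    def test_no_surviving_homozygote(self, small_state):
        for male in small_state.males:
            assert male.alleles[0] != male.alleles[1]
        for fem in small_state.females:
            assert len(fem.alleles) == 1

    def test_two_allele_equilibrium(self):
        cfg = SimConfig(
            n_females=400, n_males=400, k=2, generations=40,
            mu_point=0, mu_slip=0, mu_e9=0, z0_rate=0, seed=3,
        )
        st = simulate_population(cfg)
        freqs = []
        for counts in st.generation_counts[10:]:
            total = sum(counts.values())
            freqs.append(max(counts.values()) / total)
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)
        # with k=2 every male is a/b: half of ZZ zygotes are homozygous
        assert np.mean(st.inviable_fraction[1:]) == pytest.approx(0.25, abs=0.03)

    def test_frequency_deviation_shrinks_with_n(self):
        devs = {}
        for n in (100, 800):
            reps = []
            for s in range(5):
                cfg = SimConfig(
                    n_females=n, n_males=n, k=4, generations=20,
                    mu_point=0, mu_slip=0, mu_e9=0, z0_rate=0, seed=100 + s,
                )
                st = simulate_population(cfg)
                total = sum(st.final_counts.values())
                p = np.array(list(st.final_counts.values())) / total
                # pad lost alleles with zero frequency
                p = np.pad(p, (0, 4 - len(p)))
                reps.append(np.abs(p - 0.25).mean())
            devs[n] = np.mean(reps)
        assert devs[800] < devs[100]

    def test_allele_retention_under_balancing_selection(self):
        retained = 0
        for s in range(10):
            cfg = SimConfig(
                n_females=250, n_males=250, k=5, generations=200,
                mu_point=0, mu_slip=0, mu_e9=0, z0_rate=0, seed=500 + s,
            )
            st = simulate_population(cfg)
            retained += len(st.final_counts) == 5
        assert retained >= 9

    def test_mutation_generates_singleton_dominated_sample(self):
        cfg = SimConfig(
            n_females=800, n_males=800, k=300, generations=25,
            mu_point=5e-3, mu_slip=5e-2, mu_e9=5e-4, seed=9,
        )
        st = simulate_population(cfg)
        rng = np.random.default_rng(10)
        sample = rng.choice([f.alleles[0] for f in st.females], size=100, replace=False)
        from collections import Counter

        counts = Counter(sample.tolist())
        f1 = sum(1 for c in counts.values() if c == 1)
        assert f1 / len(counts) > 0.5
        # truncated tail: no allele reaches 10% of the sample
        assert max(counts.values()) <= 0.1 * len(sample)

    def test_seed_determinism(self, small_config, small_state):
        again = simulate_population(small_config)
        assert again.final_counts == small_state.final_counts
        assert [m.alleles for m in again.males] == [m.alleles for m in small_state.males]

    def test_extinction_signal(self):
        cfg = SimConfig(n_females=50, n_males=50, k=2, generations=5, seed=1)
        st = simulate_population(cfg, max_rounds=0)
        assert st.extinct
        assert st.extinct_generation == 1


class TestBroods:
    def test_shared_allele_cross_fractions(self, rng):
        mother = Individual("WZ", ("a",))
        father = Individual("ZZ", ("a", "b"))
        brood = simulate_brood(mother, father, 40_000, rng)
        frac = {k: v / brood.n_eggs for k, v in brood.class_counts.items()}
        for label in ("WZ-hem:a", "WZ-hem:b", "ZZ-het:a/b", "ZZ-hom:a/a"):
            assert frac[label] == pytest.approx(0.25, abs=0.01)
        assert brood.black_egg == brood.class_counts["ZZ-hom:a/a"]

    def test_nonsharing_cross_has_no_homozygotes(self, rng):
        brood = simulate_brood(
            Individual("WZ", ("c",)), Individual("ZZ", ("a", "b")), 5000, rng
        )
        assert all("hom" not in k for k in brood.class_counts)
        assert brood.black_egg == 0

    def test_z0_mother_classes(self, rng):
        brood = simulate_brood(
            Individual("Z0", ("a",)), Individual("ZZ", ("a", "b")), 40_000, rng
        )
        frac = {k: v / brood.n_eggs for k, v in brood.class_counts.items()}
        for label in ("Z0-hem:a", "Z0-hem:b", "ZZ-het:a/b", "ZZ-hom:a/a"):
            assert frac[label] == pytest.approx(0.25, abs=0.01)

    def test_same_sex_parents_rejected(self, rng):
        fem = Individual("WZ", ("a",))
        with pytest.raises(InvalidCrossError):
            simulate_brood(fem, fem, 10, rng)


class TestExpressionMatrix:
    def test_no_noise_unit_factor_equalises_classes(self):
        t = simulate_expression_matrix(
            50, 20, rng=np.random.default_rng(0), hom_factor=1.0, noise_sd=0.0
        )
        means = t.class_means()
        gc = t.gene_class.loc[t.values.index]
        ratios = {
            c: means.loc[gc == "Z", c].median() / means.loc[gc == "A", c].median()
            for c in means.columns
        }
        assert len({round(v, 12) for v in ratios.values()}) == 1

    def test_autosomal_medians_equal_across_classes(self):
        t = simulate_expression_matrix(2000, 200, rng=np.random.default_rng(1))
        means = t.class_means()
        gc = t.gene_class.loc[t.values.index]
        med = [means.loc[gc == "A", c].median() for c in means.columns]
        assert max(med) / min(med) == pytest.approx(1.0, abs=0.1)

    def test_unknown_class_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_expression_matrix(10, 10, classes=["hem", "diploid"])

    def test_seed_reproducible(self):
        a = simulate_expression_matrix(30, 10, rng=np.random.default_rng(4))
        b = simulate_expression_matrix(30, 10, rng=np.random.default_rng(4))
        assert a.values.equals(b.values)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 1},
            {"mu_point": 1.5},
            {"z0_rate": -0.1},
            {"hvr_len_bounds": (0, 24)},
            {"hvr_len_bounds": (7, 100)},
            {"n_females": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kwargs)
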