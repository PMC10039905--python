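"""Karyotype data model, chromosome-state classification and scoring."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import quad

import hehsim as h
from hehsim.core import CHROMOSOMES, ChromosomeState, N_CHROM


class TestClassifyChromosome:
    @pytest.mark.parametrize("pair,expected", [
        ((0, 0), ChromosomeState.NULLISOMY),
        ((1, 0), ChromosomeState.MONOSOMY),
        ((1, 1), ChromosomeState.HETERODISOMY),
        ((2, 0), ChromosomeState.UPID),
        ((2, 1), ChromosomeState.TRISOMY),
        ((3, 0), ChromosomeState.TRISOMY),
        ((2, 2), ChromosomeState.TETRASOMY_2_2),
        ((3, 1), ChromosomeState.TETRASOMY_3_1),
        ((4, 0), ChromosomeState.TETRASOMY_4_0),
        ((3, 2), ChromosomeState.PENTASOMY_PLUS),
        ((6, 1), ChromosomeState.PENTASOMY_PLUS),
    ])
    def test_state_table(self, pair, expected):
        assert h.classify_chromosome(*pair) is expected

    def test_symmetric_in_homologue_order(self):
        # exhaustive over all pairs up to count 6
        for a, b in itertools.product(range(7), repeat=2):
            assert h.classify_chromosome(a, b) is h.classify_chromosome(b, a)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            h.classify_chromosome(-1, 2)

    def test_vectorised_matches_scalar(self):
        pairs = list(itertools.product(range(6), repeat=2))
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        vec = h.core.classify_pair_arrays(a, b)
        for k, p in enumerate(pairs):
            assert vec[k] is h.classify_chromosome(*p)


class TestMcn:
    def test_diploid_is_46(self, diploid):
        assert h.mcn(diploid) == 46

    def test_two_extra_copies(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["21"] = (2, 1)
        copies["X"] = (2, 1)
        assert h.mcn(h.CellKaryotype(copies)) == 48

    def test_typical_heh_cell(self, heh_karyotype):
        # 4 (chr21) + 3*7 (strong-pos trisomies) + 2*15 = 55
        assert h.mcn(heh_karyotype) == 4 + 3 * 7 + 2 * 15 == 55

    def test_additive_in_single_copy_changes(self, rng):
        for _ in range(20):
            arr = rng.integers(0, 4, size=(N_CHROM, 2))
            arr[arr.sum(axis=1) == 0, 0] = 1
            base = h.CellKaryotype(arr)
            j = rng.integers(N_CHROM)
            bumped = arr.copy()
            bumped[j, 0] += 1
            assert h.mcn(h.CellKaryotype(bumped)) == h.mcn(base) + 1


class TestKaryotypeContainer:
    def test_requires_all_23_chromosomes(self):
        with pytest.raises(ValueError, match="missing"):
            h.CellKaryotype({c: (1, 1) for c in CHROMOSOMES[:-1]})

    def test_rejects_chromosome_y(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["Y"] = (1, 0)
        with pytest.raises(ValueError):
            h.CellKaryotype(copies)

    def test_round_trips_through_mapping(self, heh_karyotype):
        rebuilt = h.CellKaryotype({c: heh_karyotype.pair(c) for c in CHROMOSOMES})
        assert rebuilt == heh_karyotype


class TestAneuploidyPenalty:
    def setup_method(self):
        self.cfg = h.SelectionConfig()
        a, b, scale = self.cfg.penalty_a, self.cfg.penalty_b, self.cfg.penalty_scale
        norm = math.gamma(a) * math.gamma(b) / math.gamma(a + b)

        def integrand(u):
            return u ** (a - 1) * (1 - u) ** (b - 1) / norm

        # independent oracle: quadrature of the beta integrand
        def cdf_oracle(x):
            val, _ = quad(integrand, 0, x / scale, points=[0])
            return val

        def pdf_oracle(x):
            return integrand(x / scale) / scale

        self.cdf_oracle = cdf_oracle
        self.pdf_oracle = pdf_oracle

    def test_zero_at_and_below_diploid(self):
        for mcn in (0, 23, 45, 46):
            assert h.s_aneuploidy(mcn, self.cfg) == 0.0

    @pytest.mark.parametrize("mcn", [47, 55, 67])
    def test_cumulative_matches_quadrature(self, mcn):
        x = (mcn - 46) / 46
        expected = self.cdf_oracle(x)
        assert h.s_aneuploidy(mcn, self.cfg) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("mcn", [47, 67])
    def test_density_form_matches_integrand(self, mcn):
        cfg = self.cfg.with_(penalty_form="density")
        x = (mcn - 46) / 46
        assert h.s_aneuploidy(mcn, cfg) == pytest.approx(self.pdf_oracle(x), rel=1e-6)

    def test_nonnegative_and_monotone_cumulative(self):
        vals = h.s_aneuploidy(np.arange(40, 140), h.SelectionConfig())
        assert (vals >= 0).all()
        assert (np.diff(vals) >= 0).all()

    def test_support_clamp_beyond_scale(self):
        # MCN > 46 + 46*1.8 clamps to the CDF's upper boundary
        assert h.s_aneuploidy(200, self.cfg) == pytest.approx(1.0)


class TestSurvivalScore:
    def test_diploid_scores_half_under_both_penalty_forms(self, diploid):
        for form in ("cumulative", "density"):
            cfg = h.SelectionConfig(penalty_form=form)
            assert h.s_score(diploid, cfg) == 0.5

    def test_formula_substitution(self):
        # NT_g1 = 2, NT_g2 = 1, NT_g3 = 0 at MCN 49
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["4"] = (2, 1)
        copies["6"] = (2, 1)
        copies["21"] = (2, 1)
        kar = h.CellKaryotype(copies)
        cfg = h.SelectionConfig()
        pen = h.s_aneuploidy(49, cfg)
        assert h.s_score(kar, cfg) == pytest.approx(0.5 + (2 + 2 * 1 - pen) / 23)

    def test_single_negative_trisomy(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["16"] = (2, 1)
        kar = h.CellKaryotype(copies)
        cfg = h.SelectionConfig()
        pen = h.s_aneuploidy(47, cfg)
        assert h.s_score(kar, cfg) == pytest.approx(0.5 - (1 + pen) / 23)

    def test_penalty_outside_fraction_mode(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["16"] = (2, 1)
        kar = h.CellKaryotype(copies)
        cfg = h.SelectionConfig(penalty_inside_fraction=False)
        pen = h.s_aneuploidy(47, cfg)
        assert h.s_score(kar, cfg) == pytest.approx(0.5 - 1 / 23 - pen)

    def test_four_group_form_adds_weak_positive_term(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["8"] = (2, 1)  # group 4 under the extended score
        kar = h.CellKaryotype(copies)
        pen = h.s_aneuploidy(47, h.SelectionConfig())
        three = h.s_score(kar, h.SelectionConfig())
        four = h.s_score(kar, h.SelectionConfig(four_groups=True))
        assert three == pytest.approx(0.5 - (1 + pen) / 23)
        assert four == pytest.approx(0.5 + (0.02 - pen) / 23)

    def test_penalty_can_be_disabled(self, heh_karyotype):
        cfg = h.SelectionConfig()
        with_pen = h.s_score(heh_karyotype, cfg)
        without = h.s_score(heh_karyotype, cfg, apply_penalty=False)
        assert without > with_pen
        assert without == pytest.approx(0.5 + 9 / 23)

    def test_trisomy_only_counting_ignores_tetrasomies(self, heh_karyotype):
        cfg = h.SelectionConfig(nt_counting="trisomy_only")
        pen = h.s_aneuploidy(55, cfg)
        # tetrasomy 21 no longer counts as a group-2 gain
        assert h.s_score(heh_karyotype, cfg) == pytest.approx(0.5 + (7 - pen) / 23)


class TestSelectionConfigValidation:
    def test_groups_must_partition(self):
        with pytest.raises(ValueError):
            h.SelectionConfig(group1=frozenset({"4"}))

    def test_group2_disjointness(self):
        with pytest.raises(ValueError):
            h.SelectionConfig(group2=frozenset({"21", "4"}))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            h.SelectionConfig(upid_stop=1.5)
        with pytest.raises(ValueError):
            h.SelectionConfig(m_misseg=0.0)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            h.SelectionConfig(tracked_chromosomes=frozenset({"Y"}))


class TestUpidFrequency:
    def test_all_heterodisomic_is_zero(self, diploid):
        assert h.upid_frequency([diploid]) == 0.0

    def test_counting_one_upid(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["5"] = (2, 0)  # tracked chromosome
        kar = h.CellKaryotype(copies)
        assert h.upid_frequency([kar]) == pytest.approx(1 / 14)

    def test_untracked_upid_not_counted(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["21"] = (2, 0)
        kar = h.CellKaryotype(copies)
        assert h.upid_frequency([kar]) == 0.0

    def test_all_tracked_denominator(self):
        copies = {c: (1, 1) for c in CHROMOSOMES}
        copies["5"] = (2, 0)
        copies["7"] = (2, 1)  # trisomy shrinks the disomy denominator only
        arr = h.CellKaryotype(copies).copies[None]
        assert h.upid_frequency(arr) == pytest.approx(1 / 13)
        assert h.upid_frequency(arr, denominator="all_tracked") == pytest.approx(1 / 14)

    def test_no_disomies_degenerate_zero(self):
        arr = np.full((1, N_CHROM, 2), 2, dtype=int)  # tetraploid: no disomy
        assert h.upid_frequency(arr) == 0.0

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            h.upid_frequency([])


class TestLossOutcomes:
    def test_quoted_probabilities_from_2_1(self):
        dist = h.loss_outcomes(2, 1)
        assert dist == {
            ChromosomeState.HETERODISOMY: Fraction(2, 3),
            ChromosomeState.UPID: Fraction(1, 3),
        }

    def test_monoallelic_trisomy_always_upid(self):
        assert h.loss_outcomes(3, 0) == {ChromosomeState.UPID: Fraction(1)}

    def test_matches_exhaustive_enumeration_all_trisomic_pairs(self):
        for a in range(4):
            b = 3 - a
            # oracle: remove each physical copy in turn
            outcomes = {}
            for hom in (0, 1):
                count = (a, b)[hom]
                for _ in range(count):
                    pair = (a - 1, b) if hom == 0 else (a, b - 1)
                    st = h.classify_chromosome(*pair)
                    outcomes[st] = outcomes.get(st, 0) + 1
            oracle = {st: Fraction(n, 3) for st, n in outcomes.items()}
            assert h.loss_outcomes(a, b) == oracle

    def test_non_trisomic_rejected(self):
        with pytest.raises(ValueError):
            h.loss_outcomes(2, 2)
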