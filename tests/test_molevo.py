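"""Weighted mutation counting, fixation rates, gene bias and annotation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from coevo.data_model import (DataError, MutationStatusMatrix, Population,
                              Site, Status)
from coevo.datasets import (QBETA_COPROPAGATION_LINES, QBETA_GENOME_LENGTH,
                            QBETA_LINE_GENERATIONS, QBETA_PROPAGATION_LINES)
from coevo.molevo import (annotate_mutation, bottleneck_ne,
                          cumulative_mutation_series, fixation_rate,
                          gene_bias_binomial, lineage_rate_summary,
                          lineage_rates, poisson_rate_test, rate_welch_t,
                          status_weight)


def _single_site_matrix(statuses):
    pops = [Population(f"P{i}", 50.0 * i) for i in range(len(statuses))]
    return MutationStatusMatrix(
        sites=[Site(100, "A", "G")], populations=pops,
        status=[list(statuses)],
        lineages={"L": [p.population_id for p in pops]})


class TestStatusWeight:
    @pytest.mark.parametrize("status, weight", [
        (Status.ABSENT, 0.0), (Status.POLYMORPHIC, 0.5), (Status.FIXED, 1.0)])
    def test_weights(self, status, weight):
        assert status_weight(status) == weight


class TestCumulativeSeries:
    def test_appear_fix_revert_counts_both_legs(self):
        # absent -> fixed -> polymorphic -> absent accrues 1, 0.5, 0.5
        m = _single_site_matrix([Status.ABSENT, Status.FIXED,
                                 Status.POLYMORPHIC, Status.ABSENT])
        s = cumulative_mutation_series(m, "L")
        assert s.cumulative == [0.0, 1.0, 1.5, 2.0]

    def test_appear_fix_then_segregate(self):
        m = _single_site_matrix([Status.ABSENT, Status.FIXED,
                                 Status.POLYMORPHIC])
        s = cumulative_mutation_series(m, "L")
        assert s.cumulative == [0.0, 1.0, 1.5]

    def test_all_absent_is_zero(self):
        m = _single_site_matrix([Status.ABSENT] * 4)
        assert cumulative_mutation_series(m, "L").cumulative == [0.0] * 4

    def test_ancestral_polymorphism_contributes_half_on_fixation(self):
        m = _single_site_matrix([Status.POLYMORPHIC, Status.FIXED])
        assert cumulative_mutation_series(m, "L").cumulative == [0.0, 0.5]

    def test_unknown_lineage(self, qbeta_matrix):
        with pytest.raises(DataError):
            cumulative_mutation_series(qbeta_matrix, "line99")

    def test_qbeta_per_line_counts(self, qbeta_matrix):
        expected = {"line1": [0.0, 2.5, 4.5, 7.5],
                    "line2": [0.0, 2.5, 7.0],
                    "line3": [0.0, 1.5, 2.0],
                    "line4": [0.0, 2.5]}
        for lid, cum in expected.items():
            assert cumulative_mutation_series(qbeta_matrix, lid).cumulative \
                == cum

    def test_site_order_permutation_invariant(self, qbeta_matrix):
        perm = np.random.default_rng(0).permutation(len(qbeta_matrix.sites))
        shuffled = MutationStatusMatrix(
            sites=[qbeta_matrix.sites[i] for i in perm],
            populations=qbeta_matrix.populations,
            status=[qbeta_matrix.status[i] for i in perm],
            lineages=qbeta_matrix.lineages)
        for lid in qbeta_matrix.lineages:
            assert cumulative_mutation_series(shuffled, lid).cumulative == \
                cumulative_mutation_series(qbeta_matrix, lid).cumulative

    def test_non_decreasing(self, qbeta_matrix):
        for lid in qbeta_matrix.lineages:
            cum = cumulative_mutation_series(qbeta_matrix, lid).cumulative
            assert all(b >= a for a, b in zip(cum, cum[1:]))


class TestFixationRate:
    def test_host_rate_two_mutations_in_genome(self):
        est = fixation_rate(2, 4.73e6, 163)
        assert est.rate == pytest.approx(2.594e-9, rel=1e-3)

    def test_zero_count(self):
        assert fixation_rate(0, 4217, 163).rate == 0.0

    def test_copropagation_count_implies_printed_rate(self):
        est = fixation_rate(7.5, 4217, 163)
        assert est.rate == pytest.approx(1.091e-5, rel=1e-3)

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(DataError):
            fixation_rate(1, 0, 163)


class TestLineageRateSummary:
    def test_identical_lines_have_zero_sd(self):
        pops = [Population("Anc", 0.0), Population("E", 100.0)]
        m = MutationStatusMatrix(
            sites=[Site(10, "A", "G")], populations=pops,
            status=[[Status.ABSENT, Status.FIXED]],
            lineages={"a1": ["Anc", "E"], "a2": ["Anc", "E"],
                      "b1": ["Anc", "E"], "b2": ["Anc", "E"]})
        cmp = lineage_rate_summary(m, 1000, ["a1", "a2"], ["b1", "b2"])
        assert cmp.group_a.sd == 0.0
        assert cmp.ratio == pytest.approx(1.0)

    def test_zero_denominator_ratio_undefined(self):
        pops = [Population("Anc", 0.0), Population("E", 100.0),
                Population("F", 100.0)]
        m = MutationStatusMatrix(
            sites=[Site(10, "A", "G")], populations=pops,
            status=[[Status.ABSENT, Status.FIXED, Status.ABSENT]],
            lineages={"a": ["Anc", "E"], "b": ["Anc", "F"]})
        cmp = lineage_rate_summary(m, 1000, ["a", "a"], ["b", "b"])
        assert cmp.ratio is None

    def test_qbeta_group_rates(self, qbeta_matrix):
        gens = {k: float(v) for k, v in QBETA_LINE_GENERATIONS.items()}
        cmp = lineage_rate_summary(
            qbeta_matrix, QBETA_GENOME_LENGTH,
            QBETA_COPROPAGATION_LINES, QBETA_PROPAGATION_LINES,
            generations=gens)
        assert cmp.group_a.rate == pytest.approx(1.0486e-5, rel=1e-3)
        assert cmp.group_a.sd == pytest.approx(6.0e-7, rel=0.01)
        assert cmp.group_b.rate == pytest.approx(3.168e-6, rel=1e-3)
        assert cmp.group_b.sd == pytest.approx(5.1e-7, rel=0.01)

    def test_recovers_generating_rate_from_simulated_histories(self):
        from coevo.datasets import load_qbeta_annotation
        from coevo.simulate import (SubstitutionProcessParams,
                                    simulate_mutation_history)
        annotation = load_qbeta_annotation(with_sequence=False)
        rate, G = 1e-5, 163
        rates = []
        for seed in range(100):
            sub = SubstitutionProcessParams(
                rate_per_base_per_generation=rate, polymorphic_dwell=0,
                reversion_prob=0.0, seed=seed)
            m = simulate_mutation_history(sub, annotation, [G])
            rates.append(lineage_rates(m, annotation.genome_length)["sim"].rate)
        lam = rate * annotation.genome_length * G
        se_rate = math.sqrt(lam / 100) / (annotation.genome_length * G)
        assert abs(np.mean(rates) - rate) <= 3 * se_rate


class TestRateWelch:
    def test_identical_groups(self):
        t, df, p = rate_welch_t([1.0, 2.0], [1.0, 2.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_groups(self):
        t, df, p = rate_welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)


class TestGeneBias:
    def test_observed_fraction_at_null_gives_p_near_one(self, qbeta_annotation):
        # k/n == p0 exactly (p0 = 0.5 on a toy annotation)
        from coevo.data_model import Gene, GenomeAnnotation
        ann = GenomeAnnotation(100, [Gene("g", 1, 50)])
        pops = [Population("Anc", 0.0), Population("E", 10.0)]
        m = MutationStatusMatrix(
            sites=[Site(10, "A", "G"), Site(60, "C", "U")],
            populations=pops,
            status=[[Status.ABSENT, Status.FIXED],
                    [Status.ABSENT, Status.FIXED]],
            lineages={"L": ["Anc", "E"]})
        res = gene_bias_binomial(m, ann, "g")
        assert res.fraction == pytest.approx(0.5)
        assert res.p_value > 0.9

    def test_all_in_gene_small_n(self):
        from coevo.data_model import Gene, GenomeAnnotation
        ann = GenomeAnnotation(100, [Gene("g", 1, 50)])
        pops = [Population("Anc", 0.0), Population("E", 10.0)]
        m = MutationStatusMatrix(
            sites=[Site(i * 5 + 1, "A", "G") for i in range(5)],
            populations=pops,
            status=[[Status.ABSENT, Status.POLYMORPHIC]] * 5,
            lineages={"L": ["Anc", "E"]})
        res = gene_bias_binomial(m, ann, "g")
        # 5 half-weights double to k = n = 5 at p0 = 0.5
        assert res.p_value == pytest.approx(2 * 0.5 ** 5)

    def test_qbeta_a2_enrichment(self, qbeta_matrix, qbeta_annotation):
        res = gene_bias_binomial(qbeta_matrix, qbeta_annotation, "A2",
                                 lineages=QBETA_COPROPAGATION_LINES)
        assert res.k_in_gene == pytest.approx(9.5)
        assert res.n_total == pytest.approx(14.5)
        assert res.fraction == pytest.approx(0.655, abs=5e-4)
        assert res.p_value < 0.05

    def test_empty_tally_reports_undefined(self, qbeta_annotation):
        pops = [Population("Anc", 0.0), Population("E", 10.0)]
        m = MutationStatusMatrix(
            sites=[], populations=pops, status=[],
            lineages={"L": ["Anc", "E"]})
        res = gene_bias_binomial(m, qbeta_annotation, "A2")
        assert res.p_value is None


class TestAnnotateMutation:
    def test_printed_rows_reproduced(self, qbeta_matrix, qbeta_annotation,
                                     qbeta_printed_rows):
        by_pos = {s.genome_position: s for s in qbeta_matrix.sites}
        for pos, regions, gene_pos, codon, aa, effect in qbeta_printed_rows:
            site = by_pos[pos]
            anns = annotate_mutation(pos, site.ancestral_nt, site.evolved_nt,
                                     qbeta_annotation)
            assert [a.region for a in anns] == regions
            for a in anns:
                assert a.effect == effect
                if effect != "UTR":
                    assert a.gene_position == gene_pos
                    assert a.codon_change == codon
                    if effect == "nonsynonymous":
                        assert a.amino_acid_change == aa

    def test_ancestral_mismatch_rejected(self, qbeta_annotation):
        with pytest.raises(DataError, match="does not match reference"):
            annotate_mutation(569, "C", "A", qbeta_annotation)

    def test_heterogeneous_ancestor_matches_either_allele(self,
                                                          qbeta_annotation):
        anns = annotate_mutation(569, "G/A", "A", qbeta_annotation)
        assert anns[0].effect == "nonsynonymous"


class TestPoissonRateTest:
    def test_zero_observed_is_one(self):
        assert poisson_rate_test(0, 4.73e6, 163, 1.7e-10) == 1.0

    def test_host_rate_against_sole_passage_reference(self):
        p = poisson_rate_test(2, 4.73e6, 163, 1.7e-10)
        lam = 1.7e-10 * 4.73e6 * 163
        closed_form = 1 - math.exp(-lam) * (1 + lam)
        assert p == pytest.approx(closed_form, rel=1e-10)
        assert p < 0.01

    def test_large_lambda_limit(self):
        assert poisson_rate_test(2, 4.73e6, 163, 1.0) == pytest.approx(1.0)


class TestBottleneck:
    @pytest.mark.parametrize("count, frac, expected", [
        (1e6, 0.01, 1e4), (5e8, 1.0, 5e8), (1e5, 0.01, 1e3)])
    def test_product(self, count, frac, expected):
        assert bottleneck_ne(count, frac).bottleneck_size == pytest.approx(
            expected)

    def test_fraction_bounds(self):
        with pytest.raises(DataError):
            bottleneck_ne(1e6, 0.0)
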