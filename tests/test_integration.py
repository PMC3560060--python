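import numpy as np
import pytest

from transchrom.differential import A_SPECIFIC, B_SPECIFIC, SHARED, DifferentialResult
from transchrom.genome import GeneModel, GenomicInterval
from transchrom.integration import (
    NO_REGION,
    expression_by_category,
    expression_from_counts,
    filter_probes_control,
    methylation_by_category,
    repression_by_category,
    rpkm,
)
from transchrom.io_formats import AlignedReadSet, MethylationProbe


def _result(start, category, summit=None):
    summit = summit if summit is not None else start + 500
    return DifferentialResult(
        GenomicInterval("chrS", start, start + 1000), summit, 10, 2, 0.0, 0.5,
        fdr=0.5, category=category,
    )


def _gene(gid, tss):
    return GeneModel(gid, tss, 1000, GenomicInterval("chrS", tss, tss + 1000, "+"))


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(1000, 2000, 10**7) == pytest.approx(50.0)

    def test_zero_reads(self):
        assert rpkm(0, 2000, 10**7) == 0.0

    def test_scale_invariance(self):
        assert rpkm(2000, 2000, 2 * 10**7) == pytest.approx(rpkm(1000, 2000, 10**7))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 10**7)
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)


class TestExpressionByCategory:
    def _setup(self, a_ratios, shared_ratios):
        results, genes, expr = [], [], {}
        pos = 100_000
        for i, r in enumerate(a_ratios):
            gid = f"a{i}"
            results.append(_result(pos, A_SPECIFIC))
            genes.append(_gene(gid, pos + 600))
            expr[gid] = (float(2**r * 8 - 1), 7.0)  # log2((A+1)/(B+1)) == r
            pos += 50_000
        for i, r in enumerate(shared_ratios):
            gid = f"s{i}"
            results.append(_result(pos, SHARED))
            genes.append(_gene(gid, pos + 600))
            expr[gid] = (float(2**r * 8 - 1), 7.0)
            pos += 50_000
        return results, genes, expr

    def test_equal_expression_gives_null(self):
        results, genes, expr = self._setup([0, 0, 0], [0, 0, 0])
        out = expression_by_category(results, genes, expr)
        assert out[A_SPECIFIC].test.p_value == 1.0
        assert out[A_SPECIFIC].median == 0.0

    def test_shifted_specific_genes_exact_p(self):
        results, genes, expr = self._setup([2, 2, 2], [0, 0, 0])
        out = expression_by_category(results, genes, expr)
        assert out[A_SPECIFIC].test.p_value == pytest.approx(1 / 20)
        assert out[A_SPECIFIC].test.direction == "greater"

    def test_pseudocount_arithmetic(self):
        results = [_result(100_000, A_SPECIFIC), _result(200_000, SHARED)]
        genes = [_gene("g", 100_600), _gene("h", 200_600)]
        expr = {"g": (3.0, 0.0), "h": (1.0, 1.0)}
        out = expression_by_category(results, genes, expr)
        assert out[A_SPECIFIC].values == [pytest.approx(2.0)]

    def test_gene_hit_by_two_regions_counted_once(self):
        results = [_result(100_000, A_SPECIFIC, summit=100_500),
                   _result(100_900, A_SPECIFIC, summit=101_400),
                   _result(300_000, SHARED)]
        genes = [_gene("g", 101_000), _gene("h", 300_600)]
        expr = {"g": (1.0, 1.0), "h": (1.0, 1.0)}
        out = expression_by_category(results, genes, expr)
        assert len(out[A_SPECIFIC].values) == 1

    def test_empty_category_marked_unavailable(self):
        results = [_result(100_000, SHARED)]
        genes = [_gene("g", 100_600)]
        out = expression_by_category(results, genes, {"g": (1.0, 1.0)})
        assert not out[A_SPECIFIC].available

    def test_negated_ratios_flip_the_tail(self):
        results, genes, expr = self._setup([1.0, 1.5, 2.0], [0.1, -0.1, 0.0])
        out_up = expression_by_category(results, genes, expr)
        neg_expr = {g: (b, a) for g, (a, b) in expr.items()}
        out_dn = expression_by_category(results, genes, neg_expr)
        p_up = out_up[A_SPECIFIC].test.p_value
        p_dn = out_dn[A_SPECIFIC].test.p_value
        assert p_up <= 0.1 and p_dn >= 0.9

    def test_expression_from_counts_uses_context_totals(self):
        counts = {"g": (1000, 500), "h": (9000, 9500)}
        lengths = {"g": 2000, "h": 2000}
        expr = expression_from_counts(counts, lengths)
        assert expr["g"][0] == pytest.approx(rpkm(1000, 2000, 10_000))
        assert expr["g"][1] == pytest.approx(rpkm(500, 2000, 10_000))


class TestProbeFiltering:
    def _probe(self, pid, control_p, pos=100, beta=0.5):
        return MethylationProbe(pid, pos, {"A_1": beta}, control_p)

    def test_all_clean_probes_retained(self):
        probes = [self._probe(f"p{i}", 1.0) for i in range(5)]
        assert len(filter_probes_control(probes)) == 5

    def test_all_contaminated_probes_removed(self):
        probes = [self._probe(f"p{i}", 0.0) for i in range(5)]
        assert filter_probes_control(probes) == []

    def test_mixed_detection_threshold(self):
        probes = [self._probe("bad", 0.001), self._probe("good", 0.5)]
        kept = filter_probes_control(probes, alpha=0.01)
        assert [p.probe_id for p in kept] == ["good"]


class TestMethylationByCategory:
    def _probes(self, positions, betas_a, betas_b):
        return [
            MethylationProbe(
                f"cg{i}", pos,
                {"A_1": ba, "A_2": ba, "B_1": bb, "B_2": bb}, 0.9,
            )
            for i, (pos, ba, bb) in enumerate(zip(positions, betas_a, betas_b))
        ]

    CONTEXT_OF = {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}

    def test_identical_betas_null(self):
        results = [_result(100_000, A_SPECIFIC)]
        probes = self._probes([100_100, 100_200, 100_300], [0.4] * 3, [0.4] * 3)
        out = methylation_by_category(probes, results, self.CONTEXT_OF)
        assert out[A_SPECIFIC].test.p_value == 1.0

    def test_separated_betas_exact_p(self):
        results = [_result(100_000, A_SPECIFIC)]
        probes = self._probes(
            [100_100, 100_200, 100_300], [0.1, 0.2, 0.1], [0.8, 0.9, 0.85]
        )
        out = methylation_by_category(probes, results, self.CONTEXT_OF)
        r = out[A_SPECIFIC]
        assert r.medians["A"] == pytest.approx(0.1)
        assert r.medians["B"] == pytest.approx(0.85)
        assert r.test.p_value == pytest.approx(2 / 20)

    def test_probe_outside_regions_goes_to_background(self):
        results = [_result(100_000, A_SPECIFIC)]
        probes = self._probes([500_000], [0.7], [0.7])
        out = methylation_by_category(probes, results, self.CONTEXT_OF)
        assert out[NO_REGION].available
        assert len(out[NO_REGION].betas["A"]) == 1

    def test_medians_stay_in_unit_interval(self):
        rng = np.random.default_rng(0)
        results = [_result(100_000, A_SPECIFIC), _result(300_000, SHARED)]
        positions = list(rng.integers(90_000, 400_000, 40))
        probes = self._probes(positions, rng.uniform(0, 1, 40), rng.uniform(0, 1, 40))
        out = methylation_by_category(probes, results, self.CONTEXT_OF)
        for res in out.values():
            for med in res.medians.values():
                assert 0.0 <= med <= 1.0


def _k9(midpoints, context, replicate=1):
    mids = np.asarray(midpoints, dtype=np.int64)
    return AlignedReadSet(
        f"H3K9me3_{context}_{replicate}", context, "H3K9me3", replicate, "chrS",
        mids - 25, mids + 25,
    )


class TestRepressionByCategory:
    def _results(self, n_spec=10, n_shared=10):
        out = []
        pos = 100_000
        for _ in range(n_spec):
            out.append(_result(pos, A_SPECIFIC))
            pos += 20_000
        for _ in range(n_shared):
            out.append(_result(pos, SHARED))
            pos += 20_000
        return out

    def test_uniform_coverage_is_null(self):
        rng = np.random.default_rng(1)
        results = self._results()
        sets = [
            _k9(rng.integers(25, 600_000, size=12_000), ctx) for ctx in ("A", "B")
        ]
        rep = repression_by_category(sets, results)
        for tests in rep.within_context.values():
            assert tests["rank_sum"].p_value > 0.05
            assert tests["ks"].statistic < 0.5

    def test_seeded_elevation_detected_in_context_b(self):
        rng = np.random.default_rng(2)
        results = self._results()
        spec_regions = [r for r in results if r.category == A_SPECIFIC]
        bg_a = rng.integers(25, 600_000, size=12_000)
        bg_b = rng.integers(25, 600_000, size=12_000)
        extra = np.concatenate(
            [rng.integers(r.region.start, r.region.end, size=60) for r in spec_regions]
        )
        rep = repression_by_category([_k9(bg_a, "A"), _k9(np.concatenate([bg_b, extra]), "B")], results)
        b_tests = rep.within_context["B"]
        assert b_tests["rank_sum"].p_value <= 0.05
        spec_med = np.median(rep.scores[("B", A_SPECIFIC)])
        shared_med = np.median(rep.scores[("B", SHARED)])
        assert spec_med > shared_med
        # matched-pairs test across contexts picks up the same signal
        assert rep.between_context[A_SPECIFIC].p_value <= 0.05

    def test_single_replicate_averaging_is_identity(self):
        rng = np.random.default_rng(3)
        results = self._results(2, 2)
        mids = rng.integers(25, 600_000, size=5000)
        rep1 = repression_by_category([_k9(mids, "A"), _k9(mids, "B")], results)
        scores_a = rep1.scores[("A", SHARED)]
        scores_b = rep1.scores[("B", SHARED)]
        assert scores_a == pytest.approx(scores_b)
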