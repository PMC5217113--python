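"""Rank-sum testing, two-hit gene calls, control-based error rates."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shscreen import (
    GeneCall,
    InferenceConfig,
    LibraryManifest,
    ShRNAConstruct,
    construct_class_rates,
    construct_tests,
    control_performance,
    gene_two_hit_calls,
    rank_sum_test,
    two_hit_null_probability,
)
from shscreen.quantify import FoldChangeMatrix


def brute_force_p(x, y, sidedness="two_sided"):
    """Oracle: enumerate all C(m+n, m) assignments of the pooled values."""
    pooled = list(x) + list(y)
    m = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        us.append(sum(ranks[i] for i in idx) - m * (m + 1) / 2)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    if sidedness == "one_sided_less":
        return p_le
    if sidedness == "one_sided_greater":
        return p_ge
    return min(1.0, 2 * min(p_le, p_ge))


def fc_matrix(data: dict[str, list[float]]) -> FoldChangeMatrix:
    df = pd.DataFrame(data).T
    df.columns = [f"r{i + 1}" for i in range(df.shape[1])]
    return FoldChangeMatrix(log2fc=df, reference_id="pool", pseudocount=0.5)


def manifest_for(ids_classes) -> LibraryManifest:
    seqs = _seq_gen()
    return LibraryManifest(
        [
            ShRNAConstruct(cid, gene, cls, next(seqs))
            for cid, gene, cls in ids_classes
        ]
    )


def _seq_gen():
    rng = np.random.default_rng(2024)
    bases = "ACGT"
    seen = set()
    while True:
        s = "".join(bases[i] for i in rng.integers(0, 4, 18))
        if s not in seen:
            seen.add(s)
            yield s


class TestRankSumTest:
    def test_fully_separated_one_sided(self):
        # x entirely below y: U = 0, exactly 1 of C(6,3)=20 assignments
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6], "one_sided_less")
        assert u == 0
        assert p == pytest.approx(0.05, abs=1e-12)

    def test_identical_multisets_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = rank_sum_test(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_all_values_identical(self):
        u, p = rank_sum_test([2.0] * 5, [2.0] * 7)
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 3), (4, 4), (3, 7), (5, 5)])
    @pytest.mark.parametrize(
        "sidedness", ["two_sided", "one_sided_less", "one_sided_greater"]
    )
    def test_exact_matches_enumeration_oracle(self, m, n, sidedness):
        rng = np.random.default_rng(m * 100 + n)
        for _ in range(5):
            vals = rng.permutation(np.arange(1, m + n + 1, dtype=float))
            x, y = vals[:m], vals[m:]
            _, p = rank_sum_test(x, y, sidedness)
            assert p == pytest.approx(brute_force_p(x, y, sidedness), abs=1e-12)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=6)
            _, p = rank_sum_test(x, y)
            sp = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_large_sample_close_to_scipy_normal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=9)
        y = rng.normal(size=40)
        _, p = rank_sum_test(x, y)
        sp = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(sp.pvalue, rel=1e-6)

    def test_type_i_error_calibration(self):
        # 9 vs 40 from one continuous distribution: rejection at alpha=0.01
        # should fall in the binomial 99% CI around 0.01
        rng = np.random.default_rng(7)
        n_sim = 10_000
        alpha = 0.01
        rej = 0
        for _ in range(n_sim):
            x = rng.normal(size=9)
            y = rng.normal(size=40)
            _, p = rank_sum_test(x, y)
            rej += p <= alpha
        half = 2.576 * math.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rej / n_sim - alpha) < half


class TestConstructTests:
    def test_fully_depleted_construct(self):
        # 9 replicate values all below 40+ pooled null values
        null_genes = [(f"n{i}_sh{j}", f"NG{i}", "negative")
                      for i in range(5) for j in range(2)]
        rows = [("hit_sh1", "HIT", "test")] + null_genes
        manifest = manifest_for(rows)
        rng = np.random.default_rng(0)
        data = {"hit_sh1": list(rng.normal(-5, 0.1, 9))}
        for cid, _, _ in null_genes:
            data[cid] = list(rng.normal(0, 0.5, 9))
        calls = construct_tests(fc_matrix(data), manifest)
        hit = next(c for c in calls if c.construct_id == "hit_sh1")
        assert hit.direction == "depleted"
        assert hit.p_value < 0.01
        assert hit.significant

    def test_all_zero_matrix_neutral(self):
        rows = [
            ("a_sh1", "A", "test"),
            ("n_sh1", "N", "negative"),
            ("n_sh2", "N", "negative"),
        ]
        manifest = manifest_for(rows)
        data = {cid: [0.0] * 5 for cid, _, _ in rows}
        calls = construct_tests(fc_matrix(data), manifest)
        assert all(c.p_value == 1.0 for c in calls)
        assert all(c.direction == "neutral" for c in calls)
        assert not any(c.significant for c in calls)

    def test_null_construct_excluded_from_own_null(self):
        # a negative construct with an extreme profile must not dilute its
        # own null sample: it is testable and can reach significance
        rows = [(f"n{i}_sh1", f"N{i}", "negative") for i in range(6)]
        manifest = manifest_for(rows)
        rng = np.random.default_rng(1)
        data = {cid: list(rng.normal(0, 0.3, 9)) for cid, _, _ in rows}
        data["n0_sh1"] = list(rng.normal(-6, 0.1, 9))
        calls = construct_tests(fc_matrix(data), manifest)
        outlier = next(c for c in calls if c.construct_id == "n0_sh1")
        assert outlier.direction == "depleted"
        assert outlier.p_value < 0.01

    def test_no_null_constructs_is_error(self):
        manifest = manifest_for([("a_sh1", "A", "test"), ("n_sh1", "N", "negative")])
        fc = fc_matrix({"a_sh1": [0.1] * 3, "n_sh1": [0.0] * 3})
        with pytest.raises(ValueError, match="null class"):
            construct_tests(fc, manifest, InferenceConfig(null_class="positive"))

    def test_significance_flag_matches_alpha(self):
        rows = [
            ("a_sh1", "A", "test"),
            ("n_sh1", "N1", "negative"),
            ("n_sh2", "N2", "negative"),
            ("n_sh3", "N3", "negative"),
        ]
        manifest = manifest_for(rows)
        rng = np.random.default_rng(2)
        data = {cid: list(rng.normal(0, 1, 7)) for cid, _, _ in rows}
        for alpha in (0.5, 0.1, 0.01):
            calls = construct_tests(
                fc_matrix(data), manifest, InferenceConfig(alpha=alpha)
            )
            for c in calls:
                assert c.significant == (c.p_value <= alpha)


class TestGeneTwoHitCalls:
    def _call(self, gene, sig, direction, i):
        from shscreen.inference import ConstructCall

        return ConstructCall(
            construct_id=f"{gene}_sh{i}",
            gene=gene,
            control_class="test",
            median_log2fc=-1.0 if direction == "depleted" else 1.0,
            U_statistic=0.0,
            p_value=0.001 if sig else 0.9,
            direction=direction,
            significant=sig,
        )

    def test_two_depleted_hits_make_essential(self):
        calls = [self._call("G", i < 2, "depleted", i) for i in range(5)]
        (g,) = gene_two_hit_calls(calls)
        assert g.essential_call
        assert g.n_depleted_significant == 2

    def test_enriched_hits_never_count(self):
        calls = [self._call("G", True, "enriched", 0),
                 self._call("G", True, "enriched", 1),
                 self._call("G", True, "depleted", 2),
                 self._call("G", False, "depleted", 3),
                 self._call("G", False, "neutral", 4)]
        (g,) = gene_two_hit_calls(calls)
        assert not g.essential_call
        assert g.n_enriched_significant == 2

    def test_no_significant_calls_no_essential_genes(self):
        calls = [self._call(f"G{j}", False, "depleted", i)
                 for j in range(3) for i in range(4)]
        assert not any(g.essential_call for g in gene_two_hit_calls(calls))

    def test_monotone_adding_hit_never_revokes(self):
        base = [self._call("G", True, "depleted", 0),
                self._call("G", True, "depleted", 1)]
        assert gene_two_hit_calls(base)[0].essential_call
        more = base + [self._call("G", True, "depleted", 2)]
        assert gene_two_hit_calls(more)[0].essential_call


class TestTwoHitNullProbability:
    def test_paper_pairwise_square(self):
        assert two_hit_null_probability(0.01, 2, "paper_pairwise") == 1e-4

    def test_binomial_tail_hand_check(self):
        # 1 - 0.99^5 - 5*0.01*0.99^4
        expected = 1 - 0.99**5 - 5 * 0.01 * 0.99**4
        got = two_hit_null_probability(0.01, 5, "binomial_at_least_2")
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(9.80e-4, rel=1e-2)

    def test_zero_alpha(self):
        assert two_hit_null_probability(0.0, 7, "binomial_at_least_2") == 0.0

    def test_single_construct(self):
        assert two_hit_null_probability(0.01, 1, "binomial_at_least_2") == 0.0
        with pytest.raises(ValueError):
            two_hit_null_probability(0.01, 1, "paper_pairwise")


def _gene_calls(n_pos, n_pos_called, n_neg, n_neg_called):
    manifest_rows = []
    calls = []
    seqs = _seq_gen()
    for i in range(n_pos):
        g = f"P{i}"
        manifest_rows.append(ShRNAConstruct(f"{g}_sh1", g, "positive", next(seqs)))
        calls.append(GeneCall(g, "positive", 5, 2 if i < n_pos_called else 0, 0,
                              i < n_pos_called))
    for i in range(n_neg):
        g = f"N{i}"
        manifest_rows.append(ShRNAConstruct(f"{g}_sh1", g, "negative", next(seqs)))
        calls.append(GeneCall(g, "negative", 5, 2 if i < n_neg_called else 0, 0,
                              i < n_neg_called))
    return calls, LibraryManifest(manifest_rows)


class TestControlPerformance:
    def test_pilot_worked_example(self):
        # 17 positive-control genes, 14 recovered; 8 negatives, 1 called
        calls, manifest = _gene_calls(17, 14, 8, 1)
        perf = control_performance(calls, manifest)
        assert perf.fnr == pytest.approx(3 / 17)
        assert perf.fnr_percent == 17.6
        assert round(perf.fnr * 100) == 18
        assert perf.fpr == pytest.approx(1 / 8)
        assert perf.fpr_percent == 12.5

    def test_perfect_screen(self):
        calls, manifest = _gene_calls(5, 5, 4, 0)
        perf = control_performance(calls, manifest)
        assert perf.fnr == 0.0
        assert perf.fpr == 0.0

    def test_order_invariance(self):
        calls, manifest = _gene_calls(6, 3, 4, 2)
        fwd = control_performance(calls, manifest)
        rev = control_performance(calls[::-1], manifest)
        assert (fwd.fnr, fwd.fpr) == (rev.fnr, rev.fpr)

    def test_missing_class_reported_as_none(self):
        seqs = _seq_gen()
        manifest = LibraryManifest(
            [
                ShRNAConstruct("n_sh1", "N", "negative", next(seqs)),
                ShRNAConstruct("t_sh1", "T", "test", next(seqs)),
            ]
        )
        calls = [GeneCall("N", "negative", 1, 0, 0, False),
                 GeneCall("T", "test", 1, 0, 0, False)]
        perf = control_performance(calls, manifest)
        assert perf.fnr is None
        assert perf.fpr == 0.0


class TestConstructClassRates:
    def test_enrichment_worked_example(self):
        # 83 positive-class constructs of which 14 significantly enriched
        from shscreen.inference import ConstructCall

        calls = [
            ConstructCall(f"c{i}", f"G{i // 5}", "positive", 1.0, 0.0,
                          0.001 if i < 14 else 0.5,
                          "enriched", i < 14)
            for i in range(83)
        ]
        rates = construct_class_rates(calls)["positive"]
        assert rates.n_enriched_significant == 14
        assert round(rates.enriched_percent) == 17
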