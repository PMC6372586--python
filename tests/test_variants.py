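"""Unit and property tests for consensus merging and the filter cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from fgfrscreen.variants import (
    CallRecord,
    CohortMatrix,
    ConsensusCall,
    DuplicateRecordError,
    FilterConfig,
    InvalidAlleleError,
    Reason,
    ReferenceWindow,
    VariantKey,
    _rx2_exact_p,
    apply_site_filters,
    classify_germline,
    detect_recurrent_artifacts,
    merge_calls,
    normalize_variant,
)
from fgfrscreen.variants import test_run_bias as run_bias_test


def key(pos=100, ref="A", alt="C", chrom="1"):
    return VariantKey(chrom, pos, ref, alt)


class TestNormalizeVariant:
    def test_identity_change_rejected(self):
        with pytest.raises(InvalidAlleleError):
            normalize_variant(key(ref="A", alt="A"))

    def test_non_acgt_rejected(self):
        with pytest.raises(InvalidAlleleError):
            normalize_variant(key(ref="N", alt="A"))
        with pytest.raises(InvalidAlleleError):
            normalize_variant(key(ref="", alt="A"))

    def test_shared_prefix_trimmed(self):
        assert normalize_variant(key(ref="CA", alt="CG")) == key(pos=101, ref="A", alt="G")

    def test_lowercase_uppercased(self):
        assert normalize_variant(key(ref="a", alt="c")) == key(ref="A", alt="C")

    def test_deletion_left_aligned_against_reference(self):
        # reference ...G A T T T C... starting at 98; deleting any T of the
        # run must normalize to the leftmost representation (pos 99, AT>A)
        window = ReferenceWindow("1", 98, "GATTTC")
        oracle = None
        for raw in [key(99, "ATT", "AT"), key(100, "TT", "T"), key(101, "TT", "T")]:
            norm = normalize_variant(raw, window)
            # oracle: exhaustive left shift while the flanking base matches
            if oracle is None:
                oracle = norm
            assert norm == oracle
        assert oracle == key(pos=99, ref="AT", alt="A")

    def test_snv_normalization_idempotent(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(200):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            k = key(int(rng.integers(1, 10_000)), ref, alt)
            once = normalize_variant(k)
            assert normalize_variant(once) == once


class TestMergeCalls:
    def rec(self, caller, depth, alt_depth, k=None, sample="S1"):
        return CallRecord(sample, caller, k or key(), depth, alt_depth)

    def test_two_caller_median_consensus(self):
        calls = merge_calls([self.rec("a", 480, 140), self.rec("b", 512, 150)])
        (c,) = calls
        assert (c.caller_count, c.depth, c.alt_depth) == (2, 496, 145)
        assert c.vaf == pytest.approx(145 / 496)

    def test_half_depths_round_up(self):
        (c,) = merge_calls([self.rec("a", 101, 11), self.rec("b", 102, 12)])
        assert (c.depth, c.alt_depth) == (102, 12)  # 101.5 -> 102, 11.5 -> 12

    def test_single_caller_kept_with_count_one(self):
        (c,) = merge_calls([self.rec("a", 500, 100)])
        assert c.caller_count == 1

    def test_empty_input(self):
        assert merge_calls([]) == []

    def test_duplicate_caller_key_rejected(self):
        with pytest.raises(DuplicateRecordError):
            merge_calls([self.rec("a", 100, 10), self.rec("a", 200, 20)])

    def test_multiple_samples_rejected(self):
        with pytest.raises(ValueError):
            merge_calls([self.rec("a", 100, 10), self.rec("b", 100, 10, sample="S2")])

    @given(
        st.lists(
            st.tuples(st.integers(1, 2000), st.floats(0, 1)),
            min_size=1,
            max_size=6,
        )
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_consensus_counts_consistent(self, depth_fracs):
        # vaf * depth == alt_depth exactly, and alt never exceeds depth
        recs = [
            self.rec(f"c{i}", depth, int(round(frac * depth)))
            for i, (depth, frac) in enumerate(depth_fracs)
        ]
        (c,) = merge_calls(recs)
        assert 0 <= c.alt_depth <= c.depth
        assert c.vaf * c.depth == pytest.approx(c.alt_depth)


class TestSiteFilters:
    def call(self, caller_count=2, depth=500, alt_depth=150):
        return ConsensusCall("S1", key(), caller_count, depth, alt_depth)

    def test_clear_pass(self):
        assert apply_site_filters(self.call(), FilterConfig()).status == "PASS"

    def test_exact_thresholds_pass(self):
        # exclusion is strict (<100 reads, <20 alt reads), so equality passes
        c = apply_site_filters(self.call(2, 100, 20), FilterConfig())
        assert c.status == "PASS" and not c.reasons

    def test_all_three_failures_accumulate(self):
        c = apply_site_filters(self.call(1, 99, 19), FilterConfig())
        assert c.reasons == {Reason.ONE_CALLER, Reason.LOW_COVERAGE, Reason.LOW_ALT_READS}
        assert c.status == "FAIL"

    def test_idempotent_and_status_reason_coupling(self):
        c = apply_site_filters(self.call(1, 99, 19), FilterConfig())
        assert apply_site_filters(c, FilterConfig()).reasons == c.reasons
        assert (c.status == "FAIL") == bool(c.reasons)


def build_matrix(occurrences, n_samples=200, n_runs=2):
    """occurrences: list of (sample_idx, key, vaf)."""
    runs = {f"S{i}": f"run{1 + i % n_runs}" for i in range(n_samples)}
    entries = {}
    for idx, k, vaf in occurrences:
        entries.setdefault(k, []).append((f"S{idx}", vaf, runs[f"S{idx}"]))
    return CohortMatrix(entries=entries, cohort_samples=runs)


class TestRecurrentArtifacts:
    def test_twelve_low_vaf_carriers_flagged(self):
        m = build_matrix([(i, key(), 0.01) for i in range(12)])
        flagged = detect_recurrent_artifacts(m, FilterConfig())
        assert flagged == {key(): {f"S{i}" for i in range(12)}}

    def test_below_carrier_threshold_not_flagged(self):
        m = build_matrix([(i, key(), 0.01) for i in range(9)])
        assert detect_recurrent_artifacts(m, FilterConfig()) == {}

    def test_high_vaf_occurrence_at_artifact_site_retained(self):
        m = build_matrix([(i, key(), 0.015) for i in range(11)] + [(11, key(), 0.30)])
        flagged = detect_recurrent_artifacts(m, FilterConfig())
        assert flagged[key()] == {f"S{i}" for i in range(11)}
        assert "S11" not in flagged[key()]


class TestRunBias:
    def test_all_carriers_in_one_run_matches_hypergeometric_tail(self):
        # 2 runs x 100 samples, 10 carriers all in run1; oracle: both
        # maximally unbalanced tables are the only ones as unlikely, so
        # p = 2 * C(100,10) * C(100,0) / C(200,10) ~ 1.5e-3 — extreme, yet
        # just above the conservative 0.001 default alpha
        m = build_matrix([(2 * i, key(), 0.1) for i in range(10)], n_samples=200)
        res = run_bias_test(key(), m, FilterConfig())
        expected = min(1.0, 2 * comb(100, 10) / comb(200, 10))
        assert res.p_value == pytest.approx(expected, rel=1e-6)
        assert res.biased == (res.p_value < 0.001)
        # one more one-sided carrier pushes it over the threshold
        m11 = build_matrix([(2 * i, key(), 0.1) for i in range(11)], n_samples=200)
        assert run_bias_test(key(), m11, FilterConfig()).biased

    def test_balanced_carriers_not_biased(self):
        m = build_matrix([(i, key(), 0.1) for i in range(10)], n_samples=200)
        res = run_bias_test(key(), m, FilterConfig())
        assert res.p_value == pytest.approx(1.0)
        assert not res.biased

    def test_no_carriers(self):
        m = build_matrix([], n_samples=200)
        res = run_bias_test(key(), m, FilterConfig())
        assert res.p_value == 1.0 and not res.biased

    def test_single_run_skipped(self):
        m = build_matrix([(i, key(), 0.1) for i in range(5)], n_runs=1)
        res = run_bias_test(key(), m, FilterConfig())
        assert res.method == "skipped" and res.p_value is None and not res.biased

    def test_two_run_test_matches_hypergeometric_enumeration(self):
        # probability-mass enumeration over the hypergeometric support
        def oracle(k1, n1, n2, K):
            probs = [
                comb(n1, k) * comb(n2, K - k) / comb(n1 + n2, K)
                for k in range(max(0, K - n2), min(K, n1) + 1)
            ]
            obs = comb(n1, k1) * comb(n2, K - k1) / comb(n1 + n2, K)
            return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)))

        for n1, n2 in [(5, 5), (8, 3), (10, 7), (12, 12)]:
            runs = {f"A{i}": "run1" for i in range(n1)} | {f"B{i}": "run2" for i in range(n2)}
            for K in range(0, min(10, n1 + n2) + 1):
                for k1 in range(max(0, K - n2), min(K, n1) + 1):
                    carriers = [f"A{i}" for i in range(k1)] + [f"B{i}" for i in range(K - k1)]
                    m = CohortMatrix(
                        entries={key(): [(s, 0.1, runs[s]) for s in carriers]},
                        cohort_samples=runs,
                    )
                    res = run_bias_test(key(), m, FilterConfig())
                    assert res.p_value == pytest.approx(oracle(k1, n1, n2, K), rel=1e-6), (
                        n1, n2, K, k1,
                    )

    def test_three_run_exact_matches_carrier_set_enumeration(self):
        # independent oracle: enumerate every carrier subset of the cohort
        import itertools

        sizes = {"run1": 4, "run2": 3, "run3": 3}
        runs = {
            f"{run}_{i}": run for run, n in sizes.items() for i in range(n)
        }
        samples = sorted(runs)
        carriers = ["run1_0", "run1_1", "run1_2", "run2_0"]
        m = CohortMatrix(
            entries={key(): [(s, 0.1, runs[s]) for s in carriers]},
            cohort_samples=runs,
        )
        res = run_bias_test(key(), m, FilterConfig())
        assert res.method == "exact_rx2"

        K = len(carriers)
        run_names = sorted(sizes)
        obs_counts = tuple(sum(1 for s in carriers if runs[s] == r) for r in run_names)
        weights = {}
        for subset in itertools.combinations(samples, K):
            counts = tuple(sum(1 for s in subset if runs[s] == r) for r in run_names)
            weights[counts] = weights.get(counts, 0) + 1
        total = sum(weights.values())
        p_obs = weights[obs_counts] / total
        oracle = sum(w for c, w in weights.items() if w / total <= p_obs * (1 + 1e-9)) / total
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_permutation_fallback_close_to_exact(self):
        sizes = np.array([40, 40, 40])
        carriers = np.array([40, 12, 8])  # 60 carriers > exact cutoff of 50
        runs = {}
        i = 0
        for r, n in zip(("run1", "run2", "run3"), sizes):
            for _ in range(n):
                runs[f"S{i}"] = r
                i += 1
        samples = sorted(runs, key=lambda s: int(s[1:]))
        carrier_samples = []
        start = 0
        for r, n, k in zip(("run1", "run2", "run3"), sizes, carriers):
            carrier_samples += samples[start : start + k]
            start += n
        m = CohortMatrix(
            entries={key(): [(s, 0.1, runs[s]) for s in carrier_samples]},
            cohort_samples=runs,
        )
        res = run_bias_test(key(), m, FilterConfig(), seed=5)
        assert res.method == "chi2_sim"
        # strongly unbalanced: permutation p must be near its floor
        assert res.p_value < 0.01 and res.biased


class TestGermline:
    def consensus(self, vaf=0.5):
        return ConsensusCall("S0", key(), 2, 1000, int(1000 * vaf))

    def test_known_snp_membership(self):
        codes = classify_germline(self.consensus(), key(), {key()})
        assert Reason.KNOWN_SNP in codes

    def test_single_low_vaf_carrier_unflagged(self):
        m = build_matrix([(0, key(), 0.285)], n_samples=481)
        codes = classify_germline(self.consensus(0.285), key(), set(), m)
        assert codes == ()

    def test_high_prevalence_het_band_flagged(self):
        m = build_matrix([(i, key(), 0.5) for i in range(60)], n_samples=481)
        codes = classify_germline(self.consensus(), key(), set(), m)
        assert codes == (Reason.LIKELY_GERMLINE,)

    def test_heuristic_can_be_disabled(self):
        m = build_matrix([(i, key(), 0.5) for i in range(60)], n_samples=481)
        cfg = FilterConfig(germline_enabled=False)
        assert classify_germline(self.consensus(), key(), set(), m, cfg) == ()


class TestFilterMonotonicity:
    def test_stricter_thresholds_never_add_survivors(self, scenario17):
        from fgfrscreen.pipeline import run_variant_stage
        from fgfrscreen.variants import FilterConfig

        base = scenario17.screen
        survivors_base = set(
            map(tuple, base.survivors[["sample", "chrom", "pos", "ref", "alt"]].values)
        )
        stricter = FilterConfig(min_callers=3, min_depth=500, min_alt_reads=60)
        bundle = scenario17.bundle
        from fgfrscreen.io import records_from_frame
        from fgfrscreen.variants import screen_cohort

        rep = screen_cohort(
            records_from_frame(scenario17.calls.calls),
            scenario17.calls.manifest,
            list(bundle.models.values()),
            bundle.snp_list,
            bundle.domains,
            bundle.hotspots,
            cfg=stricter,
            targets=bundle.targets,
        )
        survivors_strict = set(
            map(tuple, rep.survivors[["sample", "chrom", "pos", "ref", "alt"]].values)
        )
        assert survivors_strict <= survivors_base
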