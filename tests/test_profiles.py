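"""Coverage/end-profile machinery: hand-computed cases, normalisation
invariants, peak and stagger behaviour, persistence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csmkd import profiles, simulate
from csmkd.errors import InputError
from csmkd.types import CleavageModel

L = {"tx": 100}


def test_coverage_single_fragment_hand_case(frag_builder):
    frags = frag_builder([("s1", "tx", 10, 20)], L)
    prof = profiles.coverage_fraction(frags, "tx", "s1")
    expected = np.zeros(100)
    expected[10:20] = 0.1
    np.testing.assert_allclose(prof.values, expected)


def test_coverage_identical_samples_identical_profiles(frag_builder):
    recs = [("a", "tx", 5, 30), ("a", "tx", 40, 80), ("b", "tx", 5, 30), ("b", "tx", 40, 80)]
    frags = frag_builder(recs, L)
    pa = profiles.coverage_fraction(frags, "tx", "a")
    pb = profiles.coverage_fraction(frags, "tx", "b")
    np.testing.assert_array_equal(pa.values, pb.values)


def test_coverage_uniform_sampling_matches_expectation(frag_builder):
    """Uniform fragment placement gives a near-uniform interior profile,
    within binomial error of the per-position expectation."""
    rng = np.random.default_rng(0)
    n, flen, Ltx = 100_000, 10, 200
    starts = rng.integers(0, Ltx - flen + 1, n)
    frags = frag_builder([("s", "tx", int(a), int(a) + flen) for a in starts], {"tx": Ltx})
    prof = profiles.coverage_fraction(frags, "tx", "s")
    # interior positions (>= flen-1 from each edge) have expectation flen/(valid starts)/total
    interior = np.arange(flen - 1, Ltx - flen + 1)
    p = flen / (Ltx - flen + 1) / flen  # per-fragment mass at a position / total mass
    se = np.sqrt(p * (1 - p) / n)
    assert np.max(np.abs(prof.values[interior] - p)) < 3.5 * se


def test_coverage_empty_flagged(frag_builder):
    frags = frag_builder([("s1", "tx", 10, 20)], L)
    prof = profiles.coverage_fraction(frags, "tx", "other_sample")
    assert prof.empty and prof.values.sum() == 0


def test_coverage_unknown_transcript_raises(frag_builder):
    frags = frag_builder([("s1", "tx", 10, 20)], L)
    with pytest.raises(KeyError):
        profiles.coverage_fraction(frags, "nope", "s1")


class TestLfcCoverage:
    def _profiles(self, frag_builder, recs_a, recs_b):
        fa = frag_builder(recs_a, L)
        fb = frag_builder(recs_b, L)
        return (
            [profiles.coverage_fraction(fa, "tx", "s1")],
            [profiles.coverage_fraction(fb, "tx", "s1")],
        )

    def test_identical_groups_all_zero(self, frag_builder):
        recs = [("s1", "tx", 10, 40), ("s1", "tx", 50, 90)]
        a, b = self._profiles(frag_builder, recs, recs)
        lfc = profiles.lfc_coverage(a, b)
        np.testing.assert_allclose(lfc.values, 0.0)
        lfc2 = profiles.lfc_coverage(a, b, epsilon=2e-6)
        np.testing.assert_allclose(lfc2.values, 0.0)

    def test_antisymmetry_under_group_swap(self, frag_builder):
        a, b = self._profiles(
            frag_builder, [("s1", "tx", 10, 40)], [("s1", "tx", 30, 90)]
        )
        fwd = profiles.lfc_coverage(a, b).values
        rev = profiles.lfc_coverage(b, a).values
        np.testing.assert_array_equal(fwd, -rev)

    def test_mismatched_transcripts_rejected(self, frag_builder):
        fa = frag_builder([("s1", "tx", 10, 40)], L)
        fb = frag_builder([("s1", "t2", 10, 40)], {"t2": 100})
        with pytest.raises(InputError):
            profiles.lfc_coverage(
                [profiles.coverage_fraction(fa, "tx", "s1")],
                [profiles.coverage_fraction(fb, "t2", "s1")],
            )

    def test_cleavage_sign_pattern(self, small_model, crrna, design_1tp):
        """5' depletion and 3' enrichment around the cut, the hallmark of
        polyA-selected libraries after cleavage."""
        frags = simulate.simulate_fragments(
            small_model, crrna, CleavageModel(cut_prob=0.8, five_prime_survival=0.0),
            design_1tp, depth=50_000, seed=13,
        )
        inj = [s.sample_id for s in design_1tp.samples if s.condition == "injected"]
        mock = [s.sample_id for s in design_1tp.samples if s.condition == "mock"]
        lfc = profiles.lfc_coverage(
            [profiles.coverage_fraction(frags, "target", s) for s in inj],
            [profiles.coverage_fraction(frags, "target", s) for s in mock],
        )
        assert lfc.values[:300].mean() < 0
        assert lfc.values[300:].mean() > 0


class TestEndDistribution:
    def test_both_ends_hand_case(self, frag_builder):
        frags = frag_builder([("s1", "tx", 10, 20)], L)
        prof = profiles.end_distribution(frags, "tx", "s1", "both", normalized=False)
        assert prof.values[10] == 1 and prof.values[19] == 1
        assert prof.values.sum() == 2

    def test_length_one_fragment_contributes_two_ends(self, frag_builder):
        frags = frag_builder([("s1", "tx", 5, 6)], L)
        prof = profiles.end_distribution(frags, "tx", "s1", "both", normalized=False)
        assert prof.values[5] == 2

    def test_normalized_sums_to_one(self, frag_builder):
        frags = frag_builder([("s1", "tx", 10, 20), ("s1", "tx", 30, 60)], L)
        for which in ("five_prime", "three_prime", "both"):
            prof = profiles.end_distribution(frags, "tx", "s1", which, normalized=True)
            assert prof.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_five_prime_spike_at_cut(self, small_model, crrna, design_1tp):
        """With no surviving 5' fragments, every 3'-fragment template starts at
        the cut, so treated five-prime ends spike exactly there."""
        frags = simulate.simulate_fragments(
            small_model, crrna, CleavageModel(cut_prob=0.9, five_prime_survival=0.0),
            design_1tp, depth=100_000, seed=17,
        )
        prof = profiles.end_distribution(frags, "target", "injected_b1_t1", "five_prime")
        interior = prof.values[1:-1]
        assert np.argmax(interior) + 1 == 300


class TestDiffEnds:
    def _ends(self, frag_builder, recs, samples):
        frags = frag_builder(recs, L)
        return [profiles.end_distribution(frags, "tx", s) for s in samples]

    def test_identical_groups_zero_with_cis_containing_zero(self, frag_builder):
        recs = [(s, "tx", 10, 40) for s in ("a", "b")] + [(s, "tx", 50, 70) for s in ("a", "b")]
        recs += [(s, "tx", 10, 40) for s in ("c", "d")] + [(s, "tx", 50, 70) for s in ("c", "d")]
        inj = self._ends(frag_builder, recs, ["a", "b"])
        mock = self._ends(frag_builder, recs, ["c", "d"])
        diff = profiles.diff_ends(inj, mock)
        np.testing.assert_allclose(diff.mean_diff, 0.0)
        assert (diff.ci_low <= 0).all() and (diff.ci_high >= 0).all()

    def test_normalized_diff_sums_to_zero(self, small_model, crrna, design_1tp, cleaved_frags):
        inj = [s.sample_id for s in design_1tp.samples if s.condition == "injected"]
        mock = [s.sample_id for s in design_1tp.samples if s.condition == "mock"]
        diff = profiles.diff_ends(
            [profiles.end_distribution(cleaved_frags, "target", s) for s in inj],
            [profiles.end_distribution(cleaved_frags, "target", s) for s in mock],
        )
        assert abs(diff.mean_diff.sum()) < 1e-9
        assert (diff.ci_low <= diff.mean_diff + 1e-12).all()
        assert (diff.mean_diff <= diff.ci_high + 1e-12).all()

    def test_mixed_normalization_rejected(self, frag_builder):
        recs = [(s, "tx", 10, 40) for s in ("a", "b", "c", "d")]
        frags = frag_builder(recs, L)
        inj = [profiles.end_distribution(frags, "tx", s, normalized=True) for s in ("a", "b")]
        mock = [profiles.end_distribution(frags, "tx", s, normalized=False) for s in ("c", "d")]
        with pytest.raises(InputError):
            profiles.diff_ends(inj, mock)

    def test_null_ci_coverage_per_position(self, small_model, crrna, design_1tp):
        """Under a no-effect simulation the per-position 95% t-intervals
        contain 0 at >= 90% of positions on average (3 vs 3)."""
        fracs = []
        for seed in range(5):
            frags = simulate.simulate_fragments(
                small_model, crrna, CleavageModel(cut_prob=0.0), design_1tp,
                depth=30_000, seed=600 + seed,
            )
            inj = [s.sample_id for s in design_1tp.samples if s.condition == "injected"]
            mock = [s.sample_id for s in design_1tp.samples if s.condition == "mock"]
            diff = profiles.diff_ends(
                [profiles.end_distribution(frags, "target", s) for s in inj],
                [profiles.end_distribution(frags, "target", s) for s in mock],
            )
            fracs.append(((diff.ci_low <= 0) & (0 <= diff.ci_high)).mean())
        assert np.mean(fracs) >= 0.90

    def test_bootstrap_ci_brackets_mean(self, cleaved_frags, design_1tp):
        inj = [s.sample_id for s in design_1tp.samples if s.condition == "injected"]
        mock = [s.sample_id for s in design_1tp.samples if s.condition == "mock"]
        diff = profiles.diff_ends(
            [profiles.end_distribution(cleaved_frags, "target", s) for s in inj],
            [profiles.end_distribution(cleaved_frags, "target", s) for s in mock],
            ci_method="bootstrap", n_boot=200, seed=1,
        )
        assert (diff.ci_low <= diff.mean_diff).all() and (diff.mean_diff <= diff.ci_high).all()


class TestPeakCall:
    def _diff(self, values):
        v = np.asarray(values, dtype=float)
        return profiles.DiffEndsProfile("tx", v, v, v, 3, 3, True)

    def test_all_zero_no_call(self):
        assert profiles.call_cleavage_peak(self._diff(np.zeros(50))) is None

    def test_single_nonzero_position_is_argmax(self):
        v = np.zeros(50)
        v[17] = 0.5
        peak = profiles.call_cleavage_peak(self._diff(v), min_z=4.0)
        assert peak is not None and peak.position == 17

    def test_tie_breaks_to_lowest_coordinate(self):
        v = np.zeros(50)
        v[[20, 30]] = 0.5
        peak = profiles.call_cleavage_peak(self._diff(v), min_z=0.0)
        assert peak.position == 20

    def test_protospacer_annotation(self, crrna, cleaved_frags, design_1tp):
        inj = [s.sample_id for s in design_1tp.samples if s.condition == "injected"]
        mock = [s.sample_id for s in design_1tp.samples if s.condition == "mock"]
        diff = profiles.diff_ends(
            [profiles.end_distribution(cleaved_frags, "target", s) for s in inj],
            [profiles.end_distribution(cleaved_frags, "target", s) for s in mock],
        )
        peak = profiles.call_cleavage_peak(diff, crrna, min_z=4.0)
        assert peak is not None
        assert abs(peak.position - 300) <= 2
        assert peak.within_protospacer


class TestStaggerScan:
    def _sim_diff(self, small_model, crrna, design, offsets, seed=19):
        frags = simulate.simulate_fragments(
            small_model, crrna, CleavageModel(cut_prob=0.8, cut_offsets=offsets),
            design, depth=100_000, seed=seed,
        )
        inj = [s.sample_id for s in design.samples if s.condition == "injected"]
        mock = [s.sample_id for s in design.samples if s.condition == "mock"]
        return profiles.diff_ends(
            [profiles.end_distribution(frags, "target", s) for s in inj],
            [profiles.end_distribution(frags, "target", s) for s in mock],
        )

    def test_single_cut_gives_no_evidence(self, small_model, crrna, design_1tp):
        diff = self._sim_diff(small_model, crrna, design_1tp, (0,))
        res = profiles.stagger_scan(diff, 300)
        assert res.verdict == "no-evidence"
        assert 0 in res.offsets

    def test_staggered_cuts_give_evidence(self, small_model, crrna, design_1tp):
        diff = self._sim_diff(small_model, crrna, design_1tp, (0, 6, 12))
        res = profiles.stagger_scan(diff, 300)
        assert res.verdict == "evidence"

    def test_zero_offsets_scores_anchor_only(self, small_model, crrna, design_1tp):
        diff = self._sim_diff(small_model, crrna, design_1tp, (0,))
        res = profiles.stagger_scan(diff, 300, n_offsets=0)
        assert res.offsets == [0]
        assert res.verdict == "no-evidence"

    def test_out_of_range_offsets_skipped(self, small_model, crrna, design_1tp):
        diff = self._sim_diff(small_model, crrna, design_1tp, (0,))
        res = profiles.stagger_scan(diff, 5, n_offsets=3)
        assert res.n_skipped > 0


class TestPersistence:
    def _frags_with_rates(self, small_model, crrna, rates, seed=23):
        design = simulate.make_design(n_batches=3, timepoints=list(rates))
        frags = simulate.simulate_fragments(small_model, crrna, None, design, depth=50_000, seed=seed)
        per_sample = {s.sample_id: rates[s.timepoint] for s in design.samples}
        frags = simulate.spike_crrna_contamination(frags, crrna, per_sample, seed=seed)
        from csmkd.types import FragmentSet

        return {
            tp: FragmentSet(
                frags.df[frags.df.sample_id.isin(design.subset(timepoint=tp).sample_ids)],
                frags.transcript_lengths,
            )
            for tp in rates
        }

    def test_equal_rates_ratio_one(self, small_model, crrna):
        by_tp = self._frags_with_rates(small_model, crrna, {"t1": 0.02, "t2": 0.02})
        res = profiles.crrna_persistence(by_tp, crrna)
        assert res.ratio == pytest.approx(1.0, rel=0.05)

    def test_decay_recovered(self, small_model, crrna):
        by_tp = self._frags_with_rates(small_model, crrna, {"t1": 0.03, "t2": 0.012})
        res = profiles.crrna_persistence(by_tp, crrna)
        assert res.ratio == pytest.approx(2.5, rel=0.1)

    def test_no_antisense_at_last_timepoint_flagged(self, small_model, crrna):
        by_tp = self._frags_with_rates(small_model, crrna, {"t1": 0.03, "t2": 0.0})
        res = profiles.crrna_persistence(by_tp, crrna)
        assert not res.defined
        assert np.isnan(res.ratio)


@given(st.lists(st.tuples(st.integers(0, 90), st.integers(1, 10)), min_size=1, max_size=30))
def test_coverage_and_end_normalisation_property(intervals):
    """Any non-empty fragment list yields unit-sum coverage fractions and
    normalised end profiles."""
    import pandas as pd

    from csmkd.types import FragmentSet

    df = pd.DataFrame(
        [("s", "tx", a, a + w, "sense", "sim") for a, w in intervals],
        columns=["sample_id", "transcript_id", "start", "end", "strand", "flag"],
    )
    frags = FragmentSet(df, {"tx": 100})
    cov = profiles.coverage_fraction(frags, "tx", "s")
    assert abs(cov.values.sum() - 1.0) < 1e-9
    ends = profiles.end_distribution(frags, "tx", "s", "both", normalized=True)
    assert abs(ends.values.sum() - 1.0) < 1e-9
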