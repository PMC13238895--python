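import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cnvassay as ca
from cnvassay.callers import CallerResult
from cnvassay.consensus import _direction_consensus, segments_to_frame


def toy_results(genome, state_rows):
    """Build one CallerResult per row of per-bin states."""
    return [
        CallerResult(caller=f"c{i}", states=np.asarray(row),
                     confidence=np.ones(len(row)), genome=genome)
        for i, row in enumerate(state_rows)
    ]


def oracle_consensus(states, baseline=2, min_support=2):
    """Independent restatement of the documented decision rule."""
    gains = sorted(s for s in states if s > baseline)
    losses = sorted(s for s in states if s < baseline)
    if len(gains) >= min_support and len(gains) > len(losses):
        side = gains
    elif len(losses) >= min_support and len(losses) > len(gains):
        side = losses
    else:
        return baseline
    best, best_key = None, None
    for s in set(side):
        key = (-side.count(s), abs(s - baseline), s)
        if best_key is None or key < best_key:
            best, best_key = s, key
    return best


class TestConsensusRule:
    @pytest.mark.parametrize("states,expected,support", [
        ((3, 3, 2), 3, 2),   # two gains agree
        ((3, 1, 2), 2, 1),   # one gain vs one loss: no directional agreement
        ((4, 3, 3), 3, 3),   # modal aberrant state among agreeing callers
        ((4, 4, 3), 4, 3),
        ((1, 1, 3), 1, 2),
        ((2, 2, 2), 2, 0),
    ])
    def test_documented_examples(self, states, expected, support):
        s, sup = _direction_consensus(np.array(states), baseline=2, min_support=2)
        assert (s, sup) == (expected, support)

    def test_brute_force_decision_table(self):
        """All 6^3 caller-state triples match the independent oracle, and no
        bin with < 2 agreeing callers is ever aberrant."""
        for triple in itertools.product(range(6), repeat=3):
            got, support = _direction_consensus(np.array(triple), 2, 2)
            assert got == oracle_consensus(triple), triple
            if got != 2:
                assert support >= 2

    def test_unanimity_when_min_support_equals_caller_count(self, flat_gc_genome):
        g = flat_gc_genome
        n = g.n_bins
        rows = [np.full(n, 2), np.full(n, 2), np.full(n, 2)]
        rows[0][:10] = 3
        rows[1][:10] = 3
        rows[2][:5] = 3
        cons = ca.consensus_calls(toy_results(g, rows), min_support=3)
        assert (cons.states[:5] == 3).all()
        assert (cons.states[5:] == 2).all()

    def test_identical_callers_reproduce_input(self, flat_gc_genome):
        g = flat_gc_genome
        rng = np.random.default_rng(0)
        row = rng.integers(0, 6, g.n_bins)
        cons = ca.consensus_calls(toy_results(g, [row, row, row]))
        assert np.array_equal(cons.states, row)

    def test_fewer_than_two_callers_rejected(self, flat_gc_genome):
        with pytest.raises(ValueError):
            ca.consensus_calls(toy_results(flat_gc_genome,
                                           [np.full(flat_gc_genome.n_bins, 2)]))

    def test_mismatched_backbones_rejected(self, flat_gc_genome, toy):
        a = toy_results(flat_gc_genome, [np.full(flat_gc_genome.n_bins, 2)])[0]
        b = toy_results(toy, [np.full(toy.n_bins, 2)])[0]
        with pytest.raises(ValueError):
            ca.consensus_calls([a, b])


class TestSegmentation:
    def test_all_baseline_gives_empty_cnv_list(self, flat_gc_genome):
        prof = ca.make_karyotype_profile(flat_gc_genome, ca.KaryotypeSpec(()))
        assert ca.segment_profile(prof) == []

    def test_simple_run(self):
        g = ca.make_genome({"chr1": 2_000_000}, bin_width=500_000)
        prof = ca.CopyNumberProfile(np.array([2, 3, 3, 2]), g)
        segs = ca.segment_profile(prof)
        assert len(segs) == 1
        (seg,) = segs
        assert (seg.start, seg.end, seg.state, seg.n_bins) == (500_000, 1_500_000, 3, 2)

    def test_cell_line_fixture_round_trip(self, grch38, cell_line_truth):
        """Noise-free segmentation reproduces the fixture's region list."""
        segs = ca.segment_profile(cell_line_truth)
        by_region = {("chr19q", 3), ("chr5", 3), ("chr11p", 3), ("chr15q", 3),
                     ("chr20p", 3), ("chr1p", 1), ("chr2q", 1), ("chr4", 1),
                     ("chr6", 1), ("chr9q", 1), ("chr13", 1), ("chr11q", 1),
                     ("chr21", 1), ("chr22", 1)}
        assert len(segs) == len(by_region)
        for region, state in by_region:
            mask = grch38.region_mask(region)
            idx = np.flatnonzero(mask)
            lo = int(grch38.bins["start"].iloc[idx[0]])
            hi = int(grch38.bins["end"].iloc[idx[-1]])
            assert any(s.chrom == grch38.bins["chrom"].iloc[idx[0]]
                       and (s.start, s.end, s.state) == (lo, hi, state)
                       for s in segs), region

    def test_expand_then_segment_is_identity(self, toy):
        rng = np.random.default_rng(3)
        states = np.repeat(rng.integers(0, 6, 20), 47)[: toy.n_bins]
        states = np.resize(states, toy.n_bins)
        prof = ca.CopyNumberProfile(states, toy)
        segs = ca.segment_profile(prof, include_baseline=True)
        rebuilt = np.empty(toy.n_bins, dtype=int)
        for seg in segs:
            mask = ((toy.bins["chrom"] == seg.chrom)
                    & (toy.bins["start"] >= seg.start)
                    & (toy.bins["end"] <= seg.end)).to_numpy()
            rebuilt[mask] = seg.state
            assert mask.sum() == seg.n_bins
        assert np.array_equal(rebuilt, states)


class TestIsvClassification:
    @pytest.mark.parametrize("score,expected", [
        (0.02, "benign"), (0.50, "uncertain"), (0.95, "pathogenic"),
        (0.05, "uncertain"), (0.0, "benign"), (1.0, "pathogenic"),
    ])
    def test_thresholds(self, score, expected):
        assert ca.classify_isv(score) == expected

    @pytest.mark.parametrize("score", [-0.1, 1.1])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            ca.classify_isv(score)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_score(self, a, b):
        rank = {"benign": 0, "uncertain": 1, "pathogenic": 2}
        lo, hi = sorted((a, b))
        assert rank[ca.classify_isv(lo)] <= rank[ca.classify_isv(hi)]

    def test_classify_segments_with_stub_scores(self):
        seg_big = ca.CNVSegment("chr1", 0, 60_000_000, state=1, n_bins=120)
        seg_small = ca.CNVSegment("chr1", 0, 1_000_000, state=3, n_bins=2)
        out = ca.classify_segments([seg_big, seg_small])
        assert out[0].classification == "pathogenic"  # 60 Mb loss saturates
        assert out[1].classification == "benign"


class TestVariantFilter:
    @pytest.mark.parametrize("impact,tools,kept", [
        ("MODERATE", {}, True),
        ("HIGH", {}, True),
        ("LOW", {"eve": "likely_pathogenic"}, True),
        ("LOW", {"eve": "benign"}, False),
        ("MODIFIER", {}, False),
        ("MODIFIER", {"cadd": "Pathogenic"}, True),
    ])
    def test_retention_rule(self, impact, tools, kept):
        v = ca.AnnotatedVariant(gene="G", impact=impact, tool_calls=tools)
        assert ([v] == ca.filter_variants([v])) is kept

    def test_unknown_impact_rejected(self):
        with pytest.raises(ValueError, match="unknown impact"):
            ca.AnnotatedVariant(gene="G", impact="SEVERE")


def _consensus_from_states(genome, states):
    states = np.asarray(states, dtype=int)
    support = np.where(states != 2, 3, 0)
    from cnvassay.consensus import ConsensusProfile

    return ConsensusProfile(states=states, support=support, genome=genome,
                            callers=("x",))


class TestProfileDiff:
    def test_identical_profiles_zero_differences(self, toy):
        rng = np.random.default_rng(1)
        states = rng.integers(1, 4, toy.n_bins)
        a = _consensus_from_states(toy, states)
        d = ca.compare_profiles(a, a)
        assert d.bins["a_only"] == d.bins["b_only"] == d.bins["shared_diff"] == 0
        assert d.normalized_bins == 0

    def test_normalized_bins_count_chr_loss(self, grch38):
        states_a = np.full(grch38.n_bins, 2)
        states_a[grch38.region_mask("chr4")] = 1
        a = _consensus_from_states(grch38, states_a)
        b = _consensus_from_states(grch38, np.full(grch38.n_bins, 2))
        d = ca.compare_profiles(a, b)
        assert d.normalized_bins == int(grch38.region_mask("chr4").sum())
        assert d.bins["b_only"] == 0

    def test_tumor_vs_cell_line_fixture_hand_oracle(self, grch38, cell_line_truth):
        """Diff of the two packaged karyotypes matches per-bin enumeration of
        the two region lists, computed independently from the masks."""
        tumor = ca.make_karyotype_profile(grch38, ca.TUMOR_KARYOTYPE)
        a = _consensus_from_states(grch38, tumor.states)
        b = _consensus_from_states(grch38, cell_line_truth.states)
        d = ca.compare_profiles(a, b)
        ab_a = tumor.states != 2
        ab_b = cell_line_truth.states != 2
        assert d.bins["a_only"] == int((ab_a & ~ab_b).sum())
        assert d.bins["b_only"] == int((~ab_a & ab_b).sum())
        assert d.bins["shared_equal"] == int(
            (ab_a & ab_b & (tumor.states == cell_line_truth.states)).sum())
        assert d.bins["shared_diff"] == int(
            (ab_a & ab_b & (tumor.states != cell_line_truth.states)).sum())
        # sanity on the specific fixtures: 15q is lost in the tumor but gained
        # in the cell line, so shared_diff covers at least 15q
        assert d.bins["shared_diff"] >= int(grch38.region_mask("chr15q").sum())

    def test_mismatched_backbones_rejected(self, toy, grch38):
        a = _consensus_from_states(toy, np.full(toy.n_bins, 2))
        b = _consensus_from_states(grch38, np.full(grch38.n_bins, 2))
        with pytest.raises(ValueError):
            ca.compare_profiles(a, b)


class TestAberrantFraction:
    def test_all_baseline_zero(self, toy):
        prof = ca.make_karyotype_profile(toy, ca.KaryotypeSpec(()))
        assert ca.aberrant_fraction(prof) == 0.0

    def test_half_by_length(self):
        g = ca.make_genome({"chr1": 2_000_000}, bin_width=500_000)
        prof = ca.CopyNumberProfile(np.array([3, 3, 2, 2]), g)
        assert ca.aberrant_fraction(prof) == 0.5

    def test_tumor_fixture_on_grch38_arms(self, grch38):
        """Deterministic value for the published tumor karyotype: ~60% of the
        autosomal genome aberrant, the published figure being an approximate
        'nearly half'."""
        prof = ca.make_karyotype_profile(grch38, ca.TUMOR_KARYOTYPE)
        assert ca.aberrant_fraction(prof) == pytest.approx(0.6056, abs=0.002)
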