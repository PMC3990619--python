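import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import barcodekit as bk
from barcodekit.distances import (
    PairwiseComparison,
    SaturationError,
    UndefinedComparisonError,
    count_substitutions,
    distance_matrix,
    divergence_time,
    genus_summaries,
    k2p,
    mean_intraspecific_divergence,
    species_summaries,
    summaries_to_frame,
)
from barcodekit.io_qc import SequenceRecord, SpecimenMetadata
from conftest import make_matrix


def k2p_oracle(P, Q):
    """Independent high-precision evaluation of the two-parameter formula."""
    from mpmath import mp, mpf

    mp.dps = 40
    P, Q = mpf(P), mpf(Q)
    return float(-mp.log(1 - 2 * P - Q) / 2 - mp.log(1 - 2 * Q) / 4)


class TestCountSubstitutions:
    def test_identical(self):
        pc = count_substitutions(SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT"))
        assert (pc.P, pc.Q, pc.overlap_bp) == (0.0, 0.0, 4)

    def test_transition(self):
        pc = count_substitutions(SequenceRecord("a", "ACGT"), SequenceRecord("b", "GCGT"))
        assert (pc.P, pc.Q) == (0.25, 0.0)

    def test_transversion(self):
        pc = count_substitutions(SequenceRecord("a", "ACGT"), SequenceRecord("b", "CCGT"))
        assert (pc.P, pc.Q) == (0.0, 0.25)

    def test_pairwise_deletion_excludes_gaps_and_ambiguity(self):
        pc = count_substitutions(
            SequenceRecord("a", "AC-TN"), SequenceRecord("b", "ACGTA")
        )
        assert pc.overlap_bp == 3  # positions 1, 2, 4 only

    def test_no_overlap_is_undefined(self):
        with pytest.raises(UndefinedComparisonError):
            count_substitutions(SequenceRecord("a", "NN--"), SequenceRecord("b", "ACGT"))


class TestK2P:
    def test_zero(self):
        assert k2p(PairwiseComparison("a", "b", 10, 0.0, 0.0)) == 0.0

    @pytest.mark.parametrize(
        "P,Q,expected",
        [(0.1, 0.0, 0.111572), (0.05, 0.05, 0.107600)],
    )
    def test_frozen_values(self, P, Q, expected):
        assert k2p(PairwiseComparison("a", "b", 100, P, Q)) == pytest.approx(
            expected, abs=5e-7
        )

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p(PairwiseComparison("a", "b", 100, 0.5, 0.3))

    def test_oracle_equivalence_on_random_pairs(self, rng):
        """1,000 random admissible (P, Q) pairs match a 40-digit
        independent evaluation to < 1e-12."""
        worst = 0.0
        n = 0
        while n < 1000:
            P, Q = rng.uniform(0, 0.5, 2)
            if 1 - 2 * P - Q <= 1e-6 or 1 - 2 * Q <= 1e-6:
                continue
            n += 1
            d = k2p(PairwiseComparison("a", "b", 100, P, Q))
            worst = max(worst, abs(d - k2p_oracle(P, Q)))
        assert worst < 1e-12

    def test_dominates_p_distance_and_jc_like_behaviour(self, rng):
        for _ in range(200):
            Q = rng.uniform(0.001, 0.4)
            P = Q / 2  # equal-rate regime
            if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
                continue
            d = k2p(PairwiseComparison("a", "b", 100, P, Q))
            assert d >= P + Q - 1e-12


class TestDistanceMatrix:
    def test_identical_sequences_zero(self, stop_free_seq):
        recs = [SequenceRecord(f"s{i}", stop_free_seq) for i in range(3)]
        m = distance_matrix(recs)
        assert np.allclose(m.d, 0.0) and m.defined.all()

    def test_symmetry_on_synthetic(self, clean_dataset):
        _, ds = clean_dataset
        recs = [r for r in ds.records if r.length_bp == 648][:30]
        m = distance_matrix(recs)
        assert np.allclose(m.d[m.defined], m.d.T[m.defined.T])
        assert np.allclose(np.diag(m.d), 0.0)

    def test_low_overlap_pair_masked(self, stop_free_seq):
        a = SequenceRecord("a", stop_free_seq)
        half = len(stop_free_seq) // 2
        b = SequenceRecord("b", stop_free_seq[:half] + "N" * (len(stop_free_seq) - half))
        c = SequenceRecord("c", stop_free_seq)
        m = distance_matrix([a, b, c], min_overlap_frac=0.60)
        # b overlaps only ~50% of its own non-gap length with a
        assert not m.defined[0, 1]
        assert m.defined[0, 2]

    def test_fewer_than_two_records_rejected(self, stop_free_seq):
        with pytest.raises(ValueError):
            distance_matrix([SequenceRecord("a", stop_free_seq)])


class TestEstimatorRecovery:
    @pytest.mark.parametrize("d_true", [0.02, 0.05, 0.10])
    def test_k2p_unbiased_under_generating_model(self, d_true):
        """Mean K2P estimate over 1,000 simulated pairs falls within 3
        Monte-Carlo standard errors of the generating distance."""
        pairs = bk.simulate_pair(d_true, kappa=3.0, L=648, n_reps=1000, seed=42)
        ests = [k2p(count_substitutions(a, b)) for a, b in pairs]
        mean, se = np.mean(ests), np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(mean - d_true) < 3 * se

    def test_raw_differences_at_two_percent(self):
        """At d = 0.02 and L = 648 the expected raw difference count is
        about 13 bp, the working threshold for OTU recognition."""
        pairs = bk.simulate_pair(0.02, kappa=3.0, L=648, n_reps=500, seed=7)
        diffs = [
            sum(1 for x, y in zip(a.nucleotides, b.nucleotides) if x != y)
            for a, b in pairs
        ]
        assert np.mean(diffs) == pytest.approx(0.02 * 648, rel=0.08)


def _meta(species_by_id, genus_by_species=None, known=None):
    out = []
    for sid, sp in species_by_id.items():
        genus = (genus_by_species or {}).get(sp, "G1")
        out.append(
            SpecimenMetadata(
                seq_id=sid, taxon_class="C", taxon_order="O", family="F",
                genus=genus, species_label=sp, locality="loc",
                known_species_in_genus=(known or {}).get(genus),
            )
        )
    return out


class TestSpeciesSummaries:
    def test_two_member_species_with_gap(self):
        m = make_matrix(
            ["a1", "a2", "b1"],
            [[0, 0.004, 0.05], [0.004, 0, 0.05], [0.05, 0.05, 0]],
        )
        meta = _meta({"a1": "A", "a2": "A", "b1": "B"})
        s = {x.species_label: x for x in species_summaries(m, meta)}
        assert s["A"].max_intra == pytest.approx(0.4)
        assert s["A"].nn_distance == pytest.approx(5.0)
        assert s["A"].barcode_gap == "present"

    def test_singleton_reported_with_hyphen(self):
        m = make_matrix(["a1", "b1"], [[0, 0.05], [0.05, 0]])
        meta = _meta({"a1": "A", "b1": "B"})
        s = {x.species_label: x for x in species_summaries(m, meta)}
        assert s["A"].max_intra is None
        assert s["A"].barcode_gap == "not_assessable"
        frame = summaries_to_frame(list(s.values()))
        assert (frame.loc[frame.species == "A", "max_intra_pct"] == "-").all()

    def test_tie_counts_as_gap_absent(self):
        m = make_matrix(
            ["a1", "a2", "b1"],
            [[0, 0.03, 0.03], [0.03, 0, 0.03], [0.03, 0.03, 0]],
        )
        meta = _meta({"a1": "A", "a2": "A", "b1": "B"})
        s = {x.species_label: x for x in species_summaries(m, meta)}
        assert s["A"].barcode_gap == "absent"

    def test_nn_matches_brute_force(self, clean_dataset):
        _, ds = clean_dataset
        recs = [r for r in ds.records if r.length_bp == 648]
        m = distance_matrix(recs)
        summaries = species_summaries(m, ds.meta)
        species_of = {mm.seq_id: mm.species_label for mm in ds.meta}
        for s in summaries:
            best = math.inf
            for i, a in enumerate(m.ids):
                for j, b in enumerate(m.ids):
                    if (
                        species_of[a] == s.species_label
                        and species_of[b] != s.species_label
                        and m.defined[i, j]
                    ):
                        best = min(best, m.d[i, j])
            if s.nn_distance is not None:
                assert s.nn_distance == pytest.approx(100 * best, abs=1e-9)

    def test_mean_intraspecific_study_level(self):
        m = make_matrix(
            ["a1", "a2", "b1", "b2"],
            [
                [0, 0.004, 0.08, 0.08],
                [0.004, 0, 0.08, 0.08],
                [0.08, 0.08, 0, 0.030],
                [0.08, 0.08, 0.030, 0],
            ],
        )
        meta = _meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        s = species_summaries(m, meta)
        assert mean_intraspecific_divergence(s) == pytest.approx((0.4 + 3.0) / 2)
        assert mean_intraspecific_divergence(s, exclude_above_pct=2.0) == pytest.approx(0.4)


class TestGenusSummaries:
    def test_mean_nn_and_completeness(self):
        m = make_matrix(
            ["a1", "b1", "c1"],
            [[0, 0.02, 0.10], [0.02, 0, 0.10], [0.10, 0.10, 0]],
        )
        meta = _meta(
            {"a1": "A", "b1": "B", "c1": "C"},
            genus_by_species={"A": "G1", "B": "G1", "C": "G2"},
            known={"G1": 4},
        )
        s = species_summaries(m, meta)
        g = {x.genus: x for x in genus_summaries(s, meta)}
        assert g["G1"].mean_nn_distance == pytest.approx(2.0)
        assert g["G1"].completeness_pct == pytest.approx(50.0)
        assert g["G2"].completeness_pct is None


class TestDivergenceTime:
    @pytest.mark.parametrize("d,expected", [(2.0, 1.0), (5.9, 2.95), (0.0, 0.0)])
    def test_pairwise_rate_conversion(self, d, expected):
        assert divergence_time(d) == pytest.approx(expected)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(2.0, 0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_matrix_symmetry_property(seed):
    """Distance matrices from random two-parameter evolution are symmetric
    with a zero diagonal and non-negative defined cells."""
    rng = np.random.default_rng(seed)
    from barcodekit.simulate import draw_root_sequence, evolve_sequence

    root = draw_root_sequence(0.4, 80, rng)
    recs = [
        SequenceRecord(f"s{i}", evolve_sequence(root, rng.uniform(0, 0.15), 2.0, rng))
        for i in range(5)
    ]
    m = distance_matrix(recs)
    assert np.allclose(m.d[m.defined], m.d.T[m.defined.T])
    assert (m.d[m.defined] >= 0).all()
    assert np.allclose(np.diag(m.d), 0)
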