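"""Fingerprint segments, concatenation and Jaccard distances."""

import numpy as np
import pytest

from aarsfp.core import EditingTable, InteractionType as IT
from aarsfp.fingerprints import (
    Fingerprint,
    SEGMENT_WIDTHS,
    build_fingerprint,
    distance_matrix,
    fp_concat,
    fp_editing,
    fp_int,
    fp_seq,
    fp_volume,
    hash_collision_diagnostic,
    jaccard_distance,
)

from conftest import make_complex, make_record


def fingerprint_from_active(active, variant="Seq+Int"):
    width = sum(SEGMENT_WIDTHS[s] for s in
                {"Seq_sim": ("seq",), "Seq+Int": ("int",),
                 "Seq+Int+Ed": ("int", "editing"),
                 "Seq+Int+Ed+Vol": ("int", "editing", "volume"),
                 "Ed": ("editing",), "Vol": ("volume",)}[variant])
    bits = np.zeros(width, dtype=bool)
    bits[list(active)] = True
    return Fingerprint(bits, variant)


class TestSeqSegment:
    def test_duplicate_residues_one_bit(self):
        c = make_complex(records=[
            make_record(residue="ARG", number=1, atoms=("N",)),
            make_record(residue="ARG", number=2, atoms=("O",)),
            make_record(residue="TYR", number=3, atoms=("N",)),
        ])
        assert fp_seq(c).sum() == 2

    def test_no_interactions_all_zero(self):
        assert fp_seq(make_complex()).sum() == 0

    def test_all_twenty_types(self):
        from aarsfp.core import STANDARD_RESIDUES

        recs = [make_record(residue=res, number=i, atoms=("N",))
                for i, res in enumerate(STANDARD_RESIDUES)]
        assert fp_seq(make_complex(records=recs)).sum() == 20

    def test_unk_and_metal_set_no_bit(self):
        c = make_complex(records=[
            make_record(residue="XYZ", atoms=("N",)),
            make_record(itype=IT.METAL_COMPLEX, residue="ZN", atoms=("O",)),
        ])
        assert fp_seq(c).sum() == 0


class TestIntSegment:
    def test_single_feature_single_bit(self):
        c = make_complex(records=[make_record(residue="TYR", atoms=("O",))])
        bits = fp_int(c)
        assert bits.sum() == 1
        assert 0 <= int(np.flatnonzero(bits)[0]) < 500

    def test_duplicate_features_idempotent(self):
        c1 = make_complex(records=[make_record(residue="TYR", atoms=("O",))])
        c2 = make_complex(records=[
            make_record(residue="TYR", atoms=("O",)),
            make_record(residue="TYR", number=999, atoms=("O",)),
        ])
        assert np.array_equal(fp_int(c1), fp_int(c2))

    def test_record_order_invariant(self):
        recs = [
            make_record(residue="TYR", atoms=("O",)),
            make_record(itype=IT.HYDROPHOBIC, residue="VAL", atoms=("CB",)),
        ]
        a = fp_int(make_complex(records=recs))
        b = fp_int(make_complex(records=recs[::-1]))
        assert np.array_equal(a, b)

    def test_distinct_features_two_bits(self):
        c = make_complex(records=[
            make_record(residue="TYR", atoms=("O",)),
            make_record(itype=IT.HYDROPHOBIC, residue="VAL", atoms=("CB",)),
        ])
        assert fp_int(c).sum() == 2

    def test_collision_rate_diagnostic(self):
        diag = hash_collision_diagnostic()
        assert diag["pair_collision_rate"] < 0.10


class TestEditingSegment:
    def test_thrrs_serine_bit(self):
        from aarsfp.core import LIGAND_CODES

        table = EditingTable({"ThrRS": frozenset({"Ser"})})
        bits = fp_editing("ThrRS", table)
        assert bits.sum() == 1
        assert bits[LIGAND_CODES.index("Ser")]

    def test_absent_aars_all_zero(self):
        assert fp_editing("GlyRS", EditingTable({})).sum() == 0

    def test_three_targets_three_bits(self):
        table = EditingTable({"LeuRS": frozenset({"Ile", "Met", "Val"})})
        assert fp_editing("LeuRS", table).sum() == 3


class TestVolumeSegment:
    @pytest.mark.parametrize("volume,bin_index", [
        (45.0, 1), (52.0, 2), (300.0, 12), (10.0, 1), (269.99, 12), (50.0, 2),
    ])
    def test_binning(self, volume, bin_index):
        bits = fp_volume(volume)
        assert bits.sum() == 1
        assert int(np.flatnonzero(bits)[0]) + 1 == bin_index

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            fp_volume(0.0)

    def test_one_hot_and_adjacent_over_grid(self):
        previous = 0
        for v in np.arange(1.0, 320.0, 0.5):
            bits = fp_volume(float(v))
            assert bits.sum() == 1
            k = int(np.flatnonzero(bits)[0]) + 1
            assert k >= previous  # bins are monotone in volume
            assert k - previous <= 1  # and adjacent (half-open edges)
            previous = k


class TestConcat:
    def test_full_variant_length_534(self):
        c = make_complex(records=[make_record(atoms=("N",))], volume=45.0)
        fp = build_fingerprint(c, "Seq+Int+Ed+Vol")
        assert len(fp) == 534

    def test_seq_sim_length_20(self):
        c = make_complex(records=[make_record(atoms=("N",))])
        assert len(build_fingerprint(c, "Seq_sim")) == 20

    def test_ed_variant_length_22(self):
        fp = fp_concat({"editing": np.zeros(22, dtype=bool)}, "Ed")
        assert len(fp) == 22

    def test_missing_segment_named(self):
        with pytest.raises(ValueError, match="volume"):
            fp_concat({"int": np.zeros(500, dtype=bool),
                       "editing": np.zeros(22, dtype=bool)}, "Seq+Int+Ed+Vol")

    def test_missing_volume_data_named(self):
        c = make_complex(records=[make_record(atoms=("N",))])
        with pytest.raises(ValueError, match="volume"):
            build_fingerprint(c, "Seq+Int+Ed+Vol")

    def test_bitstring_round_trip(self):
        fp = fingerprint_from_active({1, 2, 3})
        back = Fingerprint.from_bitstring(fp.to_bitstring(), fp.variant)
        assert np.array_equal(fp.bits, back.bits)


class TestJaccard:
    def test_identity(self):
        a = fingerprint_from_active({1, 2, 3})
        assert jaccard_distance(a, a) == 0.0

    def test_disjoint(self):
        a = fingerprint_from_active({1, 2, 3})
        b = fingerprint_from_active({4, 5, 6})
        assert jaccard_distance(a, b) == 1.0

    def test_half_overlap(self):
        a = fingerprint_from_active({1, 2, 3})
        b = fingerprint_from_active({2, 3, 4})
        assert jaccard_distance(a, b) == pytest.approx(0.5)

    def test_both_empty_zero(self):
        a = fingerprint_from_active(set())
        assert jaccard_distance(a, a) == 0.0

    def test_variant_mismatch(self):
        a = fingerprint_from_active({1}, "Seq+Int")
        b = fingerprint_from_active({1}, "Ed")
        with pytest.raises(ValueError):
            jaccard_distance(a, b)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(200):
            fps = [
                fingerprint_from_active(
                    set(rng.choice(500, size=rng.integers(1, 30),
                                   replace=False).tolist()))
                for _ in range(3)
            ]
            dab = jaccard_distance(fps[0], fps[1])
            dba = jaccard_distance(fps[1], fps[0])
            dbc = jaccard_distance(fps[1], fps[2])
            dac = jaccard_distance(fps[0], fps[2])
            assert dab == dba
            assert 0.0 <= dab <= 1.0
            assert dac <= dab + dbc + 1e-12


class TestDistanceMatrix:
    def test_identical_fps_zero_matrix(self):
        fps = [fingerprint_from_active({1, 5})] * 3
        assert np.allclose(distance_matrix(fps), 0.0)

    def test_disjoint_pair(self):
        fps = [fingerprint_from_active({1}), fingerprint_from_active({2})]
        dm = distance_matrix(fps)
        assert dm[0, 1] == dm[1, 0] == 1.0

    def test_consistent_with_pairwise_calls(self, rng):
        fps = [
            fingerprint_from_active(
                set(rng.choice(500, size=10, replace=False).tolist()))
            for _ in range(4)
        ]
        dm = distance_matrix(fps)
        for i in range(4):
            for j in range(4):
                assert dm[i, j] == pytest.approx(
                    jaccard_distance(fps[i], fps[j]), abs=1e-12)

    def test_mixed_variants_error(self):
        with pytest.raises(ValueError):
            distance_matrix([fingerprint_from_active({1}, "Seq+Int"),
                             fingerprint_from_active({1}, "Ed")])
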