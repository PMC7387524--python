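"""Occupancy, frequency-table and rank-statistics behaviour."""

import itertools

import numpy as np
import pytest

from aarsfp.core import InteractionType as IT
from aarsfp.occupancy import (
    class_frequency_from_counts,
    class_frequency_table,
    compute_occupancy,
    mann_whitney_u,
    physicochemical_distances,
    residue_count_ligand_size_correlation,
    round_half_up,
    spearman_rho,
    summarize_side_chain_recognition,
)

from conftest import make_complex, make_record


def complexes_with_backbone_hbond(n_with, n_without, aars="AlaRS", itype=IT.HYDROGEN_BOND,
                                  atom="N"):
    out = []
    for i in range(n_with):
        out.append(make_complex(
            aars=aars, structure_id=f"W{i}",
            records=[make_record(itype=itype, atoms=(atom,))],
        ))
    for i in range(n_without):
        out.append(make_complex(aars=aars, structure_id=f"X{i}"))
    return out


class TestComputeOccupancy:
    def test_nine_of_ten(self):
        prof = compute_occupancy(complexes_with_backbone_hbond(9, 1))
        assert prof.entries[("N", IT.HYDROGEN_BOND)] == pytest.approx(0.9)
        assert prof.n_structures == 10

    def test_exactly_at_cutoff_retained(self):
        # "below 0.1" is a strict inequality: 1/10 = 0.1 stays
        prof = compute_occupancy(
            complexes_with_backbone_hbond(1, 9, itype=IT.SALT_BRIDGE, atom="O")
        )
        assert prof.entries[("O", IT.SALT_BRIDGE)] == pytest.approx(0.1)

    def test_below_cutoff_removed(self):
        prof = compute_occupancy(complexes_with_backbone_hbond(1, 19))
        assert ("N", IT.HYDROGEN_BOND) not in prof.entries

    def test_duplicate_records_counted_once_per_structure(self):
        c = make_complex(records=[make_record(atoms=("N",)),
                                  make_record(atoms=("N",), number=777)])
        prof = compute_occupancy([c], cutoff=0.0)
        assert prof.entries[("N", IT.HYDROGEN_BOND)] == pytest.approx(1.0)

    def test_water_bridges_excluded(self):
        c = make_complex(records=[make_record(itype=IT.WATER_BRIDGE, atoms=("N",))])
        prof = compute_occupancy([c], cutoff=0.0)
        assert prof.entries == {}

    def test_mixed_labels_error(self):
        with pytest.raises(ValueError, match="mixed"):
            compute_occupancy([make_complex(aars="AlaRS"),
                               make_complex(aars="GlyRS")])


class TestClassFrequencyTable:
    PRINTED_CLASS_I = {IT.HYDROGEN_BOND: 468, IT.HYDROPHOBIC: 550,
                       IT.SALT_BRIDGE: 153, IT.PI_STACKING: 59,
                       IT.METAL_COMPLEX: 3}
    PRINTED_CLASS_II = {IT.HYDROGEN_BOND: 856, IT.HYDROPHOBIC: 193,
                        IT.SALT_BRIDGE: 202, IT.PI_STACKING: 144,
                        IT.METAL_COMPLEX: 50}

    def test_published_class_counts(self):
        table = class_frequency_from_counts(
            {"I": self.PRINTED_CLASS_I, "II": self.PRINTED_CLASS_II}
        )
        assert table.totals == {"I": 1233, "II": 1445}
        assert table.percentages["I"][IT.HYDROGEN_BOND] == 37.96
        assert table.percentages["II"][IT.HYDROPHOBIC] == 13.36

    def test_single_type_is_100(self):
        table = class_frequency_from_counts({"I": {IT.HYDROGEN_BOND: 1}})
        assert table.percentages["I"][IT.HYDROGEN_BOND] == 100.00

    def test_percentages_sum_to_100(self):
        table = class_frequency_from_counts(
            {"I": self.PRINTED_CLASS_I, "II": self.PRINTED_CLASS_II}
        )
        for cls in ("I", "II"):
            assert sum(table.percentages[cls].values()) == pytest.approx(
                100.0, abs=0.02
            )

    def test_counts_are_per_record_not_per_structure(self):
        c = make_complex(records=[make_record(atoms=("N",)),
                                  make_record(atoms=("N",), number=777)])
        table = class_frequency_table([c])
        assert table.counts["II"][IT.HYDROGEN_BOND] == 2

    def test_round_half_up(self):
        assert round_half_up(0.125 * 100) == 12.5
        assert round_half_up(37.955) == 37.96
        assert round_half_up(44.605) == 44.61


class TestSideChainSummary:
    def test_backbone_only_is_empty(self):
        cs = complexes_with_backbone_hbond(5, 0)
        summary = summarize_side_chain_recognition({"AlaRS": cs}, {})
        assert summary["AlaRS"] == []

    def test_side_chain_contact_renumbered(self):
        cs = [
            make_complex(
                aars="AlaRS", structure_id=f"S{i}",
                records=[make_record(itype=IT.HYDROPHOBIC, residue="VAL",
                                     number=45, atoms=("CB",))],
            )
            for i in range(5)
        ]
        maps = {f"S{i}": {45: 293} for i in range(5)}
        (entry,) = summarize_side_chain_recognition({"AlaRS": cs}, maps)["AlaRS"]
        assert (entry.position, entry.residue_type, entry.itype) == (
            293, "VAL", IT.HYDROPHOBIC)
        assert entry.mapped

    def test_unmapped_contact_flagged(self):
        cs = [
            make_complex(
                aars="AlaRS", structure_id=f"S{i}",
                records=[make_record(itype=IT.HYDROPHOBIC, residue="VAL",
                                     number=45, atoms=("CB",))],
            )
            for i in range(2)
        ]
        (entry,) = summarize_side_chain_recognition({"AlaRS": cs}, {})["AlaRS"]
        assert entry.position == 45
        assert not entry.mapped


class TestResidueCountCorrelation:
    def test_perfect_correlation_by_construction(self):
        # one structure per synthetase whose distinct-residue count equals
        # its scaffold heavy-atom count
        from aarsfp.scaffolds import build_scaffold

        cs = []
        for aars in ("GlyRS", "AlaRS", "ThrRS", "LeuRS"):
            n = len(build_scaffold(aars[:-2]).atoms)
            recs = [make_record(number=100 + k, atoms=("N",)) for k in range(n)]
            cs.append(make_complex(aars=aars, records=recs))
        r, p = residue_count_ligand_size_correlation(cs)
        assert r == pytest.approx(1.0)

    def test_constant_counts_error(self):
        cs = [make_complex(aars=a, records=[make_record(atoms=("N",))])
              for a in ("GlyRS", "AlaRS", "SerRS")]
        with pytest.raises(ValueError, match="variance"):
            residue_count_ligand_size_correlation(cs)

    def test_too_few_groups_error(self):
        cs = [make_complex(aars="GlyRS"), make_complex(aars="AlaRS")]
        with pytest.raises(ValueError, match="3"):
            residue_count_ligand_size_correlation(cs)

    def test_matches_textbook_formula(self):
        # hand-listed (mean count, size) pairs; compare against the direct
        # covariance/stddev formula computed independently here
        from aarsfp.scaffolds import build_scaffold

        counts = {"GlyRS": 2, "AlaRS": 4, "SerRS": 3, "ValRS": 6, "TrpRS": 9}
        cs = []
        for aars, k in counts.items():
            recs = [make_record(number=100 + i, atoms=("N",)) for i in range(k)]
            cs.append(make_complex(aars=aars, records=recs))
        r, _ = residue_count_ligand_size_correlation(cs)
        labels = sorted(counts)
        x = np.array([counts[a] for a in labels], dtype=float)
        y = np.array([len(build_scaffold(a[:-2]).atoms) for a in labels],
                     dtype=float)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-12)


def mw_enumeration_oracle(x, y):
    """Exhaustive label-permutation oracle for the two-sided U test."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(a, b):
        return sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0
            for xi in a for yj in b
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    us = np.array(us)
    p = min(1.0, 2 * min(np.mean(us <= u_obs + 1e-9),
                         np.mean(us >= u_obs - 1e-9)))
    return u_obs, p


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_small_example_frozen(self):
        # U and p computed by enumerating all C(5,3)=10 arrangements
        u, p = mann_whitney_u([1, 3, 5], [2, 4])
        assert u == 3.0
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(2, 6)).tolist()
        y = rng.integers(0, 6, size=rng.integers(2, 6)).tolist()
        u_ours, p_ours = mann_whitney_u(x, y)
        u_oracle, p_oracle = mw_enumeration_oracle(x, y)
        assert u_ours == pytest.approx(u_oracle)
        assert p_ours == pytest.approx(p_oracle)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_identical(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_six_elements(self):
        # d^2 = (4,1,1,4,0,4), rho = 1 - 6*14/(6*35) = 0.6
        rho, _ = spearman_rho([1, 2, 3, 4, 5, 6], [3, 1, 2, 6, 5, 4])
        assert rho == pytest.approx(0.6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])


class TestPhysicochemicalTable:
    def test_distances_condensed_length(self):
        d = physicochemical_distances(["Ala", "Val", "Leu", "Arg"])
        assert d.shape == (6,)
        assert np.all(d >= 0)

    def test_missing_analog_rejected(self):
        with pytest.raises(KeyError):
            physicochemical_distances(["Gly", "Ala"])
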