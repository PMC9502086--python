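"""Pair enumeration, occupancy, threshold filtering and the taxonomy."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from loopscan import synthetic
from loopscan.core_io import Atom, Trajectory
from loopscan.errors import LoopscanError
from loopscan.interactions import (
    ContactPairSpec,
    InteractionRecord,
    Window,
    classify,
    compute_records,
    default_window,
    enumerate_pairs,
    filter_and_classify,
    interface_strength,
    min_distance,
    min_distance_series,
    occupancy,
    records_to_table,
)
from tests.helpers import pair_spec


def two_atom_traj(distances_nm) -> Trajectory:
    atoms = [Atom(1, "OG", "SER", 1, "A"), Atom(2, "OG", "SER", 2, "A")]
    coords = np.zeros((len(distances_nm), 2, 3))
    coords[:, 1, 2] = distances_nm
    return Trajectory(atoms, coords)


class TestMinDistance:
    def test_singletons(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 0.3]])
        assert min_distance(coords, [0], [1]) == pytest.approx(0.3)

    def test_min_over_product(self):
        coords = np.array([[0.0, 0, 0], [0, 0, 0.5], [0, 0, 0.2]])
        assert min_distance(coords, [0], [1, 2]) == pytest.approx(0.2)

    def test_empty_set_rejected(self):
        with pytest.raises(LoopscanError, match="empty"):
            min_distance(np.zeros((2, 3)), [0], [])

    def test_matches_cdist_oracle(self, rng):
        coords = rng.normal(size=(12, 3))
        idx_a, idx_b = [0, 3, 5, 7, 9], [1, 2, 4, 6, 8, 10, 11]
        expected = cdist(coords[idx_a], coords[idx_b]).min()
        assert min_distance(coords, idx_a, idx_b) == pytest.approx(expected, abs=1e-12)


class TestOccupancy:
    def test_alternating_contacts_give_fifty_percent(self):
        traj = two_atom_traj([0.30, 0.40] * 5)
        assert occupancy(traj, pair_spec()) == pytest.approx(50.0)

    def test_cutoff_boundary_is_inclusive(self):
        traj = two_atom_traj([0.33] * 6)
        assert occupancy(traj, pair_spec()) == pytest.approx(100.0)

    def test_monotone_in_cutoff(self):
        traj = two_atom_traj(np.linspace(0.2, 0.6, 30))
        occs = [occupancy(traj, pair_spec(), cutoff=c) for c in (0.25, 0.33, 0.45, 0.7)]
        assert occs == sorted(occs)
        assert occs[-1] == pytest.approx(100.0)

    def test_window_restricts_frames(self):
        traj = two_atom_traj([0.40] * 5 + [0.30] * 5)
        assert occupancy(traj, pair_spec(), window=Window.last_fraction(0.5)) == 100.0
        assert occupancy(traj, pair_spec(), window=Window.all()) == 50.0

    def test_window_excluding_everything_raises(self):
        traj = two_atom_traj([0.30, 0.30])
        with pytest.raises(LoopscanError):
            Window.last_ps(-5).frame_slice(traj.times)

    def test_default_window_degrades_for_short_runs(self):
        short = two_atom_traj([0.3] * 9)
        assert default_window(short).kind == "last_fraction"

    def test_telegraph_estimate_matches_truth_and_count_oracle(self):
        scenario = synthetic.ContactScenario(
            pairs=(synthetic.ContactPairScenario(p=0.67, phi=0.5),),
            n_frames=2000,
            seed=71,
        )
        traj, truth = synthetic.gen_contact_trajectory(scenario)
        est = occupancy(traj, truth.specs[0], cutoff=0.33)
        # frame-count oracle with scipy.cdist per frame
        idx_a = [traj.atom_index(truth.specs[0].residue_a, n) for n in truth.specs[0].atoms_a]
        idx_b = [traj.atom_index(truth.specs[0].residue_b, n) for n in truth.specs[0].atoms_b]
        count = sum(
            cdist(traj.coordinates[f, idx_a], traj.coordinates[f, idx_b]).min() <= 0.33
            for f in range(traj.n_frames)
        )
        assert est == pytest.approx(100.0 * count / traj.n_frames, abs=1e-12)
        n_eff = synthetic.effective_sample_size(2000, 0.5)
        sigma = 100.0 * np.sqrt(0.67 * 0.33 / n_eff)
        assert abs(est - 67.0) <= 3 * sigma


class TestEnumeratePairs:
    def test_ten_residue_peptide_matches_brute_force(self):
        pairs = tuple(
            synthetic.ContactPairScenario(p=1.0, sigma_nm=0.0, bound_nm=0.25)
            for _ in range(5)
        )
        scenario = synthetic.ContactScenario(pairs=pairs, n_frames=2, seed=1)
        traj, _ = synthetic.gen_contact_trajectory(scenario)
        specs = enumerate_pairs(traj, None, max_residue_distance=0.6)
        # oracle: all residue pairs whose heavy-atom min distance comes
        # within range in some frame, paired donor-to-acceptor
        residues = traj.residue_numbers()
        reachable = set()
        for ra, rb in itertools.combinations(residues, 2):
            ia = [i for i, a in enumerate(traj.atoms) if a.residue_number == ra]
            ib = [i for i, a in enumerate(traj.atoms) if a.residue_number == rb]
            if min_distance_series(traj, ia, ib).min() <= 0.6:
                reachable.add((ra, rb))
        assert reachable == {(1, 2), (3, 4), (5, 6), (7, 8), (9, 10)}
        assert {(s.residue_a, s.residue_b) for s in specs} == reachable
        # every ARG-GLU pair must offer the salt bridge and H-bond variants
        kinds = {(s.residue_a, s.residue_b, s.kind) for s in specs}
        assert (1, 2, "salt-bridge") in kinds

    def test_backbone_only_residues_yield_backbone_specs(self):
        atoms = [
            Atom(1, "N", "GLY", 1), Atom(2, "CA", "GLY", 1), Atom(3, "C", "GLY", 1),
            Atom(4, "O", "GLY", 1),
            Atom(5, "N", "GLY", 5), Atom(6, "CA", "GLY", 5), Atom(7, "C", "GLY", 5),
            Atom(8, "O", "GLY", 5),
        ]
        coords = np.zeros((1, 8, 3))
        coords[0, 4:, 2] = 0.3  # second glycine close by
        coords[0, :, 0] = [0, 0.05, 0.1, 0.15, 0, 0.05, 0.1, 0.15]
        traj = Trajectory(atoms, coords)
        specs = enumerate_pairs(traj, None)
        assert specs, "expected backbone donor/acceptor pairs"
        for s in specs:
            assert set(s.atoms_a) <= {"N", "O"}
            assert set(s.atoms_b) <= {"N", "O"}
            donor_acceptor = {s.context_a, s.context_b}
            assert donor_acceptor == {"(O)", "(NH)"}

    def test_adjacent_backbone_pairs_excluded(self):
        atoms = []
        serial = 1
        for resid in (1, 2):
            for name in ("N", "CA", "C", "O"):
                atoms.append(Atom(serial, name, "GLY", resid))
                serial += 1
        coords = np.zeros((1, 8, 3))
        coords[0, :, 0] = np.arange(8) * 0.05
        specs = enumerate_pairs(Trajectory(atoms, coords), None)
        assert specs == []


class TestFilterClassify:
    def test_table_style_rows_filtered_at_strict_threshold(self):
        keep = InteractionRecord(
            spec=pair_spec(
                resid_a=37, resid_b=40, resname_a="VAL", resname_b="ALA",
                atoms_a=("O",), atoms_b=("N",), context_a="(O)", context_b="(NH)",
            ),
            occupancies=(76, 58, 66),
        )
        drop = InteractionRecord(
            spec=pair_spec(
                resid_a=37, resid_b=41, resname_a="VAL", resname_b="SER",
                atoms_a=("O",), atoms_b=("N",), context_a="(O)", context_b="(NH)",
            ),
            occupancies=(8, 14, 12),
        )
        retained = filter_and_classify([keep, drop], threshold=25.0)
        assert [r.spec.label for r in retained] == ["V37(O):A40(NH)"]
        assert retained[0].average == pytest.approx(200 / 3)
        assert drop.average == pytest.approx(34 / 3)

    def test_threshold_is_strict(self):
        rec = InteractionRecord(spec=pair_spec(), occupancies=(25.0, 25.0))
        assert filter_and_classify([rec], threshold=25.0) == []

    def test_rounded_occupancies_use_half_up(self):
        rec = InteractionRecord(spec=pair_spec(), occupancies=(76, 58, 66))
        per, avg = rec.rounded()
        assert per == [76, 58, 66]
        assert avg == 67  # 66.67 rounds half-up to 67

    def test_classification_partition(self, carrier_elements):
        cases = {
            (38, 40): "intra-loop",
            (38, 50): "loop-matrix-helix",
            (143, 152): "intra-loop",
            (167, 241): "inter-domain(2-3)",
            (30, 141): "inter-domain(1-2)",
            (240, 38): "inter-domain(3-1)",
            (236, 264): "other",  # same domain, outside loop/helix pairing
        }
        categories = {
            "intra-loop", "loop-matrix-helix", "inter-domain(1-2)",
            "inter-domain(2-3)", "inter-domain(3-1)", "other",
        }
        for (ra, rb), expected in cases.items():
            got = classify(pair_spec(resid_a=ra, resid_b=rb), carrier_elements)
            assert got == expected
            assert got in categories

    def test_uncovered_residue_warns_and_is_other(self, carrier_elements):
        with pytest.warns(UserWarning, match="element map"):
            cat = classify(pair_spec(resid_a=1, resid_b=38), carrier_elements)
        assert cat == "other"


class TestInterfaceStrength:
    def test_empty_records_all_zero(self):
        table = interface_strength([])
        assert (table["total_occupancy"] == 0).all()
        assert (table["count"] == 0).all()

    def test_single_record_lands_in_its_cell(self):
        rec = InteractionRecord(
            spec=pair_spec(resid_a=167, resid_b=241),
            occupancies=(80.0,),
            category="inter-domain(2-3)",
        )
        table = interface_strength([rec])
        row = table[(table.category == "inter-domain") & (table.slot == "2-3")]
        assert row.total_occupancy.item() == pytest.approx(80.0)
        assert row["count"].item() == 1

    def test_planted_strong_interface_dominates(self, carrier_elements):
        """A synthetic trajectory with stronger 2-3 contacts than 1-2/3-1
        must put the 2-3 interface strictly on top."""
        pairs = (
            synthetic.ContactPairScenario(p=0.9, resid_a=167, resid_b=241),
            synthetic.ContactPairScenario(p=0.9, resid_a=166, resid_b=242),
            synthetic.ContactPairScenario(p=0.4, resid_a=30, resid_b=141),
            synthetic.ContactPairScenario(p=0.4, resid_a=240, resid_b=38),
        )
        scenario = synthetic.ContactScenario(pairs=pairs, n_frames=600, seed=13)
        traj, truth = synthetic.gen_contact_trajectory(scenario)
        records = compute_records([traj], truth.specs)
        retained = filter_and_classify(records, threshold=25.0, element_map=carrier_elements)
        table = interface_strength(retained, carrier_elements)
        inter = table[table.category == "inter-domain"].set_index("slot")
        assert inter.loc["2-3", "total_occupancy"] > inter.loc["1-2", "total_occupancy"]
        assert inter.loc["2-3", "total_occupancy"] > inter.loc["3-1", "total_occupancy"]

    def test_records_table_mirrors_label_convention(self):
        rec = InteractionRecord(
            spec=pair_spec(
                resid_a=30, resid_b=141, resname_a="ARG", resname_b="ALA",
                atoms_a=("NE", "NH1", "NH2"), atoms_b=("O",),
                context_a="", context_b="(O)",
            ),
            occupancies=(98, 100, 99),
            category="inter-domain(1-2)",
        )
        table = records_to_table([rec])
        assert table.loc[0, "label"] == "R30:A141(O)"
        assert table.loc[0, "average"] == 99
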