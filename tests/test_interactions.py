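"""Salt-bridge/H-bond candidate search, distance series and classification."""

import numpy as np
import pytest
from thermofluct.core import Atom, SequenceRecord, Structure, Trajectory
from thermofluct.interactions import (
    HBOND_CUTOFF,
    SALT_BRIDGE_CUTOFF,
    InteractionPair,
    candidate_pairs,
    compare_across_homologs,
    distance_series,
)
from thermofluct.mapping import align_many, build_map
from thermofluct.synthetic import (
    FluctuationSpec,
    InteractionPlan,
    make_reference_structure,
    make_trajectory,
)


def _structure(spec):
    """spec: list of (resnum, resname, atomname, element, xyz)."""
    atoms = [Atom("A", n, rn, an, el, np.array(p, float)) for n, rn, an, el, p in spec]
    return Structure(atoms, name="toy")


def _lys_asp(dist):
    return _structure(
        [
            (1, "LYS", "CA", "C", (0, 0, 0)),
            (1, "LYS", "NZ", "N", (1, 0, 0)),
            (5, "ASP", "CA", "C", (10, 10, 10)),
            (5, "ASP", "OD1", "O", (1 + dist, 0, 0)),
        ]
    )


class TestCandidatePairs:
    def test_close_lys_asp_is_salt_bridge_candidate(self):
        pairs = candidate_pairs(_lys_asp(3.0), "salt_bridge")
        assert len(pairs) == 1
        pair = pairs[0]
        assert pair.kind == "salt_bridge"
        assert {r[2] for r in pair.residues} == {"LYS", "ASP"}
        assert pair.cutoff == SALT_BRIDGE_CUTOFF

    def test_distant_pair_is_not_a_candidate(self):
        assert candidate_pairs(_lys_asp(7.5), "salt_bridge", search_cutoff=6.0) == []

    def test_threonine_pair_is_hbond_candidate(self):
        s = _structure(
            [
                (1, "THR", "CA", "C", (0, 0, 0)),
                (1, "THR", "OG1", "O", (1, 0, 0)),
                (4, "THR", "CA", "C", (8, 8, 8)),
                (4, "THR", "OG1", "O", (1, 3.2, 0)),
            ]
        )
        pairs = candidate_pairs(s, "hydrogen_bond")
        assert len(pairs) == 1
        assert pairs[0].atom_groups == (("OG1",), ("OG1",))
        assert pairs[0].cutoff == HBOND_CUTOFF

    def test_canonical_residue_order_and_symmetry(self):
        s = _lys_asp(3.0)
        reversed_atoms = Structure(list(reversed(s.atoms)), name="rev")
        a = candidate_pairs(s, "salt_bridge")
        b = candidate_pairs(reversed_atoms, "salt_bridge")
        assert len(a) == len(b) == 1
        assert a[0].residues == b[0].residues  # reported once, canonical order

    def test_adjacent_backbone_pairs_excluded(self):
        s = _structure(
            [
                (1, "ALA", "N", "N", (0, 0, 0)),
                (1, "ALA", "CA", "C", (1.5, 0, 0)),
                (2, "ALA", "N", "N", (3.0, 0, 0)),
                (2, "ALA", "CA", "C", (4.5, 0, 0)),
            ]
        )
        assert candidate_pairs(s, "hydrogen_bond") == []

    def test_nonstandard_residue_skipped_with_warning(self, caplog):
        s = _structure(
            [
                (1, "LYS", "NZ", "N", (0, 0, 0)),
                (2, "XYZ", "OD1", "O", (3, 0, 0)),
                (3, "ASP", "OD1", "O", (2.8, 0, 0)),
            ]
        )
        with caplog.at_level("WARNING"):
            pairs = candidate_pairs(s, "salt_bridge")
        assert len(pairs) == 1
        assert "unknown chemistry" in caplog.text


class TestDistanceSeries:
    def test_static_single_frame_equals_reference_distance(self):
        s = _lys_asp(3.0)
        traj = Trajectory(s, s.coords[None], 400.0)
        pair = candidate_pairs(s, "salt_bridge")[0]
        series = distance_series(traj, pair)
        assert series.distances.shape == (1,)
        assert series.distances[0] == pytest.approx(3.0)
        assert series.occupancy == 1.0
        assert series.classification == "SB"

    def test_planted_full_occupancy(self):
        ref = make_reference_structure(20, seed=31)
        lys = next(n for _c, n, rn, _i in ref.residues() if rn == "LYS")
        plan = InteractionPlan((1, lys), ("CA", "NZ"), 2.8, 8.0, 1.0, 0.0)
        traj = make_trajectory(
            ref, FluctuationSpec.uniform(20, 0.0, seed=32), [plan], n_frames=30
        )
        pair = InteractionPair(
            kind="hydrogen_bond",
            residues=(("A", 1, "XAA"), ("A", lys, "LYS")),
            atom_groups=(("CA",), ("NZ",)),
            cutoff=3.5,
        )
        series = distance_series(traj, pair)
        assert np.allclose(series.distances, 2.8, atol=1e-9)
        assert series.occupancy == 1.0

    def test_missing_atom_errors(self):
        s = _lys_asp(3.0)
        traj = Trajectory(s, s.coords[None], 400.0)
        pair = InteractionPair(
            "salt_bridge", (("A", 1, "LYS"), ("A", 5, "ASP")), (("NZ",), ("OD2",)), 4.0
        )
        with pytest.raises(ValueError, match="missing"):
            distance_series(traj, pair)

    def test_occupancy_invariant_to_frame_order(self):
        ref = make_reference_structure(10, seed=33)
        plan = InteractionPlan((2, 8), ("CA", "CA"), 3.0, 8.0, 0.5, 0.1)
        traj = make_trajectory(
            ref, FluctuationSpec.uniform(10, 0.2, seed=34), [plan], n_frames=200
        )
        pair = InteractionPair(
            "hydrogen_bond", (("A", 2, "XAA"), ("A", 8, "XAA")), (("CA",), ("CA",)), 4.0
        )
        base = distance_series(traj, pair, cutoff=4.0).occupancy
        perm = np.random.default_rng(0).permutation(200)
        shuffled = Trajectory(ref, traj.frames[perm], 400.0)
        assert distance_series(shuffled, pair, cutoff=4.0).occupancy == base

    def test_distances_invariant_under_rigid_frame_motion(self):
        ref = make_reference_structure(10, seed=35)
        spec_plain = FluctuationSpec.uniform(10, 0.3, seed=36)
        spec_rigid = FluctuationSpec.uniform(
            10, 0.3, rigid_body_noise=(20.0, 5.0), seed=36
        )
        pair = InteractionPair(
            "hydrogen_bond", (("A", 1, "XAA"), ("A", 6, "XAA")), (("CA",), ("CA",)), 4.0
        )
        a = distance_series(make_trajectory(ref, spec_plain, [], n_frames=50), pair)
        b = distance_series(make_trajectory(ref, spec_rigid, [], n_frames=50), pair)
        assert np.allclose(a.distances, b.distances, atol=1e-9)

    def test_equivalent_atom_minimum_is_used(self):
        s = _structure(
            [
                (1, "ASP", "OD1", "O", (0, 0, 0)),
                (1, "ASP", "OD2", "O", (5, 0, 0)),
                (3, "LYS", "NZ", "N", (8, 0, 0)),
            ]
        )
        traj = Trajectory(s, s.coords[None], 400.0)
        pair = InteractionPair(
            "salt_bridge",
            (("A", 1, "ASP"), ("A", 3, "LYS")),
            (("OD1", "OD2"), ("NZ",)),
            4.0,
        )
        series = distance_series(traj, pair)
        assert series.distances[0] == pytest.approx(3.0)  # min(8.0, 3.0)


class TestCompareAcrossHomologs:
    def _map(self, sequences):
        return build_map(
            align_many([SequenceRecord(i, s) for i, s in sequences.items()])
        )

    def test_shared_occupied_pair_classified_everywhere(self):
        sequences = {"p1": "KAAAD", "p2": "KAAAD"}
        amap = self._map(sequences)
        series_by_protein = {}
        for pid in sequences:
            s = _structure(
                [
                    (1, "LYS", "NZ", "N", (0, 0, 0)),
                    (5, "ASP", "OD1", "O", (3, 0, 0)),
                ]
            )
            traj = Trajectory(s, s.coords[None], 400.0)
            pair = candidate_pairs(s, "salt_bridge")[0]
            series_by_protein[pid] = [distance_series(traj, pair)]
        table = compare_across_homologs(series_by_protein, amap, sequences)
        assert list(table["p1_class"]) == ["SB"]
        assert list(table["p2_class"]) == ["SB"]

    def test_methionine_replacement_is_ni_regardless_of_distance(self):
        # basic partner mutated to Met: no candidate exists, so the row reports
        # NI for that homolog with the Met residue named
        sequences = {"wt": "KAAAD", "mut": "MAAAD"}
        amap = self._map(sequences)
        s = _structure(
            [(1, "LYS", "NZ", "N", (0, 0, 0)), (5, "ASP", "OD1", "O", (3, 0, 0))]
        )
        traj = Trajectory(s, s.coords[None], 400.0)
        pair = candidate_pairs(s, "salt_bridge")[0]
        table = compare_across_homologs(
            {"wt": [distance_series(traj, pair)], "mut": []}, amap, sequences
        )
        assert list(table["wt_class"]) == ["SB"]
        assert list(table["mut_class"]) == ["NI"]
        assert list(table["mut_residues"]) == ["M1-D5"]

    def test_zero_occupancy_is_ni_by_threshold(self):
        sequences = {"p1": "KAAAD"}
        amap = self._map({"p1": "KAAAD", "p2": "KAAAD"})
        s = _lys_asp(5.5)  # candidate at 5.5 A, never within the 4.0 A cutoff
        traj = Trajectory(s, s.coords[None], 400.0)
        pair = candidate_pairs(s, "salt_bridge")[0]
        table = compare_across_homologs(
            {"p1": [distance_series(traj, pair)]}, amap, sequences
        )
        assert list(table["p1_class"]) == ["NI"]
        assert table["p1_occupancy"][0] == 0.0
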