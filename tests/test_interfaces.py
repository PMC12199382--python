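"""Pose ensembles: contacts, binding modes, and interface preference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_contacts
from vhhfc.fixtures import make_domain_dumbbell, make_pose_ensemble
from vhhfc.interfaces import (
    Pose,
    PoseEnsemble,
    UNBOUND,
    aggregation_interface,
    classify_binding_mode,
    interface_contacts,
    load_pose_ensemble,
    mode_label,
    mode_summary,
    ppi_preference,
)
from vhhfc.structure import Atom, Structure, annotate_domains, write_pdb


def _dimer(pair_offsets):
    """Two 3-atom chains; chain B atom i sits at chain A atom i + offset."""
    atoms_a = [Atom(i + 1, "CA", "C", i + 1, "ALA", "A",
                    i * 12.0, 0.0, 0.0, 1.7) for i in range(3)]
    atoms_b = [Atom(i + 4, "CA", "C", i + 1, "ALA", "B",
                    i * 12.0 + pair_offsets[i][0], pair_offsets[i][1],
                    pair_offsets[i][2], 1.7) for i in range(3)]
    structure = Structure(atoms_a + atoms_b)
    return Pose(structure=structure, model=0,
                receptor_idx=np.array([0, 1, 2]),
                ligand_idx=np.array([3, 4, 5]))


class TestContacts:
    def test_far_partners_have_no_contacts(self):
        pose = _dimer([(0.0, 100.0, 0.0)] * 3)
        assert interface_contacts(pose) == []

    def test_matches_exhaustive_oracle(self, small_ensemble):
        structure, _ = small_ensemble
        n = structure.n_atoms // 2
        for m in range(structure.n_models):
            pose = Pose(structure, m, np.arange(n), np.arange(n, 2 * n))
            pairs = interface_contacts(pose)
            xyz = structure.coords[m]
            oracle = [(i, j + n) for i, j in
                      brute_force_contacts(xyz[:n], xyz[n:], 5.0)]
            assert pairs == sorted(oracle)

    def test_pair_at_exactly_cutoff_included(self):
        pose = _dimer([(0.0, 5.0, 0.0), (0.0, 100.0, 0.0), (0.0, 100.0, 0.0)])
        assert interface_contacts(pose, cutoff=5.0) == [(0, 3)]

    def test_symmetric_under_role_swap(self, small_ensemble):
        structure, _ = small_ensemble
        n = structure.n_atoms // 2
        pose = Pose(structure, 0, np.arange(n), np.arange(n, 2 * n))
        swapped = Pose(structure, 0, np.arange(n, 2 * n), np.arange(n))
        forward = set(interface_contacts(pose))
        backward = {(a, b) for b, a in interface_contacts(swapped)}
        assert forward == backward


class TestBindingMode:
    def test_planted_modes_recovered(self, small_ensemble):
        structure, truth = small_ensemble
        ann = annotate_domains(structure, truth["boundaries"])
        n = structure.n_atoms // 2
        got = [classify_binding_mode(
            Pose(structure, m, np.arange(n), np.arange(n, 2 * n)), ann)
            for m in range(structure.n_models)]
        assert got == truth["modes"]

    def test_unbound_sentinel_without_contacts(self):
        pose = _dimer([(0.0, 100.0, 0.0)] * 3)
        ann = annotate_domains(pose.structure,
                               {"VHH": (1, 1), "hinge": (2, 2), "Fc": (3, None)})
        assert classify_binding_mode(pose, ann) == UNBOUND

    def test_tie_breaks_prefer_vhh_then_hinge(self):
        # receptor contacts split 1:1 between VHH (res 1) and Fc (res 3):
        # the tie resolves to VHH; the ligand touches only Fc (res 3, 4)
        atoms_a = [Atom(i + 1, "CA", "C", i + 1, "ALA", "A",
                        i * 12.0, 0.0, 0.0, 1.7) for i in range(4)]
        b_pos = {1: (0.0, 100.0, 0.0), 2: (12.0, 100.0, 0.0),
                 3: (0.0, 4.0, 0.0), 4: (24.0, 4.0, 0.0)}
        atoms_b = [Atom(i + 5, "CA", "C", i + 1, "ALA", "B",
                        *b_pos[i + 1], 1.7) for i in range(4)]
        structure = Structure(atoms_a + atoms_b)
        pose = Pose(structure, 0, np.arange(4), np.arange(4, 8))
        ann = annotate_domains(structure,
                               {"VHH": (1, 1), "hinge": (2, 2), "Fc": (3, None)})
        # contacts: (A1, B3) and (A3, B4)
        assert [(structure.atoms[i].residue_number,
                 structure.atoms[j].residue_number)
                for i, j in interface_contacts(pose)] == [(1, 3), (3, 4)]
        assert classify_binding_mode(pose, ann) == "Fc-VHH"
        assert mode_label("Fc", "VHH") == mode_label("VHH", "Fc") == "Fc-VHH"


class TestModeSummary:
    def test_single_mode_is_100_percent(self):
        structure, truth = make_pose_ensemble({"Fc-Fc": 5}, seed=3)
        ann = annotate_domains(structure, truth["boundaries"])
        n = structure.n_atoms // 2
        ens = PoseEnsemble([Pose(structure, m, np.arange(n), np.arange(n, 2 * n))
                            for m in range(structure.n_models)])
        summary = mode_summary(ens, ann)
        assert summary.counts == {"Fc-Fc": 5}
        assert summary.percentages["Fc-Fc"] == pytest.approx(100.0)

    def test_three_to_one_split(self, small_ensemble):
        structure, truth = small_ensemble
        ann = annotate_domains(structure, truth["boundaries"])
        n = structure.n_atoms // 2
        ens = PoseEnsemble([Pose(structure, m, np.arange(n), np.arange(n, 2 * n))
                            for m in range(structure.n_models)])
        summary = mode_summary(ens, ann)
        assert summary.percentages == pytest.approx(
            {"Fc-VHH": 75.0, "VHH-VHH": 25.0})
        assert sum(summary.percentages.values()) == pytest.approx(100.0)

    def test_energy_statistics_joined_by_mode(self, tmp_path, small_ensemble):
        structure, truth = small_ensemble
        path = write_pdb(structure, tmp_path / "ens.pdb")
        energies = pd.DataFrame({"pose_index": range(4),
                                 "energy_kcal_mol": [-50.0, -60.0, -40.0, -30.0]})
        ens = load_pose_ensemble(path, energies)
        ann = annotate_domains(ens.poses[0].structure, truth["boundaries"])
        summary = mode_summary(ens, ann)
        fcvhh = [e for m, e in zip(truth["modes"],
                                   [-50.0, -60.0, -40.0, -30.0])
                 if m == "Fc-VHH"]
        assert summary.mean_energy["Fc-VHH"] == pytest.approx(np.mean(fcvhh))
        assert summary.sd_energy["Fc-VHH"] == pytest.approx(np.std(fcvhh, ddof=1))


class TestLoadEnsemble:
    def test_single_model_file(self, tmp_path):
        pose = _dimer([(0.0, 4.0, 0.0)] * 3)
        path = write_pdb(pose.structure, tmp_path / "one.pdb")
        ens = load_pose_ensemble(path)
        assert len(ens) == 1

    def test_energy_row_mismatch_is_error(self, tmp_path, small_ensemble):
        structure, _ = small_ensemble
        path = write_pdb(structure, tmp_path / "ens.pdb")
        bad = pd.DataFrame({"pose_index": range(3),
                            "energy_kcal_mol": [-1.0, -2.0, -3.0]})
        with pytest.raises(ValueError, match="rows"):
            load_pose_ensemble(path, bad)

    def test_more_than_two_chains_is_error(self, tmp_path):
        atoms = [Atom(i + 1, "CA", "C", 1, "ALA", c, i * 8.0, 0.0, 0.0, 1.7)
                 for i, c in enumerate("ABC")]
        path = write_pdb(Structure(atoms), tmp_path / "three.pdb")
        with pytest.raises(ValueError, match="chains"):
            load_pose_ensemble(path)


class TestPPIP:
    def test_planted_counts_and_normalization(self, small_ensemble, tmp_path):
        structure, truth = small_ensemble
        path = write_pdb(structure, tmp_path / "ens.pdb")
        ens = load_pose_ensemble(path)
        ppip = ppi_preference(ens)
        assert ppip.counts == truth["counts"]
        assert max(ppip.preference.values()) == pytest.approx(1.0)
        for num, expected in truth["ppip"].items():
            assert ppip.preference[num] == pytest.approx(expected)

    def test_never_contacted_position_reports_zero(self, small_ensemble):
        structure, truth = small_ensemble
        n = structure.n_atoms // 2
        ens = PoseEnsemble([Pose(structure, m, np.arange(n), np.arange(n, 2 * n))
                            for m in range(structure.n_models)])
        ppip = ppi_preference(ens)
        untouched = [num for num in range(1, n + 1)
                     if num not in truth["counts"]]
        if untouched:
            assert ppip.preference_of(untouched[0]) == 0.0

    def test_counts_pool_across_ensembles_before_normalizing(self):
        s1, t1 = make_pose_ensemble({"Fc-VHH": 2}, seed=21)
        s2, t2 = make_pose_ensemble({"VHH-VHH": 2}, seed=22)
        n = s1.n_atoms // 2
        def as_ens(s):
            return PoseEnsemble([
                Pose(s, m, np.arange(n), np.arange(n, 2 * n))
                for m in range(s.n_models)])
        combined = ppi_preference([as_ens(s1), as_ens(s2)])
        merged = dict(t1["counts"])
        for k, v in t2["counts"].items():
            merged[k] = merged.get(k, 0) + v
        assert combined.counts == merged
        peak = max(merged.values())
        for num, c in merged.items():
            assert combined.preference[num] == pytest.approx(c / peak)

    def test_no_contacts_anywhere_is_error(self):
        pose = _dimer([(0.0, 100.0, 0.0)] * 3)
        with pytest.raises(ValueError, match="contact"):
            ppi_preference(PoseEnsemble([pose]))


class TestAggregationInterface:
    def test_threshold_is_strict(self):
        from vhhfc.interfaces import PPIPMap
        ppip = PPIPMap(counts={1: 10, 2: 4, 3: 6, 4: 5},
                       preference={1: 1.0, 2: 0.4, 3: 0.6, 4: 0.5})
        assert aggregation_interface(ppip) == {1, 3}
        assert aggregation_interface(ppip, threshold=1.0) == set()

    def test_union_then_threshold_oracle_across_ensembles(self):
        seeds = [31, 32, 33]
        specs = [{"Fc-VHH": 2}, {"VHH-VHH": 2}, {"hinge-VHH": 1}]
        ensembles, merged = [], {}
        for seed, spec in zip(seeds, specs):
            s, t = make_pose_ensemble(spec, seed=seed)
            n = s.n_atoms // 2
            ensembles.append(PoseEnsemble([
                Pose(s, m, np.arange(n), np.arange(n, 2 * n))
                for m in range(s.n_models)]))
            for k, v in t["counts"].items():
                merged[k] = merged.get(k, 0) + v
        ppip = ppi_preference(ensembles)
        peak = max(merged.values())
        oracle = {num for num, c in merged.items() if c / peak > 0.5}
        assert aggregation_interface(ppip) == oracle


def test_mode_recovery_on_random_ensembles():
    """Planted mode distributions are recovered exactly on random ensembles."""
    rng = np.random.default_rng(5150)
    modes = ["Fc-Fc", "Fc-VHH", "Fc-hinge", "hinge-hinge", "hinge-VHH",
             "VHH-VHH"]
    for trial in range(25):
        dist = {m: int(k) for m, k in
                zip(modes, rng.integers(0, 3, size=len(modes))) if k > 0}
        if not dist:
            continue
        structure, truth = make_pose_ensemble(dist, seed=int(rng.integers(2**31)))
        ann = annotate_domains(structure, truth["boundaries"])
        n = structure.n_atoms // 2
        ens = PoseEnsemble([Pose(structure, m, np.arange(n), np.arange(n, 2 * n))
                            for m in range(structure.n_models)])
        summary = mode_summary(ens, ann)
        expected = {}
        for m in truth["modes"]:
            expected[m] = expected.get(m, 0) + 1
        assert summary.counts == expected
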