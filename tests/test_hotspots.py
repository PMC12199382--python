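"""Oxidation liability, STAP filtering, and the combined hotspot report."""

from __future__ import annotations

import numpy as np
import pytest

from vhhfc.hotspots import (
    OxidationFlag,
    binding_critical,
    his_catalysis,
    hotspot_report,
    oxidation_risk,
    stap_filter,
)
from vhhfc.sasa import relative_sasa, shrake_rupley


class TestOxidationThresholds:
    @pytest.mark.parametrize("pct,expected", [
        (19.9, False), (20.0, False), (20.1, True), (25.3, True)])
    def test_met_strict_boundary(self, pct, expected):
        flags = oxidation_risk({162: pct}, {162: "MET"})
        assert [f.threshold_exceeded for f in flags] == [expected]

    @pytest.mark.parametrize("pct,expected", [
        (29.9, False), (30.0, False), (30.1, True), (28.0, False),
        (34.8, True), (69.2, True)])
    def test_trp_strict_boundary(self, pct, expected):
        flags = oxidation_risk({111: pct}, {111: "TRP"})
        assert [f.threshold_exceeded for f in flags] == [expected]

    def test_every_met_and_trp_evaluated_others_ignored(self):
        rel = {111: 69.2, 115: 28.0, 162: 20.5, 268: 24.8, 338: 1.5, 57: 80.0}
        names = {111: "TRP", 115: "TRP", 162: "MET", 268: "MET", 338: "MET",
                 57: "PHE"}
        flags = oxidation_risk(rel, names)
        assert {f.residue_number for f in flags} == {111, 115, 162, 268, 338}
        flagged = {f.residue_number for f in flags if f.threshold_exceeded}
        assert flagged == {111, 162, 268}

    def test_chain_keyed_relative_sasa_accepted(self):
        rel = {("A", 162): 25.0, ("B", 162): 10.0}
        flags = oxidation_risk(rel, {162: "MET"})
        assert flags[0].sasa_pct == 25.0 and flags[0].threshold_exceeded


class TestHisCatalysis:
    def test_no_histidine_means_no_catalysis(self, dipeptide):
        structure, _ = dipeptide
        flags = [OxidationFlag(1, "MET", 30.0, True)]
        out = his_catalysis(structure, flags)
        assert not out[0].his_catalysis and out[0].nearby_his == []

    def test_buried_met_with_his_and_exposed_met_partner(self,
                                                         catalysis_structure):
        structure, _ = catalysis_structure
        profile = shrake_rupley(structure)
        rel = relative_sasa(structure, profile)
        names = {n: name for _, n, name in structure.residues()}
        flags = his_catalysis(structure, oxidation_risk(rel, names))
        by_num = {f.residue_number: f for f in flags}
        buried, exposed = by_num[2], by_num[3]
        assert not buried.threshold_exceeded and buried.sasa_pct < 5.0
        assert exposed.threshold_exceeded
        # the buried Met relays through the exposed one (S-S 5.2 A <= 6)
        assert buried.his_catalysis
        # oracle: closest imidazole heavy atom really is within 10 A
        xyz = structure.coords[0]
        sd = next(i for i, a in enumerate(structure.atoms)
                  if a.residue_number == 2 and a.name == "SD")
        imid = [i for i, a in enumerate(structure.atoms)
                if a.residue_name == "HIS"
                and a.name in ("CG", "ND1", "CD2", "CE1", "NE2")]
        closest = min(np.linalg.norm(xyz[i] - xyz[sd]) for i in imid)
        assert closest <= 10.0
        assert buried.nearby_his[0][1] == pytest.approx(closest, abs=0.01)

    def test_his_beyond_radius_does_not_catalyze(self, catalysis_structure):
        structure, _ = catalysis_structure
        profile = shrake_rupley(structure)
        rel = relative_sasa(structure, profile)
        names = {n: name for _, n, name in structure.residues()}
        # shrink the search radius below the true closest distance: the
        # brute-force oracle distance decides the flag either way
        flags = his_catalysis(structure, oxidation_risk(rel, names),
                              his_radius=8.0)
        by_num = {f.residue_number: f for f in flags}
        xyz = structure.coords[0]
        sd = next(i for i, a in enumerate(structure.atoms)
                  if a.residue_number == 2 and a.name == "SD")
        imid = [i for i, a in enumerate(structure.atoms)
                if a.residue_name == "HIS"
                and a.name in ("CG", "ND1", "CD2", "CE1", "NE2")]
        closest = min(np.linalg.norm(xyz[i] - xyz[sd]) for i in imid)
        assert closest > 8.0
        assert not by_num[2].his_catalysis

    def test_exposed_met_without_his_nearby_not_catalysis_flagged(
            self, catalysis_structure):
        structure, _ = catalysis_structure
        profile = shrake_rupley(structure)
        rel = relative_sasa(structure, profile)
        names = {n: name for _, n, name in structure.residues()}
        flags = his_catalysis(structure, oxidation_risk(rel, names))
        by_num = {f.residue_number: f for f in flags}
        assert by_num[3].threshold_exceeded and not by_num[3].his_catalysis


# the worked aggregation example: nine structure-corrected aggregation
# scores above 1, three residues off the interface, two conserved
A3D_POSITIVE = {5: 1.3, 11: 1.1, 57: 1.8, 58: 1.2, 59: 1.4, 103: 1.05,
                105: 1.6, 106: 1.7, 120: 1.2}
INTERFACE = {57, 58, 59, 105, 106, 120, 130}
CONSERVED = {58, 59}


class TestSTAPFilter:
    def test_worked_example(self):
        scores = dict(A3D_POSITIVE)
        scores.update({50: 0.4, 60: -1.0})  # sub-threshold residues ignored
        assert stap_filter(scores, INTERFACE, CONSERVED) == {57, 105, 106, 120}

    def test_empty_interface_gives_empty_set(self):
        assert stap_filter(A3D_POSITIVE, set(), CONSERVED) == set()

    def test_all_candidates_conserved_gives_empty_set(self):
        assert stap_filter(A3D_POSITIVE, INTERFACE,
                           conserved=set(A3D_POSITIVE)) == set()

    def test_threshold_is_strict(self):
        assert stap_filter({7: 1.0}, {7}) == set()
        assert stap_filter({7: 1.0001}, {7}) == {7}

    def test_monotone_in_conserved_set_and_threshold(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            residues = rng.choice(200, size=30, replace=False)
            scores = {int(r): float(rng.normal(1.0, 0.5)) for r in residues}
            iface = {int(r) for r in rng.choice(200, size=60)}
            cons_small = {int(r) for r in rng.choice(200, size=10)}
            cons_big = cons_small | {int(r) for r in rng.choice(200, size=10)}
            assert stap_filter(scores, iface, cons_big) <= \
                stap_filter(scores, iface, cons_small)
            assert stap_filter(scores, iface, cons_small, threshold=1.5) <= \
                stap_filter(scores, iface, cons_small, threshold=0.5)

    def test_matches_brute_force_set_algebra_on_random_inputs(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            scores = {int(r): float(rng.normal(1.0, 1.0))
                      for r in rng.choice(100, size=20, replace=False)}
            iface = {int(r) for r in rng.choice(100, size=30)}
            cons = {int(r) for r in rng.choice(100, size=15)}
            oracle = set()
            for r, s in scores.items():
                if s > 1.0 and r in iface and r not in cons:
                    oracle.add(r)
            assert stap_filter(scores, iface, cons) == oracle


class TestBindingCritical:
    def test_six_residue_alanine_scan(self):
        ddg = {55: 1.4, 59: 2.1, 62: 1.2, 105: 3.0, 106: 2.7, 107: 1.1,
               57: 0.3, 111: -0.2}
        assert binding_critical(ddg) == {55, 59, 62, 105, 106, 107}

    def test_all_below_threshold_empty(self):
        assert binding_critical({1: 0.2, 2: -1.0, 3: 1.0}) == set()

    def test_exactly_threshold_excluded(self):
        assert binding_critical({9: 1.0}) == set()


class TestHotspotReport:
    def _combined_workflow_report(self):
        ox = [
            OxidationFlag(111, "TRP", 69.2, True),
            OxidationFlag(115, "TRP", 28.0, False),
            OxidationFlag(162, "MET", 20.5, True),
            OxidationFlag(338, "MET", 1.5, False, his_catalysis=True),
        ]
        return hotspot_report(
            redox_cys={130},
            oxidation_flags=ox,
            stap_hotspots={57, 105, 106, 120},
            binding_critical_set={55, 59, 62, 105, 106, 107},
            conserved={58, 59, 115, 162, 338},
        )

    def test_combined_hotspot_set(self):
        report = self._combined_workflow_report()
        assert report.hotspots() == {130, 57, 105, 106, 120, 111}

    def test_binding_critical_residues_never_mutable(self):
        report = self._combined_workflow_report()
        assert not report.entries[105].mutable
        assert not report.entries[106].mutable
        assert report.entries[105].excluded_because == {"binding-critical"}
        assert report.mutable() == {130, 57, 120, 111}

    def test_conserved_oxidation_sites_not_reported(self):
        report = self._combined_workflow_report()
        assert 162 not in report.entries  # conserved Met suppressed
        assert 338 not in report.entries

    def test_empty_inputs_give_empty_report(self):
        report = hotspot_report()
        assert report.hotspots() == set() and report.entries == {}

    def test_stap_and_binding_critical_residue_listed_not_mutable(self):
        report = hotspot_report(stap_hotspots={42},
                                binding_critical_set={42})
        assert report.hotspots() == {42}
        assert not report.entries[42].mutable

    def test_random_inputs_match_brute_force_reimplementation(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            redox = {int(r) for r in rng.choice(50, size=2)}
            stap = {int(r) for r in rng.choice(50, size=5)}
            critical = {int(r) for r in rng.choice(50, size=5)}
            cons = {int(r) for r in rng.choice(50, size=5)}
            flags = [OxidationFlag(int(r), "MET", 25.0, True)
                     for r in rng.choice(50, size=3)]
            report = hotspot_report(redox, flags, stap, critical, cons)
            expected_hot = redox | stap | {
                f.residue_number for f in flags
                if f.residue_number not in cons}
            assert report.hotspots() == expected_hot
            for num in expected_hot:
                should_be_mutable = num not in cons and num not in critical
                assert report.entries[num].mutable == should_be_mutable
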