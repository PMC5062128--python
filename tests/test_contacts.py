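"""Structure parsing, contact annotation and cluster detection.

The reference for contact flags is an exhaustive all-atom-pairs
brute-force computation with no vectorization shortcuts, run against
random toy structures.
"""

import io
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrfootprint.contacts import (annotate_contacts, find_clusters,
                                   parse_structure)
from tcrfootprint.errors import ConfigError, StructureError
from tcrfootprint.simulate import (ResidueDesign, ScenarioSpec,
                                   default_scenario, generate_toy_structure,
                                   random_structure_pdb)

ROLE_MAP = {"A": "mhc-heavy", "B": "beta2m", "C": "peptide",
            "D": "tcr-alpha", "E": "tcr-beta"}


def _model_from_text(text, role_map=None):
    return parse_structure(io.StringIO(text), role_map or ROLE_MAP)


def _simple_scenario(residues, clusters=()):
    return ScenarioSpec(residues=tuple(residues), clusters=tuple(clusters),
                        noise_eq=0.0, noise_diss=0.0)


# a hand-written 2-residue chain with A/B altlocs on one atom, plus the
# four partner chains required by the role map
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA AARG A   2       5.000   0.000   0.000  0.30  0.00           C
ATOM      4  CA BARG A   2       6.000   0.000   0.000  0.70  0.00           C
ATOM      5  CA  GLY B   1      30.000  30.000  30.000  1.00  0.00           C
ATOM      6  CA  GLY C   1     -30.000  30.000  30.000  1.00  0.00           C
ATOM      7  CA  GLY D   1      30.000 -30.000  30.000  1.00  0.00           C
ATOM      8  CA  GLY E   1      30.000  30.000 -30.000  1.00  0.00           C
END
"""


class TestParseStructure:
    def test_residue_count_conservation(self):
        spec = _simple_scenario([ResidueDesign(f"T{i}") for i in
                                 range(10, 22)])
        text, role_map = generate_toy_structure(spec)
        model = _model_from_text(text, role_map)
        assert len(model.by_role("mhc-heavy")) == 12

    def test_altloc_resolved_to_highest_occupancy(self):
        model = _model_from_text(ALTLOC_PDB)
        res2 = [r for r in model.residues if r.resseq == 2][0]
        assert len(res2.coords) == 1
        assert res2.coords[0][0] == pytest.approx(6.0)  # occupancy 0.70

    def test_five_chain_layout_resolves_all_roles(self):
        text, role_map = generate_toy_structure(default_scenario(0))
        model = _model_from_text(text, role_map)
        roles = {r.role for r in model.residues}
        assert roles == {"mhc-heavy", "beta2m", "peptide", "tcr-alpha",
                         "tcr-beta"}

    def test_role_for_absent_chain_is_config_error(self):
        with pytest.raises(ConfigError, match="absent"):
            _model_from_text(ALTLOC_PDB, {**ROLE_MAP, "Z": "tcr-alpha"})

    def test_unmapped_present_chain_is_config_error(self):
        role_map = dict(ROLE_MAP)
        del role_map["E"]
        with pytest.raises(ConfigError, match="no assigned role"):
            _model_from_text(ALTLOC_PDB, role_map)

    def test_chain_without_ca_is_malformed(self):
        bad = ALTLOC_PDB.replace(
            "ATOM      5  CA  GLY B   1      30.000  30.000  30.000",
            "ATOM      5  CB  GLY B   1      30.000  30.000  30.000")
        with pytest.raises(StructureError, match="no CA"):
            _model_from_text(bad)


class TestAnnotateContacts:
    def test_threshold_semantics_at_4A(self):
        spec = _simple_scenario([
            ResidueDesign("R65", contacts_tcr=True),          # 3.5 A
            ResidueDesign("E58", contacts_tcr=False,
                          proximal_only=True),                 # 5.5 A
            ResidueDesign("D61", contacts_tcr=False),          # remote
        ])
        text, role_map = generate_toy_structure(spec)
        cmap = annotate_contacts(_model_from_text(text, role_map))
        assert cmap.get("R65").contacts_tcr
        assert cmap.get("R65").within_proximity_of_tcr
        e58 = cmap.get("E58")
        assert not e58.contacts_tcr and e58.within_proximity_of_tcr
        assert 4.0 < e58.min_dist_tcr <= 6.0
        d61 = cmap.get("D61")
        assert not d61.within_proximity_of_tcr and d61.min_dist_tcr > 7.0

    def test_contact_implies_proximity_everywhere(self):
        text, role_map = generate_toy_structure(default_scenario(3))
        cmap = annotate_contacts(_model_from_text(text, role_map))
        for ann in cmap.annotations.values():
            assert (not ann.contacts_tcr) or ann.within_proximity_of_tcr
            assert ann.min_dist_tcr >= 0

    def test_peptide_contacts_match_design(self):
        sc = default_scenario(0)
        text, role_map = generate_toy_structure(sc)
        cmap = annotate_contacts(_model_from_text(text, role_map))
        designed = {r.label for r in sc.residues if r.contacts_peptide}
        flagged = {l for l, a in cmap.annotations.items()
                   if a.role == "mhc-heavy" and a.contacts_peptide}
        assert flagged == designed

    def test_flags_monotone_in_contact_threshold(self):
        rng = np.random.default_rng(5)
        text, role_map = random_structure_pdb(rng)
        model = _model_from_text(text, role_map)
        small = annotate_contacts(model, contact_threshold=3.5)
        large = annotate_contacts(model, contact_threshold=5.0)
        for label, ann in small.annotations.items():
            if ann.contacts_tcr:
                assert large.get(label).contacts_tcr

    def test_agrees_with_brute_force_oracle_on_random_structures(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            text, role_map = random_structure_pdb(rng)
            model = _model_from_text(text, role_map)
            cmap = annotate_contacts(model)
            oracle = brute_force_annotations(model, 4.0, 6.0)
            assert set(cmap.annotations) == set(oracle)
            for label, (d_tcr, d_pep) in oracle.items():
                ann = cmap.get(label)
                assert ann.min_dist_tcr == pytest.approx(d_tcr, abs=1e-9)
                if not math.isnan(d_pep):
                    assert ann.min_dist_peptide == pytest.approx(d_pep,
                                                                 abs=1e-9)
                assert ann.contacts_tcr == (d_tcr <= 4.0)
                assert ann.within_proximity_of_tcr == (d_tcr <= 6.0)

    def test_rigid_body_invariance(self):
        sc = default_scenario(1)
        rot = Rotation.from_euler("xyz", [30, -45, 60],
                                  degrees=True).as_matrix()
        text_a, role_map = generate_toy_structure(sc)
        text_b, _ = generate_toy_structure(sc, rotation=rot,
                                           translation=[5.0, -3.0, 8.0])
        cm_a = annotate_contacts(_model_from_text(text_a, role_map))
        cm_b = annotate_contacts(_model_from_text(text_b, role_map))
        for label, ann in cm_a.annotations.items():
            other = cm_b.get(label)
            # PDB coordinates carry 3 decimals; distances agree to ~1e-3
            assert other.min_dist_tcr == pytest.approx(ann.min_dist_tcr,
                                                       abs=5e-3)
            assert other.contacts_tcr == ann.contacts_tcr
            assert other.contacts_peptide == ann.contacts_peptide


def brute_force_annotations(model, contact, proximity):
    """All-pairs loop oracle: min distances per MHC/peptide residue."""
    tcr_atoms = [c for r in model.residues
                 if r.role in ("tcr-alpha", "tcr-beta") for c in r.coords]
    pep_atoms = [c for r in model.residues if r.role == "peptide"
                 for c in r.coords]
    out = {}
    for res in model.residues:
        if res.role not in ("mhc-heavy", "peptide"):
            continue
        d_tcr = math.inf
        for a in res.coords:
            for b in tcr_atoms:
                d_tcr = min(d_tcr, math.dist(a, b))
        if res.role == "mhc-heavy":
            d_pep = math.inf
            for a in res.coords:
                for b in pep_atoms:
                    d_pep = min(d_pep, math.dist(a, b))
            out[res.label] = (d_tcr, d_pep)
        else:
            out["p" + res.label] = (d_tcr, math.nan)
    return out


class TestClusters:
    def test_three_planted_pairs_recovered(self):
        sc = default_scenario(0)
        text, role_map = generate_toy_structure(sc)
        cmap = annotate_contacts(_model_from_text(text, role_map))
        candidates = ["R65", "A69", "V76", "T80", "A150", "H151", "E154",
                      "Q155", "T163", "E166"]
        clusters, singles = find_clusters(candidates, cmap)
        assert clusters == [("V76", "T80"), ("H151", "E154"),
                            ("T163", "E166")]
        assert set(singles) == {"R65", "A69", "A150", "Q155"}

    def test_dispersed_candidates_give_zero_clusters(self):
        spec = _simple_scenario(
            [ResidueDesign(l) for l in ("R65", "K66", "A69", "Q155")])
        text, role_map = generate_toy_structure(spec)
        cmap = annotate_contacts(_model_from_text(text, role_map))
        clusters, singles = find_clusters(["R65", "K66", "A69", "Q155"],
                                          cmap)
        assert clusters == []
        assert len(singles) == 4

    def test_chained_adjacency_is_transitive(self):
        # A-B adjacent and B-C adjacent => one cluster {A, B, C}
        spec = _simple_scenario(
            [ResidueDesign("V76"), ResidueDesign("T80"),
             ResidueDesign("E81")],
            clusters=[(("V76", "T80"), 0.0)])
        text, role_map = generate_toy_structure(spec)
        cmap = annotate_contacts(_model_from_text(text, role_map))
        # plant a third side chain near T80 by reusing its coordinates
        cmap.side_chains["E81"] = cmap.side_chains["T80"] + np.array(
            [[0.0, 4.0, 0.0]])
        clusters, _ = find_clusters(["V76", "T80", "E81"], cmap)
        assert clusters == [("V76", "T80", "E81")]

    def test_adjacency_graph_is_symmetric_and_irreflexive(self):
        sc = default_scenario(0)
        text, role_map = generate_toy_structure(sc)
        cmap = annotate_contacts(_model_from_text(text, role_map))
        g = cmap.adjacency_graph(["V76", "T80", "R65"])
        assert not any(a == b for a, b in g.edges)
        assert set(g.nodes) == {"V76", "T80", "R65"}
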