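"""Structural footprint: contacts, proximity and side-chain clusters.

Distances use heavy atoms only (crystal structures rarely resolve
hydrogens). A residue "contacts" a group when its minimum heavy-atom
distance to any atom of that group is at or below the contact threshold
(default 4 Å); "within proximity" uses the larger selection threshold
(default 6 Å). Side chains are heavy atoms excluding backbone N, CA, C, O
(and OXT); glycine's side-chain proxy is its CA. Author residue numbering
(PDB fields) is authoritative end to end.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .binding import CHAIN_ROLES
from .errors import ConfigError, StructureError

__all__ = [
    "ResidueModel", "StructureModel", "ResidueAnnotation", "ContactMap",
    "parse_structure", "annotate_contacts", "find_clusters",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ResidueModel:
    """One residue: heavy-atom names and coordinates, altlocs resolved."""

    chain_id: str
    role: str
    resseq: int
    icode: str
    resname: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3)

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.resname, "X")

    @property
    def label(self) -> str:
        """e.g. ``R65`` — one-letter code + author number + insertion code."""
        return f"{self.one_letter}{self.resseq}{self.icode.strip()}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode.strip())

    def side_chain_coords(self) -> np.ndarray:
        """Side-chain heavy atoms; CA proxy when none exist (glycine)."""
        mask = [name not in _BACKBONE for name in self.atom_names]
        if any(mask):
            return self.coords[np.asarray(mask)]
        if "CA" in self.atom_names:
            return self.coords[[self.atom_names.index("CA")]]
        return self.coords


@dataclass
class StructureModel:
    """Parsed complex with residues grouped by chain role."""

    residues: list[ResidueModel]

    def by_role(self, *roles: str) -> list[ResidueModel]:
        return [r for r in self.residues if r.role in roles]

    def role_coords(self, *roles: str) -> np.ndarray:
        arrs = [r.coords for r in self.by_role(*roles)]
        if not arrs:
            return np.empty((0, 3))
        return np.vstack(arrs)


def _pick_altloc(atom):
    """Highest-occupancy conformer; ties resolved to the first listed."""
    if not atom.is_disordered():
        return atom
    best = None
    for alt in atom.disordered_get_list():
        if best is None or (alt.get_occupancy() or 0) > (
                best.get_occupancy() or 0):
            best = alt
    return best


def parse_structure(source: str | Path | io.TextIOBase,
                    role_map: Mapping[str, str]) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    ``role_map`` maps chain identifiers to roles in
    ``{tcr-alpha, tcr-beta, mhc-heavy, beta2m, peptide}``. Heavy atoms only;
    waters and heteroatoms are excluded; the first model is used.
    """
    for chain_id, role in role_map.items():
        if role not in CHAIN_ROLES:
            raise ConfigError(f"unknown chain role {role!r} for chain "
                              f"{chain_id!r}")
    role_counts: dict[str, int] = {}
    for role in role_map.values():
        role_counts[role] = role_counts.get(role, 0) + 1
    if any(role_counts.get(r, 0) > 1 for r in ("mhc-heavy", "beta2m",
                                               "peptide")):
        raise ConfigError("mhc-heavy, beta2m and peptide must each map to "
                          "a single chain")

    parser = PDBParser(QUIET=True)
    if isinstance(source, (str, Path)):
        structure = parser.get_structure("complex", str(source))
    else:
        structure = parser.get_structure("complex", source)
    model = next(iter(structure))

    present = {chain.id for chain in model}
    missing = set(role_map) - present
    if missing:
        raise ConfigError(
            f"role map assigns chains absent from the structure: "
            f"{', '.join(sorted(missing))}")

    residues: list[ResidueModel] = []
    for chain in model:
        if chain.id not in role_map:
            raise ConfigError(
                f"chain {chain.id!r} present in the structure has no "
                "assigned role")
        role = role_map[chain.id]
        has_ca = False
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag != " ":  # waters / heteroatoms
                continue
            names, coords = [], []
            for atom in res:
                picked = _pick_altloc(atom)
                if picked is None:
                    continue
                element = (picked.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                names.append(picked.get_name())
                coords.append(picked.get_coord())
            if not names:
                continue
            if "CA" in names:
                has_ca = True
            residues.append(ResidueModel(
                chain_id=chain.id, role=role, resseq=resseq,
                icode=icode, resname=res.get_resname().strip(),
                atom_names=names, coords=np.asarray(coords, dtype=float)))
        if not has_ca:
            raise StructureError(
                f"chain {chain.id!r} (role {role}) has no CA atoms")
    return StructureModel(residues=residues)


@dataclass(frozen=True)
class ResidueAnnotation:
    """Interface annotation of a single MHC heavy-chain or peptide residue."""

    label: str
    chain_id: str
    resseq: int
    icode: str
    resname: str
    role: str
    min_dist_tcr: float
    min_dist_peptide: float  # NaN for peptide residues themselves
    contacts_tcr: bool
    contacts_peptide: bool
    within_proximity_of_tcr: bool


@dataclass
class ContactMap:
    """Per-residue interface annotations plus side-chain geometry.

    ``annotations`` covers every MHC heavy-chain and peptide residue, keyed
    by residue label (e.g. ``R65`` for the MHC chain, ``pM4`` for peptide
    position 4). The side-chain adjacency graph is built on demand by
    :func:`find_clusters`.
    """

    annotations: dict[str, ResidueAnnotation]
    side_chains: dict[str, np.ndarray] = field(default_factory=dict)
    contact_threshold: float = 4.0
    proximity_threshold: float = 6.0
    adjacency_threshold: float = 4.5

    def get(self, label: str) -> ResidueAnnotation | None:
        return self.annotations.get(label)

    def side_chain_distance(self, a: str, b: str) -> float:
        return float(cdist(self.side_chains[a], self.side_chains[b]).min())

    def adjacency_graph(self, candidates: Iterable[str],
                        threshold: float | None = None) -> nx.Graph:
        """Side-chain adjacency graph induced on ``candidates``.

        Symmetric and irreflexive by construction; nodes are exactly the
        candidate labels.
        """
        thr = self.adjacency_threshold if threshold is None else threshold
        labels = list(candidates)
        unknown = [l for l in labels if l not in self.side_chains]
        if unknown:
            raise ConfigError(
                f"candidate residues not in the contact map: "
                f"{', '.join(unknown)}")
        g = nx.Graph()
        g.add_nodes_from(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if self.side_chain_distance(a, b) <= thr:
                    g.add_edge(a, b)
        return g


def _min_dist(coords: np.ndarray, other: np.ndarray) -> float:
    if len(other) == 0 or len(coords) == 0:
        return math.inf
    return float(cdist(coords, other).min())


def annotate_contacts(model: StructureModel, config=None, *,
                      contact_threshold: float | None = None,
                      proximity_threshold: float | None = None,
                      adjacency_threshold: float | None = None) -> ContactMap:
    """Annotate every MHC heavy-chain and peptide residue.

    For each MHC residue: minimum heavy-atom distance to any TCR atom and
    to any peptide atom, with contact/proximity flags against the two
    thresholds. Peptide residues are annotated against the TCR likewise.
    """
    ct = contact_threshold if contact_threshold is not None else (
        config.contact_threshold if config else 4.0)
    pt = proximity_threshold if proximity_threshold is not None else (
        config.proximity_threshold if config else 6.0)
    at = adjacency_threshold if adjacency_threshold is not None else (
        config.adjacency_threshold if config else 4.5)

    tcr = model.role_coords("tcr-alpha", "tcr-beta")
    pep = model.role_coords("peptide")
    annotations: dict[str, ResidueAnnotation] = {}
    side_chains: dict[str, np.ndarray] = {}
    for res in model.by_role("mhc-heavy", "peptide"):
        d_tcr = _min_dist(res.coords, tcr)
        if res.role == "mhc-heavy":
            d_pep = _min_dist(res.coords, pep)
            label = res.label
        else:
            d_pep = math.nan
            label = "p" + res.label
        annotations[label] = ResidueAnnotation(
            label=label, chain_id=res.chain_id, resseq=res.resseq,
            icode=res.icode.strip(), resname=res.resname, role=res.role,
            min_dist_tcr=d_tcr, min_dist_peptide=d_pep,
            contacts_tcr=d_tcr <= ct,
            contacts_peptide=bool(d_pep <= ct) if not math.isnan(d_pep)
                else False,
            within_proximity_of_tcr=d_tcr <= pt)
        side_chains[label] = res.side_chain_coords()
    return ContactMap(annotations=annotations, side_chains=side_chains,
                      contact_threshold=ct, proximity_threshold=pt,
                      adjacency_threshold=at)


def find_clusters(candidates: Sequence[str], contact_map: ContactMap,
                  threshold: float | None = None
                  ) -> tuple[list[tuple[str, ...]], list[str]]:
    """Connected components of the side-chain adjacency subgraph.

    Returns ``(clusters, singletons)``: clusters are components of size >= 2
    (members sorted by author position), singletons the isolated candidates.
    """
    g = contact_map.adjacency_graph(candidates, threshold)

    def poskey(label: str):
        ann = contact_map.get(label)
        return (ann.resseq, label) if ann else (0, label)

    clusters, singles = [], []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp, key=poskey))
        if len(members) >= 2:
            clusters.append(members)
        else:
            singles.extend(members)
    clusters.sort(key=lambda c: poskey(c[0]))
    singles.sort(key=poskey)
    return clusters, singles


def contact_map_frame(cmap: ContactMap):
    """Contact map as a DataFrame (one row per annotated residue)."""
    import pandas as pd

    rows = [{
        "residue": ann.label, "chain": ann.chain_id, "position": ann.resseq,
        "resname": ann.resname, "role": ann.role,
        "min_dist_tcr_A": ann.min_dist_tcr,
        "min_dist_peptide_A": ann.min_dist_peptide,
        "contacts_tcr": ann.contacts_tcr,
        "contacts_peptide": ann.contacts_peptide,
        "within_6A_of_tcr": ann.within_proximity_of_tcr,
    } for ann in sorted(cmap.annotations.values(),
                        key=lambda a: (a.role, a.resseq, a.icode))]
    return pd.DataFrame(rows)
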