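"""Ground-truth scenario generation: binding data, panels, toy structures.

The generator emulates the experimental design the pipeline assumes:

* per-variant ground-truth K_D and k_off, with mutant affinities satisfying
  K_D,mut = K_D,wt · exp(ΔΔG_planted / RT) exactly before noise;
* equilibrium titrations following the Langmuir isotherm over a ladder of
  8 two-fold dilutions spanning 0.1–12.8 × the WT K_D, with homoscedastic
  Gaussian response noise (default σ = 2% of Max);
* single-exponential dissociation traces with Gaussian noise (default
  σ = 1 RU);
* replicate structure (default 2 independent replicates per variant);
* planted k_on effects (k_off follows via k_off = k_on · K_D);
* additive and ε-perturbed double mutants (clusters and non-adjacent
  pairs), censored variants (K_D raised above the measurable range), and
  designed peptide-contact exclusions;
* toy multi-chain PDB coordinate sets realizing the configured
  contact / proximity / cluster geometry with >= 1 Å margins.

Everything is reproducible bit-identically from (spec, seed).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .binding import (DissociationTrace, EquilibriumSeries, Mutation,
                      VariantId)
from .errors import GenerationError
from .thermo import EnergyValue

__all__ = [
    "ResidueDesign", "ScenarioSpec", "SyntheticDataset",
    "generate_binding_data", "generate_toy_structure", "default_scenario",
    "random_structure_pdb",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class ResidueDesign:
    """Planted ground truth for one scannable MHC residue.

    ``label`` is wt residue + author position (e.g. ``R65``); ``ddg`` the
    planted change in binding energy on mutation (kcal/mol, positive =
    binding weakened); ``kon_fold`` the planted fold-decrease of k_on.
    Geometry flags drive the toy structure: a residue is either a TCR
    contact, proximal-only (within 6 Å but not 4 Å), or remote.
    """

    label: str
    ddg: float = 0.0
    kon_fold: float = 1.0
    contacts_tcr: bool = True
    contacts_peptide: bool = False
    proximal_only: bool = False
    censored: bool = False

    def __post_init__(self) -> None:
        if self.contacts_tcr and self.proximal_only:
            raise GenerationError(
                f"{self.label}: contradictory geometry (both TCR contact "
                "and proximal-only)")
        if self.kon_fold <= 0:
            raise GenerationError(f"{self.label}: kon_fold must be positive")

    @property
    def wt_aa(self) -> str:
        return self.label[0]

    @property
    def position(self) -> int:
        return int(self.label[1:])

    @property
    def new_aa(self) -> str:
        """Scan substitution: Ala, or Gly when the residue is already Ala."""
        return "G" if self.wt_aa == "A" else "A"

    @property
    def variant_label(self) -> str:
        return f"{self.label}{self.new_aa}"


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete synthetic study: ground truth plus noise model."""

    residues: tuple[ResidueDesign, ...]
    clusters: tuple[tuple[tuple[str, str], float], ...] = ()
    pairs: tuple[tuple[tuple[str, str], float], ...] = ()
    tcr: str = "TCRSIM"
    wt_kd: float = 5e-6           # M
    wt_koff: float = 0.05         # s^-1
    max_response: float = 100.0   # RU, equilibrium assay
    r0: float = 50.0              # RU, kinetic assay
    noise_eq: float = 0.02        # fraction of max_response
    noise_diss: float = 1.0       # RU
    replicates: int = 2
    n_eq_points: int = 8
    n_diss_points: int = 40
    censored_kd_factor: float = 40.0  # censored K_D = factor x top ladder conc
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_kd <= 0 or self.wt_koff <= 0:
            raise GenerationError("planted K_D and k_off must be positive")
        if self.replicates < 1:
            raise GenerationError("need at least one replicate")
        labels = [r.label for r in self.residues]
        if len(set(labels)) != len(labels):
            raise GenerationError("duplicate residue labels in scenario")
        in_cluster: set[str] = set()
        for (a, b), _eps in self.clusters:
            for m in (a, b):
                if m in in_cluster:
                    raise GenerationError(
                        f"residue {m} appears in more than one cluster "
                        "(infeasible pair geometry)")
                in_cluster.add(m)
                d = self.residue(m)
                if not d.contacts_tcr:
                    raise GenerationError(
                        f"cluster member {m} must be a TCR contact")

    @property
    def rt(self) -> float:
        return 1.987 * self.temperature / 1000.0

    @property
    def ladder(self) -> np.ndarray:
        """8 two-fold dilutions spanning 0.1–12.8 × the WT K_D."""
        return self.wt_kd * 0.1 * 2.0 ** np.arange(self.n_eq_points)

    def residue(self, label: str) -> ResidueDesign:
        for r in self.residues:
            if r.label == label:
                return r
        raise GenerationError(f"unknown residue {label!r} in scenario")

    # ---- planted truth -------------------------------------------------

    def censored_ddg_bound(self, censor_factor: float = 5.0) -> float:
        """ΔΔG lower bound the pipeline will report for a censored variant."""
        return self.rt * math.log(
            censor_factor * float(self.ladder.max()) / self.wt_kd)

    def planted_kd(self, ddg_total: float, censored: bool) -> float:
        if censored:
            return self.censored_kd_factor * float(self.ladder.max())
        return self.wt_kd * math.exp(ddg_total / self.rt)

    def variant_truth(self) -> dict[str, dict]:
        """Ground-truth binding parameters for every variant in the panel."""
        kon_wt = self.wt_koff / self.wt_kd
        truth = {"WT": {"kd": self.wt_kd, "koff": self.wt_koff,
                        "kon": kon_wt, "ddg": 0.0, "censored": False,
                        "residues": ()}}

        def add(label: str, members: Sequence[ResidueDesign],
                eps: float = 0.0) -> None:
            censored = any(m.censored for m in members)
            ddg_tot = sum(m.ddg for m in members) + eps
            kd = self.planted_kd(ddg_tot, censored)
            kon_fold = math.prod(m.kon_fold for m in members)
            kon = kon_wt / kon_fold
            truth[label] = {
                "kd": kd, "koff": kon * kd, "kon": kon, "ddg": ddg_tot,
                "censored": censored,
                "residues": tuple(m.label for m in members)}

        for r in self.residues:
            add(r.variant_label, [r])
        for (a, b), eps in tuple(self.clusters) + tuple(self.pairs):
            da, db = self.residue(a), self.residue(b)
            add(f"{da.variant_label}+{db.variant_label}", [da, db], eps)
        return truth

    def panel(self) -> list[VariantId]:
        out = [VariantId(label="WT", panel=self.tcr)]
        for r in self.residues:
            out.append(VariantId.from_mutations(
                [Mutation("mhc-heavy", r.position, r.wt_aa, r.new_aa)],
                panel=self.tcr))
        for (a, b), _eps in tuple(self.clusters) + tuple(self.pairs):
            da, db = self.residue(a), self.residue(b)
            out.append(VariantId.from_mutations(
                [Mutation("mhc-heavy", da.position, da.wt_aa, da.new_aa),
                 Mutation("mhc-heavy", db.position, db.wt_aa, db.new_aa)],
                panel=self.tcr))
        return out

    def expected_footprint(self, config) -> dict:
        """What a perfect analysis of this scenario should report.

        Applies the pipeline's inclusion rules to the planted design:
        counted entries are TCR-contacting, non-peptide-contacting
        residues/clusters with ΔΔG at or above the inclusion threshold,
        clusters counted through their double mutant, censored members
        through the deterministic ΔΔG lower bound.
        """
        clustered = {m for (a, b), _ in self.clusters for m in (a, b)}
        bound = self.censored_ddg_bound(config.censor_factor)
        entries: dict[str, float] = {}
        lower_limit = False
        for r in self.residues:
            if r.label in clustered:
                continue
            if r.contacts_peptide or not r.contacts_tcr:
                continue
            if r.censored:
                entries[r.variant_label] = bound
                lower_limit = True
                continue
            if r.ddg < config.ddg_inclusion_threshold:
                continue
            entries[r.variant_label] = r.ddg
        for (a, b), eps in self.clusters:
            da, db = self.residue(a), self.residue(b)
            label = f"{da.variant_label}+{db.variant_label}"
            ddg_tot = da.ddg + db.ddg + eps
            if any(m.censored for m in (da, db)):
                entries[label] = bound
                lower_limit = True
            elif ddg_tot >= config.ddg_inclusion_threshold:
                entries[label] = ddg_tot
        sigma_ddg = sum(entries.values())
        dg_wt = self.rt * math.log(self.wt_kd)
        total = dg_wt - config.s_assoc
        pct = 100.0 * (-sigma_ddg) / total
        kinetic = tuple(sorted(
            r.label for r in self.residues
            if not r.censored and r.kon_fold > config.kinetic_fold_threshold))
        return {"included": entries, "sigma_ddg": sigma_ddg,
                "lower_limit": lower_limit, "dg_wt": dg_wt,
                "total_calc": total, "pct_mhc": pct,
                "kinetic_footprint": kinetic,
                "censored_variants": tuple(sorted(
                    r.variant_label for r in self.residues if r.censored))}


@dataclass
class SyntheticDataset:
    """Generated observations plus the ground truth that produced them."""

    spec: ScenarioSpec
    equilibrium: list[EquilibriumSeries]
    dissociation: list[DissociationTrace]
    panel: list[VariantId]
    truth: dict[str, dict]

    def write_csvs(self, out_dir) -> dict[str, str]:
        import json
        from pathlib import Path

        from .binding import (write_dissociation_table,
                              write_equilibrium_table, write_mutant_panel)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "equilibrium": str(out / "equilibrium.csv"),
            "dissociation": str(out / "dissociation.csv"),
            "panel": str(out / "panel.csv"),
            "truth": str(out / "truth.json"),
        }
        write_equilibrium_table(self.equilibrium, paths["equilibrium"])
        write_dissociation_table(self.dissociation, paths["dissociation"])
        write_mutant_panel(self.panel, paths["panel"])
        with open(paths["truth"], "w") as fh:
            json.dump({k: {kk: (list(vv) if isinstance(vv, tuple) else vv)
                           for kk, vv in v.items()}
                       for k, v in self.truth.items()}, fh, indent=2,
                      sort_keys=True)
        return paths


def generate_binding_data(spec: ScenarioSpec,
                          seed: int | None = None) -> SyntheticDataset:
    """Simulate equilibrium series and dissociation traces for a scenario."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth = spec.variant_truth()
    ladder = spec.ladder
    eq, diss = [], []
    for label in truth:
        t = truth[label]
        for rep in range(1, spec.replicates + 1):
            resp = spec.max_response * ladder / (ladder + t["kd"])
            if spec.noise_eq > 0:
                resp = resp + rng.normal(
                    0.0, spec.noise_eq * spec.max_response, size=len(ladder))
            eq.append(EquilibriumSeries(
                variant=label, replicate=rep,
                concentrations=ladder.copy(), responses=resp,
                temperature=spec.temperature))
            times = np.linspace(0.0, 4.0 / t["koff"], spec.n_diss_points)
            decay = spec.r0 * np.exp(-t["koff"] * times)
            if spec.noise_diss > 0:
                decay = decay + rng.normal(0.0, spec.noise_diss,
                                           size=len(times))
            diss.append(DissociationTrace(
                variant=label, replicate=rep, times=times,
                responses=decay))
    return SyntheticDataset(spec=spec, equilibrium=eq, dissociation=diss,
                            panel=spec.panel(), truth=truth)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_ROLE_CHAINS = {"mhc-heavy": "A", "beta2m": "B", "peptide": "C",
                "tcr-alpha": "D", "tcr-beta": "E"}

#: geometric offsets (Å): residues sit 14 Å apart along x, well beyond every
#: threshold + 1 Å margin; designated partners sit at exact sub-threshold
#: distances from the side-chain (CB) atom.
_SPACING = 14.0
_SC_RISE = 1.5       # CB sits 1.5 Å above CA
_TCR_CONTACT = 3.5   # TCR atom above CB: contact (<= 4)
_TCR_PROXIMAL = 5.5  # proximity only (4 < d <= 6)
_PEP_CONTACT = 3.5   # peptide atom below CB
_CLUSTER_GAP = 4.0   # side-chain gap within a cluster (<= 4.5)


def _apply_transform(coord, rotation, translation):
    c = np.asarray(coord, dtype=float)
    if rotation is not None:
        c = np.asarray(rotation, dtype=float) @ c
    if translation is not None:
        c = c + np.asarray(translation, dtype=float)
    return c


def generate_toy_structure(spec: ScenarioSpec, *, rotation=None,
                           translation=None
                           ) -> tuple[str, dict[str, str]]:
    """Build a minimal PDB realizing the scenario's contact design.

    Each MHC residue gets backbone N/CA/C/O plus a single side-chain
    pseudo-atom (CB); glycine gets no CB, exercising the CA-proxy rule.
    Designated residues receive a TCR pseudo-atom 3.5 Å (contact) or 5.5 Å
    (proximity only) above the side chain and/or a peptide atom 3.5 Å
    below it; cluster partners sit with side chains 4.0 Å apart. All other
    inter-residue distances exceed the thresholds by >= 1 Å. An optional
    rigid-body (rotation, translation) is applied to every atom.

    Returns (pdb_text, role_map).
    """
    designs = list(spec.residues)
    by_label = {d.label: d for d in designs}
    secondary = {}  # cluster second member -> first member
    for (a, b), _eps in spec.clusters:
        secondary[b] = a

    # x slot per residue; cluster second members share their partner's slot
    xs: dict[str, float] = {}
    slot = 0
    for d in designs:
        if d.label in secondary:
            continue
        xs[d.label] = _SPACING * slot
        slot += 1
    for b, a in secondary.items():
        if a not in xs:
            raise GenerationError(f"cluster partner {a} missing from design")
        xs[b] = xs[a]

    chains: dict[str, list] = {c: [] for c in "ABCDE"}
    tcr_toggle = 0

    def add_residue(chain: str, resname: str, resseq: int,
                    atoms: dict[str, np.ndarray]) -> None:
        chains[chain].append((resname, resseq, {
            n: _apply_transform(c, rotation, translation)
            for n, c in atoms.items()}))

    tcr_seq = {"D": 1, "C": 1, "E": 1}
    for d in designs:
        x = xs[d.label]
        y = _CLUSTER_GAP if d.label in secondary else 0.0
        ca = np.array([x, y, 0.0])
        atoms = {
            "N": ca + np.array([-1.2, -0.9, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, -0.9, 0.0]),
            "O": ca + np.array([1.2, -2.1, 0.0]),
        }
        if d.wt_aa != "G":
            atoms["CB"] = ca + np.array([0.0, 0.0, _SC_RISE])
        add_residue("A", _ONE_TO_THREE[d.wt_aa], d.position, atoms)
        anchor = atoms.get("CB", atoms["CA"])
        if d.contacts_tcr or d.proximal_only:
            dz = _TCR_CONTACT if d.contacts_tcr else _TCR_PROXIMAL
            chain = "D" if tcr_toggle % 2 == 0 else "E"
            tcr_toggle += 1
            add_residue(chain, "GLY", tcr_seq[chain],
                        {"CA": anchor + np.array([0.0, 0.0, dz])})
            tcr_seq[chain] += 1
        if d.contacts_peptide:
            add_residue("C", "GLY", tcr_seq["C"],
                        {"CA": anchor + np.array([0.0, 0.0, -_PEP_CONTACT])})
            tcr_seq["C"] += 1

    # far-away anchors so every role has >= 1 residue with a CA
    add_residue("B", "GLY", 1, {"CA": np.array([-40.0, 40.0, -40.0])})
    if not chains["C"]:
        add_residue("C", "GLY", 1, {"CA": np.array([-30.0, -30.0, -10.0])})
    add_residue("D", "GLY", 900, {"CA": np.array([-60.0, 0.0, 40.0])})
    add_residue("E", "GLY", 900, {"CA": np.array([-60.0, 10.0, 40.0])})

    role_map = {v: k for k, v in _ROLE_CHAINS.items()}
    return _build_pdb(chains), role_map


def _build_pdb(chains: dict[str, list]) -> str:
    builder = StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    serial = 1
    for chain_id in sorted(chains):
        if not chains[chain_id]:
            continue
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        for resname, resseq, atoms in chains[chain_id]:
            builder.init_residue(resname, " ", resseq, " ")
            for name, coord in atoms.items():
                builder.init_atom(name, np.asarray(coord, dtype=float),
                                  0.0, 1.0, " ", name.center(4), serial,
                                  element=name[0])
                serial += 1
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    buf = io.StringIO()
    pdbio.save(buf)
    return buf.getvalue()


def random_structure_pdb(rng: np.random.Generator, n_mhc: int = 8,
                         n_pep: int = 3, n_tcr: int = 6,
                         box: float = 18.0) -> tuple[str, dict[str, str]]:
    """A random multi-chain coordinate set for oracle stress tests.

    Residues get a CA plus 0–3 extra side-chain pseudo-atoms, uniformly
    placed in a cube of side ``box`` Å, so contact/proximity flags take
    both values across instances.
    """
    aa = list(_ONE_TO_THREE)
    chains: dict[str, list] = {c: [] for c in "ABCDE"}

    def rand_res(resseq: int):
        base = rng.uniform(0.0, box, size=3)
        atoms = {"CA": base}
        for j in range(rng.integers(0, 4)):
            atoms[f"C{'BGD'[j]}"] = base + rng.normal(0.0, 1.5, size=3)
        name = _ONE_TO_THREE[aa[rng.integers(0, len(aa))]]
        return (name, resseq, atoms)

    for i in range(n_mhc):
        chains["A"].append(rand_res(i + 1))
    chains["B"].append(rand_res(1))
    for i in range(n_pep):
        chains["C"].append(rand_res(i + 1))
    for i in range(n_tcr):
        chains["D" if i % 2 == 0 else "E"].append(rand_res(i + 1))
    role_map = {v: k for k, v in _ROLE_CHAINS.items()}
    return _build_pdb(chains), role_map


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_scenario(seed: int = 0, *, noise_eq: float = 0.02,
                     noise_diss: float = 1.0) -> ScenarioSpec:
    """The default synthetic study: one TCR panel at the scale of a real
    HLA-A2 alanine scan (20 helix positions, three side-chain clusters,
    two non-adjacent additivity pairs, one censored variant, several
    peptide-contacting exclusions and planted k_on effects).
    """
    residues = (
        ResidueDesign("E58", 0.0, contacts_tcr=False, proximal_only=True),
        ResidueDesign("D61", 0.10),
        ResidueDesign("R65", 0.80, kon_fold=2.5),
        ResidueDesign("K66", 0.0, censored=True),
        ResidueDesign("A69", 0.45),
        ResidueDesign("H70", 0.80, kon_fold=2.2, contacts_peptide=True),
        ResidueDesign("T73", -0.30),
        ResidueDesign("H74", 0.30, kon_fold=2.1, contacts_tcr=False,
                      contacts_peptide=True),
        ResidueDesign("R75", 0.15, kon_fold=2.4, contacts_tcr=False,
                      proximal_only=True),
        ResidueDesign("V76", 0.40),
        ResidueDesign("D77", 0.0, contacts_tcr=False, contacts_peptide=True),
        ResidueDesign("T80", 0.40),
        ResidueDesign("A150", 0.40),
        ResidueDesign("H151", 0.50),
        ResidueDesign("E154", 0.50),
        ResidueDesign("Q155", 0.40, kon_fold=3.0),
        ResidueDesign("A158", 0.40, contacts_tcr=False, proximal_only=True),
        ResidueDesign("T163", 0.40),
        ResidueDesign("E166", 0.45),
        ResidueDesign("W167", 1.10, contacts_tcr=True, contacts_peptide=True),
    )
    # one sub-additive cluster (joint removal costs less than the sum,
    # as for conformationally coupled neighbours); the other two additive
    clusters = ((("V76", "T80"), 0.0),
                (("H151", "E154"), -0.55),
                (("T163", "E166"), 0.0))
    pairs = ((("R65", "Q155"), 0.0),
             (("A69", "A150"), 0.0))
    return ScenarioSpec(residues=residues, clusters=clusters, pairs=pairs,
                        noise_eq=noise_eq, noise_diss=noise_diss, seed=seed)
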