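"""Footprint classification, additivity testing and ΣΔΔG assembly.

The energetic footprint of a TCR on the MHC is the set of interface
residues whose side-chain removal measurably reduces the binding energy.
The minimum total MHC contribution (ΣΔΔG) sums the contributions of
qualifying residues — TCR-contacting, not peptide-contacting, ΔΔG at or
above the inclusion threshold — with side-chain clusters counted through
their combined double mutant (mutations of adjacent side chains need not
be additive) and censored variants entering as ΔΔG lower bounds. The
kinetic footprint collects residues whose mutation decreases k_on by
strictly more than a fold threshold, implicating them in the transition
state complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .binding import VariantId
from .config import AnalysisConfig
from .contacts import ContactMap
from .errors import DataValidationError
from .sprfit import VariantKinetics
from .thermo import (EnergyLedger, EnergyValue, LedgerEntry,
                     percent_of_total, sum_contributions,
                     total_interaction_energy)

__all__ = [
    "AdditivityResult", "FootprintReport", "PairFloor",
    "classify_energetic", "classify_kinetic", "test_additivity",
    "assemble_sigma_ddg", "peptide_scan_total",
]

# inclusion reason codes
INCLUDED_SINGLE = "included-single"
INCLUDED_CLUSTER = "included-cluster"
EXCLUDED_PEPTIDE = "excluded-peptide-contact"
EXCLUDED_BELOW = "excluded-below-threshold"
EXCLUDED_ENHANCING = "excluded-affinity-enhancing"
EXCLUDED_NO_TCR = "excluded-no-tcr-contact"
CENSORED_LOWER = "censored-lower-bound"

REASON_CODES = (INCLUDED_SINGLE, INCLUDED_CLUSTER, EXCLUDED_PEPTIDE,
                EXCLUDED_BELOW, EXCLUDED_ENHANCING, EXCLUDED_NO_TCR,
                CENSORED_LOWER)


def classify_energetic(fold_kd: float, *, bins: Sequence[float] = (1.5, 2, 4),
                       censored: bool = False) -> str:
    """Bin a K_D fold-increase for presentation.

    Default bins: <1.5 "no effect", 1.5–2, 2–4, >4 fold; affinity-enhancing
    mutations (fold < 1) get their own label. Bins are right-inclusive
    (fold 3.2 falls in (2, 4]). Censored variants land in the top bin with
    a marker. Presentation only — never affects ΣΔΔG.
    """
    edges = sorted(bins)
    if censored:
        return f">{edges[-1]:g} (censored)"
    if fold_kd < 1.0:
        return "enhancing"
    if fold_kd <= edges[0]:
        return "no effect"
    for lo, hi in zip(edges, edges[1:]):
        if fold_kd <= hi:
            return f"{lo:g}-{hi:g}"
    return f">{edges[-1]:g}"


def classify_kinetic(fold_kon_decrease: float | None, *,
                     threshold: float = 2.0,
                     censored: bool = False) -> str:
    """Kinetic-footprint membership from the k_on fold-decrease vs WT.

    Membership requires a decrease strictly greater than ``threshold``
    (exactly 2.0-fold is a non-member). Censored k_on → indeterminate.
    """
    if censored or fold_kon_decrease is None:
        return "indeterminate"
    return "kinetic" if fold_kon_decrease > threshold else "non-kinetic"


@dataclass(frozen=True)
class AdditivityResult:
    """Double-mutant additivity test: ΔΔG_ab vs ΔΔG_a + ΔΔG_b."""

    variant_a: str
    variant_b: str
    variant_ab: str
    ddg_a: EnergyValue
    ddg_b: EnergyValue
    ddg_ab: EnergyValue
    deviation: float
    sigma_deviation: float
    tolerance: float
    additive: bool

    @property
    def verdict(self) -> str:
        return "additive" if self.additive else "non-additive"


def test_additivity(ddgs: Mapping[str, EnergyValue],
                    pairs: Sequence[tuple[str, str, str]],
                    *, k: float = 2.0, floor: float = 0.3
                    ) -> tuple[list[AdditivityResult], list[str]]:
    """Test ΔΔG additivity for (single a, single b, double ab) triples.

    A pair is additive iff |ΔΔG_ab − ΔΔG_a − ΔΔG_b| <= max(k·σ_dev, floor),
    with σ_dev the quadrature of the three energy errors. Triples with a
    missing or censored member are skipped with a warning.
    """
    results, warnings = [], []
    for a, b, ab in pairs:
        missing = [v for v in (a, b, ab) if v not in ddgs]
        if missing:
            warnings.append(
                f"additivity pair ({a}, {b}): missing variant(s) "
                f"{', '.join(missing)}; skipped")
            continue
        ea, eb, eab = ddgs[a], ddgs[b], ddgs[ab]
        if any(e.is_lower_limit for e in (ea, eb, eab)):
            warnings.append(
                f"additivity pair ({a}, {b}): censored member; skipped")
            continue
        dev = eab.value - (ea.value + eb.value)
        # the WT reference cancels down to a single net term in the
        # deviation (coefficient -1 +1 +1), so the shared component is
        # counted once, not three times
        shared_net = abs(eab.sigma_shared - ea.sigma_shared -
                         eb.sigma_shared)
        sigma = math.sqrt(ea.sigma ** 2 + eb.sigma ** 2 +
                          eab.sigma ** 2 + shared_net ** 2)
        tol = max(k * sigma, floor)
        results.append(AdditivityResult(
            variant_a=a, variant_b=b, variant_ab=ab, ddg_a=ea, ddg_b=eb,
            ddg_ab=eab, deviation=dev, sigma_deviation=sigma, tolerance=tol,
            additive=abs(dev) <= tol))
    return results, warnings


@dataclass
class FootprintReport:
    """Full analysis outcome for one TCR panel."""

    panel: str
    ledger: EnergyLedger
    energetic_class: dict[str, str] = field(default_factory=dict)
    kinetic_class: dict[str, str] = field(default_factory=dict)
    additivity: list[AdditivityResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def kinetic_footprint(self) -> tuple[str, ...]:
        return tuple(sorted(v for v, c in self.kinetic_class.items()
                            if c == "kinetic"))


def _single_variant_index(panel: Sequence[VariantId]
                          ) -> dict[str, VariantId]:
    """residue label -> its single-mutant scan variant (MHC heavy chain)."""
    out = {}
    for v in panel:
        if len(v.mutations) == 1 and v.mutations[0].chain_role == "mhc-heavy":
            out[v.mutations[0].residue_label] = v
    return out


def _find_double(panel: Sequence[VariantId],
                 members: Sequence[str]) -> VariantId | None:
    target = frozenset(members)
    for v in panel:
        if len(v.mutations) == len(target) and \
                frozenset(v.residue_labels) == target:
            return v
    return None


def assemble_sigma_ddg(ddgs: Mapping[str, EnergyValue],
                       panel: Sequence[VariantId],
                       config: AnalysisConfig,
                       *,
                       contact_map: ContactMap | None = None,
                       clusters: Sequence[Sequence[str]] = (),
                       manual_peptide_exclusions: Sequence[str] = (),
                       manual_tcr_contacts: Sequence[str] | None = None,
                       dg_wt: EnergyValue | None = None,
                       peptide_total: EnergyValue | None = None,
                       panel_name: str = "") -> FootprintReport:
    """Apply the exclusion and cluster rules and assemble the energy ledger.

    ``ddgs`` maps variant labels (singles and doubles) to their ΔΔG.
    Structural flags come from ``contact_map``; when no complex structure
    is available, peptide-contact exclusions are supplied manually and —
    unless ``manual_tcr_contacts`` restricts them — all panel residues are
    treated as TCR-contacting (the analyse-everything mode used when a TCR
    has no solved complex).

    ΣΔΔG = sum over counted entries, with each identified cluster counted
    through its measured double mutant (members then contribute zero
    individually) and censored members propagating a lower-limit result.
    """
    singles = _single_variant_index(panel)
    pep_manual = set(manual_peptide_exclusions)
    tcr_manual = set(manual_tcr_contacts) if manual_tcr_contacts is not None \
        else None
    warnings: list[str] = []

    def contacts_peptide(residue: str) -> bool:
        if contact_map is not None:
            ann = contact_map.get(residue)
            if ann is not None:
                return ann.contacts_peptide
        return residue in pep_manual

    def contacts_tcr(residue: str) -> bool:
        if contact_map is not None:
            ann = contact_map.get(residue)
            if ann is not None:
                return ann.contacts_tcr
            warnings.append(f"residue {residue} absent from contact map; "
                            "treated as TCR-contacting")
            return True
        if tcr_manual is not None:
            return residue in tcr_manual
        return True

    cluster_of: dict[str, tuple[str, ...]] = {}
    for cl in clusters:
        members = tuple(cl)
        for m in members:
            cluster_of[m] = members

    entries: list[LedgerEntry] = []
    counted: list[EnergyValue] = []
    handled: set[str] = set()

    def decide_exclusion(residue: str) -> str | None:
        """Reason code if the residue is structurally excluded, else None."""
        if contacts_peptide(residue):
            return EXCLUDED_PEPTIDE
        if not contacts_tcr(residue):
            return EXCLUDED_NO_TCR
        return None

    # clusters first: the double replaces its members' singles
    unique_clusters: list[tuple[str, ...]] = []
    for cl in clusters:
        t = tuple(cl)
        if t not in unique_clusters:
            unique_clusters.append(t)
    for members in unique_clusters:
        reason_excl = None
        for m in members:
            reason_excl = reason_excl or decide_exclusion(m)
        double = _find_double(panel, members)
        if double is None or double.label not in ddgs:
            warnings.append(
                f"cluster {'+'.join(members)} has no measured double "
                "mutant; falling back to naive additivity "
                "(sum of singles)")
            for m in members:
                if m not in singles or singles[m].label not in ddgs:
                    continue
                label = singles[m].label
                ev = ddgs[label]
                reason, count = _single_decision(ev, reason_excl, config)
                entries.append(LedgerEntry(
                    variant=label, residue=m,
                    reason=reason + " (naive-additivity)", counted=count,
                    ddg=ev))
                if count:
                    counted.append(ev)
                handled.add(m)
            continue
        ev = ddgs[double.label]
        reason, count = _single_decision(ev, reason_excl, config,
                                         cluster=True)
        entries.append(LedgerEntry(
            variant=double.label, residue="+".join(members),
            reason=reason, counted=count, ddg=ev))
        if count:
            counted.append(ev)
        for m in members:
            handled.add(m)
            if m in singles and singles[m].label in ddgs:
                entries.append(LedgerEntry(
                    variant=singles[m].label, residue=m,
                    reason=INCLUDED_CLUSTER, counted=False,
                    ddg=ddgs[singles[m].label]))

    # remaining singles
    for residue, variant in singles.items():
        if residue in handled or variant.label not in ddgs:
            continue
        ev = ddgs[variant.label]
        reason, count = _single_decision(
            ev, decide_exclusion(residue), config)
        entries.append(LedgerEntry(variant=variant.label, residue=residue,
                                   reason=reason, counted=count, ddg=ev))
        if count:
            counted.append(ev)

    entries.sort(key=lambda e: e.variant)
    ledger = EnergyLedger(panel=panel_name, entries=entries, dg_wt=dg_wt)
    ledger.s_assoc = EnergyValue(config.s_assoc, config.s_assoc_sigma,
                                 provenance="config")
    if counted:
        sig = sum_contributions(counted, provenance="sigma_ddg")
        ledger.sigma_ddg = sig
        ledger.mhc_contribution = -sig
    if dg_wt is not None:
        ledger.total_calc = total_interaction_energy(
            dg_wt, ledger.s_assoc, error_mode=config.total_error_mode)
        if ledger.mhc_contribution is not None:
            ledger.pct_mhc_calc = percent_of_total(
                ledger.mhc_contribution, ledger.total_calc)
    if peptide_total is not None and ledger.mhc_contribution is not None:
        ledger.total_exp = sum_contributions(
            [ledger.mhc_contribution, peptide_total],
            provenance="total_exp")
        ledger.pct_mhc_exp = percent_of_total(
            ledger.mhc_contribution, ledger.total_exp)
    return FootprintReport(panel=panel_name, ledger=ledger,
                           warnings=warnings)


def _single_decision(ev: EnergyValue, exclusion: str | None,
                     config: AnalysisConfig,
                     cluster: bool = False) -> tuple[str, bool]:
    """(reason code, counted?) for one candidate entry."""
    if exclusion is not None:
        return exclusion, False
    if ev.is_lower_limit:
        return CENSORED_LOWER, True
    if ev.value < 0:
        if config.include_enhancing:
            return (INCLUDED_CLUSTER if cluster else INCLUDED_SINGLE), True
        return EXCLUDED_ENHANCING, False
    if ev.value < config.ddg_inclusion_threshold:
        return EXCLUDED_BELOW, False
    return (INCLUDED_CLUSTER if cluster else INCLUDED_SINGLE), True


@dataclass(frozen=True)
class PairFloor:
    """A conservative combined ΔΔG floor for two adjacent peptide residues.

    When one member of an adjacent pair is unmeasurable, their joint
    contribution is taken to be at least ``floor_ddg`` (kcal/mol) — i.e.
    a contribution of at most −floor_ddg.
    """

    residue_a: str
    residue_b: str
    floor_ddg: float


def peptide_scan_total(ddgs: Mapping[str, EnergyValue],
                       tcr_contacting: Sequence[str],
                       pair_floors: Sequence[PairFloor] = ()
                       ) -> tuple[EnergyValue, list[str]]:
    """Total contribution of TCR-contacting peptide side chains.

    Sums contributions (−ΔΔG) over TCR-contacting peptide residues. A
    declared adjacent pair with a censored (or missing) member enters as
    its floor instead of its members' individual values; a censored
    residue covered by no pair floor is excluded with a warning (the
    conservative choice). The result is flagged as a lower limit whenever
    a floor or censoring was involved.
    """
    warnings: list[str] = []
    paired: set[str] = set()
    members: list[EnergyValue] = []
    lower = False
    for pf in pair_floors:
        pair = (pf.residue_a, pf.residue_b)
        evs = [ddgs.get(r) for r in pair]
        unmeasurable = any(e is None or e.is_lower_limit for e in evs)
        if unmeasurable:
            paired.update(pair)
            members.append(EnergyValue(
                value=-pf.floor_ddg, bound="lower",
                provenance=f"pair-floor {pf.residue_a}+{pf.residue_b}"))
            lower = True
    for residue in tcr_contacting:
        if residue in paired:
            continue
        ev = ddgs.get(residue)
        if ev is None:
            warnings.append(f"peptide residue {residue}: no ΔΔG; skipped")
            continue
        if ev.is_lower_limit:
            warnings.append(
                f"peptide residue {residue}: unmeasurable with no pair "
                "floor; excluded (conservative)")
            lower = True
            continue
        members.append(-ev)
    if not members:
        raise DataValidationError("no measurable peptide contributions")
    total = sum_contributions(members, provenance="peptide_scan_total")
    if lower and not total.is_lower_limit:
        total = EnergyValue(value=total.value, sigma=total.sigma,
                            sigma_shared=total.sigma_shared, bound="lower",
                            provenance=total.provenance)
    return total, warnings


def classify_panel(report: FootprintReport,
                   kinetics: Mapping[str, VariantKinetics],
                   config: AnalysisConfig) -> None:
    """Attach energetic and kinetic class labels for every mutant variant."""
    for label, k in kinetics.items():
        if label == "WT":
            continue
        if k.censored:
            report.energetic_class[label] = classify_energetic(
                math.inf, censored=True)
            report.kinetic_class[label] = classify_kinetic(
                None, censored=True)
        else:
            report.energetic_class[label] = classify_energetic(k.fold_kd)
            report.kinetic_class[label] = classify_kinetic(
                k.fold_kon_decrease,
                threshold=config.kinetic_fold_threshold)
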