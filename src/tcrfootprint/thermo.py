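"""Binding free-energy arithmetic with error propagation.

Conventions
-----------
* ΔG° = RT ln K_D with K_D in molar (negative for sub-molar K_D).
* ΔΔG = RT ln(K_D,mut / K_D,wt): positive when the mutation weakens binding.
  A residue's contribution to the binding energy is −ΔΔG.
* Total interaction energy: Total_calc = ΔG° − S_assoc, where S_assoc
  (default 5 ± 1 kcal/mol) is the unfavorable association entropy at the
  1 M standard state.
* Uncertainties combine in quadrature everywhere except Total_calc, whose
  default is linear addition σ(ΔG°) + σ(S_assoc). Linear addition is the
  only rule that reproduces the ±1.12 / ±1.06 totals printed alongside
  ΔG° errors of ±0.12 / ±0.06 with S_assoc = 5 ± 1; it is configurable
  (``total_error_mode``) because quadrature is the more common convention.

Correlated errors
-----------------
Every per-variant ΔΔG in a panel shares the same WT K_D estimate, so their
errors are not independent: summing many ΔΔG values in quadrature would
understate the ΣΔΔG error. :class:`EnergyValue` therefore carries the
WT-derived error component separately (``sigma_shared``);
:func:`sum_contributions` combines independent components in quadrature and
shared components linearly. Values built with a plain uncertainty
(``sigma_shared=0``) reduce to pure quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import DataValidationError

__all__ = [
    "EnergyValue", "EnergyLedger", "LedgerEntry", "delta_g_standard", "ddg",
    "total_interaction_energy", "percent_of_total", "sum_contributions",
]


@dataclass(frozen=True)
class EnergyValue:
    """An energy in kcal/mol with uncertainty and bound semantics.

    ``bound == 'point'`` is an ordinary measurement; ``bound == 'lower'``
    marks a lower limit of magnitude (e.g. ΔΔG ≥ 3.16 kcal/mol for a variant
    whose affinity was too weak to measure, or a ΣΔΔG containing one).

    ``sigma`` is the error component independent between variants;
    ``sigma_shared`` the component correlated across a panel (it stems from
    the common WT reference measurement).
    """

    value: float
    sigma: float = 0.0
    bound: str = "point"
    sigma_shared: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_shared < 0:
            raise DataValidationError("uncertainty must be non-negative")
        if self.bound not in ("point", "lower"):
            raise DataValidationError(
                f"bound must be 'point' or 'lower', got {self.bound!r}")

    @property
    def uncertainty(self) -> float:
        """Total 1σ uncertainty (independent ⊕ shared, quadrature)."""
        return math.hypot(self.sigma, self.sigma_shared)

    @property
    def is_lower_limit(self) -> bool:
        return self.bound == "lower"

    def __neg__(self) -> "EnergyValue":
        return replace(self, value=-self.value)

    def display(self) -> str:
        from .binding import fmt_energy
        prefix = ">" if self.is_lower_limit else ""
        if self.uncertainty > 0:
            return (f"{prefix}{fmt_energy(self.value)} ± "
                    f"{fmt_energy(self.uncertainty)}")
        return f"{prefix}{fmt_energy(self.value)}"


def delta_g_standard(kd: float, rt: float, kd_sigma: float = 0.0,
                     provenance: str = "") -> EnergyValue:
    """ΔG° = RT ln K_D (K_D in molar); σ = RT·(σ_KD/K_D)."""
    if kd <= 0:
        raise DataValidationError("K_D must be positive")
    return EnergyValue(value=rt * math.log(kd), sigma=rt * kd_sigma / kd,
                       provenance=provenance or "delta_g_standard")


def ddg(kd_mut: float, kd_wt: float, rt: float,
        sigma_mut: float = 0.0, sigma_wt: float = 0.0,
        mut_is_bound: bool = False, provenance: str = "") -> EnergyValue:
    """ΔΔG = RT ln(K_D,mut / K_D,wt).

    For a censored mutant pass its K_D lower bound as ``kd_mut`` with
    ``mut_is_bound=True``; the result is a lower-limit ΔΔG. The WT-derived
    error term RT·(σ_wt/K_D,wt) is stored as the shared component.
    """
    if kd_mut <= 0 or kd_wt <= 0:
        raise DataValidationError("affinities must be positive")
    value = rt * math.log(kd_mut / kd_wt)
    return EnergyValue(
        value=value,
        sigma=0.0 if mut_is_bound else rt * sigma_mut / kd_mut,
        sigma_shared=rt * sigma_wt / kd_wt,
        bound="lower" if mut_is_bound else "point",
        provenance=provenance or "ddg")


def total_interaction_energy(dg: EnergyValue, s_assoc: EnergyValue,
                             error_mode: str = "linear") -> EnergyValue:
    """Total = ΔG° − S_assoc (S_assoc > 0, the association entropy)."""
    if s_assoc.value < 0:
        raise DataValidationError("association entropy must be >= 0")
    if error_mode == "linear":
        sigma = dg.uncertainty + s_assoc.uncertainty
    elif error_mode == "quadrature":
        sigma = math.hypot(dg.uncertainty, s_assoc.uncertainty)
    else:
        raise ValueError(f"unknown error_mode {error_mode!r}")
    return EnergyValue(value=dg.value - s_assoc.value, sigma=sigma,
                       bound=dg.bound, provenance="total_interaction_energy")


def percent_of_total(contribution: EnergyValue,
                     total: EnergyValue) -> tuple[float, float]:
    """100 × contribution/total with relative errors combined in quadrature.

    Both energies must share the sign convention (negative = favorable).
    Returns (percent, sigma_percent), unrounded.
    """
    if total.value == 0:
        raise DataValidationError("total interaction energy must be nonzero")
    if contribution.value * total.value < 0:
        raise DataValidationError(
            "contribution and total must have the same sign")
    pct = 100.0 * contribution.value / total.value
    rel = math.hypot(
        contribution.uncertainty / abs(contribution.value)
        if contribution.value else 0.0,
        total.uncertainty / abs(total.value))
    return pct, abs(pct) * rel


def sum_contributions(values: Sequence[EnergyValue],
                      provenance: str = "sum_contributions") -> EnergyValue:
    """Sum of energies; independent σ in quadrature, shared σ linearly.

    Any lower-limit member makes the sum a lower limit of magnitude.
    """
    values = list(values)
    if not values:
        raise DataValidationError("cannot sum an empty contribution list")
    total = sum(v.value for v in values)
    sigma_ind = math.sqrt(sum(v.sigma ** 2 for v in values))
    sigma_shared = sum(v.sigma_shared for v in values)
    bound = "lower" if any(v.is_lower_limit for v in values) else "point"
    return EnergyValue(value=total, sigma=sigma_ind,
                       sigma_shared=sigma_shared, bound=bound,
                       provenance=provenance)


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

def _ev_to_dict(ev: EnergyValue | None) -> dict | None:
    if ev is None:
        return None
    return {"value": ev.value, "sigma": ev.sigma,
            "sigma_shared": ev.sigma_shared, "bound": ev.bound,
            "provenance": ev.provenance}


def _ev_from_dict(doc: dict | None) -> EnergyValue | None:
    if doc is None:
        return None
    return EnergyValue(**doc)


@dataclass(frozen=True)
class LedgerEntry:
    """Per-variant ΔΔG with its ΣΔΔG inclusion decision."""

    variant: str
    ddg: EnergyValue
    residue: str | None = None
    reason: str = ""
    counted: bool = False

    @property
    def contribution(self) -> EnergyValue:
        """Contribution to the binding energy, −ΔΔG."""
        return -self.ddg


@dataclass
class EnergyLedger:
    """Aggregate energy decomposition for one TCR panel."""

    panel: str = ""
    entries: list[LedgerEntry] = field(default_factory=list)
    dg_wt: EnergyValue | None = None
    sigma_ddg: EnergyValue | None = None          # ΣΔΔG (positive scale)
    mhc_contribution: EnergyValue | None = None   # −ΣΔΔG
    total_calc: EnergyValue | None = None
    total_exp: EnergyValue | None = None
    pct_mhc_calc: tuple[float, float] | None = None
    pct_mhc_exp: tuple[float, float] | None = None
    s_assoc: EnergyValue | None = None

    def entry(self, variant: str) -> LedgerEntry:
        for e in self.entries:
            if e.variant == variant:
                return e
        raise KeyError(variant)

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "entries": [
                {"variant": e.variant, "residue": e.residue,
                 "reason": e.reason, "counted": e.counted,
                 "ddg": _ev_to_dict(e.ddg)} for e in self.entries],
            "dg_wt": _ev_to_dict(self.dg_wt),
            "sigma_ddg": _ev_to_dict(self.sigma_ddg),
            "mhc_contribution": _ev_to_dict(self.mhc_contribution),
            "total_calc": _ev_to_dict(self.total_calc),
            "total_exp": _ev_to_dict(self.total_exp),
            "pct_mhc_calc": list(self.pct_mhc_calc)
                if self.pct_mhc_calc else None,
            "pct_mhc_exp": list(self.pct_mhc_exp)
                if self.pct_mhc_exp else None,
            "s_assoc": _ev_to_dict(self.s_assoc),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EnergyLedger":
        return cls(
            panel=doc["panel"],
            entries=[LedgerEntry(variant=e["variant"], residue=e["residue"],
                                 reason=e["reason"], counted=e["counted"],
                                 ddg=_ev_from_dict(e["ddg"]))
                     for e in doc["entries"]],
            dg_wt=_ev_from_dict(doc["dg_wt"]),
            sigma_ddg=_ev_from_dict(doc["sigma_ddg"]),
            mhc_contribution=_ev_from_dict(doc["mhc_contribution"]),
            total_calc=_ev_from_dict(doc["total_calc"]),
            total_exp=_ev_from_dict(doc["total_exp"]),
            pct_mhc_calc=tuple(doc["pct_mhc_calc"])
                if doc["pct_mhc_calc"] else None,
            pct_mhc_exp=tuple(doc["pct_mhc_exp"])
                if doc["pct_mhc_exp"] else None,
            s_assoc=_ev_from_dict(doc["s_assoc"]),
        )
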