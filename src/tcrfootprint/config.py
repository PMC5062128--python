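"""Analysis configuration.

All tunable thresholds of the pipeline live in one dataclass with the
defaults used throughout: SPR experiments at 25 °C (RT = 0.592 kcal/mol),
a 4 Å heavy-atom contact threshold, a 6 Å proximity threshold for selecting
mutable residues, a 4.5 Å side-chain adjacency threshold for clusters, a
strict >2-fold k_on criterion for the kinetic footprint, and an association
entropy of 5 ± 1 kcal/mol used to convert ΔG° into a total interaction
energy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError

#: Gas constant in cal mol^-1 K^-1.
GAS_CONSTANT_CAL = 1.987


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and physical constants driving the analysis.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin (default 298.15 K, i.e. 25 °C).
    gas_constant_cal : float
        Gas constant R in cal mol^-1 K^-1.
    s_assoc, s_assoc_sigma : float
        Association entropy penalty (kcal/mol) subtracted from ΔG° to
        estimate the total interaction energy, with its uncertainty.
    contact_threshold : float
        Heavy-atom distance (Å) below or at which two residues are in
        contact.
    proximity_threshold : float
        Distance (Å) defining "within proximity of the TCR" (residue
        selection for the scan).
    adjacency_threshold : float
        Min side-chain heavy-atom distance (Å) at or below which two
        residues count as adjacent (cluster detection).
    kinetic_fold_threshold : float
        A mutation is in the kinetic footprint iff it decreases k_on by
        strictly more than this fold factor.
    ddg_inclusion_threshold : float
        Minimum ΔΔG (kcal/mol) for a mutation to count as reducing the
        binding energy (ΣΔΔG inclusion).
    additivity_k, additivity_floor : float
        A double mutant is additive iff |deviation| <= max(k·σ_dev, floor).
    censor_factor : float
        A fitted K_D above censor_factor × the top tested concentration is
        reported as not measurable, with K_D >= censor_factor × top.
    include_enhancing : bool
        Whether affinity-enhancing mutations (ΔΔG < 0) enter ΣΔΔG.
    total_error_mode : str
        'linear' adds σ(ΔG°) and σ(S_assoc) arithmetically when forming the
        total interaction energy; 'quadrature' combines them in quadrature.
    seed : int
        Seed for any stochastic stage (simulation).
    """

    temperature: float = 298.15
    gas_constant_cal: float = GAS_CONSTANT_CAL
    s_assoc: float = 5.0
    s_assoc_sigma: float = 1.0
    contact_threshold: float = 4.0
    proximity_threshold: float = 6.0
    adjacency_threshold: float = 4.5
    kinetic_fold_threshold: float = 2.0
    ddg_inclusion_threshold: float = 0.25
    additivity_k: float = 2.0
    additivity_floor: float = 0.3
    censor_factor: float = 5.0
    include_enhancing: bool = False
    total_error_mode: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "temperature", "gas_constant_cal", "s_assoc", "contact_threshold",
            "proximity_threshold", "adjacency_threshold",
            "kinetic_fold_threshold", "ddg_inclusion_threshold",
            "additivity_k", "additivity_floor", "censor_factor",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"config field {name!r} must be positive")
        if self.s_assoc_sigma < 0:
            raise ConfigError("s_assoc_sigma must be non-negative")
        if self.total_error_mode not in ("linear", "quadrature"):
            raise ConfigError(
                "total_error_mode must be 'linear' or 'quadrature'")

    @property
    def rt(self) -> float:
        """RT in kcal mol^-1 (0.592 at 298.15 K)."""
        return self.gas_constant_cal * self.temperature / 1000.0

    @classmethod
    def from_dict(cls, doc: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(
                f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**doc)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = json.load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("config JSON must be an object")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = AnalysisConfig()
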