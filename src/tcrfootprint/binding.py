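"""Data model and file I/O for SPR observations and mutant panels.

CSV layouts
-----------
equilibrium : ``variant, replicate, concentration_M, response_RU``
    (the concentration column may instead be ``concentration_uM`` or
    ``concentration_nM``; values are converted to molar on read)
dissociation : ``variant, replicate, time_s, response_RU``
panel : ``variant, chain_role, position, wt_aa, new_aa`` — a double mutant
    spans two rows sharing a label such as ``V76A+T80A``.

Concentrations are stored in molar internally because ΔG° = RT ln K_D
requires K_D expressed in M.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, ParseError, SchemaError

CHAIN_ROLES = ("tcr-alpha", "tcr-beta", "mhc-heavy", "beta2m", "peptide")

_CONC_UNITS = {"concentration_M": 1.0, "concentration_uM": 1e-6,
               "concentration_nM": 1e-9}


@dataclass(frozen=True)
class Mutation:
    """A single point substitution on one chain of the complex."""

    chain_role: str
    position: int
    wt_aa: str
    new_aa: str
    icode: str = ""

    def __post_init__(self) -> None:
        if self.chain_role not in CHAIN_ROLES:
            raise DataValidationError(
                f"unknown chain role {self.chain_role!r}; "
                f"expected one of {CHAIN_ROLES}")
        for attr in ("wt_aa", "new_aa"):
            aa = getattr(self, attr)
            if len(aa) != 1 or not aa.isalpha():
                raise DataValidationError(
                    f"{attr} must be a 1-letter amino-acid code, got {aa!r}")

    @property
    def residue_label(self) -> str:
        """Residue key, e.g. ``R65`` (wt residue + author position)."""
        return f"{self.wt_aa}{self.position}{self.icode}"

    @property
    def label(self) -> str:
        """Mutation label, e.g. ``R65A``."""
        return f"{self.residue_label}{self.new_aa}"


@dataclass(frozen=True)
class VariantId:
    """A pMHC variant: WT or one/two substitutions, e.g. ``V76A+T80A``."""

    label: str
    mutations: tuple[Mutation, ...] = ()
    panel: str = ""

    def __post_init__(self) -> None:
        keys = [(m.chain_role, m.position, m.icode) for m in self.mutations]
        if len(set(keys)) != len(keys):
            raise DataValidationError(
                f"variant {self.label!r} mutates the same position twice")

    @classmethod
    def from_mutations(cls, mutations: Sequence[Mutation],
                       panel: str = "") -> "VariantId":
        muts = tuple(sorted(mutations,
                            key=lambda m: (m.chain_role, m.position, m.icode)))
        label = "+".join(m.label for m in muts) if muts else "WT"
        return cls(label=label, mutations=muts, panel=panel)

    @property
    def is_wt(self) -> bool:
        return not self.mutations

    @property
    def is_scan(self) -> bool:
        """True if every substitution is to Ala or Gly (side-chain removal)."""
        return all(m.new_aa in ("A", "G") for m in self.mutations)

    @property
    def nonstandard_substitutions(self) -> tuple[Mutation, ...]:
        """Substitutions to residues other than Ala/Gly (permitted, flagged)."""
        return tuple(m for m in self.mutations if m.new_aa not in ("A", "G"))

    @property
    def residue_labels(self) -> tuple[str, ...]:
        return tuple(m.residue_label for m in self.mutations)


def _validated_xy(x: np.ndarray, y: np.ndarray, what: str,
                  xname: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError(f"{what}: x and y must be equal-length 1-D")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataValidationError(f"{what}: non-finite values")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise DataValidationError(
            f"{what}: {xname} values must be distinct (strictly increasing "
            "after sort)")
    return x, y


@dataclass
class EquilibriumSeries:
    """Equilibrium binding of graded analyte concentrations, one replicate.

    ``responses[i]`` is the steady-state response (RU) at injected analyte
    concentration ``concentrations[i]`` (molar). Points are sorted by
    concentration on construction.
    """

    variant: str
    replicate: int
    concentrations: np.ndarray
    responses: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        self.concentrations, self.responses = _validated_xy(
            self.concentrations, self.responses,
            f"equilibrium series {self.variant}/{self.replicate}",
            "concentration")
        if np.any(self.concentrations <= 0):
            raise DataValidationError(
                f"equilibrium series {self.variant}/{self.replicate}: "
                "concentrations must be strictly positive")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class DissociationTrace:
    """Response decay after the analyte injection ends, one replicate.

    ``skip_initial`` trims the first seconds from the fit window (bulk
    refractive-index artifacts right after the injection stop).
    """

    variant: str
    replicate: int
    times: np.ndarray
    responses: np.ndarray
    skip_initial: float = 0.0

    def __post_init__(self) -> None:
        self.times, self.responses = _validated_xy(
            self.times, self.responses,
            f"dissociation trace {self.variant}/{self.replicate}", "time")
        if np.any(self.times < 0):
            raise DataValidationError(
                f"dissociation trace {self.variant}/{self.replicate}: "
                "times must be non-negative")
        if self.skip_initial < 0:
            raise DataValidationError("skip_initial must be non-negative")

    def window(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, responses) inside the fit window."""
        keep = self.times >= self.skip_initial
        return self.times[keep], self.responses[keep]

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str],
                numeric: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, header required") from None
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} "
                f"at line(s) {lines}")
        if df[col].isna().any():
            lines = ", ".join(
                str(i + 2) for i in df.index[df[col].isna()][:5])
            raise ParseError(
                f"{path}: empty cell in column {col!r} at line(s) {lines}")
        # to_numeric only screens for errors; the conversion itself goes
        # through numpy's correctly-rounded parser so round-trips are exact
        df[col] = df[col].to_numpy(dtype=str).astype(float)
    return df


def _conc_column(df_columns: Iterable[str], path) -> tuple[str, float]:
    for name, scale in _CONC_UNITS.items():
        if name in df_columns:
            return name, scale
    raise SchemaError(
        f"{path}: missing required column 'concentration_M' "
        "(or concentration_uM / concentration_nM)")


def read_equilibrium_table(path: str | Path,
                           temperature: float = 298.15
                           ) -> list[EquilibriumSeries]:
    """Read an equilibrium binding CSV into per-(variant, replicate) series."""
    head = pd.read_csv(path, nrows=0)
    col, scale = _conc_column([c.strip() for c in head.columns], path)
    df = _read_table(path, ["variant", "replicate", col, "response_RU"],
                     ["replicate", col, "response_RU"])
    df["_conc_M"] = df[col] * scale
    if np.any(df["_conc_M"] <= 0):
        raise DataValidationError(
            f"{path}: non-positive concentration(s)")
    dup = df.duplicated(subset=["variant", "replicate", "_conc_M"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise DataValidationError(
            f"{path}: duplicate (variant, replicate, concentration) "
            f"at line {line}")
    out = []
    for (variant, replicate), grp in df.groupby(
            ["variant", "replicate"], sort=True):
        out.append(EquilibriumSeries(
            variant=str(variant), replicate=int(replicate),
            concentrations=grp["_conc_M"].to_numpy(),
            responses=grp["response_RU"].to_numpy(),
            temperature=temperature))
    return out


def write_equilibrium_table(series: Sequence[EquilibriumSeries],
                            path: str | Path) -> None:
    rows = []
    for s in series:
        for c, r in zip(s.concentrations, s.responses):
            rows.append((s.variant, s.replicate, repr(float(c)),
                         repr(float(r))))
    df = pd.DataFrame(rows, columns=["variant", "replicate",
                                     "concentration_M", "response_RU"])
    df.to_csv(path, index=False)


def read_dissociation_table(path: str | Path,
                            skip_initial: float = 0.0
                            ) -> list[DissociationTrace]:
    """Read a dissociation-phase CSV into per-(variant, replicate) traces."""
    df = _read_table(path, ["variant", "replicate", "time_s", "response_RU"],
                     ["replicate", "time_s", "response_RU"])
    dup = df.duplicated(subset=["variant", "replicate", "time_s"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise DataValidationError(
            f"{path}: duplicate (variant, replicate, time) at line {line}")
    out = []
    for (variant, replicate), grp in df.groupby(
            ["variant", "replicate"], sort=True):
        out.append(DissociationTrace(
            variant=str(variant), replicate=int(replicate),
            times=grp["time_s"].to_numpy(),
            responses=grp["response_RU"].to_numpy(),
            skip_initial=skip_initial))
    return out


def write_dissociation_table(traces: Sequence[DissociationTrace],
                             path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, r in zip(tr.times, tr.responses):
            rows.append((tr.variant, tr.replicate, repr(float(t)),
                         repr(float(r))))
    df = pd.DataFrame(rows, columns=["variant", "replicate", "time_s",
                                     "response_RU"])
    df.to_csv(path, index=False)


def read_mutant_panel(path: str | Path, panel: str = "",
                      synthesize_wt: bool = True) -> list[VariantId]:
    """Read the mutant panel CSV; double mutants span rows sharing a label."""
    df = _read_table(path, ["variant", "chain_role", "position",
                            "wt_aa", "new_aa"], [])
    if df.empty:
        raise DataValidationError(f"{path}: no variants")
    variants: list[VariantId] = []
    seen_wt = False
    for label, grp in df.groupby("variant", sort=False):
        label = str(label)
        if label.upper() == "WT":
            seen_wt = True
            variants.append(VariantId(label="WT", panel=panel))
            continue
        try:
            muts = tuple(
                Mutation(chain_role=str(row.chain_role).strip(),
                         position=int(float(row.position)),
                         wt_aa=str(row.wt_aa).strip(),
                         new_aa=str(row.new_aa).strip())
                for row in grp.itertuples())
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: bad mutation row for variant {label!r}: {exc}"
            ) from exc
        variants.append(VariantId(label=label, mutations=muts, panel=panel))
    if not seen_wt and synthesize_wt:
        variants.insert(0, VariantId(label="WT", panel=panel))
    return variants


def write_mutant_panel(variants: Sequence[VariantId],
                       path: str | Path) -> None:
    rows = []
    for v in variants:
        if v.is_wt:
            rows.append((v.label, "", "", "", ""))
        for m in v.mutations:
            rows.append((v.label, m.chain_role, m.position, m.wt_aa,
                         m.new_aa))
    pd.DataFrame(rows, columns=["variant", "chain_role", "position",
                                "wt_aa", "new_aa"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results serialization (ledger -> CSV/JSON)
# ---------------------------------------------------------------------------

def fmt_energy(value: float) -> str:
    """Display rounding for energies: 2 decimals, trailing zeros stripped."""
    s = f"{value:.2f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def fmt_percent(value: float) -> int:
    """Whole-percent display rounding (half away from zero)."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


def write_results_table(ledger, path: str | Path, format: str = "csv",
                        kinetics=None) -> None:
    """Serialize an :class:`~tcrfootprint.thermo.EnergyLedger`.

    ``format='csv'`` writes one display row per variant (censored K_D cells
    rendered ``n.m.`` with a machine-readable bound column); ``format='json'``
    dumps the full-precision ledger, which round-trips bit-identically via
    :meth:`EnergyLedger.from_dict`.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(ledger.to_dict(), fh, indent=2, sort_keys=True)
        return
    if format != "csv":
        raise ValueError(f"unknown results format {format!r}")
    kin = kinetics or {}
    rows = []
    for entry in ledger.entries:
        k = kin.get(entry.variant)
        censored = entry.ddg.bound == "lower"
        kd_disp = "n.m." if (k is not None and k.censored) else (
            "" if k is None else repr(float(k.kd)))
        rows.append({
            "variant": entry.variant,
            "residue": entry.residue or "",
            "kd_M": kd_disp,
            "kd_lower_bound_M": (
                repr(float(k.kd_lower_bound)) if k is not None and k.censored
                else ""),
            "koff_s": "" if k is None or k.koff is None else repr(float(k.koff)),
            "kon_Ms": "" if k is None or k.kon is None else repr(float(k.kon)),
            "fold_kd": "" if k is None or k.fold_kd is None else
                       repr(float(k.fold_kd)),
            "fold_kon_decrease": "" if k is None or k.fold_kon_decrease is None
                                 else repr(float(k.fold_kon_decrease)),
            "ddg_kcal_mol": repr(float(entry.ddg.value)),
            "ddg_sigma": repr(float(entry.ddg.uncertainty)),
            "ddg_display": (">" if censored else "") + fmt_energy(
                entry.ddg.value),
            "bound": entry.ddg.bound,
            "reason": entry.reason,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
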