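"""End-to-end orchestration: fits → thermodynamics → contacts → footprint.

A single JSON config document drives a run. Top-level sections:

``analysis``
    scalar overrides of :class:`~tcrfootprint.config.AnalysisConfig`;
``inputs``
    paths to real data: ``equilibrium``, ``dissociation``, ``panel`` CSVs
    plus an optional ``structure`` PDB with its ``role_map``;
``simulate``
    a synthetic scenario instead of real inputs (mutually exclusive with
    ``inputs``); either ``{"default": true}`` or explicit residue designs;
``footprint``
    manual ``clusters`` / ``peptide_exclusions`` / ``tcr_contacts`` (used
    when no structure is available), ``additivity_pairs`` and an optional
    ``peptide_scan`` block.

Outputs written to the run directory: kinetics.csv, contact_map.csv (when
a structure is present), ledger.json, summary.csv, report.md and
manifest.json. Machine-readable outputs are byte-identical for identical
config + seed (the manifest, which carries a timestamp, is excluded from
that guarantee).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .binding import (read_dissociation_table, read_equilibrium_table,
                      read_mutant_panel, write_results_table)
from .config import AnalysisConfig
from .contacts import annotate_contacts, contact_map_frame, find_clusters, \
    parse_structure
from .errors import ConfigError, TcrFootprintError
from .footprint import (FootprintReport, PairFloor, assemble_sigma_ddg,
                        classify_panel, peptide_scan_total, test_additivity)
from .simulate import (ResidueDesign, ScenarioSpec, default_scenario,
                       generate_binding_data, generate_toy_structure)
from .sprfit import aggregate_replicates, fit_dissociation, fit_equilibrium, \
    with_fold_changes
from .thermo import EnergyValue, ddg as ddg_op, delta_g_standard

logger = logging.getLogger("tcrfootprint")


@dataclass
class RunManifest:
    """Provenance record emitted next to every set of outputs."""

    config: dict
    seed: int | None
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scenario_from_config(doc: dict, seed: int | None) -> ScenarioSpec:
    doc = dict(doc)
    if doc.pop("default", False):
        spec = default_scenario(seed if seed is not None else 0)
        return spec
    residues = tuple(ResidueDesign(**r) for r in doc.pop("residues", []))
    clusters = tuple((tuple(c["members"]), float(c.get("epsilon", 0.0)))
                     for c in doc.pop("clusters", []))
    pairs = tuple((tuple(p["members"]), float(p.get("epsilon", 0.0)))
                  for p in doc.pop("pairs", []))
    if seed is not None:
        doc["seed"] = seed
    return ScenarioSpec(residues=residues, clusters=clusters, pairs=pairs,
                        **doc)


def fit_panel(equilibrium, dissociation, config: AnalysisConfig):
    """Fit every series/trace and aggregate replicates per variant."""
    eq_by_variant: dict[str, list] = {}
    for series in equilibrium:
        fit = fit_equilibrium(series, censor_factor=config.censor_factor)
        eq_by_variant.setdefault(series.variant, []).append(fit)
    diss_by_variant: dict[str, list] = {}
    for trace in dissociation:
        fit = fit_dissociation(trace)
        diss_by_variant.setdefault(trace.variant, []).append(fit)
    results = {}
    for variant, fits in eq_by_variant.items():
        results[variant] = aggregate_replicates(
            variant, fits, diss_by_variant.get(variant, ()))
    return with_fold_changes(results)


def ddg_table(kinetics, config: AnalysisConfig) -> dict[str, EnergyValue]:
    """Per-variant ΔΔG vs WT (lower bounds for censored variants)."""
    wt = kinetics["WT"]
    out: dict[str, EnergyValue] = {}
    for label, k in kinetics.items():
        if label == "WT":
            continue
        if k.censored:
            out[label] = ddg_op(k.kd_lower_bound, wt.kd, config.rt,
                                sigma_wt=wt.kd_sigma, mut_is_bound=True,
                                provenance=label)
        else:
            out[label] = ddg_op(k.kd, wt.kd, config.rt,
                                sigma_mut=k.kd_sigma, sigma_wt=wt.kd_sigma,
                                provenance=label)
    return out


def kinetics_frame(kinetics) -> pd.DataFrame:
    rows = []
    for label in sorted(kinetics):
        k = kinetics[label]
        rows.append({
            "variant": label, "n_replicates": k.n_replicates,
            "kd_M": "n.m." if k.censored else k.kd,
            "kd_lower_bound_M": k.kd_lower_bound if k.censored else "",
            "kd_spread": k.kd_spread, "koff_s": k.koff,
            "koff_spread": k.koff_spread, "kon_Ms": k.kon,
            "kon_sigma": k.kon_sigma, "fold_kd": k.fold_kd,
            "fold_koff": k.fold_koff,
            "fold_kon_decrease": k.fold_kon_decrease,
        })
    return pd.DataFrame(rows)


def run_pipeline(config_doc: dict, out_dir: str | Path,
                 seed: int | None = None) -> FootprintReport:
    """Execute the full analysis described by ``config_doc``.

    Returns the :class:`FootprintReport`; writes all artifacts to
    ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig.from_dict(config_doc.get("analysis", {}))
    fp_cfg = config_doc.get("footprint", {})
    manifest = RunManifest(config=config_doc, seed=seed)

    has_inputs = "inputs" in config_doc
    has_sim = "simulate" in config_doc
    if has_inputs == has_sim:
        raise ConfigError(
            "config must contain exactly one of 'inputs' (real data) or "
            "'simulate' (synthetic scenario)")

    structure_source = None
    role_map = None
    scenario = None
    if has_sim:
        logger.info("stage simulate: generating synthetic scenario")
        scenario = _scenario_from_config(config_doc["simulate"], seed)
        dataset = generate_binding_data(scenario)
        equilibrium, dissociation = dataset.equilibrium, dataset.dissociation
        panel = dataset.panel
        if config_doc["simulate"].get("structure", True):
            pdb_text, role_map = generate_toy_structure(scenario)
            (out / "toy_structure.pdb").write_text(pdb_text)
            structure_source = out / "toy_structure.pdb"
    else:
        inputs = config_doc["inputs"]
        for key in ("equilibrium", "dissociation", "panel"):
            if key not in inputs:
                raise ConfigError(f"inputs section missing {key!r}")
            manifest.input_digests[key] = _sha256(Path(inputs[key]))
        logger.info("stage read: loading input tables")
        equilibrium = read_equilibrium_table(inputs["equilibrium"],
                                             analysis.temperature)
        dissociation = read_dissociation_table(
            inputs["dissociation"], inputs.get("skip_initial", 0.0))
        panel = read_mutant_panel(inputs["panel"])
        if "structure" in inputs:
            structure_source = Path(inputs["structure"])
            manifest.input_digests["structure"] = _sha256(structure_source)
            role_map = inputs.get("role_map")
            if not role_map:
                raise ConfigError("inputs.structure requires inputs.role_map")

    try:
        logger.info("stage fit: %d equilibrium series, %d dissociation "
                    "traces", len(equilibrium), len(dissociation))
        kinetics = fit_panel(equilibrium, dissociation, analysis)
        ddgs = ddg_table(kinetics, analysis)
        wt = kinetics["WT"]
        dg_wt = delta_g_standard(wt.kd, analysis.rt, wt.kd_sigma,
                                 provenance="WT")

        contact_map = None
        clusters = [tuple(c) for c in fp_cfg.get("clusters", [])]
        if structure_source is not None:
            logger.info("stage contacts: annotating structure")
            model = parse_structure(structure_source, role_map)
            contact_map = annotate_contacts(model, analysis)
            contact_map_frame(contact_map).to_csv(
                out / "contact_map.csv", index=False)
            if not clusters:
                candidates = [
                    res for res, v in _residue_ddgs(panel, ddgs).items()
                    if v.value >= analysis.ddg_inclusion_threshold
                    or v.is_lower_limit]
                candidates = [
                    r for r in candidates
                    if (ann := contact_map.get(r)) is not None
                    and ann.contacts_tcr and not ann.contacts_peptide]
                clusters, _ = find_clusters(candidates, contact_map)

        peptide_total = None
        if "peptide_scan" in fp_cfg:
            ps = fp_cfg["peptide_scan"]
            pep_ddgs = {k: EnergyValue(**v) if isinstance(v, dict)
                        else EnergyValue(value=float(v))
                        for k, v in ps["ddgs"].items()}
            floors = [PairFloor(*pf) for pf in ps.get("pair_floors", [])]
            peptide_total, pep_warn = peptide_scan_total(
                pep_ddgs, ps["tcr_contacting"], floors)
            manifest.warnings.extend(pep_warn)

        logger.info("stage footprint: assembling the energy ledger")
        report = assemble_sigma_ddg(
            ddgs, panel, analysis, contact_map=contact_map,
            clusters=clusters,
            manual_peptide_exclusions=fp_cfg.get("peptide_exclusions", ()),
            manual_tcr_contacts=fp_cfg.get("tcr_contacts"),
            dg_wt=dg_wt, peptide_total=peptide_total,
            panel_name=(scenario.tcr if scenario else
                        fp_cfg.get("panel_name", "panel")))
        classify_panel(report, kinetics, analysis)

        pairs = [tuple(p) for p in fp_cfg.get("additivity_pairs", [])]
        if not pairs and scenario is not None:
            for (a, b), _eps in scenario.pairs + scenario.clusters:
                da, db = scenario.residue(a), scenario.residue(b)
                pairs.append((da.variant_label, db.variant_label,
                              f"{da.variant_label}+{db.variant_label}"))
        results, add_warn = test_additivity(
            ddgs, pairs, k=analysis.additivity_k,
            floor=analysis.additivity_floor)
        report.additivity = results
        report.warnings.extend(add_warn)
        manifest.warnings.extend(report.warnings)
    except TcrFootprintError as exc:
        raise type(exc)(f"pipeline stage failed: {exc}") from exc

    kinetics_frame(kinetics).to_csv(out / "kinetics.csv", index=False)
    write_results_table(report.ledger, out / "ledger.json", "json")
    write_results_table(report.ledger, out / "summary.csv", "csv",
                        kinetics=kinetics)
    from .report import render_report
    (out / "report.md").write_text(render_report(report, "md"))
    manifest.timestamp = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True,
                   default=str))
    logger.info("run complete: outputs in %s", out)
    return report


def _residue_ddgs(panel, ddgs) -> dict[str, EnergyValue]:
    out = {}
    for v in panel:
        if len(v.mutations) == 1 and v.mutations[0].chain_role == "mhc-heavy" \
                and v.label in ddgs:
            out[v.mutations[0].residue_label] = ddgs[v.label]
    return out
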