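"""Human-readable summaries of a footprint analysis.

Layout mirrors the standard energy-decomposition table: ΔG°, calculated
and experimental totals, the MHC side-chain contribution and its percent
of the total, each ± its error, with energies rounded to two decimals and
percents to whole numbers. Stored values are never rounded — rounding is
display-only.
"""

from __future__ import annotations

from .binding import fmt_energy, fmt_percent
from .footprint import FootprintReport
from .thermo import EnergyValue


def _cell(ev: EnergyValue | None) -> str:
    return "n.d." if ev is None else ev.display()


def _pct_cell(pct: tuple[float, float] | None) -> str:
    if pct is None:
        return "n.d."
    value, sigma = pct
    if sigma > 0:
        return f"{fmt_percent(value)} ± {fmt_percent(sigma) or 1}"
    return f"{fmt_percent(value)}"


def render_report(report: FootprintReport, format: str = "md") -> str:
    """Render a per-panel summary (markdown table + reason codes)."""
    if format not in ("md", "text"):
        raise ValueError(f"unknown report format {format!r}")
    ledger = report.ledger
    lines: list[str] = []
    title = f"Energy decomposition — {report.panel or 'panel'}"
    if format == "md":
        lines += [f"# {title}", ""]
        header = ["panel", "dG0", "Total_calc", "Total_exp",
                  "MHC contribution", "MHC (%)"]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        pct = _pct_cell(ledger.pct_mhc_calc)
        if ledger.pct_mhc_exp is not None:
            pct += f", {_pct_cell(ledger.pct_mhc_exp)}"
        lines.append("| " + " | ".join([
            report.panel or "panel", _cell(ledger.dg_wt),
            _cell(ledger.total_calc), _cell(ledger.total_exp),
            _cell(ledger.mhc_contribution), pct]) + " |")
    else:
        lines += [title, "-" * len(title)]
        lines.append(
            f"dG0 {_cell(ledger.dg_wt)} | Total_calc "
            f"{_cell(ledger.total_calc)} | Total_exp "
            f"{_cell(ledger.total_exp)} | MHC "
            f"{_cell(ledger.mhc_contribution)} | "
            f"{_pct_cell(ledger.pct_mhc_calc)}")
    lines.append("")

    if not ledger.entries:
        lines.append("no qualifying residues")
        return "\n".join(lines) + "\n"

    lines.append("## Per-residue decisions" if format == "md"
                 else "Per-residue decisions")
    for entry in ledger.entries:
        mark = "included" if entry.counted else "excluded"
        lines.append(
            f"- {entry.variant} ({entry.residue or '-'}): "
            f"ddG {entry.ddg.display()} kcal/mol — {entry.reason} "
            f"[{mark}]")
    if report.additivity:
        lines.append("")
        lines.append("## Additivity tests" if format == "md"
                     else "Additivity tests")
        for res in report.additivity:
            lines.append(
                f"- {res.variant_ab}: deviation "
                f"{fmt_energy(res.deviation)} ± "
                f"{fmt_energy(res.sigma_deviation)} kcal/mol "
                f"(tolerance {fmt_energy(res.tolerance)}) — {res.verdict}")
    if report.kinetic_class:
        members = report.kinetic_footprint
        lines.append("")
        lines.append("## Kinetic footprint" if format == "md"
                     else "Kinetic footprint")
        lines.append("- " + (", ".join(members) if members
                             else "no members"))
    if report.warnings:
        lines.append("")
        lines.append("## Warnings" if format == "md" else "Warnings")
        lines += [f"- {w}" for w in report.warnings]
    return "\n".join(lines) + "\n"
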