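"""End-to-end orchestration: bundle → torsions → core atoms → clustering →
domains → per-domain range refinement → report.

The two benign failure modes of the method are reported, never raised to the
caller: a bundle without usable torsions yields status ``"no core atoms"``
(e.g. CA-only depositions) and a bundle in which no clustering stage offers
a large enough cluster yields ``"no domains found"`` (typical for short,
largely disordered peptides).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from os import PathLike
from typing import Sequence

from .bundle import StructureBundle
from .domains import (
    OrderParameterTable,
    annotate_order_parameters,
    cluster_core_atoms,
    distance_variance_matrix,
    evaluate_trace,
    extract_domains,
    find_core_atoms,
    select_clustering_stage,
    select_order_cutoff,
)
from .errors import (
    DegenerateOrderParameters,
    EmptySelection,
    NoCoreAtoms,
    NoDomainsFound,
)
from .refine import RangeResult, RefinementParams, refine_domain
from .structure_io import read_bundle
from .torsions import compute_torsions

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_CORE = "no core atoms"
STATUS_NO_DOMAINS = "no domains found"

#: CLI exit codes per status (input errors exit 1).
EXIT_CODES = {STATUS_OK: 0, STATUS_NO_CORE: 2, STATUS_NO_DOMAINS: 3}


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    input: str
    status: str
    params: RefinementParams
    torsion_mode: str
    n_conformers: int
    n_residues: int
    domains: list[RangeResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    order_cutoff: float | None = None
    n_core_atoms: int = 0
    runtime_s: float = 0.0

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_selected(self) -> int:
        return sum(d.n_residues for d in self.domains)

    @property
    def n_gaps(self) -> int:
        return sum(d.n_gaps for d in self.domains)

    @property
    def coverage(self) -> float:
        """Selected residues as a fraction of the full sequence, in [0, 1]."""
        if self.n_residues == 0:
            return 0.0
        return self.n_selected / self.n_residues


def run(
    source: str | PathLike | StructureBundle,
    params: RefinementParams | None = None,
    torsion_mode: str = "all",
    model_limit: int | None = None,
    label: str | None = None,
) -> RunReport:
    """Execute the full pipeline on a PDB file path or an in-memory bundle.

    ``torsion_mode`` is "all" (every rotatable dihedral, the default) or
    "phipsichi1" (restrict order parameters to φ, ψ and χ1).
    """
    if torsion_mode not in ("all", "phipsichi1"):
        raise ValueError("torsion_mode must be 'all' or 'phipsichi1'")
    params = params or RefinementParams()
    t0 = time.perf_counter()

    if isinstance(source, StructureBundle):
        bundle = source
        name = label or "<bundle>"
    else:
        bundle = read_bundle(source, model_limit=model_limit)
        name = label or str(source)

    report = RunReport(
        input=name,
        status=STATUS_OK,
        params=params,
        torsion_mode=torsion_mode,
        n_conformers=bundle.n_conformers,
        n_residues=bundle.n_residues,
    )

    torsions = compute_torsions(bundle)
    if torsion_mode == "phipsichi1":
        torsions = [t for t in torsions if t.name in ("phi", "psi", "chi1")]
    if not torsions:
        report.status = STATUS_NO_CORE
        report.warnings.append("no rotatable torsion angles in input")
        report.runtime_s = time.perf_counter() - t0
        return report
    annotate_order_parameters(torsions)

    cutoff: float | None
    try:
        table = OrderParameterTable.from_records(torsions)
        cutoff = select_order_cutoff(table)
    except DegenerateOrderParameters:
        cutoff = None
        report.warnings.append(
            "all order parameters equal; every torsion-bearing residue is core"
        )
    report.order_cutoff = cutoff

    try:
        core = find_core_atoms(bundle, torsions, cutoff)
    except NoCoreAtoms as exc:
        report.status = STATUS_NO_CORE
        report.warnings.append(str(exc))
        report.runtime_s = time.perf_counter() - t0
        return report
    report.n_core_atoms = core.count
    logger.info("core atoms: %d (cutoff %s)", core.count, cutoff)

    try:
        if core.count < 2:
            raise NoDomainsFound("no domains found: fewer than 2 core atoms")
        v = distance_variance_matrix(
            bundle, core, normalization=params.variance_normalization
        )
        trace = cluster_core_atoms(v)
        evaluate_trace(trace, bundle, core)
        stage = select_clustering_stage(trace, params.mu)
        domains = extract_domains(trace, stage, params.mu, params.m, bundle)
    except NoDomainsFound as exc:
        report.status = STATUS_NO_DOMAINS
        report.warnings.append(str(exc))
        report.runtime_s = time.perf_counter() - t0
        return report

    for dom in domains:
        try:
            result = refine_domain(bundle, dom.extended_positions, params)
        except EmptySelection:
            report.warnings.append(
                "domain dropped: no residues with complete backbone"
            )
            continue
        if result.n_residues == 0:
            report.warnings.append("domain dropped: refinement removed all residues")
            continue
        report.domains.append(result)

    if not report.domains:
        report.status = STATUS_NO_DOMAINS
        report.warnings.append("no domains found")
    report.runtime_s = time.perf_counter() - t0
    return report


# ----------------------------------------------------------------- reporting
def _range_str(rng: tuple[str, str, str]) -> str:
    chain, first, last = rng
    return f"{chain}:{first}..{last}"


def report_to_dict(report: RunReport) -> dict:
    """Schema-stable structured form of a report."""
    return {
        "input": report.input,
        "status": report.status,
        "parameters": {
            "mu": report.params.mu,
            "m": report.params.m,
            "gamma": report.params.gamma,
            "delta": report.params.delta,
            "delta_abs": report.params.delta_abs,
            "g": report.params.g,
            "torsion_mode": report.torsion_mode,
        },
        "n_conformers": report.n_conformers,
        "n_residues": report.n_residues,
        "n_core_atoms": report.n_core_atoms,
        "order_cutoff": report.order_cutoff,
        "n_domains": report.n_domains,
        "n_selected": report.n_selected,
        "n_gaps": report.n_gaps,
        "coverage": report.coverage,
        "domains": [
            {
                "ranges": [
                    {"chain": c, "first": f, "last": l} for c, f, l in d.ranges
                ],
                "n_residues": d.n_residues,
                "n_gaps": d.n_gaps,
                "rmsd": d.rmsd,
            }
            for d in report.domains
        ],
        "warnings": list(report.warnings),
    }


def format_report(report: RunReport, fmt: str = "text") -> str:
    """Serialize a report as human-readable text or stable JSON."""
    if fmt == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if fmt != "text":
        raise ValueError("format must be 'text' or 'json'")
    lines = [f"Input: {report.input}"]
    lines.append(
        f"Conformers: {report.n_conformers}   Residues: {report.n_residues}   "
        f"Core atoms: {report.n_core_atoms}"
    )
    if report.status != STATUS_OK:
        lines.append(report.status)
    for i, d in enumerate(report.domains, start=1):
        ranges = ", ".join(_range_str(r) for r in d.ranges)
        lines.append(
            f"Domain {i}: {ranges} ({d.n_residues} residues, RMSD {d.rmsd:.2f} Å)"
        )
    lines.append(
        f"Coverage: {100.0 * report.coverage:.1f}%   "
        f"Domains: {report.n_domains}   Intra-domain gaps: {report.n_gaps}"
    )
    for w in report.warnings:
        lines.append(f"Warning: {w}")
    return "\n".join(lines)
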