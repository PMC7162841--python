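"""End-to-end analysis: structure -> symmetry -> protodomains -> report.

Stages degrade gracefully: a failure in one stage is recorded in the report
and later stages that do not depend on it still run.  Reports are plain
dictionaries with a versioned schema and deterministic serialization (sorted
keys, no timestamps), so re-running the same input and config is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import AnalysisConfig
from .protodomains import (
    ProtodomainError,
    assign_tm_segments,
    delineate_protodomains,
    provisional_segments,
    topology_code,
)
from .structure import (
    InsufficientDataError,
    MembraneFrame,
    StructureModel,
    orient_fallback,
    read_structure,
)
from .superpose import (
    SuperpositionError,
    align_protodomains,
    derive_sequence_alignment,
    percent_identity,
    resolve_protodomain,
)
from .symmetry import (
    assign_point_group,
    detect_internal_symmetry,
    detect_quaternary_symmetry,
)

SCHEMA_VERSION = 1


@dataclass
class AnalysisReport:
    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.data, indent=1, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def __getitem__(self, key):
        return self.data[key]

    def get(self, key, default=None):
        return self.data.get(key, default)


def run_analysis(
    structure: StructureModel | str | Path,
    config: AnalysisConfig | None = None,
    orient: str = "auto",
    n_term_side: str = "EC",
    chain_id: str | None = None,
) -> AnalysisReport:
    """Run the full pseudo-symmetry protodomain analysis on one structure.

    ``orient='auto'`` trusts a membrane-pre-oriented input (mid-plane at
    z = 0, EC side at z > 0) and falls back to an axis-derived frame only
    when no membrane-spanning segment is found; ``'opm'`` and ``'fallback'``
    force either behaviour.  ``chain_id`` picks the chain for the tertiary
    analysis (default: first chain).
    """
    config = config or AnalysisConfig()
    stages: dict[str, str] = {}
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "stages": stages,
    }

    if not isinstance(structure, StructureModel):
        structure = read_structure(structure)
    report["structure_id"] = structure.id
    report["n_chains"] = len(structure.chains)
    stages["read"] = "ok"

    chain = structure.chain(chain_id) if chain_id else structure.chains[0]
    report["chain_analyzed"] = chain.chain_id

    # membrane frame
    frame = structure.frame or MembraneFrame(core_half_width=config.core_half_width)
    provenance = "opm_pre_oriented"
    segments = assign_tm_segments(structure, frame, chain, config)
    if orient == "fallback" or (orient == "auto" and not segments):
        try:
            prov = provisional_segments(chain, config)
            frame = orient_fallback(structure, prov, n_term_side)
            frame = MembraneFrame(frame.normal, frame.z_offset, config.core_half_width)
            segments = assign_tm_segments(structure, frame, chain, config)
            provenance = "fallback"
        except InsufficientDataError as exc:
            stages["orient"] = f"failed: {exc}"
    report["frame"] = {
        "provenance": provenance,
        "normal": [round(float(x), 6) for x in frame.normal],
        "z_offset": round(float(frame.z_offset), 4),
    }
    stages["orient"] = stages.get("orient", "ok")

    report["tm_segments"] = [
        {
            "index": s.index,
            "start": s.first_residue.seq_number,
            "end": s.last_residue.seq_number,
            "direction": s.direction,
            "h_center": s.h_center.seq_number,
        }
        for s in segments
    ]
    stages["segments"] = "ok" if segments else "no TM segments found"

    # quaternary symmetry
    quaternary = None
    try:
        quaternary = detect_quaternary_symmetry(structure, frame, config)
        report["quaternary"] = quaternary.to_dict()
        stages["quaternary"] = "ok"
    except Exception as exc:  # stage-level failure, keep going
        stages["quaternary"] = f"failed: {exc}"

    # tertiary symmetry
    tertiary = None
    if len(segments) >= 4:
        try:
            tertiary = detect_internal_symmetry(structure, segments, frame, 2, config)
            if not tertiary.detected:
                order3 = detect_internal_symmetry(structure, segments, frame, 3, config)
                if order3.detected:
                    tertiary = order3
            report["tertiary"] = tertiary.to_dict()
            stages["tertiary"] = "ok"
        except Exception as exc:
            stages["tertiary"] = f"failed: {exc}"
    else:
        stages["tertiary"] = "skipped: fewer than 4 TM segments"

    # point group
    try:
        pg = assign_point_group(tertiary, quaternary, frame, config)
        report["point_group"] = pg.to_dict()
        stages["point_group"] = "ok"
    except Exception as exc:
        stages["point_group"] = f"failed: {exc}"

    # protodomain delineation, alignment and topology code
    if tertiary is not None and tertiary.detected and tertiary.order == 2:
        try:
            pd1, pd2, linkers = delineate_protodomains(segments, tertiary)
            block = {
                "protodomain_1": pd1.label,
                "protodomain_2": pd2.label,
                "linker_segments": linkers,
            }
            fit = align_protodomains(structure, segments, pd1, pd2, config)
            aln = derive_sequence_alignment(
                fit.correspondence,
                resolve_protodomain(structure, segments, pd1),
                resolve_protodomain(structure, segments, pd2),
            )
            block["superposition"] = fit.to_dict()
            block["alignment"] = {"rows": list(aln)}
            try:
                block["percent_identity"] = round(percent_identity(aln), 2)
            except SuperpositionError as exc:
                block["percent_identity"] = None
            if len(pd1.segments) == 3:
                try:
                    code = topology_code(pd1, pd2, segments, frame, config)
                    block["topology_code"] = str(code)
                except ProtodomainError as exc:
                    block["topology_code"] = None
                    stages["topology_code"] = f"failed: {exc}"
            report["protodomains"] = block
            stages["protodomains"] = "ok"
        except (ProtodomainError, SuperpositionError) as exc:
            stages["protodomains"] = f"failed: {exc}"
    else:
        stages["protodomains"] = "skipped: no order-2 tertiary symmetry"

    return AnalysisReport(report)
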