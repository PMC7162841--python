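"""Transmembrane segments, hydrophobic centers, protodomain delineation and
topology-conformation/assembly codes.

A protodomain is a supersecondary structure (here an ordered group of 3 or 4
membrane-spanning helices) that generates a full tertiary domain by
duplication plus a symmetry operation, with an optional linker helix.  Each
TM helix carries a *hydrophobic center*: the residue whose Cα sits closest to
the membrane mid-plane, the anchor used both for seeding structural
alignments and for splitting helices into extracellular-facing (EC) and
intracellular-facing (IC) halves.

The topology code (e.g. ``132c/s21a``) summarizes, viewed from the EC side,
how the three helices of the first protodomain are arranged (digit order and
clockwise ``c`` / counterclockwise ``cc`` chirality) and which helix pairs
form the symmetric inter-protodomain interface (``sXY`` plus ``p``/``a`` for
parallel or antiparallel axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AnalysisConfig
from .structure import Chain, MembraneFrame, Residue, StructureModel, z_of


class ProtodomainError(Exception):
    pass


@dataclass
class TMSegment:
    """A membrane-spanning helix at Cα resolution."""

    index: int
    residues: list[Residue]
    direction: str              # 'up' = C-terminus on the EC side
    axis: np.ndarray            # unit vector, signed along direction
    centroid: np.ndarray
    h_center_index: int         # position of the hydrophobic center

    @property
    def first_residue(self) -> Residue:
        return self.residues[0]

    @property
    def last_residue(self) -> Residue:
        return self.residues[-1]

    @property
    def h_center(self) -> Residue:
        return self.residues[self.h_center_index]

    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], float)


@dataclass(frozen=True)
class ProtodomainDef:
    """Ordered group of TM segment indices forming one protodomain.

    Indices are strictly increasing except for explicitly constructed
    reordered definitions used in cross-topology comparisons.
    """

    segments: tuple[int, ...]
    label: str = ""
    reordered: bool = False

    def __post_init__(self) -> None:
        if not self.reordered and list(self.segments) != sorted(set(self.segments)):
            raise ProtodomainError(
                f"segment indices must be strictly increasing: {self.segments}"
            )
        if not self.label:
            object.__setattr__(
                self, "label", "TM" + "".join(str(i + 1) for i in self.segments)
            )


@dataclass
class TopologyCode:
    arrangement: str                # e.g. '132'
    chirality: str                  # 'c' or 'cc'
    assembly: list[str]             # e.g. ['s21a']

    def __str__(self) -> str:
        return f"{self.arrangement}{self.chirality}/" + "/".join(self.assembly)


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Inertial axis of a helix: leading right-singular vector of centered Cα."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient N -> C
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _make_segment(index: int, residues: list[Residue], frame: MembraneFrame) -> TMSegment:
    coords = np.array([r.ca for r in residues], float)
    axis = _helix_axis(coords)
    zs = [z_of(r, frame) for r in residues]
    direction = "up" if zs[-1] > zs[0] else "down"
    h_idx = int(np.argmin(np.abs(zs)))  # argmin ties break N-terminally
    return TMSegment(index, residues, direction, axis, coords.mean(axis=0), h_idx)


def helical_runs(chain: Chain, config: AnalysisConfig | None = None) -> list[list[Residue]]:
    """Maximal locally-helical runs of a chain, membrane tests not applied.

    Runs are contiguous stretches (consecutive Cα closer than 4.2 Å) of at
    least ``min_segment_length`` residues whose Cα i -> i+3 distances fall in
    ``helix_d13_range`` for at least ``helical_fraction`` of positions.
    """
    config = config or AnalysisConfig()
    residues = chain.residues
    if not residues:
        return []
    coords = chain.coords()
    # contiguous stretches: consecutive in author numbering and spatially
    # bonded (chain breaks and unmodeled loops violate one or the other)
    stretches: list[list[int]] = [[0]]
    for i in range(1, len(residues)):
        num_jump = (
            residues[i].chain_id != residues[i - 1].chain_id
            or (residues[i].seq_number - residues[i - 1].seq_number > 1
                and not residues[i].insertion_code)
        )
        if num_jump or np.linalg.norm(coords[i] - coords[i - 1]) > 6.0:
            stretches.append([i])
        else:
            stretches[-1].append(i)
    lo, hi = config.helix_d13_range
    runs: list[list[Residue]] = []
    for idxs in stretches:
        if len(idxs) < config.min_segment_length:
            continue
        n = len(idxs)
        marked = np.zeros(n, bool)
        for k in range(n - 3):
            d = np.linalg.norm(coords[idxs[k + 3]] - coords[idxs[k]])
            if lo <= d <= hi:
                marked[k : k + 4] = True
        # maximal marked runs, bridging unmarked gaps of <= 2 (helix kinks)
        positions: list[int] = []
        gap = 0

        def flush() -> None:
            if len(positions) >= config.min_segment_length and \
                    np.mean(marked[positions]) >= config.helical_fraction:
                runs.append([residues[idxs[p]] for p in positions])
            positions.clear()

        for pos in range(n):
            if marked[pos]:
                if positions and gap:
                    positions.extend(range(positions[-1] + 1, pos))
                positions.append(pos)
                gap = 0
            elif positions:
                gap += 1
                if gap > 2:
                    flush()
                    gap = 0
        flush()
    return runs


def provisional_segments(
    chain: Chain, config: AnalysisConfig | None = None
) -> list[TMSegment]:
    """Helical runs packaged as segments in a provisional lab frame.

    Used to bootstrap :func:`protosym.structure.orient_fallback` when the
    input is not membrane-pre-oriented; directions and hydrophobic centers
    are relative to the provisional frame and must be re-derived afterwards.
    """
    frame = MembraneFrame()
    return [
        _make_segment(i, run, frame)
        for i, run in enumerate(helical_runs(chain, config))
    ]


def assign_tm_segments(
    structure: StructureModel,
    frame: MembraneFrame,
    chain: str | Chain,
    config: AnalysisConfig | None = None,
) -> list[TMSegment]:
    """Detect membrane-spanning helices along one chain.

    A segment is a maximal run of >= ``min_segment_length`` residues that is
    locally helical (Cα i -> i+3 distance within ``helix_d13_range`` for at
    least ``helical_fraction`` of the run) and either crosses the membrane
    mid-plane or traverses >= ``span_fraction`` of the core width.  Runs are
    additionally broken where consecutive Cα are more than 4.2 Å apart
    (chain breaks / unmodeled loops).
    """
    config = config or AnalysisConfig()
    if isinstance(chain, str):
        chain = structure.chain(chain)
    segments: list[TMSegment] = []
    for run in helical_runs(chain, config):
        zs = np.array([z_of(r, frame) for r in run])
        crosses = zs.min() < 0.0 < zs.max()
        span = zs.max() - zs.min()
        if not crosses and span < 2 * config.core_half_width * config.span_fraction:
            continue
        # exclude runs entirely outside the membrane core
        if zs.min() > config.core_half_width or zs.max() < -config.core_half_width:
            continue
        segments.append(_make_segment(len(segments), run, frame))
    return segments


KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

# von Heijne-style biological hydrophobicity (apparent dG of membrane
# insertion, sign-flipped so that hydrophobic residues score high).
VON_HEIJNE = {
    "A": -0.11, "R": -2.58, "N": -2.05, "D": -3.49, "C": 0.13, "Q": -2.36,
    "E": -2.68, "G": -0.74, "H": -2.06, "I": 0.60, "L": 0.55, "K": -2.71,
    "M": 0.10, "F": 0.32, "P": -2.23, "S": -0.84, "T": -0.52, "W": -0.30,
    "Y": -0.68, "V": 0.31, "X": 0.0,
}

HYDROPATHY_SCALES = {"kyte-doolittle": KYTE_DOOLITTLE, "von-heijne": VON_HEIJNE}


def predict_tm_hydropathy(
    sequence: str,
    scale: str = "kyte-doolittle",
    window: int = 19,
    threshold: float = 1.6,
) -> list[tuple[int, int]]:
    """Sliding-window hydropathy prediction of TM regions.

    Centered moving average of per-residue hydropathy; maximal runs above
    ``threshold`` are merged when separated by fewer than 3 residues and
    trimmed/split to 17-25 residues around each run's hydropathy maximum.
    Returns 0-based inclusive (start, end) pairs.
    """
    if scale not in HYDROPATHY_SCALES:
        raise ValueError(
            f"unknown scale {scale!r}; available: {sorted(HYDROPATHY_SCALES)}"
        )
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if len(sequence) < window:
        raise ValueError("sequence shorter than window")
    table = HYDROPATHY_SCALES[scale]
    values = np.array([table.get(a.upper(), 0.0) for a in sequence])
    half = window // 2
    avg = np.convolve(values, np.ones(window) / window, mode="valid")
    centers = np.arange(half, half + len(avg))
    above = avg > threshold

    runs: list[list[int]] = []
    for ci, flag in zip(centers, above):
        if flag:
            if runs and ci - runs[-1][-1] == 1:
                runs[-1].append(ci)
            else:
                runs.append([ci])
    # merge runs separated by < 3 residues
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] < 3:
            merged[-1] = list(range(merged[-1][0], run[-1] + 1))
        else:
            merged.append(run)

    avg_at = dict(zip(centers.tolist(), avg.tolist()))
    regions: list[tuple[int, int]] = []

    def emit(start: int, end: int) -> None:
        length = end - start + 1
        if length < 17:
            # extend symmetrically within the sequence
            need = 17 - length
            start = max(0, start - (need + 1) // 2)
            end = min(len(sequence) - 1, start + 16)
            start = max(0, end - 16)
        regions.append((start, end))

    for run in merged:
        start, end = run[0], run[-1]
        while end - start + 1 > 25:
            peak = max(range(start, end + 1), key=lambda c: avg_at.get(c, -1e9))
            w_start, w_end = max(start, peak - 10), min(end, peak + 10)
            w_start = max(start, w_end - 20)
            emit(w_start, w_end)
            left_len = w_start - start
            right_len = end - w_end
            if left_len >= 17 and left_len >= right_len:
                end = w_start - 1
            elif right_len >= 17:
                start = w_end + 1
            else:
                start, end = 0, -1
                break
        if end - start + 1 >= 1 and end >= start:
            emit(start, end)
    regions.sort()
    return regions


def delineate_protodomains(
    segments: list[TMSegment],
    split,
) -> tuple[ProtodomainDef, ProtodomainDef, list[int]]:
    """Turn a symmetry split into two protodomain definitions.

    ``split`` is either a SymmetryAssignment (its ``split`` attribute holds
    two tuples of segment indices) or an explicit pair of index tuples.
    Returns the two protodomains and the indices of any skipped linker
    helices lying between them (e.g. TM4 in parallel 7TMH domains).
    """
    ranges = getattr(split, "split", split)
    if ranges is None or len(ranges) != 2:
        raise ProtodomainError(f"split does not define two protodomains: {split!r}")
    a, b = (tuple(int(i) for i in r) for r in ranges)
    valid = set(range(len(segments)))
    if not set(a) <= valid or not set(b) <= valid:
        raise ProtodomainError("split references unknown segment indices")
    if set(a) & set(b):
        raise ProtodomainError(f"overlapping protodomains: {a} vs {b}")
    pd1, pd2 = ProtodomainDef(a), ProtodomainDef(b)
    between = [i for i in valid if max(a) < i < min(b)] if max(a) < min(b) else []
    linkers = [i for i in between if i not in a and i not in b]
    return pd1, pd2, linkers


def _projection_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed in-plane basis (e1, e2) with e1 x e2 = normal.

    In these 2D coordinates a positive signed area is counterclockwise as
    seen from the EC side (the viewer looks along -normal).
    """
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _project(points: np.ndarray, frame: MembraneFrame) -> np.ndarray:
    e1, e2 = _projection_basis(frame.normal)
    return np.stack([points @ e1, points @ e2], axis=1)


def _signed_area(p: np.ndarray) -> float:
    return 0.5 * float(
        (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
        - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
    )


def topology_code(
    pd1: ProtodomainDef,
    pd2: ProtodomainDef,
    segments: list[TMSegment],
    frame: MembraneFrame,
    config: AnalysisConfig | None = None,
) -> TopologyCode:
    """Topology-conformation/assembly code of a 3TMH protodomain pair.

    Chirality: ``c`` when traversing pd1's helices in label order 1 -> 2 -> 3
    turns clockwise in the EC-side projection, ``cc`` otherwise.  Arrangement:
    the helix of pd1 farthest (in projection) from pd2's centroid is the apex
    and becomes the middle digit; the two interface helices flank it, smaller
    label first.  Assembly: one ``sXY(p|a)`` code per mutual-nearest
    inter-protodomain helix pair with projected centroid distance below
    ``contact_cut`` (symmetric duplicates collapsed, larger label written
    first, codes sorted).
    """
    config = config or AnalysisConfig()
    if len(pd1.segments) != 3 or len(pd2.segments) != 3:
        raise ProtodomainError("topology codes are defined for 3-helix protodomains")
    segs1 = [segments[i] for i in pd1.segments]
    segs2 = [segments[i] for i in pd2.segments]
    c1 = _project(np.array([s.centroid for s in segs1]), frame)
    c2 = _project(np.array([s.centroid for s in segs2]), frame)

    area = _signed_area(c1)
    if abs(area) <= config.min_triangle_area:
        raise ProtodomainError(
            f"chirality undefined: projected centroids nearly collinear "
            f"(area {abs(area):.2f} Å²)"
        )
    chirality = "cc" if area > 0 else "c"  # positive = counterclockwise from EC

    partner_centroid = c2.mean(axis=0)
    dists_to_partner = np.linalg.norm(c1 - partner_centroid, axis=1)
    apex = int(np.argmax(dists_to_partner))
    flank = sorted(i for i in range(3) if i != apex)
    arrangement = f"{flank[0] + 1}{apex + 1}{flank[1] + 1}"

    dmat = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=2)
    codes: dict[tuple[int, int], str] = {}
    for i in range(3):
        j = int(np.argmin(dmat[i]))
        if dmat[i, j] >= config.contact_cut:
            continue
        if int(np.argmin(dmat[:, j])) != i:
            continue  # not mutual-nearest
        rel = "p" if float(np.dot(segs1[i].axis, segs2[j].axis)) > 0 else "a"
        a, b = i + 1, j + 1
        key = (max(a, b), min(a, b))
        codes.setdefault(key, f"s{key[0]}{key[1]}{rel}")
    return TopologyCode(arrangement, chirality, sorted(codes.values()))


def write_mfta(
    path: str | Path,
    seq_id: str,
    sequence: str,
    segments: list[TMSegment],
    chain: Chain,
) -> None:
    """Annotated FASTA: sequence plus per-residue TM markup with *h* flags.

    The markup line uses ``M`` inside TM segments, ``h`` at each hydrophobic
    center and ``.`` elsewhere.
    """
    index = {r.key: i for i, r in enumerate(chain.residues)}
    markup = ["."] * len(sequence)
    for seg in segments:
        for r in seg.residues:
            markup[index[r.key]] = "M"
        markup[index[seg.h_center.key]] = "h"
    text = f">{seq_id}\n{sequence}\n>{seq_id}|tm-markup\n{''.join(markup)}\n"
    Path(path).write_text(text)


def segments_to_tsv(path: str | Path, segments: list[TMSegment]) -> None:
    import pandas as pd

    rows = [
        {
            "index": s.index,
            "start": s.first_residue.seq_number,
            "end": s.last_residue.seq_number,
            "direction": s.direction,
            "h_center": s.h_center.seq_number,
            "axis_x": round(float(s.axis[0]), 6),
            "axis_y": round(float(s.axis[1]), 6),
            "axis_z": round(float(s.axis[2]), 6),
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
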