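"""Internal (tertiary) pseudo-symmetry, quaternary cyclic symmetry, and
point-group assignment.

Tertiary detection enumerates contiguous equal-helix-count splits of the TM
segment list (sliding the second block to allow a skipped linker helix, e.g.
TM123 vs TM567 with a TM4 linker), structurally aligns each candidate
protodomain pair, and keeps the lowest-RMSD candidate whose rotation is
consistent with the tested cyclic order.  Quaternary detection superposes
equivalent chains onto each other and accepts Cn when the resulting rotations
share an axis and hit the expected multiples of 360/n.  A tertiary C2 axis
lying in the membrane plane combined with a quaternary Cn axis along the
normal yields a dihedral group Dn; parallel axes stay cyclic.
"""

from __future__ import annotations

import difflib
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig
from .protodomains import ProtodomainDef, TMSegment
from .structure import MembraneFrame, StructureModel
from .superpose import (
    AlignmentFailedError,
    SuperpositionError,
    align_units,
    chain_correspondence,
    kabsch_superpose,
    HelixUnit,
)


class SymmetryError(Exception):
    pass


@dataclass
class SymmetryAssignment:
    level: str                      # 'tertiary' | 'quaternary'
    order: int                      # 1 = no symmetry found
    angle: float | None = None      # deg
    axis: np.ndarray | None = None
    axis_membrane_angle: float | None = None   # deg in [0, 90]
    topology_class: str = "n/a"     # 'parallel' | 'inverted' | 'n/a'
    rmsd: float | None = None
    split: tuple | None = None      # protodomain index tuples or chain order

    @property
    def detected(self) -> bool:
        return self.order >= 2

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "order": self.order,
            "angle_deg": None if self.angle is None else round(float(self.angle), 3),
            "axis": None if self.axis is None else [round(float(x), 6) for x in self.axis],
            "axis_membrane_angle_deg": (
                None if self.axis_membrane_angle is None
                else round(float(self.axis_membrane_angle), 3)
            ),
            "topology_class": self.topology_class,
            "rmsd": None if self.rmsd is None else round(float(self.rmsd), 4),
            "split": self.split,
        }


@dataclass
class PointGroup:
    label: str                      # 'C2'..'C6', 'D2'..'D5', 'none'
    tertiary: SymmetryAssignment | None = None
    quaternary: SymmetryAssignment | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "tertiary": None if self.tertiary is None else self.tertiary.to_dict(),
            "quaternary": None if self.quaternary is None else self.quaternary.to_dict(),
        }


def rotation_to_angle_axis(
    rotation: np.ndarray, frame: MembraneFrame | None = None
) -> tuple[float, np.ndarray | None]:
    """Angle (deg, in [0, 180]) and unit axis of a proper rotation.

    The identity has an undefined axis, signalled by ``None``.  When a frame
    is supplied the reported axis is flipped, if needed, so that its dot
    product with the membrane normal is non-negative (the axis denotes the
    rotation line; for reporting we pick the EC-ward representative).
    """
    r = np.asarray(rotation, float)
    if r.shape != (3, 3) or not np.allclose(r.T @ r, np.eye(3), atol=1e-6) \
            or not np.isclose(np.linalg.det(r), 1.0, atol=1e-6):
        raise SymmetryError("input is not a proper orthonormal rotation")
    rotvec = Rotation.from_matrix(r).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < 1e-7:
        return 0.0, None
    axis = rotvec / np.linalg.norm(rotvec)
    if frame is not None and float(np.dot(axis, frame.normal)) < 0:
        axis = -axis
    return angle, axis


def _axis_membrane_angle(axis: np.ndarray, frame: MembraneFrame) -> float:
    cosang = abs(float(np.dot(axis, frame.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _axes_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two axis *lines* in [0, 90] degrees."""
    cosang = abs(float(np.dot(a, b)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _segment_units(segments: list[TMSegment], idxs: tuple[int, ...]) -> list[HelixUnit]:
    return [
        HelixUnit(list(segments[i].residues), segments[i].h_center_index,
                  segments[i].axis)
        for i in idxs
    ]


def detect_internal_symmetry(
    structure: StructureModel,
    segments: list[TMSegment],
    frame: MembraneFrame,
    candidate_order: int = 2,
    config: AnalysisConfig | None = None,
    split: tuple | None = None,
) -> SymmetryAssignment:
    """Detect Cn pseudo-symmetry within one chain's helix bundle.

    A user-supplied ``split`` (two tuples of segment indices) bypasses the
    candidate enumeration, mirroring how hard cases are handled manually.
    Returns an order-1 assignment (not an exception) when no candidate
    aligns under ``rmsd_accept`` with the expected rotation angle.
    """
    config = config or AnalysisConfig()
    n = len(segments)
    none = SymmetryAssignment("tertiary", 1)
    if n < 4:
        return none

    target_angle = 360.0 / candidate_order
    candidates: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    if split is not None:
        candidates = [tuple(tuple(int(i) for i in b) for b in split)]
    elif candidate_order == 2:
        k = n // 2
        first = tuple(range(k))
        for off in range(k, n - k + 1):
            candidates.append((first, tuple(range(off, off + k))))
    elif candidate_order == 3:
        k = n // 3
        if k >= 1 and 3 * k <= n:
            candidates.append((tuple(range(k)), tuple(range(k, 2 * k))))
    else:
        raise ValueError("tertiary candidate_order must be 2 or 3")

    best: SymmetryAssignment | None = None
    for blk_a, blk_b in candidates:
        try:
            fit = align_units(
                _segment_units(segments, blk_a), _segment_units(segments, blk_b), config
            )
        except SuperpositionError:
            continue
        angle, axis = rotation_to_angle_axis(fit.rotation, frame)
        if axis is None or abs(angle - target_angle) > config.angle_tol:
            continue
        if fit.rmsd > config.rmsd_accept:
            continue
        if candidate_order == 3:
            # the same rotation must also carry block 2 onto block 3
            blk_c = tuple(range(2 * (n // 3), 3 * (n // 3)))
            try:
                fit23 = align_units(
                    _segment_units(segments, blk_b), _segment_units(segments, blk_c),
                    config,
                )
            except SuperpositionError:
                continue
            angle23, axis23 = rotation_to_angle_axis(fit23.rotation, frame)
            if axis23 is None or abs(angle23 - target_angle) > config.angle_tol \
                    or _axes_angle(axis, axis23) > config.perp_tol:
                continue
        mem_angle = _axis_membrane_angle(axis, frame)
        topo = (
            "parallel" if mem_angle < config.parallel_max_axis_angle else "inverted"
        )
        cand = SymmetryAssignment(
            "tertiary", candidate_order, angle, axis, mem_angle, topo,
            fit.rmsd, (blk_a, blk_b),
        )
        if best is None or cand.rmsd < best.rmsd:
            best = cand
    return best or none


def _chain_identity(a: str, b: str) -> float:
    return difflib.SequenceMatcher(a=a, b=b, autojunk=False).ratio()


def _equivalent_chain_sets(structure: StructureModel, threshold: float) -> list[list[int]]:
    n = len(structure.chains)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if _chain_identity(structure.chains[i].sequence,
                           structure.chains[j].sequence) >= threshold:
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=len, reverse=True)


def detect_quaternary_symmetry(
    assembly: StructureModel,
    frame: MembraneFrame | None = None,
    config: AnalysisConfig | None = None,
) -> SymmetryAssignment:
    """Detect cyclic symmetry of the chain assembly.

    Chains are grouped into equivalence sets by sequence identity; for the
    largest set of n chains, chain 1 is superposed onto every other chain and
    Cn is accepted when the n-1 rotations share a common axis (within
    ``perp_tol``) with angles at distinct multiples of 360/n (within
    ``angle_tol``).
    """
    config = config or AnalysisConfig()
    none = SymmetryAssignment("quaternary", 1)
    if len(assembly.chains) < 2:
        return none
    groups = _equivalent_chain_sets(assembly, config.identity_threshold)
    group = groups[0]
    n = len(group)
    if n < 2:
        return none

    rotations, rmsds = [], []
    ref_chain = assembly.chains[group[0]]
    for j in group[1:]:
        ca, cb = chain_correspondence(assembly.chains[j], ref_chain)
        if len(ca) < 3:
            return none
        fit = kabsch_superpose(ca, cb)
        rotations.append(fit.rotation)
        rmsds.append(fit.rmsd)

    axes, angles = [], []
    for r in rotations:
        angle, axis = rotation_to_angle_axis(r)
        if axis is None:
            return none
        axes.append(axis)
        angles.append(angle)

    ref_axis = axes[0]
    if frame is not None and float(np.dot(ref_axis, frame.normal)) < 0:
        ref_axis = -ref_axis
    signed = []
    for axis, angle in zip(axes, angles):
        if _axes_angle(axis, ref_axis) > config.perp_tol:
            return none
        s = angle if float(np.dot(axis, ref_axis)) >= 0 else -angle
        signed.append(s % 360.0)

    expected = {k * 360.0 / n: k for k in range(1, n)}
    seen: set[int] = set()
    for s in signed:
        match = None
        for target, k in expected.items():
            delta = min(abs(s - target), 360.0 - abs(s - target))
            if delta <= config.angle_tol:
                match = k
                break
        if match is None or match in seen:
            return none
        seen.add(match)

    mean_axis = np.zeros(3)
    for axis in axes:
        mean_axis += axis if float(np.dot(axis, ref_axis)) >= 0 else -axis
    mean_axis /= np.linalg.norm(mean_axis)
    if frame is not None and float(np.dot(mean_axis, frame.normal)) < 0:
        mean_axis = -mean_axis
    mem_angle = None if frame is None else _axis_membrane_angle(mean_axis, frame)
    return SymmetryAssignment(
        "quaternary", n, 360.0 / n, mean_axis, mem_angle, "n/a",
        float(max(rmsds)), tuple(assembly.chains[i].chain_id for i in group),
    )


def assign_point_group(
    tertiary,
    quaternary: SymmetryAssignment | None,
    frame: MembraneFrame | None = None,
    config: AnalysisConfig | None = None,
) -> PointGroup:
    """Combine tertiary and quaternary assignments into a point group.

    Dn: tertiary C2 axis perpendicular (within ``perp_tol``) to a quaternary
    Cn axis.  Cn: parallel axes, or only one level detected.  ``tertiary``
    may also be a list of assignments; two perpendicular internal C2 axes
    alone yield D2 (the hierarchical, domain-duplicated case).
    """
    config = config or AnalysisConfig()
    tert_list = [t for t in (tertiary if isinstance(tertiary, (list, tuple))
                             else [tertiary]) if t is not None and t.detected]
    tert = tert_list[0] if tert_list else None
    quat = quaternary if quaternary is not None and quaternary.detected else None

    if tert is None and quat is None:
        return PointGroup("none", tert, quat)
    if len(tert_list) >= 2 and quat is None:
        a, b = tert_list[0], tert_list[1]
        if a.order == b.order == 2 and \
                abs(_axes_angle(a.axis, b.axis) - 90.0) <= config.perp_tol:
            return PointGroup("D2", a, None)
    if quat is None:
        return PointGroup(f"C{tert.order}", tert, None)
    if tert is None:
        return PointGroup(f"C{quat.order}", None, quat)
    angle = _axes_angle(tert.axis, quat.axis)
    if tert.order == 2 and abs(angle - 90.0) <= config.perp_tol:
        return PointGroup(f"D{quat.order}", tert, quat)
    if angle <= config.perp_tol:
        return PointGroup(f"C{quat.order}", tert, quat)
    return PointGroup("none", tert, quat)
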