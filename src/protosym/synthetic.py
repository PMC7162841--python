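"""Synthetic pseudo-symmetric helix bundles and alignments with ground truth.

The generators emit the same kinds of objects the analysis consumes - Cα-only
structures in a membrane frame and FASTA alignments - together with the
ground truth (protodomain ranges, symmetry axes, topology codes, hydrophobic
centers, per-site substitution behaviour) needed to test every pipeline
stage without external downloads.

Geometry uses textbook α-helix parameters (1.5 Å rise and 100° turn per
residue, 2.3 Å helix radius).  A domain is built from one protodomain of
idealized vertical helices duplicated by a 180° rotation: about the membrane
normal for a parallel topology (axis orthogonal to the membrane planes, as
in SWEET/PnuC/GPCR-like bundles, optionally with a TM4-like linker helix) or
about an in-plane axis for an inverted topology (TRIC/MFS-like).  Domains
may further oligomerize on a ring to form Cn quaternary assemblies.  Noise
is i.i.d. isotropic Gaussian on Cα positions, seeded.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Chain, MembraneFrame, Residue, StructureModel

RISE = 1.5          # Å per residue along the helix axis
TURN = 100.0        # degrees per residue
RADIUS = 2.3        # Å, Cα helix radius

_HYDROPHOBIC_CYCLE = "LVIFAGLMVA"


class SyntheticError(Exception):
    pass


class ClashError(SyntheticError):
    pass


@dataclass
class BundleSpec:
    """Recipe for one pseudo-symmetric helix-bundle domain."""

    helix_count: int = 3
    helix_length: int = 22
    helix_xy_positions: tuple[tuple[float, float], ...] | None = None
    helix_directions: tuple[str, ...] | None = None
    symmetry_mode: str = "parallel"       # 'parallel' | 'inverted'
    linker_helix: bool = False
    linker_xy: tuple[float, float] = (0.0, -13.0)
    oligomer_order: int = 1
    ring_radius: float = 25.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helix_count not in (3, 4):
            raise SyntheticError("helix_count per protodomain must be 3 or 4")
        if self.helix_xy_positions is None:
            if self.helix_count == 3:
                # parallel: protodomains meet across the symmetry axis at the
                # origin; inverted: they stack across the in-plane x axis
                self.helix_xy_positions = (
                    ((5.0, 6.0), (11.0, 0.0), (5.0, -6.0))
                    if self.symmetry_mode == "parallel"
                    else ((-6.0, 4.0), (0.0, 8.0), (6.0, 4.0))
                )
            else:
                self.helix_xy_positions = (
                    ((5.0, 10.0), (11.0, 4.0), (11.0, -4.0), (5.0, -10.0))
                    if self.symmetry_mode == "parallel"
                    else ((-9.0, 4.0), (-3.0, 8.0), (3.0, 8.0), (9.0, 4.0))
                )
        if self.helix_directions is None:
            self.helix_directions = tuple(
                "up" if k % 2 == 0 else "down" for k in range(self.helix_count)
            )
        self.helix_xy_positions = tuple(
            (float(x), float(y)) for x, y in self.helix_xy_positions
        )
        self.helix_directions = tuple(self.helix_directions)
        if len(self.helix_xy_positions) != self.helix_count \
                or len(self.helix_directions) != self.helix_count:
            raise SyntheticError("positions/directions must match helix_count")
        if self.noise_sigma < 0:
            raise SyntheticError("noise_sigma must be >= 0")
        if self.symmetry_mode not in ("parallel", "inverted"):
            raise SyntheticError("symmetry_mode must be 'parallel' or 'inverted'")


@dataclass
class GroundTruth:
    """What the generator actually built, for recovery tests."""

    protodomain_segments: tuple[tuple[int, ...], tuple[int, ...]]
    protodomain_ranges: tuple[tuple[int, int], tuple[int, int]]  # author numbering
    tertiary_order: int
    tertiary_axis: tuple[float, float, float]
    topology_class: str
    topology_code: str | None
    h_center_numbers: dict[int, int]      # segment index -> author seq number
    linker_segment: int | None = None
    quaternary_order: int = 1
    quaternary_axis: tuple[float, float, float] | None = None
    frame: MembraneFrame = field(default_factory=MembraneFrame)

    def validate_against(self, model: StructureModel) -> None:
        numbers = {r.seq_number for r in model.chains[0]}
        for lo, hi in self.protodomain_ranges:
            if lo not in numbers or hi not in numbers:
                raise SyntheticError("ground-truth range not resolvable in structure")
        for axis in (self.tertiary_axis, self.quaternary_axis):
            if axis is not None and not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
                raise SyntheticError("ground-truth axis not unit length")

    def to_json(self, path: str | Path) -> None:
        data = {
            "protodomain_segments": [list(s) for s in self.protodomain_segments],
            "protodomain_ranges": [list(r) for r in self.protodomain_ranges],
            "tertiary_order": self.tertiary_order,
            "tertiary_axis": list(self.tertiary_axis),
            "topology_class": self.topology_class,
            "topology_code": self.topology_code,
            "h_center_numbers": {str(k): v for k, v in self.h_center_numbers.items()},
            "linker_segment": self.linker_segment,
            "quaternary_order": self.quaternary_order,
            "quaternary_axis": (
                None if self.quaternary_axis is None else list(self.quaternary_axis)
            ),
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(ref, direction))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, direction) * direction
    u /= np.linalg.norm(u)
    return u, np.cross(direction, u)


def make_ideal_helix(
    n_res: int,
    origin: np.ndarray,
    direction: np.ndarray,
    phase: float = 0.0,
) -> np.ndarray:
    """Canonical α-helix Cα trace: 1.5 Å rise, 100°/residue, 2.3 Å radius.

    ``origin`` is the axis point of the first residue; all Cα lie exactly on
    a cylinder of radius 2.3 Å about the axis through ``origin`` along
    ``direction``.
    """
    if n_res < 4:
        raise SyntheticError("n_res must be >= 4")
    direction = np.asarray(direction, float)
    norm = float(np.linalg.norm(direction))
    if norm < 1e-12:
        raise SyntheticError("zero direction vector")
    direction = direction / norm
    u, v = _perp_basis(direction)
    i = np.arange(n_res)[:, None]
    ang = np.radians(phase + TURN * np.arange(n_res))[:, None]
    return (
        np.asarray(origin, float)
        + direction * (RISE * i)
        + RADIUS * (np.cos(ang) * u + np.sin(ang) * v)
    )


@dataclass
class _HelixPlan:
    xy: tuple[float, float]
    direction: str          # 'up' | 'down'
    start_number: int
    phase: float


def _build_helix(plan: _HelixPlan, n_res: int, chain_id: str,
                 seq_iter) -> list[Residue]:
    half_span = (n_res - 1) * RISE / 2.0
    if plan.direction == "up":
        origin = np.array([plan.xy[0], plan.xy[1], -half_span])
        d = np.array([0.0, 0.0, 1.0])
    else:
        origin = np.array([plan.xy[0], plan.xy[1], half_span])
        d = np.array([0.0, 0.0, -1.0])
    coords = make_ideal_helix(n_res, origin, d, plan.phase)
    return [
        Residue(chain_id, plan.start_number + k, "", next(seq_iter), coords[k])
        for k in range(n_res)
    ]


def _check_clashes(plans: list[_HelixPlan]) -> None:
    for a, b in itertools.combinations(plans, 2):
        d = np.hypot(a.xy[0] - b.xy[0], a.xy[1] - b.xy[1])
        if d < 4.0:
            raise ClashError(
                f"helix axes at {a.xy} and {b.xy} are {d:.2f} Å apart (< 4 Å)"
            )


def _gt_topology_code(spec: BundleSpec) -> str | None:
    """Topology code implied by the spec, from plain 2D arithmetic.

    Independent of the structural pipeline: works directly on the specified
    helix xy positions and up/down directions.
    """
    if spec.helix_count != 3:
        return None
    p1 = np.array(spec.helix_xy_positions, float)
    if spec.symmetry_mode == "parallel":
        p2 = -p1                                 # 180° about the z axis
        dirs2 = list(spec.helix_directions)
    else:
        p2 = p1 * np.array([1.0, -1.0])          # 180° about the x axis
        dirs2 = ["down" if d == "up" else "up" for d in spec.helix_directions]
    # chirality from the shoelace sign in the (x, y) plane (EC view)
    area = 0.5 * (
        (p1[1, 0] - p1[0, 0]) * (p1[2, 1] - p1[0, 1])
        - (p1[2, 0] - p1[0, 0]) * (p1[1, 1] - p1[0, 1])
    )
    if abs(area) <= 1.0:
        return None
    chirality = "cc" if area > 0 else "c"
    apex = int(np.argmax(np.linalg.norm(p1 - p2.mean(axis=0), axis=1)))
    flank = sorted(i for i in range(3) if i != apex)
    arrangement = f"{flank[0] + 1}{apex + 1}{flank[1] + 1}"
    dmat = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
    codes = {}
    for i in range(3):
        j = int(np.argmin(dmat[i]))
        if dmat[i, j] >= 12.0 or int(np.argmin(dmat[:, j])) != i:
            continue
        rel = "p" if spec.helix_directions[i] == dirs2[j] else "a"
        key = (max(i + 1, j + 1), min(i + 1, j + 1))
        codes.setdefault(key, f"s{key[0]}{key[1]}{rel}")
    return f"{arrangement}{chirality}/" + "/".join(sorted(codes.values()))


def make_pseudo_symmetric_domain(spec: BundleSpec) -> tuple[StructureModel, GroundTruth]:
    """One chain holding two protodomains related by a C2 operation.

    Protodomain 2 is protodomain 1 rotated 180° about the membrane normal
    (parallel mode) or about the in-plane x axis (inverted mode); numbering
    leaves loop-sized gaps between helices, and an optional linker helix sits
    between the protodomains as in 7TMH parallel domains.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.helix_count
    plans: list[_HelixPlan] = []
    seg_labels: list[str] = []

    for k in range(n):
        plans.append(_HelixPlan(spec.helix_xy_positions[k], spec.helix_directions[k],
                                0, phase=40.0 * k))
        seg_labels.append("pd1")
    if spec.linker_helix:
        if spec.symmetry_mode != "parallel":
            raise SyntheticError("linker helix only meaningful in parallel mode")
        last_dir = spec.helix_directions[-1]
        plans.append(_HelixPlan(spec.linker_xy,
                                "down" if last_dir == "up" else "up", 0, phase=20.0))
        seg_labels.append("linker")
    for k in range(n):
        x, y = spec.helix_xy_positions[k]
        if spec.symmetry_mode == "parallel":
            # 180° about z; the phase shift realizes the rotated azimuth
            xy2, dir2, phase2 = (-x, -y), spec.helix_directions[k], 40.0 * k + 180.0
        else:
            # 180° about x; the down-helix basis change already supplies the
            # azimuthal flip, so the phase is unchanged
            xy2 = (x, -y)
            dir2 = "down" if spec.helix_directions[k] == "up" else "up"
            phase2 = 40.0 * k
        plans.append(_HelixPlan(xy2, dir2, 0, phase=phase2))
        seg_labels.append("pd2")
    _check_clashes(plans)

    for g, plan in enumerate(plans):
        plan.start_number = 10 + 40 * g

    seq_iter = itertools.cycle(_HYDROPHOBIC_CYCLE)
    residues: list[Residue] = []
    seg_ranges: list[tuple[int, int]] = []
    for plan in plans:
        helix = _build_helix(plan, spec.helix_length, "A", seq_iter)
        seg_ranges.append((helix[0].seq_number, helix[-1].seq_number))
        residues.extend(helix)

    if spec.noise_sigma > 0:
        residues = [
            Residue(r.chain_id, r.seq_number, r.insertion_code, r.aa,
                    r.ca + rng.normal(0.0, spec.noise_sigma, 3))
            for r in residues
        ]

    frame = MembraneFrame()
    model = StructureModel("SYNTH", [Chain("A", residues)], frame)

    pd1 = tuple(i for i, lab in enumerate(seg_labels) if lab == "pd1")
    pd2 = tuple(i for i, lab in enumerate(seg_labels) if lab == "pd2")
    linker = next((i for i, lab in enumerate(seg_labels) if lab == "linker"), None)
    if spec.symmetry_mode == "parallel":
        axis, topo = (0.0, 0.0, 1.0), "parallel"
    else:
        axis, topo = (1.0, 0.0, 0.0), "inverted"

    h_centers: dict[int, int] = {}
    for idx, (lo, hi) in enumerate(seg_ranges):
        seg_res = [r for r in residues if lo <= r.seq_number <= hi]
        zs = np.abs([r.ca[2] for r in seg_res])
        h_centers[idx] = seg_res[int(np.argmin(zs))].seq_number

    gt = GroundTruth(
        protodomain_segments=(pd1, pd2),
        protodomain_ranges=(
            (seg_ranges[pd1[0]][0], seg_ranges[pd1[-1]][1]),
            (seg_ranges[pd2[0]][0], seg_ranges[pd2[-1]][1]),
        ),
        tertiary_order=2,
        tertiary_axis=axis,
        topology_class=topo,
        topology_code=_gt_topology_code(spec),
        h_center_numbers=h_centers,
        linker_segment=linker,
        frame=frame,
    )
    gt.validate_against(model)
    return model, gt


def make_oligomer(
    domain: StructureModel,
    n: int,
    seed: int = 0,
    noise_sigma: float = 0.0,
    ring_radius: float = 25.0,
    ground_truth: GroundTruth | None = None,
) -> tuple[StructureModel, GroundTruth | None]:
    """Cn ring of copies of a domain about the membrane normal.

    Each chain is the input domain translated to the ring radius and rotated
    by successive 360/n° steps, with optional per-chain Gaussian noise.
    """
    if n < 2:
        raise SyntheticError("oligomer order must be >= 2")
    if n > 26:
        raise SyntheticError("chain identifiers exhausted (n > 26)")
    rng = np.random.default_rng(seed)
    base = domain.chains[0]
    chains: list[Chain] = []
    shift = np.array([ring_radius, 0.0, 0.0])
    for k in range(n):
        theta = np.radians(360.0 * k / n)
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        cid = chr(ord("A") + k)
        noise = (
            rng.normal(0.0, noise_sigma, (len(base), 3)) if noise_sigma > 0
            else np.zeros((len(base), 3))
        )
        chains.append(Chain(cid, [
            Residue(cid, r.seq_number, r.insertion_code, r.aa,
                    rot @ (r.ca + shift) + noise[i])
            for i, r in enumerate(base)
        ]))
    model = StructureModel(f"{domain.id}_C{n}", chains, domain.frame)
    gt = None
    if ground_truth is not None:
        gt = GroundTruth(
            protodomain_segments=ground_truth.protodomain_segments,
            protodomain_ranges=ground_truth.protodomain_ranges,
            tertiary_order=ground_truth.tertiary_order,
            tertiary_axis=ground_truth.tertiary_axis,
            topology_class=ground_truth.topology_class,
            topology_code=ground_truth.topology_code,
            h_center_numbers=ground_truth.h_center_numbers,
            linker_segment=ground_truth.linker_segment,
            quaternary_order=n,
            quaternary_axis=(0.0, 0.0, 1.0),
            frame=ground_truth.frame,
        )
        gt.validate_against(model)
    return model, gt


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_synthetic_msa(
    ancestor: str,
    n_seqs: int,
    sub_rate: float,
    seed: int = 0,
    site_rates: np.ndarray | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Star-topology MSA: every row mutates the ancestor independently.

    Each site substitutes with probability ``sub_rate`` (or its per-site
    override ``site_rates``), the replacement drawn uniformly from the other
    19 residues; no indels.  Returns ``[(id, sequence), ...]`` plus ground
    truth (ancestor and per-row mutated positions).
    """
    if not ancestor:
        raise SyntheticError("ancestor must be non-empty")
    rates = (np.full(len(ancestor), float(sub_rate)) if site_rates is None
             else np.asarray(site_rates, float))
    if rates.shape != (len(ancestor),) or rates.min() < 0 or rates.max() > 1:
        raise SyntheticError("site rates must be probabilities, one per site")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    mutated: list[list[int]] = []
    for i in range(n_seqs):
        hits = rng.random(len(ancestor)) < rates
        seq = list(ancestor)
        positions = []
        for j in np.flatnonzero(hits):
            alternatives = [a for a in AA20 if a != ancestor[j]]
            seq[j] = alternatives[rng.integers(len(alternatives))]
            positions.append(int(j))
        rows.append((f"seq{i + 1}", "".join(seq)))
        mutated.append(positions)
    gt = {"ancestor": ancestor, "mutated_positions": mutated, "site_rates": rates.tolist()}
    return rows, gt


def inject_gaps(
    rows: list[tuple[str, str]], cells: list[tuple[int, int]]
) -> list[tuple[str, str]]:
    """Replace stated (row, column) cells with gap characters."""
    out = [list(seq) for _, seq in rows]
    for r, c in cells:
        out[r][c] = "-"
    return [(rows[i][0], "".join(out[i])) for i in range(len(rows))]


def write_fasta(rows: list[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text("".join(f">{i}\n{s}\n" for i, s in rows))
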