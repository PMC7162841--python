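"""Rigid superposition and structure-based protodomain alignment.

The protodomain aligner replaces the interactive optimization used in the
original analyses with a deterministic three-stage procedure:

1. SEED - pair helix *k* of one protodomain with helix *k* of the other and
   match residues by signed rank relative to each helix's hydrophobic center
   (center with center, +-1 with +-1, ...), truncating to the shorter side.
2. FIT / REFINE - Kabsch superposition on the current pairs, then up to
   ``max_iter`` rounds of rebuilding the correspondence by order-preserving
   dynamic programming on the inter-Ca distance matrix (match score
   ``max(0, d_cut - d_ij)``, free gaps at helix boundaries, penalized gaps
   inside helices), stopping when the RMSD change falls below ``converge``.
3. TRIM - drop pairs whose residual exceeds ``trim_cut`` and refit.

RMSD is the criterion of record throughout; helical alignments are allowed to
shift registers by whole turns (+-4 residues) and the DP stage evaluates all
registers and keeps the best-scoring one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .structure import Residue


class SuperpositionError(Exception):
    pass


class DegenerateInputError(SuperpositionError):
    pass


class AlignmentFailedError(SuperpositionError):
    pass


@dataclass(frozen=True)
class Correspondence:
    """Order-preserving residue pairing between two units (no crossings)."""

    pairs: tuple[tuple[Residue, Residue], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([p[0].ca for p in self.pairs], float)
        b = np.array([p[1].ca for p in self.pairs], float)
        return a, b


@dataclass
class SuperpositionResult:
    """Least-squares rigid map of unit B onto unit A and its residual."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    correspondence: Correspondence | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, float)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise SuperpositionError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise SuperpositionError("rotation is not proper (det != +1)")
        self.rotation = r
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": [round(float(x), 9) for x in self.rotation.ravel()],
            "translation": [round(float(x), 9) for x in self.translation],
            "rmsd": round(float(self.rmsd), 6),
            "n_pairs": int(self.n_pairs),
        }


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation/translation of ``coords_b`` onto ``coords_a``.

    Closed-form Kabsch solution via SVD with the reflection excluded.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DegenerateInputError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise DegenerateInputError(f"need >= 3 points, got {len(a)}")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    p, q = b - cb_, a - ca_
    u, _, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ca_ - rot @ cb_
    rmsd = float(np.sqrt(((b @ rot.T + t - a) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rot, t, rmsd, len(a))


def chain_correspondence(chain_a, chain_b) -> tuple[np.ndarray, np.ndarray]:
    """Matched Cα coordinate arrays of two chains of (nearly) equal sequence.

    Equal-length chains pair 1:1; otherwise matched blocks of the sequence
    pair (longest contiguous matches, order-preserving) are used.
    """
    import difflib

    if len(chain_a) == len(chain_b):
        return chain_a.coords(), chain_b.coords()
    sm = difflib.SequenceMatcher(a=chain_a.sequence, b=chain_b.sequence,
                                 autojunk=False)
    ia: list[int] = []
    ib: list[int] = []
    for block in sm.get_matching_blocks():
        ia.extend(range(block.a, block.a + block.size))
        ib.extend(range(block.b, block.b + block.size))
    return chain_a.coords()[ia], chain_b.coords()[ib]


def superpose_chains(chain_a, chain_b) -> SuperpositionResult:
    """Kabsch superposition of chain B onto chain A via sequence matching."""
    ca, cb = chain_correspondence(chain_a, chain_b)
    if len(ca) < 3:
        raise DegenerateInputError("chains share fewer than 3 matched residues")
    return kabsch_superpose(ca, cb)


@dataclass
class HelixUnit:
    """One membrane-spanning helix of an alignment unit.

    ``h_index`` is the position of the hydrophobic center within ``residues``.
    """

    residues: list[Residue]
    h_index: int
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if not 0 <= self.h_index < len(self.residues):
            raise ValueError("h_index outside helix")

    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], float)


def _seed_pairs(ha: HelixUnit, hb: HelixUnit, offset: int = 0) -> list[tuple[int, int]]:
    """Signed-rank pairing around the hydrophobic centers of one helix pair.

    ``offset`` shifts B's register by whole residues (used to probe the
    one-turn +-4 ambiguity of helical alignments).
    """
    hb_eff = hb.h_index + offset
    lo = -min(ha.h_index, hb_eff)
    hi = min(len(ha.residues) - 1 - ha.h_index, len(hb.residues) - 1 - hb_eff)
    return [
        (ha.h_index + r, hb_eff + r)
        for r in range(lo, hi + 1)
        if 0 <= hb_eff + r < len(hb.residues)
    ]


def dp_helix_pair(
    dist: np.ndarray, d_cut: float, gap_penalty: float
) -> list[tuple[int, int]]:
    """Best order-preserving matching of one helix pair.

    Maximizes ``sum(d_cut - d_ij)`` over matched pairs (matches allowed only
    under ``d_cut``) minus ``gap_penalty`` for every *interior* skipped
    residue - a residue lying strictly between matched residues of its own
    helix.  Residues outside the matched span (helix boundaries) are free, so
    every register shift, including whole-turn +-4 shifts, is evaluated on an
    equal footing.
    """
    n, m = dist.shape
    neg = -np.inf
    f = np.full((n, m), neg)            # best score of matchings ending at (i, j)
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    # prefix_val[i][j] = max over i' < i, j' < j of f[i', j'] + gap_penalty*(i'+j')
    prefix_val = np.full((n + 1, m + 1), neg)
    prefix_arg = np.empty((n + 1, m + 1), dtype=object)
    for i in range(n):
        for j in range(m):
            if dist[i, j] < d_cut:
                s = d_cut - dist[i, j]
                who = prefix_arg[i, j]
                extend = prefix_val[i, j] - gap_penalty * (i + j - 2)
                if who is not None and extend > 0.0:
                    f[i, j] = s + extend
                    parent[(i, j)] = who
                else:
                    f[i, j] = s
                    parent[(i, j)] = None
            best, best_arg = prefix_val[i, j + 1], prefix_arg[i, j + 1]
            if prefix_val[i + 1, j] > best:
                best, best_arg = prefix_val[i + 1, j], prefix_arg[i + 1, j]
            cand = f[i, j] + gap_penalty * (i + j)
            if cand > best:
                best, best_arg = cand, (i, j)
            prefix_val[i + 1, j + 1] = best
            prefix_arg[i + 1, j + 1] = best_arg
    if not parent:
        return []
    end = max(parent, key=lambda ij: f[ij])
    pairs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = end
    while cur is not None:
        pairs.append(cur)
        cur = parent[cur]
    pairs.reverse()
    return pairs


def _fit(pairs_res: list[tuple[Residue, Residue]]) -> SuperpositionResult:
    a = np.array([p[0].ca for p in pairs_res], float)
    b = np.array([p[1].ca for p in pairs_res], float)
    res = kabsch_superpose(a, b)
    res.correspondence = Correspondence(tuple(pairs_res))
    return res


def align_units(
    unit_a: Sequence[HelixUnit],
    unit_b: Sequence[HelixUnit],
    config: AnalysisConfig | None = None,
) -> SuperpositionResult:
    """Seed/refine/trim structural alignment of two helix-bundle units.

    The seed register is probed at whole-turn shifts (0, -4, +4 residues,
    the usual ambiguity of helical alignments); each seed is refined and
    trimmed independently and the lowest final RMSD wins.
    """
    config = config or AnalysisConfig()
    best: SuperpositionResult | None = None
    err: AlignmentFailedError | None = None
    for register in (0, -4, 4):
        try:
            fit = _align_units_register(unit_a, unit_b, config, register)
        except AlignmentFailedError as exc:
            err = exc
            continue
        if best is None or fit.rmsd < best.rmsd - 1e-12:
            best = fit
    if best is None:
        raise err or AlignmentFailedError("alignment failed in every register")
    return best


def _align_units_register(
    unit_a: Sequence[HelixUnit],
    unit_b: Sequence[HelixUnit],
    config: AnalysisConfig,
    register: int,
) -> SuperpositionResult:
    if len(unit_a) != len(unit_b):
        raise AlignmentFailedError(
            f"helix-count mismatch: {len(unit_a)} vs {len(unit_b)}"
        )
    if not unit_a:
        raise AlignmentFailedError("empty units")

    # SEED
    pairs: list[tuple[Residue, Residue]] = []
    for ha, hb in zip(unit_a, unit_b):
        for ia, ib in _seed_pairs(ha, hb, register):
            pairs.append((ha.residues[ia], hb.residues[ib]))
    if len(pairs) < 3:
        raise AlignmentFailedError("too few seed pairs")
    fit = _fit(pairs)

    # REFINE
    for _ in range(config.max_iter):
        new_pairs: list[tuple[Residue, Residue]] = []
        for ha, hb in zip(unit_a, unit_b):
            ca = ha.coords()
            cb = fit.apply(hb.coords())
            dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            for ia, ib in dp_helix_pair(dist, config.d_cut, config.internal_gap_penalty):
                new_pairs.append((ha.residues[ia], hb.residues[ib]))
        if len(new_pairs) < 3:
            break
        new_fit = _fit(new_pairs)
        done = abs(new_fit.rmsd - fit.rmsd) < config.converge
        fit = new_fit
        if done:
            break

    # TRIM
    a, b = fit.correspondence.coords()
    residual = np.linalg.norm(fit.apply(b) - a, axis=1)
    keep = residual <= config.trim_cut
    kept = [p for p, k in zip(fit.correspondence.pairs, keep) if k]
    if len(kept) < config.min_final_pairs:
        raise AlignmentFailedError(
            f"alignment failed: only {len(kept)} pairs under {config.trim_cut} Å"
        )
    if len(kept) < len(fit.correspondence.pairs):
        fit = _fit(kept)
    return fit


def resolve_protodomain(structure, segments, pd) -> list[HelixUnit]:
    """Materialize a protodomain definition into helix units with residues."""
    units = []
    for idx in pd.segments:
        seg = segments[idx]
        units.append(
            HelixUnit(list(seg.residues), seg.h_center_index, np.asarray(seg.axis, float))
        )
    return units


def align_protodomains(structure, segments, pd_a, pd_b, config=None) -> SuperpositionResult:
    """Structurally align two protodomains of one structure (B onto A)."""
    return align_units(
        resolve_protodomain(structure, segments, pd_a),
        resolve_protodomain(structure, segments, pd_b),
        config,
    )


def derive_sequence_alignment(correspondence: Correspondence,
                              unit_a: Sequence[HelixUnit],
                              unit_b: Sequence[HelixUnit]) -> tuple[str, str]:
    """Gapped pairwise sequence alignment implied by a residue correspondence.

    Matched residues share a column; unmatched residues between matches are
    emitted against gaps, A-side first.
    """
    res_a = [r for h in unit_a for r in h.residues]
    res_b = [r for h in unit_b for r in h.residues]
    index_a = {r.key: i for i, r in enumerate(res_a)}
    index_b = {r.key: i for i, r in enumerate(res_b)}
    row_a: list[str] = []
    row_b: list[str] = []
    ia = ib = 0
    for ra, rb in correspondence.pairs:
        ja, jb = index_a[ra.key], index_b[rb.key]
        while ia < ja:
            row_a.append(res_a[ia].aa)
            row_b.append("-")
            ia += 1
        while ib < jb:
            row_a.append("-")
            row_b.append(res_b[ib].aa)
            ib += 1
        row_a.append(res_a[ja].aa)
        row_b.append(res_b[jb].aa)
        ia, ib = ja + 1, jb + 1
    while ia < len(res_a):
        row_a.append(res_a[ia].aa)
        row_b.append("-")
        ia += 1
    while ib < len(res_b):
        row_a.append("-")
        row_b.append(res_b[ib].aa)
        ib += 1
    return "".join(row_a), "".join(row_b)


class UndefinedIdentityError(SuperpositionError):
    pass


def percent_identity(alignment: tuple[str, str]) -> float:
    """100 x identical aligned columns / columns with both residues present."""
    row_a, row_b = alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    both = [(a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"]
    if not both:
        raise UndefinedIdentityError("no aligned columns")
    same = sum(1 for a, b in both if a == b)
    return 100.0 * same / len(both)


@dataclass
class ReferenceAlignmentEntry:
    label: str
    rmsd: float | None
    alignment: tuple[str, str] | None
    error: str | None = None


def align_to_reference(
    units: Sequence[tuple[str, Sequence[HelixUnit]]],
    config: AnalysisConfig | None = None,
) -> list[ReferenceAlignmentEntry]:
    """Align every entry onto the first one and report per-entry RMSD.

    Pairwise failures are reported per entry, never raised.  The merged view
    is reference-projected: each row is the entry's sequence written against
    the reference residues (insertions relative to the reference dropped).
    """
    if len(units) < 2:
        raise AlignmentFailedError("align_to_reference needs >= 2 entries")
    ref_label, ref_unit = units[0]
    out = [ReferenceAlignmentEntry(ref_label, 0.0, None)]
    for label, unit in units[1:]:
        try:
            fit = align_units(ref_unit, unit, config)
            aln = derive_sequence_alignment(fit.correspondence, ref_unit, unit)
            out.append(ReferenceAlignmentEntry(label, fit.rmsd, aln))
        except SuperpositionError as exc:
            out.append(ReferenceAlignmentEntry(label, None, None, error=str(exc)))
    return out
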