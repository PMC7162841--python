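"""Column-wise sequence similarity of structure-based alignments.

The statistic is a piecewise remapping of BLOSUM62: every pair of residues in
an alignment column is scored 1 when their BLOSUM62 entry is >= 4, then 0.75,
0.50, 0.25 and 0.125 for entries 3, 2, 1 and 0, and 0 for any negative entry.
Scores are summed over all within-column pairs and divided by the number of
comparisons; multiplied by 100 this gives a similarity percentage - the
smaller, the more the aligned region has diverged.  Splitting each TM helix
at its hydrophobic center yields separate percentages for the
extracellular-facing (EC) and intracellular-facing (IC) halves, the contrast
the analysis is after (e.g. ligand-binding EC halves diverging faster than
G-protein-binding IC halves in receptor families).

Gap handling: pairs involving a gap are excluded from both the numerator and
the denominator.  Pairs involving ``X`` (nonstandard residue) score 0 but
still count as comparisons.  The hydrophobic-center column belongs to
neither half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# The standard published BLOSUM62 integer matrix (triangular, row order
# ARNDCQEGHILKMFPSTWYV), embedded so the score mapping has a single,
# checksummable source of truth.
_B62_ORDER = "ARNDCQEGHILKMFPSTWYV"
_B62_TRIANGLE = """
4
-1 5
-2 0 6
-2 -2 1 6
0 -3 -3 -3 9
-1 1 0 0 -3 5
-1 0 0 2 -4 2 5
0 -2 0 -1 -3 -2 -2 6
-2 0 1 -1 -3 0 0 -2 8
-1 -3 -3 -3 -1 -3 -3 -4 -3 4
-1 -2 -3 -4 -1 -2 -3 -4 -3 2 4
-1 2 0 -1 -3 1 1 -2 -1 -3 -2 5
-1 -1 -2 -3 -1 0 -2 -3 -2 1 2 -1 5
-2 -3 -3 -3 -2 -3 -3 -3 -1 0 0 -3 0 6
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4 7
1 -1 1 0 -1 0 0 0 -1 -2 -2 0 -1 -2 -1 4
0 -1 0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1 1 5
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1 1 -4 -3 -2 11
-2 -2 -2 -3 -2 -1 -2 -3 2 -1 -1 -2 -1 3 -3 -2 -2 2 7
0 -3 -3 -3 -1 -2 -2 -3 -3 3 1 -2 1 -1 -2 -2 0 -3 -1 4
"""


def _build_blosum62() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    rows = [r.split() for r in _B62_TRIANGLE.strip().splitlines()]
    for i, row in enumerate(rows):
        for j, value in enumerate(row):
            a, b = _B62_ORDER[i], _B62_ORDER[j]
            table[(a, b)] = table[(b, a)] = int(value)
    return table


BLOSUM62 = _build_blosum62()

_CUSTOM_MAP = {3: 0.75, 2: 0.50, 1: 0.25, 0: 0.125}


class DivergenceError(Exception):
    pass


def custom_pair_score(a: str, b: str) -> float:
    """Piecewise similarity score of one aligned residue pair.

    BLOSUM62 >= 4 -> 1; 3/2/1/0 -> 0.75/0.50/0.25/0.125; negative -> 0.
    Any pair involving ``X`` scores 0.
    """
    a, b = a.upper(), b.upper()
    if a == "X" or b == "X":
        return 0.0
    try:
        s = BLOSUM62[(a, b)]
    except KeyError:
        raise DivergenceError(f"not an amino-acid letter pair: {a!r}, {b!r}") from None
    if s >= 4:
        return 1.0
    return _CUSTOM_MAP.get(s, 0.0)


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise DivergenceError("an MSA needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise DivergenceError("MSA rows differ in length")
        if len(self.ids) != len(self.rows):
            raise DivergenceError("ids and rows differ in count")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "MSA":
        return cls([i for i, _ in pairs], [s for _, s in pairs])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise DivergenceError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])


@dataclass
class SimilarityResult:
    scope: str
    percentage: float       # NaN when undefined (no comparisons)
    n_comparisons: int

    @property
    def defined(self) -> bool:
        return self.n_comparisons > 0


def msa_similarity(msa: MSA, columns: Iterable[int] | None = None,
                   scope: str = "full") -> SimilarityResult:
    """Similarity percentage over the stated columns (all columns if None).

    Sums :func:`custom_pair_score` over every unordered pair of rows with
    non-gap letters in each column; the percentage is 100 x total / number of
    comparisons.  An all-gap range gives an undefined (NaN) result, flagged
    via ``n_comparisons == 0``, never an exception.
    """
    cols = range(msa.n_cols) if columns is None else list(columns)
    total = 0.0
    n = 0
    for c in cols:
        if not 0 <= c < msa.n_cols:
            raise DivergenceError(f"column {c} out of bounds")
        letters = [row[c] for row in msa.rows if row[c] != "-"]
        for i in range(len(letters)):
            for j in range(i + 1, len(letters)):
                total += custom_pair_score(letters[i], letters[j])
                n += 1
    pct = math.nan if n == 0 else 100.0 * total / n
    return SimilarityResult(scope, pct, n)


@dataclass
class TMRegion:
    """One TM helix of one sequence, in alignment-column coordinates."""

    tm_index: int
    start_col: int
    end_col: int            # inclusive
    h_center_col: int
    n_term_side: str        # 'EC' | 'IC': side the region's start faces

    def __post_init__(self) -> None:
        if not self.start_col <= self.h_center_col <= self.end_col:
            raise DivergenceError(
                f"TM{self.tm_index}: h_center column outside the region"
            )
        if self.n_term_side not in ("EC", "IC"):
            raise DivergenceError("n_term_side must be 'EC' or 'IC'")

    @property
    def columns(self) -> range:
        return range(self.start_col, self.end_col + 1)


# TMRegionMap: {sequence id: [TMRegion, ...]} with non-overlapping, ordered
# regions per sequence.
TMRegionMap = dict


def split_ec_ic(region: TMRegion) -> tuple[list[int], list[int]]:
    """EC-facing and IC-facing column sets of one TM region.

    Columns strictly before the hydrophobic center lie on the side the
    N-terminal end faces; the center column belongs to neither half.  A
    center at the region edge leaves the corresponding half empty.
    """
    before = list(range(region.start_col, region.h_center_col))
    after = list(range(region.h_center_col + 1, region.end_col + 1))
    if region.n_term_side == "EC":
        return before, after
    return after, before


def _validate_map(msa: MSA, region_map: TMRegionMap) -> list[TMRegion]:
    ref_id = msa.ids[0]
    if ref_id not in region_map:
        raise DivergenceError(f"no TM map entry for reference sequence {ref_id!r}")
    ref_set = {r.tm_index for r in region_map[ref_id]}
    for seq_id in msa.ids:
        if seq_id not in region_map:
            raise DivergenceError(f"no TM map entry for sequence {seq_id!r}")
        got = {r.tm_index for r in region_map[seq_id]}
        if got != ref_set:
            raise DivergenceError(
                f"sequence {seq_id!r} has TM indices {sorted(got)}, "
                f"expected {sorted(ref_set)}"
            )
    regions = sorted(region_map[ref_id], key=lambda r: r.start_col)
    for a, b in zip(regions, regions[1:]):
        if b.start_col <= a.end_col:
            raise DivergenceError(
                f"TM{a.tm_index} and TM{b.tm_index} regions overlap"
            )
    return regions


def default_protodomain_split(tm_indices: Sequence[int]) -> dict[str, list[int]]:
    """Symmetric split of the TM list into two protodomains.

    Even counts split in half; odd counts skip the middle (linker) helix,
    e.g. 7 TMs -> TM123 vs TM567.
    """
    idx = sorted(tm_indices)
    k = len(idx) // 2
    if len(idx) % 2 == 0:
        return {"protodomain_1": idx[:k], "protodomain_2": idx[k:]}
    return {"protodomain_1": idx[:k], "protodomain_2": idx[k + 1:]}


def score_tm_halves(
    msa: MSA,
    region_map: TMRegionMap,
    protodomains: dict[str, list[int]] | None = None,
) -> list[SimilarityResult]:
    """Per-TM full/EC/IC similarity percentages plus protodomain aggregates.

    Column ranges are taken from the reference (first) sequence's map entry;
    all sequences must annotate the same TM indices.  TM lengths across the
    two protodomains are deliberately NOT equalized, so the statistic captures
    the true divergence of each region.  Protodomain aggregates are plain
    averages of the constituent per-TM percentages.
    """
    regions = _validate_map(msa, region_map)
    results: list[SimilarityResult] = []
    per_tm: dict[int, dict[str, SimilarityResult]] = {}
    for region in regions:
        name = f"TM{region.tm_index}"
        ec_cols, ic_cols = split_ec_ic(region)
        full = msa_similarity(msa, region.columns, scope=name)
        ec = msa_similarity(msa, ec_cols, scope=f"{name}_EC")
        ic = msa_similarity(msa, ic_cols, scope=f"{name}_IC")
        per_tm[region.tm_index] = {"full": full, "EC": ec, "IC": ic}
        results.extend([full, ec, ic])

    if protodomains is None:
        protodomains = default_protodomain_split([r.tm_index for r in regions])
    for pd_name, tms in protodomains.items():
        for kind, suffix in (("full", ""), ("EC", "_EC"), ("IC", "_IC")):
            parts = [per_tm[t][kind] for t in tms if t in per_tm]
            defined = [p for p in parts if p.defined]
            pct = (
                float(np.mean([p.percentage for p in defined]))
                if defined else math.nan
            )
            results.append(
                SimilarityResult(
                    f"{pd_name}{suffix}", pct, sum(p.n_comparisons for p in parts)
                )
            )
    all_cols = [c for r in regions for c in r.columns]
    results.append(msa_similarity(msa, all_cols, scope="full"))
    return results


def read_tm_map_tsv(path: str | Path) -> TMRegionMap:
    """TM-region map from TSV with columns
    seq_id, tm_index, start_col, end_col, h_center_col, n_term_side."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"seq_id", "tm_index", "start_col", "end_col", "h_center_col",
                "n_term_side"}
    missing = required - set(df.columns)
    if missing:
        raise DivergenceError(f"TM map missing columns: {sorted(missing)}")
    out: TMRegionMap = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.seq_id), []).append(
            TMRegion(int(row.tm_index), int(row.start_col), int(row.end_col),
                     int(row.h_center_col), str(row.n_term_side))
        )
    return out


def results_to_tsv(results: list[SimilarityResult], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "scope": r.scope,
                "percentage": round(r.percentage, 6) if r.defined else "",
                "n_comparisons": r.n_comparisons,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
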