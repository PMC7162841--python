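"""Motif co-occurrence odds ratios on alignment columns.

Given two motif queries (sets of alignment columns with expected residues,
wildcards allowed), each scoreable sequence falls into one cell of a 2x2
contingency table and the odds ratio ``n11*n00 / (n10*n01)`` measures how
strongly the two motifs co-occur: an odds ratio of 2 means a sequence
carrying motif A is twice as likely to carry motif B.  Sequences with a gap
at any queried column are unscoreable and dropped (and reported).  The
Haldane-Anscombe correction (add 0.5 to every cell) keeps the ratio finite
when a cell is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .divergence import MSA


class CoevolutionError(Exception):
    pass


@dataclass(frozen=True)
class MotifQuery:
    """Alignment columns plus the expected letters (``x`` = wildcard)."""

    positions: tuple[int, ...]
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) != len(self.positions):
            raise CoevolutionError("pattern length must equal positions length")
        if list(self.positions) != sorted(set(self.positions)):
            raise CoevolutionError("positions must be strictly increasing")

    @classmethod
    def parse(cls, text: str) -> "MotifQuery":
        """Parse CLI syntax like ``"412:S"`` or ``"1003:N,1004:S"``."""
        pairs = []
        for item in text.split(","):
            col, _, letter = item.partition(":")
            if not col.strip().isdigit() or len(letter.strip()) != 1:
                raise CoevolutionError(f"bad motif component {item!r}")
            pairs.append((int(col), letter.strip()))
        pairs.sort()
        return cls(tuple(c for c, _ in pairs), "".join(l for _, l in pairs))


def match_motif(row: str, query: MotifQuery) -> bool | None:
    """True/False match, or None when a queried column holds a gap."""
    for col, want in zip(query.positions, query.pattern):
        if not 0 <= col < len(row):
            raise CoevolutionError(f"column {col} out of bounds")
        have = row[col]
        if have == "-":
            return None
        if want.lower() == "x":
            continue
        if have.upper() != want.upper():
            return False
    return True


@dataclass
class OddsRatioResult:
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float               # may be inf when uncorrected
    correction_applied: bool
    n_unscoreable: int = 0

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)

    def log_se(self) -> float:
        """Woolf standard error of log(OR), on the corrected table."""
        cells = [c + (0.5 if self.correction_applied else 0.0) for c in self.counts]
        if any(c == 0 for c in cells):
            return math.inf
        return math.sqrt(sum(1.0 / c for c in cells))

    def to_dict(self) -> dict:
        return {
            "n11": self.n11, "n10": self.n10, "n01": self.n01, "n00": self.n00,
            "odds_ratio": self.odds_ratio,
            "correction_applied": self.correction_applied,
            "n_unscoreable": self.n_unscoreable,
        }


def odds_ratio(
    msa: MSA,
    query_a: MotifQuery,
    query_b: MotifQuery,
    correction: str = "none",
) -> OddsRatioResult:
    """2x2 co-occurrence odds ratio of two motifs over the MSA rows."""
    if correction not in ("none", "haldane"):
        raise CoevolutionError("correction must be 'none' or 'haldane'")
    n11 = n10 = n01 = n00 = dropped = 0
    for row in msa.rows:
        a = match_motif(row, query_a)
        b = match_motif(row, query_b)
        if a is None or b is None:
            dropped += 1
            continue
        if a and b:
            n11 += 1
        elif a:
            n10 += 1
        elif b:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    if total == 0:
        raise CoevolutionError("zero scoreable sequences")
    apply_corr = correction == "haldane" and 0 in (n11, n10, n01, n00)
    if apply_corr:
        a11, a10, a01, a00 = (c + 0.5 for c in (n11, n10, n01, n00))
    else:
        a11, a10, a01, a00 = float(n11), float(n10), float(n01), float(n00)
    if a10 * a01 == 0.0:
        ratio = math.inf
    else:
        ratio = (a11 * a00) / (a10 * a01)
    return OddsRatioResult(n11, n10, n01, n00, ratio, apply_corr, dropped)
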