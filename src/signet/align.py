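"""Pairwise global alignment and star-progressive multiple alignment.

Signature discovery operates on an alignment of the reference panel. Panels
aligned elsewhere (any aligner emitting gapped FASTA) can be ingested
directly; for unaligned input this module provides an affine-gap
Needleman-Wunsch/Gotoh pairwise aligner and a star-progressive multiple
aligner ("once a gap, always a gap") adequate for barcode-scale congeneric
divergence.

The traceback is deterministic: on score ties the diagonal move is
preferred over a gap in the second sequence ("up"), which is preferred
over a gap in the first ("left").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .seqio import GAP, IUPAC_SETS, SeqRecord

__all__ = [
    "ScoringScheme",
    "DEFAULT_SCHEME",
    "Alignment",
    "ConfigError",
    "base_score",
    "global_align",
    "build_msa",
]

NEG_INF = float("-inf")


class ConfigError(ValueError):
    """Invalid scoring configuration."""


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: a gap of length k costs gap_open + k*gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ConfigError("match reward must be positive")
        if self.mismatch >= 0:
            raise ConfigError("mismatch penalty must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ConfigError("gap penalties must be <= 0")


#: Default scheme for barcode-scale sequences with few indels.
DEFAULT_SCHEME = ScoringScheme()


def base_score(a: str, b: str, s: ScoringScheme) -> int:
    """Score two IUPAC bases: match when their base sets intersect.

    A concrete base therefore matches an ambiguity code that contains it;
    two ambiguity codes match when they share at least one base. This is a
    conservative choice for diagnosticity (an N never creates a mismatch).
    """
    if a in IUPAC_SETS and b in IUPAC_SETS and IUPAC_SETS[a] & IUPAC_SETS[b]:
        return s.match
    return s.mismatch


@dataclass
class Alignment:
    """Equal-length gapped rows over a common coordinate system."""

    rows: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        L = len(self.rows[0].seq)
        if any(len(r.seq) != L for r in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0].seq)

    def column(self, j: int) -> list[str]:
        return [r.seq[j] for r in self.rows]

    def col_to_ungapped(self, row: int) -> list[Optional[int]]:
        """Per column: ungapped offset in that row's sequence, or None at gaps."""
        out: list[Optional[int]] = []
        k = 0
        for ch in self.rows[row].seq:
            if ch == GAP:
                out.append(None)
            else:
                out.append(k)
                k += 1
        return out

    def degapped_row(self, row: int) -> str:
        return self.rows[row].seq.replace(GAP, "")

    @classmethod
    def from_equal_length(cls, records: Sequence[SeqRecord]) -> "Alignment":
        """Treat equal-length ungapped records as trivially aligned columns."""
        L = len(records[0].seq)
        if any(len(r.seq) != L for r in records):
            raise ValueError("records must have equal length")
        rows = [
            SeqRecord(r.id, r.seq, r.species, r.role, is_gapped=True)
            for r in records
        ]
        return cls(rows)


def _gapped(rec: SeqRecord, seq: str) -> SeqRecord:
    return SeqRecord(rec.id, seq, rec.species, rec.role, is_gapped=True)


def _as_record(x: "SeqRecord | str", default_id: str) -> tuple[Optional[SeqRecord], str]:
    if isinstance(x, SeqRecord):
        if x.is_gapped:
            raise ValueError("global_align expects ungapped records")
        return x, x.seq
    return None, x.upper()


def global_align(
    a: "SeqRecord | str", b: "SeqRecord | str", s: ScoringScheme = DEFAULT_SCHEME
) -> tuple[Optional[Alignment], int]:
    """Optimal global alignment of two ungapped sequences under *s*.

    Returns a two-row alignment and its score. An empty sequence aligns to
    all-gaps (a length-k gap costs ``gap_open + k*gap_extend``); two empty
    sequences yield score 0 and no alignment.
    """
    rec_a, x = _as_record(a, "seq_a")
    rec_b, y = _as_record(b, "seq_b")
    n, m = len(x), len(y)
    go, ge = s.gap_open, s.gap_extend
    if n == 0 and m == 0:
        return None, 0

    # States: 0 = M (diagonal), 1 = X (gap in b, consumes a: "up"),
    #         2 = Y (gap in a, consumes b: "left").
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr: dict[tuple[int, int, int], int] = {}

    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = go + i * ge
    for j in range(1, m + 1):
        Y[0][j] = go + j * ge

    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            sc = base_score(xi, y[j - 1], s)
            # Tie-breaks throughout prefer M, then X ("up"), then Y ("left").
            best, arg = M[i - 1][j - 1], 0
            if X[i - 1][j - 1] > best:
                best, arg = X[i - 1][j - 1], 1
            if Y[i - 1][j - 1] > best:
                best, arg = Y[i - 1][j - 1], 2
            M[i][j] = best + sc
            ptr[(i, j, 0)] = arg
            best, arg = M[i - 1][j] + go + ge, 0
            if X[i - 1][j] + ge > best:
                best, arg = X[i - 1][j] + ge, 1
            if Y[i - 1][j] + go + ge > best:
                best, arg = Y[i - 1][j] + go + ge, 2
            X[i][j] = best
            ptr[(i, j, 1)] = arg
            best, arg = M[i][j - 1] + go + ge, 0
            if X[i][j - 1] + go + ge > best:
                best, arg = X[i][j - 1] + go + ge, 1
            if Y[i][j - 1] + ge > best:
                best, arg = Y[i][j - 1] + ge, 2
            Y[i][j] = best
            ptr[(i, j, 2)] = arg

    finals = (M[n][m], X[n][m], Y[n][m])
    score = max(finals)
    state = finals.index(score)  # prefers M > X > Y on ties

    ga: list[str] = []
    gb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if j == 0:
            ga.append(x[i - 1])
            gb.append(GAP)
            i -= 1
            continue
        if i == 0:
            ga.append(GAP)
            gb.append(y[j - 1])
            j -= 1
            continue
        if state == 0:
            ga.append(x[i - 1])
            gb.append(y[j - 1])
            state = ptr[(i, j, 0)]
            i, j = i - 1, j - 1
        elif state == 1:
            ga.append(x[i - 1])
            gb.append(GAP)
            state = ptr[(i, j, 1)]
            i -= 1
        else:
            ga.append(GAP)
            gb.append(y[j - 1])
            state = ptr[(i, j, 2)]
            j -= 1
    ga.reverse()
    gb.reverse()

    # placeholder records only carry id/species metadata; seq is replaced
    row_a = rec_a if rec_a is not None else SeqRecord("seq_a", x if x else "N")
    row_b = rec_b if rec_b is not None else SeqRecord("seq_b", y if y else "N")
    aln = Alignment([_gapped(row_a, "".join(ga)), _gapped(row_b, "".join(gb))])
    return aln, int(score)


def _merge_into_master(
    master: str, center_gapped: str
) -> tuple[str, list[int], list[int]]:
    """Merge two gapped views of the same center sequence.

    Returns the merged center string plus, for each output column, the
    source column in *master* (or -1 for an inserted gap) and in
    *center_gapped* (or -1). Both inputs degap to the same sequence.
    """
    out: list[str] = []
    from_master: list[int] = []
    from_new: list[int] = []
    i = j = 0
    while i < len(master) or j < len(center_gapped):
        mi = master[i] if i < len(master) else None
        cj = center_gapped[j] if j < len(center_gapped) else None
        if mi is not None and cj is not None and mi != GAP and cj != GAP:
            out.append(mi)
            from_master.append(i)
            from_new.append(j)
            i += 1
            j += 1
        elif mi == GAP:
            out.append(GAP)
            from_master.append(i)
            from_new.append(-1)
            i += 1
        else:  # cj == GAP (insertion in the new pairwise alignment)
            out.append(GAP)
            from_master.append(-1)
            from_new.append(j)
            j += 1
    return "".join(out), from_master, from_new


def build_msa(
    records: Sequence[SeqRecord], s: ScoringScheme = DEFAULT_SCHEME
) -> Alignment:
    """Star-progressive multiple alignment.

    The center is the record maximizing its summed pairwise score against
    all others (first on ties); every other record is merged through the
    center's coordinates with the "once a gap, always a gap" rule. Row
    order follows input order.
    """
    records = list(records)
    if any(r.is_gapped for r in records):
        raise ValueError("build_msa expects ungapped records")
    if len(records) == 1:
        warnings.warn("single-record MSA is trivial", stacklevel=2)
        return Alignment([_gapped(records[0], records[0].seq)])
    n = len(records)
    scores = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            _, sc = global_align(records[i], records[j], s)
            scores[i][j] = scores[j][i] = sc
    sums = [sum(row) for row in scores]
    center = max(range(n), key=lambda i: (sums[i], -i))

    master = records[center].seq
    aligned: dict[int, str] = {center: master}
    for idx in range(n):
        if idx == center:
            continue
        pair, _ = global_align(records[center], records[idx], s)
        c_g, o_g = pair.rows[0].seq, pair.rows[1].seq
        new_master, from_master, from_new = _merge_into_master(master, c_g)
        for k in list(aligned):
            old = aligned[k]
            aligned[k] = "".join(
                old[src] if src >= 0 else GAP for src in from_master
            )
        aligned[idx] = "".join(
            o_g[src] if src >= 0 else GAP for src in from_new
        )
        master = new_master
        aligned[center] = master

    rows = [_gapped(records[i], aligned[i]) for i in range(n)]
    return Alignment(rows)
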