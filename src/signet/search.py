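"""Local similarity search for short queries with Karlin-Altschul statistics.

A word-seeded, ungapped x-drop extension search over both strands of a
small sequence set, reporting BLAST-style metrics: raw score S, bit score
S' = (lambda*S - ln K)/ln 2 and expectation E = m*n*2^(-S').

Signature queries are 30-40 bp, so gapped extension is deliberately out of
scope; E-values use the raw search-space product m*n without edge-effect
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .seqio import SeqRecord, revcomp

__all__ = [
    "SearchParams",
    "SearchHit",
    "SearchParameterError",
    "bit_score",
    "evalue",
    "seed_extend_search",
    "hits_to_tsv",
]


class SearchParameterError(ValueError):
    """Invalid search parameterization (word size, lambda, K...)."""


@dataclass(frozen=True)
class SearchParams:
    """Scoring and significance parameters.

    ``lambda_ka`` and ``k_ka`` are the Karlin-Altschul parameters for the
    +1/-2 scoring system; they are exposed because published values depend
    on the search program and database composition. ``db_length_n`` and
    ``query_length_m`` default to the actual lengths at search time.
    """

    word_size: int = 7
    match: int = 1
    mismatch: int = -2
    x_drop: int = 10
    lambda_ka: float = 1.28
    k_ka: float = 0.46
    db_length_n: int | None = None
    query_length_m: int | None = None

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise SearchParameterError("word_size must be >= 4")
        if self.lambda_ka <= 0:
            raise SearchParameterError("lambda_ka must be positive")
        if not (0 < self.k_ka < 1):
            raise SearchParameterError("k_ka must lie in (0, 1)")
        if self.match <= 0 or self.mismatch >= 0:
            raise SearchParameterError("match must be > 0 and mismatch < 0")


@dataclass(frozen=True)
class SearchHit:
    """One ungapped local hit; coordinates are half-open, subject forward strand."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-"
    raw_score: int
    bit_score: float
    evalue: float
    identity: float  # percent
    query_cover: float  # percent
    mismatches: int = 0


def bit_score(S: int, p: SearchParams) -> float:
    """Normalized score S' = (lambda*S - ln K) / ln 2."""
    return (p.lambda_ka * S - math.log(p.k_ka)) / math.log(2.0)


def evalue(S_prime: float, p: SearchParams) -> float:
    """Expected chance hits E = m * n * 2^(-S')."""
    m = p.query_length_m
    n = p.db_length_n
    if not m or not n or m <= 0 or n <= 0:
        raise SearchParameterError("query_length_m and db_length_n must be positive")
    return m * n * math.pow(2.0, -S_prime)


def _extend(query: str, subject: str, qs: int, ss: int, length: int,
            p: SearchParams) -> tuple[int, int, int]:
    """X-drop ungapped extension of an exact seed.

    Returns (q_start, q_end, score) of the best-scoring extension of the
    seed ``query[qs:qs+length] == subject[ss:ss+length]`` along its diagonal.
    """
    score = length * p.match
    best = score
    # right extension
    qe, se = qs + length, ss + length
    best_qe = qe
    cur = score
    while qe < len(query) and se < len(subject):
        cur += p.match if query[qe] == subject[se] else p.mismatch
        qe += 1
        se += 1
        if cur > best:
            best, best_qe = cur, qe
        elif best - cur > p.x_drop:
            break
    # left extension, starting from the best right-extended score
    cur = best
    qb, sb = qs, ss
    best_qb = qs
    while qb > 0 and sb > 0:
        qb -= 1
        sb -= 1
        cur += p.match if query[qb] == subject[sb] else p.mismatch
        if cur > best:
            best, best_qb = cur, qb
        elif best - cur > p.x_drop:
            break
    return best_qb, best_qe, best


def _search_one_strand(query: str, query_id: str, subject: SeqRecord,
                       p: SearchParams) -> list[tuple[int, int, int]]:
    """All distinct best extensions (q_start, q_end, score) on one strand."""
    w = p.word_size
    subj = subject.seq
    words: dict[str, list[int]] = {}
    for i in range(len(query) - w + 1):
        words.setdefault(query[i : i + w], []).append(i)
    out: list[tuple[int, int, int, int]] = []
    for j in range(len(subj) - w + 1):
        positions = words.get(subj[j : j + w])
        if not positions:
            continue
        for qs in positions:
            diag = j - qs
            qb, qe, score = _extend(query, subj, qs, j, p.word_size, p)
            out.append((diag, qb, qe, score))
    # dedupe identical intervals on the same diagonal, keep best score
    best: dict[tuple[int, int, int], int] = {}
    for diag, qb, qe, score in out:
        k = (diag, qb, qe)
        if k not in best or score > best[k]:
            best[k] = score
    return [(qb, qe, sc, diag) for (diag, qb, qe), sc in best.items()]


def _select_non_overlapping(cands: list[SearchHit]) -> list[SearchHit]:
    """Greedy best-first selection of subject-disjoint hits."""
    cands = sorted(cands, key=lambda h: (-h.raw_score, h.s_start, h.q_start))
    chosen: list[SearchHit] = []
    for h in cands:
        if all(
            h.s_end <= c.s_start or h.s_start >= c.s_end for c in chosen
        ):
            chosen.append(h)
    return chosen


def seed_extend_search(
    query: SeqRecord, db: Sequence[SeqRecord], p: SearchParams = SearchParams()
) -> list[SearchHit]:
    """Search *query* against every record in *db*, both strands.

    Exact ``word_size``-mers seed ungapped x-drop extensions; per subject
    the best non-overlapping hits are kept. Hits carry identity
    (matches/alignment length), query coverage, bit score and E-value, and
    are returned sorted by bit score (descending).
    """
    q = query.seq.replace("-", "")
    if len(q) < p.word_size:
        raise SearchParameterError(
            f"query length {len(q)} < word_size {p.word_size}"
        )
    n_db = p.db_length_n or sum(len(r.seq) for r in db)
    eff = replace(p, db_length_n=n_db, query_length_m=len(q))

    all_hits: list[SearchHit] = []
    for subject in db:
        cands: list[SearchHit] = []
        for strand, qseq in (("+", q), ("-", revcomp(q))):
            for qb, qe, score, diag in _search_one_strand(qseq, query.id, subject, eff):
                sb, se = qb + diag, qe + diag
                length = qe - qb
                matches = sum(
                    1 for k in range(length) if qseq[qb + k] == subject.seq[sb + k]
                )
                if strand == "-":
                    oqb, oqe = len(q) - qe, len(q) - qb
                else:
                    oqb, oqe = qb, qe
                sp = bit_score(score, eff)
                cands.append(
                    SearchHit(
                        query_id=query.id,
                        subject_id=subject.id,
                        q_start=oqb,
                        q_end=oqe,
                        s_start=sb,
                        s_end=se,
                        strand=strand,
                        raw_score=score,
                        bit_score=sp,
                        evalue=evalue(sp, eff),
                        identity=100.0 * matches / length,
                        query_cover=100.0 * length / len(q),
                        mismatches=length - matches,
                    )
                )
        all_hits.extend(_select_non_overlapping(cands))
    all_hits.sort(key=lambda h: (-h.bit_score, h.subject_id, h.s_start))
    return all_hits


def hits_to_tsv(hits: Sequence[SearchHit]) -> str:
    """BLAST outfmt-6-like TSV rendering of hits."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    h.query_id,
                    h.subject_id,
                    f"{h.identity:.2f}",
                    h.q_end - h.q_start,
                    h.mismatches,
                    h.q_start,
                    h.q_end,
                    h.s_start,
                    h.s_end,
                    f"{h.evalue:.2e}",
                    f"{h.bit_score:.1f}",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
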