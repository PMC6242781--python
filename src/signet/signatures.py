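"""Species-diagnostic SNP calling and nucleotide-signature extraction.

A *diagnostic site* is an alignment column where (nearly) all sequences of
the target species share an allele that no other panel species carries. A
*nucleotide signature* is a short (default 30-40 bp) ungapped window of a
target reference sequence that contains one or more diagnostic sites and,
as a whole, occurs in no non-target panel sequence. Such windows remain
amplifiable from heavily degraded DNA where a full barcode fails.

Diagnosticity here is allele-presence-based: the target allele must be
absent from *all* non-target rows, matching the absolute-specificity
notion the signatures are meant to certify. An ambiguity code in a
non-target row whose base set contains the target allele disqualifies the
column (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import Alignment
from .search import SearchHit, SearchParams, seed_extend_search
from .seqio import GAP, IUPAC_SETS, ReferencePanel, SeqRecord

__all__ = [
    "DiagnosticSite",
    "SignatureConstraints",
    "NucleotideSignature",
    "DiscoveryError",
    "find_diagnostic_sites",
    "extract_signature",
    "verify_uniqueness",
]


class DiscoveryError(RuntimeError):
    """No qualifying signature window exists under the given constraints."""


@dataclass(frozen=True)
class DiagnosticSite:
    """One species-diagnostic alignment column."""

    column: int
    target_allele: str
    background_alleles: frozenset[str]
    fixed_in_target: bool = True
    n_excluded_target_rows: int = 0  # gap/N target rows left out of the denominator


@dataclass(frozen=True)
class SignatureConstraints:
    """Window-length and fixedness constraints for signature extraction."""

    l_min: int = 30
    l_max: int = 40
    min_sites: int = 1
    fixedness: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.l_min <= self.l_max):
            raise ValueError("need 0 < l_min <= l_max")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if not (0 < self.fixedness <= 1):
            raise ValueError("fixedness must lie in (0, 1]")


@dataclass(frozen=True)
class NucleotideSignature:
    """A unique diagnostic window on a reference record.

    ``start``/``end`` are ungapped, half-open coordinates on the forward
    strand of ``ref_record``; ``site_offsets`` locate the diagnostic sites
    within the signature sequence itself.
    """

    species: str
    seq: str
    ref_record: str
    start: int
    end: int
    site_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if GAP in self.seq:
            raise ValueError("signature sequence must be ungapped")
        if len(self.seq) != self.end - self.start:
            raise ValueError("signature length inconsistent with coordinates")
        if not self.site_offsets:
            raise ValueError("signature must contain at least one diagnostic site")
        if any(o < 0 or o >= len(self.seq) for o in self.site_offsets):
            raise ValueError("site offsets must fall inside the signature")

    def __len__(self) -> int:
        return len(self.seq)


def _rows_by_species(
    aln: Alignment, panel: ReferencePanel, target: str
) -> tuple[list[int], list[int]]:
    panel_ids = {r.id for r in panel.records}
    for row in aln.rows:
        if row.id not in panel_ids:
            raise LookupError(f"alignment row {row.id!r} absent from panel")
    tgt = [i for i, r in enumerate(aln.rows) if r.species == target]
    bkg = [i for i, r in enumerate(aln.rows) if r.species != target]
    if not tgt:
        raise LookupError(f"target species {target!r} has no rows in the alignment")
    return tgt, bkg


def find_diagnostic_sites(
    aln: Alignment,
    panel: ReferencePanel,
    target: str,
    c: SignatureConstraints = SignatureConstraints(),
) -> list[DiagnosticSite]:
    """Columns where the target species carries a private allele.

    A column qualifies when (i) at least ``c.fixedness`` of the informative
    target rows (gaps and N excluded from the denominator) share a concrete
    allele, (ii) no non-target row carries that allele -- an ambiguity code
    containing it also disqualifies -- and (iii) the allele is not a gap.
    Sites are returned sorted by column.
    """
    tgt, bkg = _rows_by_species(aln, panel, target)
    sites: list[DiagnosticSite] = []
    for col in range(aln.length):
        chars = [aln.rows[i].seq[col] for i in tgt]
        informative = [ch for ch in chars if ch not in (GAP, "N")]
        n_excluded = len(chars) - len(informative)
        if not informative:
            continue
        counts: dict[str, int] = {}
        for ch in informative:
            counts[ch] = counts.get(ch, 0) + 1
        allele, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if allele not in "ACGT":
            continue
        frac = count / len(informative)
        if frac < c.fixedness:
            continue
        bkg_chars = {aln.rows[i].seq[col] for i in bkg}
        clash = any(
            ch != GAP and allele in IUPAC_SETS.get(ch, frozenset())
            for ch in bkg_chars
        )
        if clash:
            continue
        sites.append(
            DiagnosticSite(
                column=col,
                target_allele=allele,
                background_alleles=frozenset(bkg_chars - {allele}),
                fixed_in_target=(frac >= c.fixedness),
                n_excluded_target_rows=n_excluded,
            )
        )
    return sites


def verify_uniqueness(
    sig: NucleotideSignature,
    panel: ReferencePanel,
    max_ident: float = 1.0,
    search_params: SearchParams = SearchParams(),
) -> tuple[bool, list[SearchHit]]:
    """Check that the signature occurs in no non-target panel sequence.

    A non-target record is an *offender* when the local search finds a hit
    covering the full query with identity >= ``max_ident``. Returns
    (unique, offenders sorted by identity descending).
    """
    query = SeqRecord(id=f"sig_{sig.species.replace(' ', '_')}", seq=sig.seq)
    db = [r.degapped() for r in panel.records if r.species != sig.species]
    if not db:
        return True, []
    hits = seed_extend_search(query, db, search_params)
    offenders = [
        h
        for h in hits
        if h.query_cover >= 100.0 - 1e-9 and h.identity >= max_ident * 100.0 - 1e-9
    ]
    offenders.sort(key=lambda h: (-h.identity, h.subject_id))
    return (not offenders), offenders


def extract_signature(
    aln: Alignment,
    panel: ReferencePanel,
    target: str,
    sites: Sequence[DiagnosticSite],
    c: SignatureConstraints = SignatureConstraints(),
    max_ident: float = 1.0,
) -> NucleotideSignature:
    """Extract the shortest unique window containing diagnostic sites.

    The window lives on the first target row (input order). Candidate
    windows are scanned shortest-first, left-to-right, so the result is
    the leftmost window of minimal admissible length that (a) holds at
    least ``c.min_sites`` diagnostic sites, (b) is gap-free in the
    reference row, and (c) passes :func:`verify_uniqueness`. Lengths grow
    toward ``l_max`` before the search fails.
    """
    if not sites:
        raise DiscoveryError("no diagnostic sites supplied")
    tgt, _ = _rows_by_species(aln, panel, target)
    rep = tgt[0]
    rep_row = aln.rows[rep]
    col_map = aln.col_to_ungapped(rep)
    ref_seq = aln.degapped_row(rep)

    # diagnostic-site columns mapped onto ungapped reference offsets
    site_pos: list[int] = []
    for site in sites:
        off = col_map[site.column]
        if off is None:
            continue  # site falls in a gap of the representative row
        if rep_row.seq[site.column] == site.target_allele:
            site_pos.append(off)
    if not site_pos:
        raise DiscoveryError(
            "no diagnostic site is realized on the representative row"
        )
    site_pos.sort()

    blocking: Optional[SearchHit] = None
    for L in range(c.l_min, c.l_max + 1):
        if L > len(ref_seq):
            break
        for start in range(0, len(ref_seq) - L + 1):
            inside = [p - start for p in site_pos if start <= p < start + L]
            if len(inside) < c.min_sites:
                continue
            candidate = NucleotideSignature(
                species=target,
                seq=ref_seq[start : start + L],
                ref_record=rep_row.id,
                start=start,
                end=start + L,
                site_offsets=tuple(inside),
            )
            unique, offenders = verify_uniqueness(candidate, panel, max_ident)
            if unique:
                return candidate
            blocking = offenders[0]
    msg = "no qualifying signature window"
    if blocking is not None:
        msg += (
            f"; best candidate blocked by panel hit in {blocking.subject_id!r}"
            f" at {blocking.identity:.1f}% identity"
        )
    raise DiscoveryError(msg)
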