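"""Species-specific PCR assays: primer metrics, pair design, in-silico PCR.

The wet-lab notion of a "species-specific" primer pair is modeled by a
mismatch-tolerance policy: a primer binds a template site when it aligns
with at most ``max_mismatch`` mismatches overall and *zero* mismatches in
its 3'-terminal ``three_prime_anchor`` bases (polymerase extension is most
sensitive to 3' mispairing). An amplicon is predicted whenever a forward
site and a downstream reverse-complement site fall within the allowed
product-size range.

Melting temperatures use nearest-neighbor thermodynamics
(Bio.SeqUtils.MeltingTemp) with a salt correction at the stated oligo
concentration; the Wallace 2+4 rule is used below 14 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .seqio import ReferencePanel, SeqRecord, load_primer_fixture, revcomp
from .signatures import NucleotideSignature

__all__ = [
    "TmParams",
    "Primer",
    "Assay",
    "PcrParams",
    "AmpliconHit",
    "PrimerDesignConstraints",
    "DesignError",
    "primer_tm",
    "gc_percent",
    "has_3prime_self_dimer",
    "design_primer_pairs",
    "insilico_pcr",
    "detect_species",
    "load_assay_fixture",
]


class DesignError(RuntimeError):
    """No primer pair satisfies the design constraints."""


@dataclass(frozen=True)
class TmParams:
    """Conditions for nearest-neighbor melting-temperature prediction."""

    monovalent_salt_mM: float = 50.0
    oligo_conc_uM: float = 0.25
    nn_table: str = "DNA_NN4"  # SantaLucia & Hicks (2004) unified parameters

    def __post_init__(self) -> None:
        if self.monovalent_salt_mM <= 0 or self.oligo_conc_uM <= 0:
            raise ValueError("concentrations must be positive")


def primer_tm(seq: str, p: TmParams = TmParams()) -> float:
    """Melting temperature (deg C) of an unambiguous primer.

    Nearest-neighbor prediction with monovalent-salt correction for
    primers >= 14 nt; Wallace rule (2*AT + 4*GC) below that.
    """
    seq = seq.upper()
    if any(ch not in "ACGT" for ch in seq):
        raise ValueError("primer_tm requires an unambiguous A/C/G/T sequence")
    if len(seq) < 14:
        return float(_mt.Tm_Wallace(seq))
    table = getattr(_mt, p.nn_table)
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=table,
            Na=p.monovalent_salt_mM,
            # split the total oligo concentration over both duplex strands,
            # giving the standard CT/4 term for non-self-complementary duplexes
            dnac1=p.oligo_conc_uM * 500.0,  # nM
            dnac2=p.oligo_conc_uM * 500.0,
            saltcorr=5,
        )
    )


def gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * sum(1 for ch in seq if ch in "GC") / len(seq)


def has_3prime_self_dimer(seq: str, k: int = 5) -> bool:
    """True when the 3'-terminal k bases perfectly pair within the primer.

    A minimal self-dimer screen: if the reverse complement of the last k
    bases occurs anywhere in the primer, two copies can anneal with their
    3' ends paired and extend on each other.
    """
    seq = seq.upper()
    if len(seq) < k:
        return False
    return revcomp(seq[-k:]) in seq


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'."""

    name: str
    seq: str
    tm: float
    gc: float

    def __post_init__(self) -> None:
        if not (15 <= len(self.seq) <= 30):
            raise ValueError(f"primer {self.name}: length {len(self.seq)} outside 15..30")
        if any(ch not in "ACGT" for ch in self.seq):
            raise ValueError(f"primer {self.name}: ambiguous bases not allowed")

    @property
    def length(self) -> int:
        return len(self.seq)

    @classmethod
    def from_seq(cls, name: str, seq: str, tm_params: TmParams = TmParams()) -> "Primer":
        seq = seq.upper()
        return cls(name=name, seq=seq, tm=primer_tm(seq, tm_params), gc=gc_percent(seq))


@dataclass(frozen=True)
class Assay:
    """A species-specific primer pair with its expected product size."""

    forward: Primer
    reverse: Primer
    target_species: str
    expected_amplicon: int
    anneal_temp: float = 50.0

    def __post_init__(self) -> None:
        if self.expected_amplicon < self.forward.length + self.reverse.length:
            raise ValueError(
                "expected amplicon shorter than the two primers combined"
            )


@dataclass(frozen=True)
class PcrParams:
    """Binding tolerance policy for in-silico PCR."""

    max_mismatch: int = 2
    three_prime_anchor: int = 3  # 3'-terminal bases that must match exactly
    min_amplicon: int = 50
    max_amplicon: int = 2000

    def __post_init__(self) -> None:
        if self.min_amplicon >= self.max_amplicon:
            raise ValueError("min_amplicon must be < max_amplicon")
        if self.max_mismatch < 0 or self.three_prime_anchor < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product on the template's forward strand."""

    template_id: str
    start: int
    end: int
    f_mismatches: int
    r_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _binding_sites(
    primer_site: str, template: str, p: PcrParams, anchor_at_start: bool
) -> list[tuple[int, int]]:
    """(position, mismatches) of tolerated occurrences of *primer_site*.

    ``primer_site`` is the sequence expected on the template's forward
    strand. For a forward primer the 3' anchor is its *last* bases; for a
    reverse primer (given here as its reverse complement) the anchor is
    the *first* bases of the site.
    """
    L = len(primer_site)
    t = p.three_prime_anchor
    out: list[tuple[int, int]] = []
    for pos in range(len(template) - L + 1):
        window = template[pos : pos + L]
        anchor = window[:t] if anchor_at_start else window[L - t :]
        panchor = primer_site[:t] if anchor_at_start else primer_site[L - t :]
        if anchor != panchor:
            continue
        mm = sum(1 for a, b in zip(window, primer_site) if a != b)
        if mm <= p.max_mismatch:
            out.append((pos, mm))
    return out


def insilico_pcr(
    a: Assay, template: SeqRecord, p: PcrParams = PcrParams()
) -> list[AmpliconHit]:
    """Predict PCR products of assay *a* on an ungapped template.

    The forward primer is matched on the forward strand, the reverse
    primer as its reverse complement downstream; each binding tolerates at
    most ``max_mismatch`` mismatches and none within the 3' anchor.
    Products outside [min_amplicon, max_amplicon] are discarded. An empty
    list means no product.
    """
    if template.is_gapped:
        raise ValueError("insilico_pcr expects an ungapped template")
    seq = template.seq
    fwd_sites = _binding_sites(a.forward.seq, seq, p, anchor_at_start=False)
    rev_sites = _binding_sites(revcomp(a.reverse.seq), seq, p, anchor_at_start=True)
    hits: list[AmpliconHit] = []
    for fpos, fmm in fwd_sites:
        for rpos, rmm in rev_sites:
            end = rpos + a.reverse.length
            if end <= fpos + a.forward.length:
                continue
            length = end - fpos
            if p.min_amplicon <= length <= p.max_amplicon:
                hits.append(
                    AmpliconHit(
                        template_id=template.id,
                        start=fpos,
                        end=end,
                        f_mismatches=fmm,
                        r_mismatches=rmm,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def detect_species(
    pool: Sequence[SeqRecord],
    assays: Sequence[Assay],
    p: PcrParams = PcrParams(),
) -> dict[str, tuple[bool, list[AmpliconHit]]]:
    """Species presence calls for a fragment pool.

    A species is present when its assay yields at least one amplicon from
    any pool fragment; the supporting amplicons are retained as evidence.
    """
    targets = [a.target_species for a in assays]
    if len(set(targets)) != len(targets):
        raise ValueError("assays must target distinct species")
    out: dict[str, tuple[bool, list[AmpliconHit]]] = {}
    for assay in assays:
        evidence: list[AmpliconHit] = []
        for frag in pool:
            evidence.extend(insilico_pcr(assay, frag, p))
        out[assay.target_species] = (bool(evidence), evidence)
    return out


@dataclass(frozen=True)
class PrimerDesignConstraints:
    """Search space and acceptance thresholds for primer-pair design."""

    primer_len_min: int = 18
    primer_len_max: int = 21
    tm_min: float = 48.0
    tm_max: float = 64.0
    max_tm_diff: float = 5.0
    amplicon_min: int = 70
    amplicon_max: int = 140
    max_pairs: int = 10
    pcr: PcrParams = field(default_factory=PcrParams)
    tm_params: TmParams = field(default_factory=TmParams)


def _candidate_primers(
    ref: str, lengths: range, c: PrimerDesignConstraints
) -> list[tuple[int, int, float]]:
    """(start, length, tm) windows passing Tm and self-dimer screens."""
    out: list[tuple[int, int, float]] = []
    for start in range(len(ref)):
        for L in lengths:
            if start + L > len(ref):
                break
            window = ref[start : start + L]
            if any(ch not in "ACGT" for ch in window):
                continue
            tm = primer_tm(window, c.tm_params)
            if not (c.tm_min <= tm <= c.tm_max):
                continue
            out.append((start, L, tm))
    return out


def _specificity_margin(
    fwd: str, rev: str, non_targets: Sequence[SeqRecord], p: PcrParams
) -> int:
    """Minimal combined mismatch load at which any non-target amplifies.

    Bindings are probed with a relaxed tolerance (anchor enforced, up to
    ``max_mismatch + 3`` mismatches per primer); the margin is the
    smallest f+r mismatch total over amplifiable configurations, or a
    large sentinel when no non-target can amplify even relaxed.
    """
    relaxed = PcrParams(
        max_mismatch=p.max_mismatch + 3,
        three_prime_anchor=p.three_prime_anchor,
        min_amplicon=p.min_amplicon,
        max_amplicon=p.max_amplicon,
    )
    sentinel = 2 * relaxed.max_mismatch + 1
    best = sentinel
    rev_site = revcomp(rev)
    for rec in non_targets:
        seq = rec.degapped().seq
        f_sites = _binding_sites(fwd, seq, relaxed, anchor_at_start=False)
        if not f_sites:
            continue
        r_sites = _binding_sites(rev_site, seq, relaxed, anchor_at_start=True)
        for fpos, fmm in f_sites:
            for rpos, rmm in r_sites:
                end = rpos + len(rev)
                length = end - fpos
                if relaxed.min_amplicon <= length <= relaxed.max_amplicon:
                    best = min(best, fmm + rmm)
    return best


def design_primer_pairs(
    panel: ReferencePanel,
    target: str,
    sig: NucleotideSignature,
    constraints: PrimerDesignConstraints = PrimerDesignConstraints(),
) -> list[Assay]:
    """Design species-specific primer pairs whose product covers a
    diagnostic site of *sig*.

    Candidate forward/reverse windows on the signature's reference record
    are screened for length, Tm window, Tm balance and 3' self-dimers;
    pairs whose product misses every diagnostic site, or that amplify any
    non-target panel sequence under the PCR tolerance policy, are
    discarded. Survivors are ranked by (specificity margin descending,
    Tm difference ascending, product start) and returned as assays.
    """
    ref_rec = next((r for r in panel.records if r.id == sig.ref_record), None)
    if ref_rec is None:
        raise LookupError(f"signature reference {sig.ref_record!r} not in panel")
    ref = ref_rec.degapped().seq
    non_targets = [r for r in panel.records if r.species != target]
    sites_abs = [sig.start + o for o in sig.site_offsets]
    lengths = range(constraints.primer_len_min, constraints.primer_len_max + 1)

    fwd_cands = [
        (s, L, tm)
        for (s, L, tm) in _candidate_primers(ref, lengths, constraints)
        if not has_3prime_self_dimer(ref[s : s + L])
    ]
    rev_cands = [
        (s, L, tm, revcomp(ref[s : s + L]))
        for (s, L, tm) in _candidate_primers(ref, lengths, constraints)
        if not has_3prime_self_dimer(revcomp(ref[s : s + L]))
    ]

    scored: list[tuple[int, float, int, Assay]] = []
    blocking: Optional[str] = None
    for fs, fL, ftm in fwd_cands:
        for rs, rL, rtm_, rseq in rev_cands:
            end = rs + rL
            amp = end - fs
            if not (constraints.amplicon_min <= amp <= constraints.amplicon_max):
                continue
            if end <= fs + fL + 1:
                continue
            if abs(ftm - rtm_) > constraints.max_tm_diff:
                continue
            if not any(fs <= p_ < end for p_ in sites_abs):
                continue  # product must cover a diagnostic site
            fwd_seq = ref[fs : fs + fL]
            margin = _specificity_margin(
                fwd_seq, rseq, non_targets, constraints.pcr
            )
            if margin <= 2 * constraints.pcr.max_mismatch:
                # a non-target could amplify within tolerance: not specific
                blocking = f"non-target amplifiable at mismatch load {margin}"
                continue
            fwd = Primer.from_seq(f"{target[:2].upper()}F_{fs}", fwd_seq,
                                  constraints.tm_params)
            rev = Primer.from_seq(f"{target[:2].upper()}R_{rs}", rseq,
                                  constraints.tm_params)
            scored.append(
                (margin, abs(ftm - rtm_), fs,
                 Assay(fwd, rev, target, amp))
            )
    scored.sort(key=lambda t: (-t[0], t[1], t[2], t[3].expected_amplicon))
    if not scored:
        raise DesignError(
            "no specific primer pair found"
            + (f" ({blocking})" if blocking else "")
        )
    return [a for _, _, _, a in scored[: constraints.max_pairs]]


def load_assay_fixture() -> list[Assay]:
    """The six published primer pairs as :class:`Assay` objects."""
    assays: list[Assay] = []
    for entry in load_primer_fixture():
        fwd = Primer.from_seq(entry["name_f"], entry["seq_f"])
        rev = Primer.from_seq(entry["name_r"], entry["seq_r"])
        assays.append(
            Assay(
                forward=fwd,
                reverse=rev,
                target_species=entry["target_species"],
                expected_amplicon=int(entry["amplicon_size"]),
                anneal_temp=float(entry.get("anneal_temp", 50.0)),
            )
        )
    return assays
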