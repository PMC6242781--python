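"""Seeded generators for panels, mixture pools and degraded-DNA pools.

These emulate the statistical structure the signature method relies on:
a marker region (ITS2-scale, a few hundred bp) with congeneric divergence
between species, little variation within species, and one or two fixed
diagnostic substitutions private to each species of interest. Mixture
pools model powdered two-species blends at weight ratios; decoction pools
model boiling-induced fragmentation with a mean fragment length that
decays exponentially in boil time.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .seqio import ReferencePanel, Role, SeqRecord

__all__ = [
    "PanelSpec",
    "Fragment",
    "FragmentPool",
    "simulate_panel",
    "simulate_mixture_pool",
    "simulate_decoction",
]

BASES = "ACGT"


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a labeled marker-gene panel with planted diagnostic sites.

    ``planted_sites`` maps species name -> [(position, allele), ...]; each
    planted allele is forced in every member of its species and forced
    absent at that position in every other species.
    """

    seed: int
    n_species: int = 4
    n_seq_per_species: int = 5
    seq_length: int = 300
    interspecies_divergence: float = 0.05
    intraspecies_divergence: float = 0.0
    planted_sites: Mapping[str, Sequence[tuple[int, str]]] = field(
        default_factory=dict
    )
    roles: Optional[Mapping[str, Role]] = None

    def __post_init__(self) -> None:
        for d in (self.interspecies_divergence, self.intraspecies_divergence):
            if not (0 <= d < 0.5):
                raise ValueError("divergences must lie in [0, 0.5)")
        for sp, sites in self.planted_sites.items():
            for pos, allele in sites:
                if not (0 <= pos < self.seq_length):
                    raise ValueError(f"planted position {pos} outside sequence")
                if allele not in BASES:
                    raise ValueError(f"planted allele {allele!r} not concrete")

    def species_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_species)]


@dataclass(frozen=True)
class Fragment:
    """A degraded-DNA fragment with its provenance on the source template."""

    record: SeqRecord
    source_id: str
    start: int
    end: int


@dataclass(frozen=True)
class FragmentPool:
    """A pool of fragments, as produced by grinding/boiling simulations."""

    fragments: tuple[Fragment, ...]
    mean_len: float
    boil_time: float = 0.0
    decay_rate: float = 0.0

    @property
    def records(self) -> list[SeqRecord]:
        return [f.record for f in self.fragments]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability *rate*, to a different base."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = rng.random(len(seq)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in range(4) if b != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_panel(spec: PanelSpec) -> ReferencePanel:
    """Generate a labeled panel per *spec* (reproducible for a given seed).

    An ancestor sequence is mutated once per species (interspecies rate)
    and again per individual (intraspecies rate); planted alleles are then
    written into every member of their species and forced absent at those
    positions in all other species.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.species_names()
    ancestor = rng.integers(0, 4, size=spec.seq_length)
    species_seqs = {
        sp: _mutate(ancestor, spec.interspecies_divergence, rng) for sp in names
    }
    individuals: dict[str, list[np.ndarray]] = {
        sp: [
            _mutate(species_seqs[sp], spec.intraspecies_divergence, rng)
            for _ in range(spec.n_seq_per_species)
        ]
        for sp in names
    }
    # enforce planted diagnostic sites
    for sp, sites in spec.planted_sites.items():
        if sp not in individuals:
            raise ValueError(f"planted species {sp!r} not in panel")
        for pos, allele in sites:
            a_idx = BASES.index(allele)
            for seq in individuals[sp]:
                seq[pos] = a_idx
            for other, seqs in individuals.items():
                if other == sp:
                    continue
                for seq in seqs:
                    if seq[pos] == a_idx:
                        alternatives = [b for b in range(4) if b != a_idx]
                        seq[pos] = alternatives[int(rng.integers(0, 3))]

    roles = dict(spec.roles) if spec.roles else None
    records: list[SeqRecord] = []
    species_roles: dict[str, Role] = {}
    for si, sp in enumerate(names):
        role = (
            roles.get(sp, Role.OTHER)
            if roles
            else (Role.OFFICIAL if si == 0 else Role.ADULTERANT)
        )
        species_roles[sp] = role
        for k, seq in enumerate(individuals[sp]):
            records.append(
                SeqRecord(
                    id=f"{sp}_{k + 1}",
                    seq="".join(BASES[b] for b in seq),
                    species=sp,
                    role=role,
                )
            )
    return ReferencePanel(records=records, species_roles=species_roles)


def _draw_fragment(
    template: SeqRecord,
    mean_len: float,
    rng: np.random.Generator,
    idx: int,
) -> Fragment:
    """One fragment: uniform start, geometric length with the given mean.

    The length is drawn by inverse-CDF from a single uniform, so pools
    built from a common seed at decreasing mean lengths are coupled:
    every fragment shrinks monotonically as the mean decreases.
    """
    L = len(template.seq)
    start = int(rng.integers(0, L))
    u = float(rng.random())
    if mean_len <= 1.0:
        length = 1
    else:
        p = 1.0 / mean_len
        length = 1 + int(math.log1p(-u) / math.log1p(-p))
    end = min(L, start + max(1, length))
    rec = SeqRecord(
        id=f"{template.id}:frag{idx}:{start}-{end}",
        seq=template.seq[start:end],
        species=template.species,
        role=template.role,
    )
    return Fragment(record=rec, source_id=template.id, start=start, end=end)


def simulate_mixture_pool(
    panel: ReferencePanel,
    weights: Mapping[str, float],
    n_fragments: int,
    mean_len: float,
    seed: int,
) -> FragmentPool:
    """Fragment pool from a weighted species mixture.

    Each fragment's source species is drawn proportional to the mass
    weights (which must sum to 1), its template uniformly among that
    species' records, its start uniformly, and its length geometrically
    with the given mean (truncated at the template end).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {total})")
    species = list(weights)
    for sp in species:
        if not panel.records_for(sp):
            raise ValueError(f"species {sp!r} has no records in the panel")
    probs = np.array([weights[sp] for sp in species], dtype=float)
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    for i in range(n_fragments):
        sp = species[int(rng.choice(len(species), p=probs))]
        recs = panel.records_for(sp)
        template = recs[int(rng.integers(0, len(recs)))]
        fragments.append(_draw_fragment(template, mean_len, rng, i))
    return FragmentPool(fragments=tuple(fragments), mean_len=mean_len)


def simulate_decoction(
    template: SeqRecord,
    t: float,
    lambda0: float,
    k_deg: float,
    n_fragments: int,
    seed: int,
) -> FragmentPool:
    """Fragment pool after boiling for *t* minutes.

    The mean fragment length decays exponentially with boil time,
    lambda(t) = lambda0 * exp(-k_deg * t). With a fixed seed the pools at
    different times are coupled (common random numbers), so a fragment's
    span is non-increasing in t and assay detection is monotone per seed.
    """
    if t < 0:
        raise ValueError("boil time must be >= 0")
    if lambda0 <= 0 or k_deg < 0:
        raise ValueError("lambda0 must be > 0 and k_deg >= 0")
    mean_len = lambda0 * math.exp(-k_deg * t)
    rng = np.random.default_rng(seed)
    fragments = tuple(
        _draw_fragment(template, mean_len, rng, i) for i in range(n_fragments)
    )
    return FragmentPool(
        fragments=fragments,
        mean_len=mean_len,
        boil_time=t,
        decay_rate=k_deg,
    )
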