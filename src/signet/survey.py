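"""Product classification and market-survey adulteration statistics.

Each product carries the set of species detected by the signature assays.
Against a policy naming the official species and the known adulterants, a
product is:

* ``authentic`` -- only official species detected;
* ``adulterated_mixture`` -- official and adulterant species together;
* ``substituted`` -- adulterants but no official species (counterfeit);
* ``nonpanel_substituted`` -- only species outside both sets (e.g. a
  Salvia miltiorrhiza substitution);
* ``no_detection`` -- nothing detected.

The headline adulteration rate counts mixtures plus substitutions over
all products; non-panel substitutions are tallied separately so that the
difference from "everything non-authentic" stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

from .seqio import ProductRecord

__all__ = [
    "Category",
    "ClassificationPolicy",
    "SurveySummary",
    "classify_product",
    "summarize_survey",
]

OFFICIAL_DEFAULT = frozenset({"Cistanche deserticola", "Cistanche tubulosa"})
ADULTERANT_DEFAULT = frozenset(
    {
        "Cynomorium songaricum",
        "Cistanche sinensis",
        "Boschniakia rossica",
        "Orobanche coerulescens",
    }
)


class Category(str, Enum):
    AUTHENTIC = "authentic"
    ADULTERATED_MIXTURE = "adulterated_mixture"
    SUBSTITUTED = "substituted"
    NONPANEL_SUBSTITUTED = "nonpanel_substituted"
    NO_DETECTION = "no_detection"


@dataclass(frozen=True)
class ClassificationPolicy:
    """Which species count as official and which as known adulterants."""

    official_set: frozenset[str] = OFFICIAL_DEFAULT
    adulterant_set: frozenset[str] = ADULTERANT_DEFAULT

    def __post_init__(self) -> None:
        if not self.official_set or not self.adulterant_set:
            raise ValueError("official and adulterant sets must be non-empty")
        if self.official_set & self.adulterant_set:
            raise ValueError("official and adulterant sets must be disjoint")


def classify_product(
    detected: Iterable[str], policy: ClassificationPolicy = ClassificationPolicy()
) -> Category:
    """Classify a detected-species set (mutually exclusive, exhaustive)."""
    detected = frozenset(detected)
    if not detected:
        return Category.NO_DETECTION
    has_official = bool(detected & policy.official_set)
    has_adulterant = bool(detected & policy.adulterant_set)
    if has_official and has_adulterant:
        return Category.ADULTERATED_MIXTURE
    if has_adulterant:
        return Category.SUBSTITUTED
    if detected <= policy.official_set:
        return Category.AUTHENTIC
    # remaining: some non-panel species present (possibly alongside official
    # ones); grouped as the non-panel case to keep the partition exhaustive
    return Category.NONPANEL_SUBSTITUTED


def _rate(count: int, n: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in reports."""
    if n == 0:
        return 0.0
    return float(
        (Decimal(100 * count) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class SurveySummary:
    """Aggregate adulteration statistics over a set of products."""

    n_products: int
    n_authentic: int
    n_adulterated_mixture: int
    n_substituted: int
    n_nonpanel_substituted: int
    n_no_detection: int
    rate_adulteration: float
    rate_mixture: float
    rate_substitution: float
    raw_rate_adulteration: float
    per_species_detection_counts: dict[str, int]
    classifications: dict[str, Category]

    def __post_init__(self) -> None:
        total = (
            self.n_authentic
            + self.n_adulterated_mixture
            + self.n_substituted
            + self.n_nonpanel_substituted
            + self.n_no_detection
        )
        if total != self.n_products:
            raise ValueError("category counts must partition the products")


def summarize_survey(
    products: Sequence[ProductRecord],
    policy: ClassificationPolicy = ClassificationPolicy(),
    subset: Optional[Callable[[ProductRecord], bool]] = None,
) -> SurveySummary:
    """Classify every product and aggregate the survey statistics.

    ``rate_adulteration`` = (mixtures + substitutions) / n * 100; products
    substituted with species outside the panel are counted in their own
    category (and in no rate). An optional *subset* predicate restricts
    the summary, e.g. to one dose form or source table.
    """
    if subset is not None:
        products = [p for p in products if subset(p)]
    if not products:
        raise ValueError("no products to summarize")
    counts = {c: 0 for c in Category}
    classifications: dict[str, Category] = {}
    species_counts: dict[str, int] = {}
    for prod in sorted(products, key=lambda p: p.product_id):
        cat = classify_product(prod.detected_species, policy)
        counts[cat] += 1
        classifications[prod.product_id] = cat
        for sp in prod.detected_species:
            species_counts[sp] = species_counts.get(sp, 0) + 1
    n = len(products)
    n_mix = counts[Category.ADULTERATED_MIXTURE]
    n_sub = counts[Category.SUBSTITUTED]
    return SurveySummary(
        n_products=n,
        n_authentic=counts[Category.AUTHENTIC],
        n_adulterated_mixture=n_mix,
        n_substituted=n_sub,
        n_nonpanel_substituted=counts[Category.NONPANEL_SUBSTITUTED],
        n_no_detection=counts[Category.NO_DETECTION],
        rate_adulteration=_rate(n_mix + n_sub, n),
        rate_mixture=_rate(n_mix, n),
        rate_substitution=_rate(n_sub, n),
        raw_rate_adulteration=100.0 * (n_mix + n_sub) / n,
        per_species_detection_counts=dict(sorted(species_counts.items())),
        classifications=classifications,
    )
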