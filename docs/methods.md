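# Methods

This note records the models, conventions and design choices behind
`signet`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic data can and cannot
show.

## Coordinates, alphabet, names

All coordinates are 0-based, half-open, on the forward strand of the
stored sequence. Sequences are uppercase IUPAC DNA; `-` is the only gap
character and is legal only in records belonging to an aligned (gapped)
FASTA dialect, which requires equal record lengths. Species names are
full binomials; the abbreviations used in the source tables
("Cy. songaricum") are resolved through a synonym map. FASTA is written
with a 70-column wrap and read with any wrap.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh
three-state recursion). A gap of length k costs `gap_open + k*gap_extend`;
the default scheme (+1 match, −2 mismatch, −5 open, −2 extend) suits
barcode-scale sequences where indels are rare and diagnosticity should
not be diluted by generous mismatch scoring. Ambiguity codes score as a
match when the two base sets intersect — an `N` can never create a
mismatch — which is the conservative direction for diagnosticity.
Traceback ties are broken diagonal > up > left, making output
deterministic.

The multiple aligner is star-progressive: the center is the record with
the highest summed pairwise score (first on ties), and other records are
merged through the center's coordinates under "once a gap, always a gap".
This is adequate for congeneric marker-gene divergence (a few percent,
few indels); for anything harder, align externally and feed the gapped
FASTA in — every downstream step accepts pre-aligned input.

## Diagnostic sites and signatures

A column is diagnostic for a target species when (i) at least a
`fixedness` fraction (default 1.0) of the informative target rows — gaps
and `N` are excluded from the denominator — share one concrete base,
(ii) no non-target row carries that base, with an ambiguity code whose
set contains it also disqualifying, and (iii) the base is not a gap.
Diagnosticity is thus allele-presence-based, not frequency-based: a
single non-target copy of the allele kills the column. That matches the
absolute-specificity claim a diagnostic assay must certify.

Signature extraction scans windows on the first target row (input
order), shortest length first (default 30→40 bp), leftmost first, and
returns the first window that contains `min_sites` diagnostic sites and
whose sequence yields no full-coverage hit at ≥ `max_ident` identity
(default 1.0) in any non-target panel record, as judged by the package's
own local search. The representative-row and leftmost tie-breaks are
arbitrary but fixed, so discovery is reproducible; nothing in the
published signatures constrains how the window boundaries were chosen.

## Local search and significance

The uniqueness check and the signature verification tool use a
BLAST-style word-seeded search: exact 7-mers (default) seed ungapped
x-drop extensions on both strands; per subject the best non-overlapping
hits are kept. Gapped extension is deliberately omitted — 30–40 bp
queries essentially never need it, and an ungapped score is what the
identity/coverage thresholds assume. Bit scores use
`S' = (λS − ln K)/ln 2` with defaults λ = 1.28, K = 0.46 for the +1/−2
system, and `E = m·n·2^(−S')` on the raw search-space product, without
the finite-length edge correction used by production BLAST. These
statistics rank and filter hits inside the package; they are not meant to
reproduce any external database's printed scores, which depend on the
program, parameterization and database size used there.

## Melting temperature and primer design

Tm is nearest-neighbor (SantaLucia & Hicks 2004 unified parameters via
Biopython) with the ΔS salt correction `0.368·(N−1)·ln[Na+]` at 50 mM
monovalent salt and a 0.25 µM total oligo concentration split over both
strands (the standard CT/4 term for non-self-complementary duplexes).
Below 14 nt the Wallace 2+4 rule is used. The test suite cross-checks
the implementation against an independently written calculator with
published parameters to within 0.5 °C.

Primer design enumerates 18–21 nt windows (the range spanned by the six
published primers) on the signature's reference record, requires Tm in
48–64 °C with ≤ 5 °C pair imbalance, rejects primers whose 3'-terminal
5-mer can pair within the primer (a minimal self-dimer screen), and keeps
pairs whose product (70–140 bp, spanning the published 71–134 bp sizes)
covers at least one diagnostic site. A pair is *specific* when no
non-target panel sequence can amplify under the PCR tolerance policy;
surviving pairs are ranked by specificity margin (the smallest combined
mismatch load at which any non-target would amplify, probed with a
relaxed tolerance), then Tm balance.

## In-silico PCR

A primer binds where it aligns with at most `max_mismatch` mismatches
(default 2) and zero mismatches in its 3'-terminal `three_prime_anchor`
bases (default 3), encoding the fact that polymerase extension is most
sensitive to 3' mispairing. A product is reported for every
forward-site/reverse-site pair whose length falls in
[`min_amplicon`, `max_amplicon`] (defaults 50–2000 bp). The wet-lab
experiments the model mirrors demonstrate specificity but never
parameterize it; these defaults are documented guesses, and both knobs
are exposed. Annealing temperature is carried as assay metadata (50 °C
per the published thermal program) and plays no role in the matching
model.

## qPCR sensitivity

For a two-species mixture at weight ratio r:1, the minor component's
quantification cycle is modeled as `Cq = a + b·log10(r)`, fitted by
ordinary least squares on the detected points; "not detected" entries are
right-censored and excluded rather than imputed, because the instrument's
censoring cycle is unknown. A 1/sd² weighted fit is available but not the
default — the packaged table's replicate SDs are small and nearly
homoscedastic. Efficiency is `E = 10^(1/|b|) − 1`; the detection limit is
`LOD = 10^((cq_cutoff − a)/b)` with a default cutoff of 37 cycles, chosen
between the largest Cq printed in the dilution table (37.08) and the
censoring boundary, and configurable.

Two caveats the package surfaces rather than hides. First, the dilution
curves are convex: a single global line underpredicts late-cycle Cq, so
the extrapolated LOD exceeds the empirically observed censoring boundary
(e.g. ~6.8×10⁴ for the *Cy. songaricum* row whose last detection is at
15000:1). The LOD should be read as a model extrapolation, not a
calibrated detection claim. Second, `check_monotonicity` reports
adjacent-pair Cq inversions; the packaged table contains exactly one, in
the *O. coerulescens* row at its detection edge (36.38 at 30000:1 vs
36.16 at 40000:1), and the corresponding acceptance test is left failing
as a faithful record of that datum.

## Survey classification

Products are classified from their detected-species sets: authentic
(⊆ official set, non-empty), adulterated mixture (official and adulterant
both present), substituted (adulterant present, official absent),
non-panel substitution (detections outside both sets, possibly alongside
official species — grouped this way to keep the partition exhaustive),
and no detection. The headline adulteration rate is
(mixtures + substitutions)/n, excluding non-panel cases, which are
counted separately so the difference from "everything non-authentic"
stays visible. Rates are rounded half-up to one decimal, as printed in
survey reports; raw fractions are also emitted.

## Synthetic data

`simulate_panel` mutates a random ancestor per species (interspecies
rate, default 0.05 substitutions/site — congeneric marker-gene scale)
and per individual (intraspecies rate, default 0), then forces planted
diagnostic alleles into every member of their species and out of every
other species. One or two planted sites per target mirror the 1–2 SNP
structure the published signatures carry. Substitutions are uniform
(Jukes–Cantor-like); indels are not simulated, because diagnostic-site
calling excludes gap columns anyway.

Fragment pools draw a source (by mass weight for mixtures), a uniform
start, and a geometric length via inverse-CDF from a single uniform,
truncated at the template end. The geometric model is a one-parameter
stand-in for fragmentation; no fragment-length data exist for the
decoction experiments beyond band presence/absence. Decoction pools decay
the mean fragment length as `λ(t) = λ0·exp(−k_deg·t)`; the defaults
λ0 = 500 bp and k_deg = 0.012 min⁻¹ were chosen once so that a 123-bp
assay's detection survives ~150 min of boiling and collapses by 210–240
min, matching the qualitative band-loss pattern. Because lengths come
from inverse-CDF draws, pools generated from a common seed at different
boil times are coupled: every fragment shrinks monotonically with t, so
per-replicate detection is monotone by construction and the Monte-Carlo
detection curve is smooth at modest replicate counts.

What passing synthetic tests shows: the pipeline recovers exactly the
planted truth, never cross-detects species that differ at primer 3'
anchors, and degrades monotonically with fragmentation. What they cannot
show: performance on real ITS2 panels with indels, paralogs, incomplete
lineage sorting or sequencing noise, none of which the generators
emulate.

## Problem sizes

Test and acceptance runs use panels of 4 species × 3–5 sequences of
120–300 bp, 200-replicate parameter-recovery simulations, and 40-replicate
× 25-fragment decoction pools per boil time — sizes at which every
brute-force oracle (exhaustive alignment enumeration at length ≤ 6,
quadratic local-alignment scans at ~1 kb, naive column scans) is exact
and the whole suite runs in well under a minute.

## Known limitations

* Ungapped-only local search; signatures spanning indels are out of scope.
* The star MSA has no iterative refinement; heavily gapped panels should
  be aligned externally.
* E-values lack edge-effect correction and are for internal ranking only.
* Thermodynamic duplex simulation (ΔG off-target prediction, hairpin
  folding) is not modeled; the self-dimer screen is sequence-based.
* LOD extrapolation assumes log-linearity through the detection edge,
  which the real dilution curves visibly violate.
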