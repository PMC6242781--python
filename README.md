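# signet

Species-diagnostic **nucleotide signatures** for authenticating processed
herbal products, built around the Cistanches Herba (*Rou Cong Rong*)
reference system: the official species *Cistanche deserticola* and
*Cistanche tubulosa* versus the known adulterants *Cynomorium songaricum*,
*Cistanche sinensis*, *Boschniakia rossica* and *Orobanche coerulescens*.

Full-length DNA barcodes (e.g. the ~230-bp ITS2 region) fail on pills,
extracts and decoctions because processing fragments the DNA. A
*nucleotide signature* is a 30–40 bp window of the barcode containing one
or more diagnostic SNPs — an allele private to one species in the
reference universe — which stays amplifiable from degraded templates.
`signet` implements the whole workflow for analysts and toolmakers in
herbal-product quality control:

* **seqio** — FASTA/CSV I/O, IUPAC alphabet enforcement, packaged
  fixtures: the four published signatures (30/34/37/31 bp), the six
  species-specific primer pairs, the qPCR dilution table and the
  66-product market survey.
* **align** — affine-gap Needleman–Wunsch/Gotoh pairwise alignment and a
  star-progressive MSA (pre-aligned FASTA is accepted everywhere).
* **signatures** — diagnostic-SNP column calling and minimal-unique-window
  extraction with panel-wide uniqueness verification.
* **search** — word-seeded, ungapped x-drop local search with
  Karlin–Altschul statistics: bit score `S' = (λS − ln K)/ln 2`,
  expectation `E = m·n·2^(−S')`.
* **assay** — nearest-neighbor primer Tm, species-specific primer-pair
  design, in-silico PCR with a 3'-anchored mismatch policy, and species
  presence calls on fragment pools.
* **quant** — qPCR sensitivity: `Cq = a + b·log10(ratio)` fits,
  amplification efficiency `E = 10^(1/|b|) − 1`, detection-limit
  extrapolation.
* **survey** — product classification (authentic / adulterated mixture /
  substituted / non-panel substitution) and aggregate adulteration rates.
* **synthetic** — seeded generators for SNP-planted panels, weighted
  mixture pools and boiling-degraded (decoction) fragment pools.

## Worked example

Classify the 66 packaged market products and fit the qPCR dilution models:

```console
$ signet survey
n = 66: authentic 41, mixtures 13, substituted 11, non-panel 1, no detection 0
adulteration 36.4% (mixtures 19.7%, substitution 16.7%)
```

36.4% of products contain an adulterant: 19.7% mix an adulterant with
genuine material and 16.7% contain adulterant species only. One slice
batch was substituted with *Salvia miltiorrhiza*, a species outside the
reference panel, and is counted separately.

```console
$ signet qpcr | head -3
Cynomorium songaricum: Cq = 21.65 + 3.177*log10(r), R^2 = 0.9755, E = 106.4%, LOD ~ 67512:1
Cistanche sinensis: Cq = 19.59 + 3.734*log10(r), R^2 = 0.9937, E = 85.3%, LOD ~ 45940:1
Boschniakia rossica: Cq = 13.01 + 4.943*log10(r), R^2 = 0.9761, E = 59.3%, LOD ~ 71435:1
```

Each line is a dilution series of one adulterant mixed into genuine
material at weight ratios from 10:1 to 60000:1: the quantification cycle
rises log-linearly as the minor component is diluted, the slope's
magnitude near 3.32 indicates near-perfect per-cycle doubling, and the
LOD column extrapolates the largest ratio still predicted to be
detectable at the Cq-37 cutoff (an extrapolation that overshoots the
observed censoring boundary; see `docs/methods.md`).

Discovery on your own panel:

```bash
signet discover --panel panel.fasta --roles roles.csv \
    --target "Cynomorium songaricum" --lmin 30 --lmax 40 --out sig.fasta
signet primers --panel panel.fasta --sig sig.fasta --out primers.json
signet pcr --assays primers.json --template pool.fasta --max-mm 2 --anchor 3
```

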