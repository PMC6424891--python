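# Methods

## Quantification model

The counting unit is the annotated ORF (GFF3 `CDS` features; the type →
class mapping is configurable). A read, represented by its
reference-consuming span as a 1-based inclusive interval, is assigned to
every ORF it overlaps by at least one nucleotide. Gapped or soft-clipped
alignments contribute only their reference-consuming span; bacterial data
carry no intron logic. Two read-level filters run first, in a fixed order:

1. **uniqueness** — a read is unique iff its SAM record is primary,
   non-supplementary, has `NH` absent or `NH=1`, has `MAPQ > 0`, and no
   secondary record with the same name appears in the file. Alternative
   policies (`mapq`, `flag-only`) are selectable; "unique" is an
   aligner-dependent notion and the default is the strictest reading
   available from standard SAM annotations.
2. **rRNA/tRNA removal** — any remaining read overlapping an annotated
   rRNA or tRNA feature by ≥ 1 nt is removed. The ≥ 1 nt rule mirrors the
   ORF-assignment rule; requiring full containment instead would retain
   boundary reads whose origin is ambiguous.

Uniqueness is filtered first so that a non-unique rRNA read is always
accounted as non-unique; the order is a bookkeeping convention that makes
`FilterStats` deterministic (the retained set is order-independent).

**Multi-ORF reads.** A read overlapping *k* ORFs increments each of the
*k* counts but contributes once to *N* (the number of distinct reads
overlapping any protein-coding region). This keeps each ORF's count
self-contained and keeps *N* equal to its definition as a count of
*sequences*. Consequently Σᵢ rᵢ ≥ 1, with equality when no read straddles
two ORFs. A `multi_orf="discard"` mode drops straddling reads entirely,
for sensitivity analysis. Overlap lookup uses an interval tree and is
tested for exact equality against a naive all-pairs scan.

**Normalizations.** Within a sample, hits per kilobase
hᵢ = 1000·cᵢ/Lᵢ with Lᵢ the ORF length in nt. Across samples, relative
abundance rᵢ = cᵢ/N. Both use the same filtered read set.

## Differential transcription

The per-gene quantity compared between conditions is the proportion
cᵢ/N. Replicates within a condition are pooled by summing counts before
proportions are formed (matching the pooling of replicate culture
aliquots in the experimental design the simulator emulates). The
dispatch rule is structural, not data-driven: the **two-proportion pooled
z-test** when the baseline condition is replicated, the **Pearson 2×2
chi-square** (1 df) when both conditions are single libraries. Both tests
are two-sided. No continuity correction is applied, preserving χ² = z²
exactly — the two branches are therefore the same test, differing only in
the reported statistic, which keeps single-library comparisons comparable
with replicated ones. The z statistic is reported as baseline proportion
minus other (positive z = higher in baseline); a degenerate pooled
proportion (0 or 1) yields z = 0, p = 1, and a degenerate 2×2 table
yields χ² = 0, p = 1 with a warning.

A non-default `z_mode="replicate"` uses the mean and standard error of
per-replicate proportions instead of pooled counts; it is provided for
dispersion diagnostics and is not the tested contract.

**Multiple testing.** Raw p-values are primary. Benjamini–Hochberg
q-values are computed over all tested ORFs and reported alongside, so
either can be thresholded.

**Ratios and classes.** The condition ratio is r₂/r₁. When r₁ = 0 the
ratio is undefined (`NaN`, class `undefined`) rather than infinite; the
underlying counts are still tested. An optional Haldane correction shifts
every count and each N by +0.5 before abundances are formed, for users
who need finite ratios. Change classes use inclusive thresholds — ≥ 10×
(`up_10x`), ≥ 2× (`up_2x`), ≤ 0.1 (`down_90pct`), ≤ 0.5 (`down_50pct`),
else `unchanged` — the higher class winning. Inclusivity at the boundary
is a convention ("a twofold increase" does not resolve it) and is
configurable.

**Regulon summaries.** Per regulon and comparison: member count, median
ratio (undefined ratios excluded and counted), per-class counts, and a
verdict — `mixed` when ≥ 25% of members fall in up classes *and* ≥ 25% in
down classes, otherwise `up` for median ratio ≥ 2, `down` for ≤ 0.5, else
`unchanged`. These cut-offs are reporting conventions for a qualitative
roll-up, not inferential statements.

## Synthetic data generator

The generator emulates the statistical structure of a far-red-light
photoacclimation study: seven conditions (triplicated white-light
control; single libraries for far-red light, erythromycin under both
lights, and three regulator knockouts in far-red light) and three
regulons — a 20-gene cluster induced 10³–4.35×10⁴-fold in far-red light
(induction absent in the rfpB/rfpC knockouts, weak 2–5× in rfpA, and
attenuated ~90% by erythromycin), a 15-gene phycobiliprotein/photosystem
set repressed to 5–50% of baseline in far-red light and more strongly by
erythromycin, and a 5-gene antibiotic-response set induced 50–670-fold by
erythromycin.

* **Genome layout**: non-overlapping ORFs (default 1,000; lengths uniform
  on 300–3,000 nt) plus one rRNA (2,900 nt) and one tRNA (80 nt) feature,
  placed left-to-right with random 20–200 nt gaps on a single reference.
* **Baseline abundances**: log-normal weights (σ = 1 on the natural-log
  scale), a conventional model of the heavy-tailed mRNA abundance
  distribution; a uniform law is available. Induced-regulon members get a
  pinned baseline weight (0.1 relative to the law's median) instead of a
  drawn one: these genes are nearly silent but reliably detectable at
  baseline (expected count ≈ 120 at the default 2×10⁶ depth), which is a
  property of the emulated biology and also the only way to guarantee a
  minimum baseline coverage for all members simultaneously.
* **Compositional truth**: condition abundances are baseline × factor,
  renormalized to sum to 1. Renormalization means observable ratios differ
  from raw factors — with the default scenario the induced cluster
  captures most of the mRNA pool in far-red light and every other gene's
  relative abundance is compressed ~15-fold. Truth tables store
  post-renormalization abundances and all recovery tests compare against
  those, never against raw factors.
* **Sampling**: multinomial at the configured depth (the minimal model
  consistent with proportion-based testing); optional
  Dirichlet-multinomial overdispersion (concentration parameter; real
  library dispersion is not estimable from the emulated design, so this
  is for sensitivity analysis only).
* **Reads**: fixed-length (100 nt), ungapped, uniform within the source
  feature; a boundary-jitter mode lets reads overhang feature ends to
  exercise the ≥ 1 nt rule. A configured fraction is placed in rRNA
  features and a configured fraction flagged non-unique. One pseudo-random
  stream per (seed, condition, replicate, purpose) via `SeedSequence`
  spawn keys, so adding a condition or sample never perturbs the others.

What the simulator does **not** model: sequence content and error
profiles, GC/positional bias, fragment-length distributions, operon
structure, antisense transcription, or the aligner itself. Tests passing
on simulated data therefore validate the counting, normalization,
testing and classification machinery — not robustness to real-library
artifacts upstream of the alignment file.

## Numerical and testing choices

* Coordinates are 1-based inclusive at every interface (GFF3/SAM
  convention); interval trees use half-open intervals internally and the
  conversion is invisible at the API.
* The 2×2 Pearson statistic is evaluated in the closed form
  (N₁+N₂)(c₁(N₂−c₂) − c₂(N₁−c₁))² / ((c₁+c₂)(N₁+N₂−c₁−c₂)N₁N₂) and
  cross-checked against an independent contingency-table implementation;
  the χ² = z² identity is verified to 10⁻⁹ relative tolerance on random
  tables.
* Null calibration is checked at 10,000 ORFs with expected count ≈ 500.
  Proportion tests on counts are discrete: at expected count ~100 the
  lattice spacing of the z statistic (≈ 1/√(2E)) alone contributes ~0.03
  of Kolmogorov–Smirnov distance against the continuous uniform, so the
  calibration stratum uses well-covered ORFs where discreteness
  contributes ≲ 0.013.
* Ratio-recovery on the default scenario is judged by coverage: each
  well-covered gene (baseline expected count ≥ 100) gets an exact
  binomial 99% interval on its observable ratio (99.5% quantiles on each
  margin), and the observed miss rate must be consistent with the nominal
  1% (4σ binomial band). A per-gene assertion would fail ~1% of ~900
  genes by construction.
* TSV floats are written with `%.10g`; run outputs are byte-identical for
  identical (config, seed).
* Test problem sizes (e.g. 2×10⁶ reads per sample for scenario recovery,
  10⁴ null ORFs, 100 randomized counting instances) were chosen as the
  smallest scales at which the distributional checks have stable power;
  the whole suite runs in well under a minute.

## Known limitations

* The uniqueness policy is an operational reading of "uniquely mapped";
  aligners differ, and SAM files without `NH`/meaningful MAPQ degrade to
  the flag-based fallback.
* Proportion tests treat replicate-summed counts as one binomial sample;
  true biological replicate dispersion beyond multinomial sampling is not
  modelled (the non-default replicate z-mode gives a rough diagnostic).
  Users needing dispersion-aware inference should use a count-model GLM.
* Compositional effects are faithfully propagated, not corrected: under
  extreme induction, unchanged genes show reduced relative abundance by
  design.
* The chi-square branch is asymptotic; very low-count ORFs in
  single-versus-single comparisons have conservative, discrete p-values.
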