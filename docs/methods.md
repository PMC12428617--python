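# Methods

## Screening model

The unit of input is a replicate peak table: compounds × replicate
samples of raw GC-MS peak areas, with missing entries meaning
non-detection. Zeros in input files are mapped to missing on read — a
zero area is an absence call by the peak picker, not a measured
quantity — while lipid and amino-acid tables keep zeros as values.

Two per-compound filters precede any scoring:

* **Detection rate** (detected replicates / total replicates) must
  exceed 0.5. The comparison is strict, so 2-of-4 detection is
  excluded; an `inclusive` switch relaxes both filters to ≥/≤ for users
  who read the rules as closed bounds.
* **Coefficient of variation** (sample SD with the n−1 denominator,
  divided by the mean, both over *detected* replicates only) must be
  below 0.30, again strict. With typical replicate counts of four, the
  unbiased SD is the defensible default; `ddof` is configurable. A
  compound with a single detected replicate has no defined CV and is
  removed with a logged warning rather than silently kept.

Both filters use only per-compound statistics, so they commute; the
tests assert this on random tables. A filter that removes everything
warns but does not raise — downstream stages accept empty sets.

**Relative percentage content.** C%ᵢ = 100·mean areaᵢ/Σⱼ mean areaⱼ over
the compounds surviving both filters. The denominator is fixed *before*
the odor-threshold join: the packaged reference panel's C% column sums
to ≈ 14.9%, which is only consistent with a denominator covering the
full screened profile (dozens of compounds without threshold
annotations), so C% is never renormalized after the join. The join
itself is an inner join on canonicalized names (case-fold, whitespace
collapse, comma-spacing normalization, synonym table mapping systematic
GC-library names like "Butanoic acid, ethyl ester" to trivial names);
duplicate database entries for one canonical name are an error.

## ROAV

The standard is the compound maximizing C%/T — the kernel of the ROAV
ratio, and the operationalization that uniquely reproduces the reference
panel's choice of 1-octen-3-ol as standard. Its ROAV is set to exactly
100 (not recomputed through the formula, avoiding a 100·(1±ε) wobble);
every other compound scores 100·(C%_A/C%_stan)·(T_stan/T_A). Ties on
C%/T are broken by canonical name order and logged. Scores are kept at
full precision internally; exports can round to 4 decimals to mirror the
reference table's display.

Categories: characteristic at ROAV ≥ 1, modifier at 0.1 ≤ ROAV < 1,
both lower bounds inclusive as stated; a "negligible" band below 0.1 is
added for completeness. On the packaged panel the rule yields 15
characteristic compounds even though the panel is described as 28
characteristic compounds — 13 of its rows score orders of magnitude
below 1. The package implements the stated rule and surfaces the
discrepancy in its tests rather than reproducing the count.

**Class composition.** Integer percent shares per chemical class use
largest-remainder (Hamilton) apportionment so shares always sum to
exactly 100; remainder ties go to the larger count, then
lexicographically earlier name. On the reference profile's counts
(15/19/9/10/13/14 over 80 volatiles) this gives 19% aldehydes and 24%
alcohols, with the 12.5/17.5 remainder tie resolved in favour of the
larger class.

## Lipid shorthand grammar

`ClassCode '(' ChainSpec (Sep ChainSpec)* ')'` with Sep ∈ {`_`, `/`}
(`/` = sn-positions known; any `_` makes them unknown), and
`ChainSpec = [O-|P-] carbons ':' double_bonds (';' token)*`. Suffix
tokens `O`, `nO`, `On` all normalize to an extra-oxygen count (shorthand
dialects differ in digit placement); anything else (e.g. the `T` in
`ST(24:1;O3;T/20:1)`) is preserved verbatim in `extra_tokens` — lossless
beats speculative. Whitespace anywhere is treated as print typography
and stripped. A single ChainSpec with no separator is a sum-composition
name (`PC(O-34:3)`); multi-chain names store per-chain detail and derive
their sums, so chain-sum consistency holds by construction and is
asserted on parse/format round trips. The canonical formatter emits the
digit-first oxygen dialect, so formatting canonicalizes rather than
byte-preserves; round trips are compared structurally.

The class-code → category registry ships with GL (TG, DG, MG, betaine
lipids DGCC/DGTS, glycosyldiacylglycerols), GP (PC, PE, PS, PI, PG, PA,
lyso-species), SP (SM, Cer, HexCer, SHexCer, PE-Cer — PE-Cer is a
ceramide backbone, hence SP not GP), FA (FA, FAHFA, NAGly), ST (ST, CE,
SE) and PR. The full 44-subclass registry of any given study is not
recoverable from its text, so the registry is user-replaceable and a
lenient mode maps unknown codes to "unknown". Key-lipid selection
defaults to top-14 mean relative abundance — the panel size reported for
ham — because no explicit selection criterion is stated for it.

## Amino acids

The default taste map covers the 20 proteinogenic amino acids plus
L-ornithine, L-citrulline, 4-aminobutyric acid and beta-alanine. Three
assignments are fixed by the ham study's own statements (L-alanine
sweet, L-lysine sweet-bitter, L-valine neutral); the rest follow the
common food-chemistry classes (Gly/Ser/Thr/Pro/Gln sweet, Asp/Glu umami,
aromatic and branched-chain plus Arg/His/Met/Orn bitter, the remainder
neutral). All assignments are overridable; strict mode rejects unmapped
names. Key amino acids are those with mean relative content ≥ 40
(inclusive, as printed), the mean taken across samples since a
per-sample rule is not stated. Units are carried opaquely — the input's
scale is never rescaled, and the cutoff is interpreted on that same
scale.

## Correlation

Pearson r on pairwise-complete observations across the intersected
sample columns (≥ 3 required; pairs with fewer complete observations are
suppressed with a warning, as are zero-variance features). p-values come
from the exact t transform t = r·√((n−2)/(1−r²)) with n−2 df
(`scipy.stats.pearsonr`). Benjamini–Hochberg adjustment across the whole
pair grid is on by default — a 14×28 grid is 392 tests — and can be
disabled to mirror unadjusted reports. With four samples the test warns
that p-values carry almost no power. One numerical choice: exact affine
dependence accumulates ~n·ε rounding in the normalized dot product, so
|r| within 10⁻¹² of 1 is snapped to exactly ±1 (with p = 0); data that
close to collinear without being affine is indistinguishable at double
precision anyway.

## Synthetic data

Replicate noise is log-normal, parameterized so the *arithmetic* mean
equals the planted content and the *arithmetic* CV equals the requested
one (σ² = ln(1+cv²), µ = ln mean − σ²/2): peak areas are positive and
right-skewed. Dropout is i.i.d. Bernoulli per cell, encoded as missing.
Defaults follow the emulated study design: 4 replicates, and the
28-compound panel's relative contents (plus a bulk unannotated
compound) as the true composition; replicate CV 0.15 and dropout 0.05
in the simulation driver are mid-range values for semi-quantified
GC-MS peak areas. Lipid names are drawn from the parser's own grammar
with carbons 8–26 and unsaturation capped by chain length (≈ 22:6 at
most), class frequencies from a weight map (the driver uses the
dominant-subclass shares reported for ham: TG 25.29%, DG 13.43%, DGCC
8.47%, …); every generated name parses by construction, which the tests
verify rather than assume. Planted correlations use a latent bivariate
standard normal with correlation exactly r mapped affinely to positive
abundances (loc 100, scale 10) — an affine map preserves Pearson r
exactly, which a log-normal copula would not; draws below zero are
~23σ events and are not clipped. The amino-acid profile is a synthetic
24-amino-acid panel ordered L-alanine > L-lysine > L-valine with seven
entries at or above the key cutoff, matching the qualitative ordering
reported for ham.

What the generators do *not* emulate: chromatographic drift and
co-elution, inter-compound correlation within a block, heteroscedastic
calibration error, or realistic lipid isomer distributions. Passing
tests therefore demonstrate correctness of the screening/scoring
arithmetic and recoverability under idealized noise, not instrument-level
robustness.

## Problem sizes and determinism

Test and driver sizes are chosen for exactness of the check rather than
scale: screening oracle equivalence on 100 random ≤ 20×4 tables,
1,000-name parser corpora, 100-seed Monte-Carlo correlation recovery at
n = 200, CV calibration at 1,000 replicates. Every stochastic path takes
an explicit integer seed into a private `numpy.random.Generator`; there
is no global RNG state, and identical seeds give bit-identical tables
and identical pipeline manifests (manifests record package version,
config, SHA-256 input hashes and seed, and deliberately contain no
timestamp).

## Known limitations

* ROAV reproduction from printed inputs is bounded by their 4-decimal
  rounding: for C% ≤ 0.003 the reachable relative error is ~2%, and the
  tests check the input-rounding envelope there instead of a fixed
  relative tolerance.
* The threshold database is a 28-compound panel for one matrix;
  thresholds are matrix-dependent and the DB is meant to be replaced
  for other foods.
* Four-replicate designs give correlation estimates with near-zero
  power; the package reports them (flagged), as block correlation on
  such designs is descriptive, not inferential.
* Retention-index support is a bare Kovats interpolation utility; no
  alignment or RI-based identification is attempted.
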