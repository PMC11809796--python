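# Methods

## The inference problem

Polygenic adaptation moves many trait-associated alleles by individually
small amounts, so single-locus selection scans miss it. Both tests in this
package aggregate over a trait SNP set ascertained from GWAS summary
statistics and ask whether the aggregate frequency pattern in a focal
population (or regional group of populations) exceeds what neutral drift
predicts, using genome-wide resampling of *matched* control SNPs as the
null. Matching controls for the ascertainment of GWAS SNPs: discovered SNPs
are not frequency-typical of the genome, so controls must share their
minor-allele-frequency (MAF) bin, and — for the multi-population test — their
B-value bin, since background selection shifts both diversity and
differentiation of linked neutral sites.

## Input preparation

GWAS rows are joined to the frequency panel on (chromosome, position) with
allele-set reconciliation — direct match or strand complement;
strand-ambiguous A/T and C/G pairs are dropped outright (conservative: their
orientation cannot be verified without frequency heuristics), as are
irreconcilable pairs and multi-allelic positions, all counted in a drop
report. Effects are re-oriented so the effect allele is always the panel's
`allele1`; the operation is idempotent. Join on position rather than SNP id
avoids rs-vs-`chrom:pos` dialect mismatches across sources.

Trait SNP sets take rows with p below the chosen threshold (the two
conventional cutoffs 1e-9 and 1e-6 are the sweep defaults), orient each SNP
to its trait-increasing allele (effect allele if β > 0, otherwise the other
allele; β exactly 0 defines no direction and is dropped), and keep one SNP
per LD block — the minimum-p SNP, with ties broken by position then id so
the result is invariant to input row order. Positions are 1-based in
tables; BED intervals are 0-based half-open; membership tests use
pos−1 ∈ [start, end). SNPs outside every block count as singleton blocks.
An empty set is a legal result: downstream tests report `NA` rather than
raising, so a multi-trait sweep always emits one row per (trait, threshold).

## Matched resampling nulls

Bins: MAF bin width 0.02 (indices 0–24, boundary value 0.5 mapped into the
top bin); B-value bin width 100 over 0–1000 (indices 0–9, value 1000 in the
top bin). The pairwise test matches on the *mean* MAF of the two compared
populations — the averaging set is not fixed by convention, and the mean of
the compared pair is this package's documented reading. The outlier test
matches on focal-population MAF *and* B-value, both for the control sets
and for the covariance pool; SNPs with no B-value annotation are never
candidates rather than receiving a default bin.

Control sets draw, for each trait SNP slot, one candidate uniformly with
replacement across sets, plus a fair-coin allele-orientation flag from the
same seeded stream. Under neutrality the trait-increasing label is
exchangeable, so random orientation centers the null at zero; pre-drawing
the flags in one place makes both tests' nulls reproducible from a single
seed. A control SNP may serve two different trait SNPs in one set when
their bins coincide, but a trait SNP of the tested trait is never its own
control. Trait SNPs with zero candidates are a hard error in strict mode
and are excluded with a warning in lenient mode (the sweep uses lenient so
one unmatchable SNP cannot kill a cell).

The covariance pool reserves up to a cap of distinct candidates per trait
SNP (default 2,000) and consumes them round-robin until ~100,000 distinct
SNPs are collected, deduplicated across trait SNPs.

## Pairwise test

`D = mean_l [f_target − f_reference]` over trait-increasing alleles. The
empirical one-sided p-value is the literal, tie-inclusive proportion of
control sets with mean difference ≥ D — it can be exactly 0; an
(r+1)/(n+1) estimator is available behind a flag for downstream
multiplicity work but is never the default. The signed report multiplies p
by the sign of D; two-sided summaries are derived, never primary.

## Regional outlier test

Genetic value `Z_m = Σ_l β_l f_ml` with no diploid factor of 2 — the
constant cancels in standardization. Scaling by `√(Σ β² ε(1−ε))` (ε the
unweighted cross-population mean at each trait SNP) puts the centered
vector on the scale of the drift covariance `F̂`, estimated from the pool
as the mean outer product of `(f − ε)/√(ε(1−ε))`; SNPs fixed panel-wide
are dropped and pools under 100 usable SNPs flag the estimate unstable.
The unweighted ε (rather than sample-size weighting) is a deliberate
simplification: population sample sizes are not part of the input contract.

**Conditioning.** Estimating F̂ around the cross-population mean makes it
exactly centered (`F̂·1 = 0`), so the naive construction — condition the
focal region's mean value on the other regions' values after centering the
whole vector — is exactly degenerate: the focal value is a deterministic
linear function of the others and the conditional variance is identically
zero. The test therefore uses *leave-focal-out centering*: values are
re-centered on the mean of the non-focal populations before conditioning.
The leave-out-centered covariance is exactly recoverable from the centered
F̂ (the transformation annihilates the centering direction), the focal
coordinate regains positive conditional variance, and the one remaining
rank deficiency — now confined to the conditioning coordinates — is handled
by Moore–Penrose pseudo-inverse with relative tolerance 1e-8. This keeps
the statistic invariant to region labeling (the alternative of dropping one
region is not), reproduces the forced antisymmetry of the two-region case
exactly, and yields z ≈ N(0,1) under the null (the control-set z standard
deviation sits near 1; the suite checks it stays within [0.8, 1.25]).
Per-population z-scores use the identical construction with singleton
groups. A conditional variance at zero with a nonzero residual raises an
error naming the region partition; a zero residual (e.g. a panel with no
differentiation at all) defines z = 0.

The empirical p is two-sided on |z| — the direction is reported separately
via the sign of z — because outlier calls are conventionally reported with a
graphical direction rather than a stated one-sided rule. Control-set genetic
values reuse the matched trait SNP's β and the pre-drawn orientation flags,
each set rescaled by its own `√(Σ β² ε(1−ε))`.

## Response classification

Genes with both adjusted p-values strictly below the threshold (default
0.1, one shared threshold for both contrasts — configurable) are labeled by
the sign product of their two log fold changes: negative = blunted
(population difference opposes the treatment response), positive =
enhanced. Exact zero logFCs carry no sign; they are excluded and counted
(measure-zero in real data, possible in constructed tables). Blunted +
enhanced + zero-excluded partitions the qualifying set exactly.

## Synthetic cohorts

The generator emulates the statistical structure the tests assume, not any
particular demography:

- **Population structure.** A block drift covariance `F_true`:
  `between_var` shared within a region, `+ within_var` on the diagonal,
  zero across regions. Defaults: 4 regions × 3 populations (12
  populations), between 0.02, within 0.01 — continental-scale F_ST
  magnitudes with a clearly separated regional signal.
- **Frequencies.** Ancestral ε ~ U[0.05, 0.95] (a common-variant panel);
  population frequencies ~ MVN(ε, ε(1−ε)F_true), clipped to [0,1].
  Clipping mimics fixation and keeps determinism trivial; it slightly
  deflates covariance at extreme ε (measured effect on recovery: ~2%
  relative Frobenius error, well inside tolerance).
- **GWAS.** 100 trait SNPs with β ~ N(0, 0.5²); se = 1/√(2·N·q(1−q)) with
  N = 100,000 (biobank scale) and q the first population's frequency; p
  from the two-sided normal test. Effect-allele reporting is randomized to
  exercise harmonization; allele pairs are drawn strand-unambiguous so
  harmonization retains every simulated SNP.
- **Alternative.** The directional shift moves the trait-increasing allele
  by `s·|β|·p(1−p)` in target populations — the classical selection
  differential, effect-proportional and frequency-dependent, matching the
  polygenic alternative both tests target. s = 0 is bit-exact identity.
- **Annotations.** B-values uniform on {0,…,1000}; LD blocks are contiguous
  runs of 25 SNPs within a chromosome — real LD blocks vary in size, but
  only block *membership* matters to the pipeline.
- **Contrast tables.** Significant genes draw both adjusted p uniform below
  the threshold, others above; no multiplicity machinery is simulated.

What passing tests therefore show: the pipeline is correctly calibrated and
powered *under exchangeable, MVN-drift, annotation-independent conditions*.
Real data add LD within blocks, ascertainment interacting with B-values,
non-Gaussian drift at extreme frequencies, and GWAS stratification — none
of which the generator emulates, so field results still require the usual
caution.

## Problem sizes and numerical choices

The benchmark suite and `scripts/acceptance.py` use: 200 neutral cohorts
(50,000 SNPs, 12 populations, 100 trait SNPs, 1,000 control sets) for null
calibration; 20 replicates per shift strength over s ∈ {0, 0.1, 0.25, 0.5}
with common random numbers across s for power; 20 replicates of 20,000-SNP
pools for covariance recovery; 10,000 sampled sets against a 36-point
exhaustive null on the toy instance. The full script runs in well under
five minutes on one CPU. Paper-scale defaults (10,000 pairwise sets, 5,000
outlier sets, 100,000-SNP pools) remain the CLI and sweep defaults.

Determinism: every sampling routine takes an explicit integer seed; sweep
cells derive independent streams via `SeedSequence(seed, spawn_key=(trait,
threshold))`; rerunning a sweep with the same config and inputs is
byte-identical, and control pools are cached by content hash. Empirical
p-values use exact comparisons (ties count toward the null, per the
tie-inclusive estimator); centering identities hold to 1e-10 and the
vectorized statistics match per-SNP loop oracles to 1e-12.

## Known limitations

No LD-aware matching or covariate matching beyond MAF and B-value; no
Q_X-style omnibus statistic across all populations; no liftover,
imputation, or multi-allelic handling (such rows are dropped with a
report); VCF ingestion is not provided — tab-separated frequency tables are
the contract. The regional test's leave-focal-out conditional is one
principled resolution of an under-determined construction; alternatives
(dropping a region, omnibus statistics) would give numerically different,
though similarly calibrated, z-scores.
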