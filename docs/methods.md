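# Methods

`dietmem` implements the statistical workflow of a three-diet "cellular
memory" study design: mice fed ad libitum (AL), diet-restricted to 60% of AL
intake (DR), or restricted and then switched back to AL (DR-AL). The
questions the toolkit answers are (1) which genes change expression under DR
and whether those changes persist after the switch, and (2) whether promoter
DNA methylation, measured base-by-base in targeted bisulfite amplicons,
moves with them.

## Pooled-library differential expression

The expression arm of the design pools the n=5 animals of each group into a
single RNA-seq library per tissue, so there are no biological replicates and
dispersion cannot be estimated. The model is deliberately minimal: the count
`X` of a gene in a library of `N` total mapped reads is Poisson with rate
proportional to expression. For Poisson counts the square root is the
variance-stabilizing transform — `Var(sqrt(X)) ≈ 1/4` regardless of the
mean — so `Var(sqrt(X/N)) ≈ 1/(4N)` by the delta method, and

    z = ( sqrt(x1/N1) − sqrt(x2/N2) ) / ( 0.5 · sqrt(1/N1 + 1/N2) )

is approximately standard normal when the two libraries share a true rate.
Two-sided p-values are corrected with Benjamini-Hochberg across the genes
tested in that contrast (each tissue/contrast is its own BH family). A gene
is called differentially expressed when `q < alpha` (default 0.05) **and**
the signed fold change clears a magnitude threshold (default 1.25). Fold
change is the rate ratio reported as `+r` when `r ≥ 1` and `−1/r` otherwise,
so its magnitude is always ≥ 1. Genes with zero counts in both libraries are
excluded from the BH family (their z is 0 by construction and including them
only dilutes the correction); a pseudocount (default 0.5) is added to both
counts, only when one of them is zero, to keep the ratio finite.

Normalization is by total mapped reads, the quantity the Z-test formula
needs. No size-factor (DESeq-style) normalization is applied; the two
coincide only when totals are proportional to size factors, and the
unreplicated Z-test path is the one this package implements.

Type-I error of the test is checked by simulation: at a null Poisson rate of
λ=100 and 10^5 genes, the empirical rejection rate at p<0.05 falls in
[0.045, 0.055].

**What a green test does not establish:** real RNA-seq counts are
over-dispersed relative to Poisson; on real data this test is a *hypothesis
discovery* screen, anti-conservative to an unknown degree, and the
persistence calls downstream inherit that caveat.

## Persistence classification

A gene is *persistent* when it is significant in DR vs. AL and significant
in the same direction in DR-AL vs. AL (both against the same AL reference).
This is the strict, default rule; a `lenient` option instead requires
significance in DR only plus a same-sign fold change in DR-AL. Genes
significant only in DR-AL are reported separately as "new" changes, never as
persistent. Cross-tissue reports intersect the persistent sets with plain
set semantics (full intersection plus all pairwise intersections).

## Bisulfite amplicon (BSAS) quantitation

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine is protected and reads as C. Reads are placed on the
amplicon reference by ungapped comparison in bisulfite space: at reference
cytosines both C and T match; elsewhere the read must match literally. The
best (fewest-mismatch, then leftmost) offset wins; reads whose mismatch
fraction exceeds `max_mm` (default 0.1) everywhere are rejected and counted.
Full local alignment is unnecessary because BSAS amplicons are short,
primer-defined, and fixed in orientation; only the top strand is modeled.

Per annotated cytosine — CG when followed by G, CH otherwise (H = A, C, or
T) — a placed read contributes a methylated (C), unmethylated (T), or
ignored (other base) call. Percent methylation is `100·C/(C+T)`. Sites must
clear `min_coverage` (default 1000, the depth the assay is designed for) in
every sample to enter group statistics.

Total methylation per sample and context is the **unweighted mean of
per-site percentages** — invariant to coverage imbalance between sites; a
read-weighted pooled fraction is available via `weighting="read-weighted"`
and coincides with the site mean when coverage is uniform. Group comparisons
use one-way ANOVA with Tukey's HSD on totals, and one-way ANOVA with BH
across individual sites, CG and CH adjusted as **separate families** (they
are biologically distinct classes and are reported separately). Effect sizes
are reported as percent decrease vs. the AL mean: `100·(mean_AL −
mean_g)/mean_AL`.

Degenerate inputs: constant groups give ANOVA F=0, p=1 when the means agree
(and F=∞, p=0 when they differ but within-group variance is zero); Tukey p
is 1 and 0 respectively in those cases. Methylation statistics operate on
the percent scale directly, with no logit transform.

## Comparative-Ct qPCR

Technical replicates (default 3) are averaged arithmetically on the Ct
scale. Per sample, `ΔCt = mean target Ct − mean control Ct` (β-actin-style
endogenous control), `ΔΔCt = ΔCt − mean ΔCt of the calibrator group`
(default AL), and relative expression `rq = 2^(−ΔΔCt)`. The calibrator
group's rq values have geometric mean 1 by construction. rq is invariant to
any plate-wide Ct shift applied to both genes equally. Group ANOVA/Tukey
uses rq as the response by default (`--response dct` switches to ΔCt).
Amplification-efficiency correction (Pfaffl) is out of scope.

## Synthetic data: the stated world

The generators emulate the study's designs with explicit ground truth:

- **Counts** (`ExpressionScenario`): three groups, one pooled library each;
  defaults n_genes=10,000, 3×10^7 mapped reads per library, baseline mean
  100 reads/gene, 5% up + 5% down at 2-fold, 30% of effects persistent.
  Affected-gene counts are deterministic (`round(frac·n)`); which genes are
  affected is drawn from the seed. Counts are independent Poisson draws —
  matching the analysis model exactly, which is the point of a calibration
  bench but also its limitation (no over-dispersion, no correlation between
  genes, no library-prep artifacts).
- **Amplicons** (`make_amplicon`): random sequence with CG dinucleotides
  planted exactly at the requested offsets and nowhere else (generation
  forbids G after C, then plants); every other cytosine is CH, and the final
  base is never C so every site's context is well defined.
- **Bisulfite reads** (`MethylationScenario`): full-length, top-strand reads
  at configurable depth (default 2000 ≥ the assay's 1000×); each annotated
  cytosine is methylated per its site-and-group probability; unmethylated
  cytosines convert with probability `conversion_efficiency`; uniform
  base-call errors are applied last. Incomplete conversion therefore
  *inflates* apparent methylation by ≈ `100·(1−efficiency)` points at an
  unmethylated site — the classic confound, exposed as its own knob and
  verified against that closed form. Not modeled: paired ends, indels, PCR
  duplicates, strand choice, CHG/CHH subdivision.
- **qPCR plates** (`QpcrScenario`): per-group true log2 offsets; target Ct
  replicates are `target mean − offset + N(0, sd)` (default sd 0.1 cycles,
  5 samples/group, 3 replicates — a realistic plate).

Determinism: identical scenario + seed reproduce byte-identical outputs;
pipeline reports embed the full configuration and replay exactly.

## Known limitations

- The Z-test is anti-conservative on over-dispersed real data (above).
- Single-strand, ungapped placement cannot handle indels or reverse-strand
  amplicons.
- Persistence percentages from real pooled data depend on unpublished raw
  libraries; the package reproduces the *procedure* and validates it on
  simulations, not the original tissue-level numbers.
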