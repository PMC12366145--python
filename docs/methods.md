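# Methods

## The within-family statistic

For proband *i* in family *f* with instrument score *y*, reference set
*R(f)* (unaffected parents, or unaffected siblings), and population SD
*σ* for that instrument,

```
WFSD_i = (y_i − mean_{j∈R(f)} y_j) / σ
```

The SD in the denominator is the *population* SD, not the reference set's:
the statistic expresses the proband's displacement from the family baseline
in population units, so values are comparable across families and
instruments. Published norms supply σ for SRS T (10), the Vineland scales
and IQ (15); SCQ and ADOS severity scores have no established norms, so σ
is estimated from the dataset (sample SD, n−1; defaults 10.45 / 2.17 /
2.13 / 2.61 carried from large trio cohorts) and stamped
`dataset_derived`. The estimation pool (all scored individuals vs probands
vs relatives only) is a configuration choice; the default pools everyone
scored, which slightly inflates σ when probands are shifted but keeps the
estimate usable in cohorts without relative phenotyping.

Signs are never flipped: WFSD keeps the raw direction, so "worse" is
positive on SRS/SCQ/ADOS and negative on Vineland/IQ. Downstream severity
logic is direction-aware instead.

Unaffected siblings can be scored as *pseudo-probands* against the parental
reference. Their deviations form the within-family null: under no
sibling-specific effects and no ascertainment on siblings, the mean pseudo-
proband WFSD is zero. In real ascertained cohorts it is mildly negative
(screened, less-affected siblings); the package asserts the simulation null,
not any real-data value.

## Disruptive DNV calls

Consequence classes come from the most severe VEP term: truncating terms
(frameshift, splice acceptor/donor, stop gain) are PTV only with LOFTEE
high-confidence support — a missing flag is accepted with a logged waiver
(strict mode rejects), an explicit low-confidence flag demotes to `other`
because a failed verification is neither a validated truncation nor a
validated protein-altering event. Missense and other protein-altering
terms are MIS; synonymous terms SYN.

Disruptiveness: PTV qualifies with gene LOEUF strictly below 0.37; MIS with
MPC at or above 2. Missing scores never qualify. Subgroups are mutually
exclusive with PTV-first precedence (strongest-class assignment, the
field's convention when one proband carries both).

QC rule sets reproduce the per-cohort thresholds of the source call sets
(e.g. Korean WGS heterozygous SNVs: QUAL ≥ 7.5, GQmean ≥ 36, DPmean ≥ 34,
AB in [0.275, 0.725]; SPARK: AB < 0.8 with internal AC = 1). The
per-sample DNV-count outlier rule ("nine median standard deviations") is
read as count > median + 9 × (1.4826 × MAD) of per-sample counts — a
scaled-MAD robust SD; both the multiplier and the scale constant are config
fields and the reading is recorded in the audit trail. The allele-frequency
filter treats absent gnomAD AF as novel (passes). Outlier exclusion removes
a sample's variants, never its phenotypes.

## Severity, association, discovery

Two severity definitions are treated as equivalent expressions of one
criterion: raw SRS T ≥ 76 equals mean 50 + 2.6 × SD 10, matching
WFSD ≥ 2.6 when the deviation is taken from the population mean. Both
thresholds are inclusive. The "better-than-expected" subgroup is
WFSD < 2.0. Association uses the two-sided Fisher exact p-value; the odds
ratio is the sample cross-product with Haldane 0.5 correction on zero
cells, and the 95% CI is the Woolf normal approximation on the log OR (the
CI method is a package choice; no method is canonical here). Gene discovery
lists genes with ≥ `min_carriers` (default 1) disruptive DNVs among severe
probands — recurrence is exposed rather than fixed because published gene
counts do not pin down a recurrence rule. Gene-set enrichment is a
one-sided Fisher overlap test on user-supplied sets with BH FDR across the
target collection; a zero overlap is clamped to non-positive log OR (the
raw Haldane estimate can exceed zero for lopsided margins, which would
misreport "enrichment" with no overlapping genes).

## Dispersion outliers

Per grid cell (variant type × phenotype × score type; eight cells), the
unscaled MAD of carrier outcomes is computed per gene — unscaled because
the calling threshold is calibrated against the cell's own MAD
distribution, so the 1.4826 constant would cancel. A carrier with several
qualifying variants in one gene contributes once; one hitting several genes
contributes to each. Genes need ≥ 2 carriers to enter the mean/SD pool
(singleton MADs are identically zero and would deflate it). Outlier rules:
MAD > cell mean + 2 × sample SD; > 2 carriers; and for WFSD cells, at least
one carrier beyond the 95th percentile of |WFSD| pooled over the cell —
absolute value because adaptive-ability deviations are negative, "any
carrier" because a single extreme family is exactly the signal sought.

A caveat the validation quantifies: with 4 carriers the MAD estimate
itself is extremely noisy. Even if the cell threshold were known without
error, a gene whose carrier spread is 4× background exceeds mean + 2 SD
with probability ≈ 0.78 (direct Monte-Carlo of the MAD of four normal
draws). Sensitivity ≥ 0.9 at that boundary is therefore not achievable by
this rule; it is reached only around ≥ 6 carriers with ≥ 5× spread. The
validation suite asserts the boundary condition faithfully (and that test
is expected to fail), alongside a check that measured sensitivity agrees
with the analytic ceiling and that the null false-call rate stays within
the rule's nominal level (~0.04 observed, ≤ 0.05 asserted).

## pTDT

Deviation = proband PS − mid-parental mean PS, computed only where both
parents are scored. Deviations are reported raw and standardized by the SD
of the mid-parental distribution (the field-standard normalization; the raw
version is kept because the source analyses do not state a denominator).
One-sample t against zero per group; between-group comparisons use Welch's
t (unequal variances, the safe default).

## The synthetic cohort generator

Each child's latent score is
`population mean + b·(midparent − mean) + family residual + individual residual`,
with parents drawn from the population. Defaults: b = 0.5 and a variance
budget (family residual carrying a quarter of the population variance)
chosen so the child's marginal SD equals the population SD, implying a
child–midparent correlation of b/√2 ≈ 0.35 — the scale reported for
unaffected siblings in large trio cohorts. Carrier rates default to 3.9%
(dnPTV) and 3.1% (dnMIS), the observed proband frequencies in sequenced
ASD cohorts; carrier status is fixed *before* ascertainment so the enrolled
cohort reproduces those observed rates. Planted gene effects are expressed
in population-SD units and oriented toward severity per instrument
(up for SRS/SCQ/ADOS, down for Vineland/IQ). Site-level heterogeneity is a
per-carrier normal draw added to the gene's mean effect — the minimal
mechanism that makes dispersion-outlier genes recoverable; the draw is
refreshed on each ascertainment attempt, so enrolled carriers
under-represent protective sites, as real ascertainment would.

Ascertainment rejection-samples the family's phenotypes until the proband
crosses the configured severity threshold (default SRS T ≥ 60, the clinical
band; bounded retries, then a hard error for infeasible thresholds). Two
consequences are deliberate: enrolled parents shift toward severity (the
familial-correlation structure of ascertained cohorts), and the
carrier-vs-non-carrier contrast is attenuated below the planted effect
(conditioning on crossing a threshold helps non-carriers more). Effect
*recovery* is therefore asserted only without ascertainment, where the WFSD
contrast is unbiased for the planted δ; with ascertainment the tests assert
direction and attenuation only. Polygenic scores: parents N(0,1), child =
midparent + Mendelian noise (variance ½), probands optionally shifted by an
over-transmission parameter in mid-parental-SD units (default 0.2,
representative of reported polygenic over-transmission in ASD probands).
Missingness is completely at random per role × instrument (defaults 5%
probands, 20% relatives) — a simplification; real missingness is driven by
clinic protocols and participant cooperation and is not missing-completely-
at-random, so missingness-sensitivity conclusions do not transfer. Sibling
counts are categorical (0/1/2 with probabilities 0.3/0.6/0.1). One RNG
substream per family index keeps earlier families stable when a cohort is
enlarged.

What the generator does not emulate: assortative mating, shared
environment beyond a single family residual, instrument ceilings/floors and
discreteness, site-specific effect *directions* within a gene (only
magnitude dispersion), and cohort-specific instrument availability. Passing
recovery tests therefore demonstrates estimator correctness under the
stated model, not robustness to these real-data features.

## Numerical and design choices

- GLM contrasts are identity-link least squares (outcomes are continuous);
  complete-case deletion on missing covariates; categorical covariates are
  dummy-coded with non-carriers as baseline; collinearity is handled by the
  pinv solver.
- The KS diagnostic standardizes the sample by its own mean/SD and compares
  to the standard normal (Lilliefors-style); the Anderson–Darling p-value
  comes from the normal-case approximation.
- The 2D profile reports the norm of per-axis means (displacement of the
  centroid); the mean of per-family norms is also computed because the two
  aggregations answer different questions and diverge for dispersed clouds.
  Only families with both instruments enter.
- Multiplex families keep the first affected child in file order as the
  analysis proband; other affected children are excluded from both proband
  analyses and reference sets. Affected parents are excluded from
  reference sets.
- Tables are TSV (UTF-8, header row); missing values read as "" or "NA",
  written as "NA"; floats are read with round-trip precision so
  write-read-write is byte-stable. Display rounding is half-up at two
  decimals; stored values keep full precision.
- Validation problem sizes: 2,000-family cohorts for effect recovery
  (pooled over 3 replicate seeds in the reproduction script), 200
  replicates of 300 families for the efficiency comparison, 200 replicate
  cells for outlier operating characteristics, 1,000 replicates for pTDT
  calibration — sizes chosen to put Monte-Carlo error well below the
  asserted margins.

## Known limitations

- Carrier-effect attenuation under ascertainment is a property of the
  design, not removable by WFSD; real-cohort contrasts are likewise
  attenuated relative to the counterfactual unascertained effect.
- The MAD outlier rule is underpowered below ~6 carriers per gene (see
  above); calls at 3–4 carriers should be treated as screening hits.
- Dataset-derived SDs depend on the pooling choice; changing the pool
  rescales WFSD for those instruments.
- The Woolf CI degrades for very sparse 2×2 tables; the Fisher p-value does
  not.
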