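# Methods

This note documents the models, parameter choices and numerical details
behind `pinemeth`, and what the simulation-based tests do and do not show.

## Site-level model

A bisulfite experiment observes, per cytosine, a pair of counts
(methylated, unmethylated calls).  The site ratio `mc/(mc+uc)` is reported
only at coverage ≥ `coverage_min` (default 4 reads); every regional
statistic is count-weighted (`Σmc / Σ(mc+uc)` over the covered sites of
the region) rather than a mean of site ratios, so deeply covered sites
carry proportionally more weight.  A flag (`site_mean_bins`) switches to
unweighted site means for sensitivity analyses.

Plus- and minus-strand CG sites are kept as separate sites (not collapsed
into dyads); this keeps the forward/reverse strand-consistency comparison
meaningful.  Cytosines whose trinucleotide would extend past a chromosome
end, or contains an ambiguous base, are excluded (the latter tallied).

Bisulfite conversion is estimated from the lambda spike-in as
`1 − Σmc/Σtotal` pooled over all lambda cytosines.  It is reported as QC
only; observed ratios are **not** corrected for non-conversion.  The
"methylated-site fraction" statistic calls a site methylated when a
one-sided binomial test of its methylated count against the non-conversion
rate survives BH FDR at 0.05 — the standard WGBS convention for this
otherwise underdetermined call.

## DMR detection

The genome is tiled with non-overlapping 1000-bp bins (the last bin of a
chromosome may be short; it is kept).  A bin enters testing for a context
when it contains at least one cytosine of that context and has total read
coverage ≥ 4 in at least one involved sample.  Replicate counts are summed
within each group and the pooled 2×2 table is tested with a two-sided
Fisher's exact test.  Windowed count tests of this kind are the standard
for replicate-poor WGBS designs; a logistic-regression variant was
considered and rejected for the default because with two replicates per
group it reduces to nearly the same pooled comparison at higher cost.

The Fisher p-value is computed vectorized: tables sharing margins are
grouped, the hypergeometric pmf over the shared support is evaluated once
in log space via `gammaln`, and the two-sided p is the summed probability
of all outcomes no more likely than the observed one.  The tie window in
log-pmf space is `1e-11 + 2e-15·M·(ln M + 1)` for table total `M`, which
tracks the floating-point error of the log-gamma sums so that exact
pmf ties (symmetric tables) are always included.  The implementation is
checked against exhaustive exact-integer enumeration for all tables with
margins ≤ 60 and against an independent library implementation on random
tables.

BH adjustment is applied separately per context within each comparison,
because the effect-size floors are context-specific (0.2 / 0.15 / 0.1 for
CG / CHG / CHH).  Calls require `p_adj < 0.01` strictly and `|Δ| ≥` the
floor.  Adjacent significant bins are not merged; all consensus logic
works on bin identity on the shared grid.

## Age-trend procedure

Age DMRs come from the wide-gap comparisons (35v2, 35v5, 14v2).  Because
methylation also drifts between genetically identical samples, DMRs are
additionally called between the two replicates within each age, with the
same test and thresholds; any age-DMR bin that recurs as a replicate-DMR
bin of the same context at any age is excluded.  Both the fraction of
replicate DMRs overlapping age DMRs and the fraction of age DMRs reserved
are reported per context.  A bin is a consensus hyper- (hypo-) DMR when
called in that direction in ≥ 2 comparisons; bins called in both
directions are dropped (tallied) — the rule for this conflict case was an
open choice and dropping is the conservative one.

Trajectories are per-age pooled levels (replicates summed, then the ratio)
of reserved bins.  Ages are treated as ordered categories, not calendar
years: with four time points and a maximum unit change c = 1 there are 27
integer model profiles starting at 0, and exhaustively enumerating them
replaces the profile-selection step that short-time-series clustering
tools need for larger spaces.  Each trajectory is standardized (first
value subtracted, scaled by its range) and assigned to the profile with
the highest Pearson correlation; ties go to the lower profile index
(correlations are rounded to 12 decimals first so mirror-symmetric ties
resolve deterministically), and flat trajectories go to the zero reference
profile and are excluded from significance testing.  The expected
assignment rate per profile is estimated from `n_permutations` (default
1000) passes in which every trajectory's time order is independently
permuted; the estimate is floored at `0.5/(n_perm·n_traj)` to avoid a
degenerate zero rate.  The one-sided binomial tail p of the observed count
is BH-adjusted across the 26 non-flat profiles.

Element assignment paints each basepair with its highest-priority element
(TE > gene body > promoter, i.e. 2 kb upstream of the TSS strand-aware,
> downstream 2 kb > intergenic) and gives a bin the highest-priority
element it overlaps by ≥ 1 bp, so counts partition the DMR set.  Gene
linkage uses body ± 2 kb overlap and is deliberately non-exclusive.

## Metaprofiles

Bodies are proportionally divided into 20 bins; flanks are fixed 2 kb in
20 fixed-width 100-bp bins — proportional bodies with fixed flanks is
standard metaplot practice and keeps flank decay lengths comparable across
features.  Orientation follows the feature strand.  Features with bodies
shorter than the bin count are skipped and tallied.  The intron-length
groups default to ≤1 / 1–5 / 5–20 / >20 kb; the exact breaks behind
published four-group figures are generally not printed, so they are
configurable.  The exon-only profile concatenates exons in transcript
order and reports a 3′-skew statistic, mean(last 5 bins) − mean(first
5 bins), per intron-count group (0 / 1–2 / 3–5 / ≥6).

## Expression linkage

Gene-level grouping uses mean TPM across samples with right-closed breaks
(0, 1, 10, 50]; TPM = 0 is its own group.  The per-sample two-group flank
comparison ((0,1] vs >1) uses each sample's own TPM.  Mann–Whitney tests
are two-sided; the implementation uses the exact null distribution when
both groups have ≤ 8 observations with no ties and the normal
approximation with continuity and tie correction otherwise (group sizes
in practice are in the hundreds).  The compact letter display uses the
insert-and-absorb algorithm on the raw pairwise p-values at alpha = 0.01
(no multiplicity adjustment across pairs, matching the stated threshold
convention).  Marker segments are user-supplied genomic intervals scored
in one context; per-age levels pool replicates, and Pearson r is taken
over the four age points against per-age mean TPM and against age rank.

## Synthetic methylome generator

The generator defines the study conditions: 4 ages (2, 5, 14, 35 years) ×
2 replicates, mean coverage 20× with gamma-Poisson overdispersion
(dispersion 0.2 — real WGBS coverage is substantially overdispersed;
the exact value is not identifiable from published summaries and is
configurable), and a 0.5% bisulfite non-conversion rate acting additively
on the unmethylated fraction (`p_obs = p + (1−p)·0.005`); sequencing error
is otherwise ignored.  Background levels per context and feature class
default to a conifer-like landscape: CG/CHG high (TE 0.85/0.70,
intron 0.70/0.55, exon 0.50/0.35, intergenic 0.40/0.30) and CHH low
(0.02–0.08).  TEs are inserted preferentially into intergenic space and
introns ≥ 5 kb by a renewal (gap–TE–gap) process whose fill ratio is
solved against an edge-corrected host capacity; on gene-sparse genomes the
realized fraction lands within a few percent of the target, while on
gene-dense genomes fragmentation of the host space can leave it a few
percent short.

A per-gene uniform random effect shifts exon and flank levels (spread 0.8
for CG, 0.5 for CHG, 0.02 for CHH), and expression is coupled negatively
to the gene's true exon+downstream CG/CHG methylation:
`log TPM = 7 − 12·m + N(0, 0.4) + N(0, 0.3)` (gene and sample noise).
The slope/intercept map the methylation range onto a TPM range of roughly
0.25–400 so that all five TPM groups are populated.  The lowest
`zero_tpm_fraction` (default 13%) of genes by computed TPM fall below a
detection floor and are set to 0 — modelling censoring, which makes the
TPM = 0 group the most-methylated group, as a negative-coupling model
implies.  The fraction of zero-TPM genes in real samples is not calibrated
from data; it is configurable.

Planted signals: age-DMR bins take a linear per-age series (default
0.4 → 0.7 for hyper, reversed for hypo) over the *age index* — linear in
ordinal time, matching the ordinal treatment in the clustering stage;
replicate-variable bins fix replicate 1 at 0.3 and replicate 2 at 0.6 in
one context (default CG) at every age, an age-independent difference at
twice the CG call floor; marker genes (forced to the plus strand with a
first intron ≥ 9 kb) carry a strictly decreasing CHG series
(0.70/0.55/0.40/0.25) over a segment from −2.5 kb upstream through the
first exon into the first intron, with strictly increasing TPM
(5/15/25/35) — linear in age index so the level–TPM correlation is −1
before noise.  All randomness derives from named child streams of the
config seed; identical configs give byte-identical outputs.

### What the generator does not emulate

Read-level artifacts (M-bias, PCR duplicates, mapping bias), SNPs
overlapping cytosines, correlated methylation along reads, chromosome-arm
scale covariates, and biological between-replicate variance beyond the
explicitly planted replicate-variable bins.  Passing the recovery tests
therefore shows that the statistical machinery is correct and calibrated
under the stated model, not that the pipeline is robust to upstream
artifacts real data would carry.

## Problem sizes used by the tests and acceptance script

The packaged analyses run at desk scale: a 2×1-Mb genome with 120 genes
(≈0.76 M cytosines, 8 samples) for the recovery checks, 1 Mb for the null
calibration, 2 Mb with 250 short genes for the expression linkage, and a
150-kb lambda genome (≈1.2×10⁷ site-reads pooled).  These sizes make the
full suite run in minutes while keeping every per-bin count within a
factor of a few of the deep-coverage regime the thresholds were designed
for.

## Known limitations

* The windowed Fisher test pools replicates and therefore does not model
  biological between-replicate dispersion; the replicate-exclusion step is
  the compensating control, exactly as in the emulated design.
* Bin-identity overlap ties all consensus logic to one fixed grid;
  signals straddling a bin boundary dilute into two bins.
* The permutation null of the trend clustering treats trajectories as
  exchangeable across time points, which is correct for the planted model
  but conservative if levels were autocorrelated in time.
* With ~10³ profile bins checked at once, individual bins are expected to
  exceed 3 SE occasionally even when perfectly calibrated; aggregate
  calibration (mean/sd of standardized deviations, tail fractions) is the
  meaningful check.
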