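# Methods

## Data model and coordinate conventions

The unit of analysis is an **APA site** (one cleavage/polyadenylation
position) with a strand-aware rank along the transcript's sense
direction: *proximal* (nearest the stop codon), *distal* (farthest),
*internal* between them, *single* for one-site genes. On the plus
strand ranks increase with genomic coordinate; on the minus strand they
decrease. Ranking is a pure sort, so it is invariant under input
permutation, and reversing the strand swaps proximal and distal for the
same coordinates; coordinate ties are broken by site id for
determinism.

Genomic intervals are 0-based half-open internally (BED semantics);
cleavage positions are stored 1-based, matching how site coordinates
are printed. Conversion happens only in I/O code. A 3′UTR is
constructed from the shared sense-strand UTR start (the *anchor*) and a
cleavage site; for two isoforms sharing the anchor,
`length_distal − length_proximal = |pos_distal − pos_proximal|` on
either strand — the identity behind the worked example
(107 bp + 1241 bp = 1348 bp).

**Usage polarity.** PDUI is natively "fraction of transcripts using the
distal site", so 1 means all-long-3′UTR. QAPA's PAU is per-isoform; the
gene-level usage of a multi-isoform QAPA gene is defined as the PAU of
its distal-ranked isoform, giving both indices the same
higher-is-longer polarity and making ΔPAU and ΔPDUI sign-comparable.
For genes with more than two sites this distal-isoform convention is a
design choice (no standard exists); internal sites are retained but do
not define the gene-level trend.

**Missingness.** Usage cells may be missing (DaPars emits `NA` for
low-coverage samples) and are stored as NaN, never imputed; all
statistics drop missing values pairwise. A zero-expression gene yields
all-missing PAU rather than 0 or uniform: absence of usage evidence is
not zero usage.

## Input dialects

*QAPA*: per-isoform rows; mandatory columns are matched by documented
synonyms (`Gene`/`Gene_ID`, `UTR3.Start`/`LastExon.Start`, …) because
the format's field list is prose-specified rather than fixed; sample
columns are recognised by their terminal `TPM`/`PAU` token after `.` or
`_`, with the sample id being the stripped prefix. The TPM and PAU
column sets must name the same samples. *DaPars*: the `Gene` field
encodes `transcript|gene|chrom|strand`; each row yields the predicted
proximal site plus a distal site at the 3′UTR end (locus end on `+`,
locus start on `−`). *Generic*: a documented minimal dialect
(`feature_id, gene_symbol, chrom, strand, proximal_pos, distal_pos` +
one usage column per sample) for any other quantifier; because it
stores only the two cleavage positions, its UTR is the inter-site span.
All writers are round-trip safe (`parse(write(x))` is field-for-field
identical); decimal commas are rejected and encodings are limited to
UTF-8/ASCII for determinism.

## Differential usage

ΔPAU/ΔPDUI is the difference of group means (first declared group minus
second) over non-missing values, so it is antisymmetric under group
swap. Two groups are compared with the two-sided Mann–Whitney U test:
exact enumeration when both groups have ≤ 8 observations and no ties
(verified in tests against an exhaustive-permutation oracle), the
normal approximation with tie correction otherwise; more than two
groups use the Kruskal–Wallis omnibus test with no post-hoc procedure.
If every pooled observation is identical the comparison degenerates to
p = 1. p-values are Benjamini–Hochberg adjusted across all features of
a run; raw p is reported alongside since no adjustment convention is
standard for this analysis. The trend call is
*lengthened* if `delta ≥ min_delta` and `q < alpha`, *shortened* if
`delta ≤ −min_delta` and `q < alpha`, else *unchanged*, with defaults
`min_delta = 0.1` (an effect below 0.1 on a [0,1] index is rarely
biologically interesting; exposed as a flag) and `alpha = 0.05`. The
top/bottom-*n* split (default n = 30 per tail) orders samples by
(value, sample id) so boundary ties resolve identically across runs.

## Correlation

Pearson *r* (default — the target is a *linear* usage–expression
relationship; Spearman optional) with the two-sided t-based p on n − 2
degrees of freedom, an OLS line, and the 95% confidence band for the
mean response from the t distribution; the band's width grows with
distance from the mean of x and its pointwise coverage is checked by
simulation (95% ± 2% over 1000 replicates). Constant inputs or fewer
than 3 complete pairs raise errors rather than propagating NaN. The
dataset-level screen keeps features with |r| > 0.3 and p < 0.05, sorted
by |r|; at cohort scale (n ≈ 100) a null feature clears the |r| gate
with probability ≈ 0.002, so a 100-feature screen yields a fraction of
a false positive on average — the gate controls relevance, not FDR.
Expression is used on the TPM scale by default (matching how such data
are usually plotted); a `log2(TPM+1)` flag is available. Grouped
correlation applies the same estimator within each group of a sample
assignment.

## Survival

For one gene, samples are split at the median of its usage index;
values equal to the median go to the *low* group (a deterministic,
documented convention — with an even sample count and distinct values
this is the usual half/half split). Curves are Kaplan–Meier
product-limit estimates (via lifelines), with the median survival time
as the earliest t with S(t) ≤ 0.5, undefined under heavy censoring.
Groups are compared with the two-group log-rank test computed from the
pooled risk-set table: χ² = (O_h − E_h)²/ΣV with 1 df, where V is the
per-event-time hypergeometric variance. The hazard ratio is the O/E
(Pike) estimate `(O_high/E_high)/(O_low/E_low)` — no Cox model is
fitted because no covariates enter the analysis — and is flagged
unstable whenever a group has zero observed events. The in-package
tabulation is cross-checked against lifelines' `logrank_test` in the
suite, and the type-I error rate is verified by simulation (0.05 ± 0.02
over 1000 null replicates at 50 per group). Time units are whatever
the clinical table declares (days or months); no conversion is
attempted.

## Motif and track annotation

The polyadenylation signal is scanned on the transcript's sense strand
in a window ending at the cleavage site. Default motifs: AATAAA
(canonical PAS), ATTAAA (its most common variant, removable by flag),
and TGTA (the DNA sense-strand form of the CFI/NUDT21-binding UGUA
element). Default window: 100 nt, wide enough to contain both the
canonical ~10–40 nt PAS geometry and upstream UGUA elements; offsets
are reported from the motif's first base to the cleavage site, and
overlapping occurrences all count (verified against a brute-force
substring scan). Minus-strand windows are extracted from the genome
FASTA and reverse-complemented internally, so users supply plain
genomic FASTA. Track overlap uses half-open interval semantics
(intersection length ≥ 1; strands must match when `stranded`), via an
interval tree checked against an O(n·m) oracle. Queries accept symbols
and ids (exact, case-insensitive), 1-based inclusive `chrom:start-end`
ranges (a site matches iff its cleavage position lies inside), and
gene lists whose unknown entries are reported, never dropped.

## Synthetic cohorts

`gen_usage` draws per-feature baselines uniformly on (0.2, 0.8), shifts
the second group's mean by `delta` for the affected fraction, adds
Gaussian noise and clips to [0, 1]. Affected baselines are kept at
least 0.1 inside the boundary after the shift so clipping does not eat
the injected effect; residual clipping bias near the edges is the known
cost of a bounded index. Defaults (500 features, 30 per group, 20%
affected, delta −0.3, noise sd 0.1) are the study-scale conditions the
test suite certifies. Expression coupling uses the latent-variable
construction `r·z_usage + √(1−r²)·noise` mapped affinely to a positive
TPM scale, which hits the target correlation within ±0.1 at n ≥ 100;
survival coupling draws exponential times with hazard
`(1/scale)·hr^z_usage` (hr is the per-standard-deviation hazard ratio)
under independent exponential censoring calibrated to the requested
censoring fraction. All generation flows through one integer seed and
is byte-reproducible.

What the generator does **not** emulate: read-level noise, library-size
or GC effects, correlated features, batch structure, or the heavy-tailed
missingness of real DaPars output (missingness is uniform at a stated
rate). Passing tests therefore certify the statistical machinery under
idealised sampling, not robustness to real-data artefacts.

## CLI and reproducibility

The project bundle is a plain directory (normalized dialect TSV,
expression/clinical TSVs, JSON manifest with counts and SHA-256
checksums) rather than an opaque container, for transparency and
diff-ability. Outputs carry a `run_log.json` recording command
parameters; logs contain no timestamps, so identical invocations yield
byte-identical outputs. Exit codes: 0 success, 1 user error, 2 data
error. Plots (KM curves) are optional byproducts behind a flag; the
analytic surface is the TSVs.

## Known limitations

No covariate adjustment or paired designs in differential usage; no
post-hoc tests after Kruskal–Wallis; no partial correlation or network
inference; no Cox regression, competing risks or stratification; no
intronic-APA classification (the model is 3′UTR APA); annotation
databases (PAS catalogues, RBP/miRNA tracks) must be supplied by the
user as BED.
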