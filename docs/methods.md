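# Methods

`smrcoloc` implements a summary-statistics colocalization pipeline for
annotating GWAS loci with candidate causal genes, together with the
evidence-aggregation protocol used to combine expression colocalization with
literature and bioinformatics prioritization for 51 coronary-artery-disease
(CAD) loci.

## Locus selection and matching

A locus is the ±250 kb window (inclusive ends) around a lead SNP.
Discovery uses greedy P-ranked clumping: the most significant SNP below the
genome-wide threshold (default P < 5×10⁻⁸) becomes a lead and absorbs all
SNPs within the flank on its chromosome; the procedure repeats on the
remainder. Loci found in a mixed-ancestry meta-analysis are retained only
when a European-ancestry dataset shows at least one SNP in the window at
P < 5×10⁻⁷, and the locus is then re-anchored on that European lead — LD-based
tests must be referred to a homogeneous-ancestry panel, so the European
signal defines the working window.

Loci from two source datasets are declared the same signal when their lead
SNPs are less than 250 kb apart on the same chromosome (strict inequality).
Matching is one-to-one: the globally closest eligible pair is matched first.
The two known overlapping-but-unmatched pairs in the packaged evidence table
sit 269.4 kb and 344.2 kb apart (half-up rounding of 269,397 and 344,241 bp
to one decimal in kb), so both members of each pair are analyzed as separate
loci.

Design choices where the procedure was genuinely open: greedy
most-significant-first clumping (the standard reconstruction when only the
final locus list is published); one-to-one greedy-by-distance conflict
resolution in matching; deterministic tie-breaks everywhere (position, then
rsid). Multi-signal decomposition (conditional analysis) is deliberately out
of scope.

## Harmonization and SNP filters

GWAS and cis-eQTL tables are read through a column-mapping dialect into one
canonical schema; `z` is derived as `beta/se` and two-sided p-values from
the normal tail where absent (some eQTL resources publish only Z-scores).
Effect alleles are aligned by allele letters; when effect/other labels are
swapped between datasets the eQTL beta and z are negated. Palindromic (A/T,
C/G) SNPs are retained and matched by letters by default — no strand filter
is applied — with a `drop_palindromic` flag as a safety valve. Allele-
incompatible SNPs are dropped and counted.

Eligible SNPs must be present in both datasets with MAF ≥ 0.03 in both
(inclusive); instrument candidates additionally need squared GWAS Z ≥ 10
(inclusive). The instrument ("top SNP") is the candidate with the lowest
GWAS p-value; a config flag switches to eQTL-ranked instrument choice. When
a dataset lacks MAF, the reference panel's allele frequency is substituted
if a panel is supplied; otherwise the SNP fails the MAF filter, which the
filter's "in both datasets" wording makes mandatory.

## SMR and HEIDI

At the top SNP, the SMR statistic

T_SMR = z_G² · z_E² / (z_G² + z_E²)

is referred to χ²₁, and the Wald ratio b_xy = b_G / b_E estimates the effect
of expression on the trait, with delta-method standard error
se_xy = |b_xy| · √(1/z_G² + 1/z_E²). SMR p-values are adjusted by
Benjamini–Hochberg across all probe×tissue pairs in a run (one global
family; switchable to per-tissue). Underflowing p-values are clamped at
1e-300 and reported with three significant digits.

HEIDI tests whether the Wald ratio is homogeneous across SNPs in LD with the
instrument. Candidates are SNPs from the analysis set with r² to the top SNP
in [0.05, 0.9] (excluding near-perfect proxies, which carry no independent
information, and near-independent SNPs, which carry no signal), ranked by
eQTL significance and capped at 20; the test requires at least 3 candidates
and otherwise reports a skip. For each candidate, d_i = b_xy(i) − b_xy(top).
The covariance of the d vector is assembled by a first-order delta expansion
carrying the LD correlations,

Cov(b̂_xy(i), b̂_xy(j)) ≈ b_xy(i)·b_xy(j)·[ r_ij/(z_G(i) z_G(j)) + r_ij/(z_E(i) z_E(j)) ],

with the top-SNP cross terms included. The statistic S = Σ (d_i/sd_i)² is
referred to the weighted sum Σ λ_k χ²₁, λ being the eigenvalues of the
correlation matrix of the standardized d (ridge 1e-8). The tail probability
is evaluated by Imhof's characteristic-function inversion: the integral is
truncated where its envelope 1/(u·ρ(u)) falls below 1e-13 and computed by
adaptive quadrature; if the quadrature's error estimate exceeds 1e-6 the
code falls back to two-moment (Satterthwaite) matching and records which
path was used in the result.

A probe×tissue colocalizes ("pass") iff its SMR FDR is below 0.05 **and**
HEIDI was tested (3–20 SNPs) with p ≥ 0.001. An SMR-significant probe whose
HEIDI was skipped is reported `untested_heidi` rather than silently passed
or failed; HEIDI rejection yields `fail_heidi` (linkage, not pleiotropy).

Degenerate inputs: z_G = z_E = 0 is an undefined statistic; b_E = 0 an
undefined ratio; all-zero d gives p = 1 directly (perfect homogeneity).

## Theta metric

As a second colocalization check, theta is computed as the Pearson
correlation between the allele-aligned GWAS and eQTL Z-score vectors over
the locus's filtered shared SNPs (the same analysis set as SMR/HEIDI,
without removing the top SNP, so the two checks see the same data). The
original metric's exact formula is not published in a reproducible form, so
this correlation reading is an explicit surrogate behind a single strategy
point (`theta_metric`) where an alternative formula can be substituted; its
numbers are not claimed to replicate any external implementation. The call
is `colocalized` iff |θ| > 0.7 and the SNP count exceeds 3 (both strict);
with ≤ 3 SNPs or a constant vector the probe is `untested`.

## LD panel

LD is the Pearson correlation of genotype hard-call dosages — the standard
composite estimate on unphased data, with no extra 2p(1−p) standardization.
Panels come from VCF (GT hard calls, biallelic SNVs; sporadic missing calls
mean-imputed) or a plain dosage matrix; monomorphic variants never enter LD
computation, and a panel-level MAF ≥ 0.03 filter is available. Evidence
grouping ("arrow" annotation) joins SNP-linked evidence whose SNPs are
identical or have r² ≥ 0.8 and takes connected components — transitive
closure makes the grouping deterministic and order-independent.

## Evidence aggregation and the packaged table

The packaged fixture transcribes the 51-locus evidence table: lead SNP and
GRCh37 position, nearest gene, genes prioritized by SMR/HEIDI, literature
candidates (with "strong" marking the well-known CAD genes), three SNP-based
prioritization studies (two carrying integer scores with printed ranges
1–11 and 2–54), one gene-based association study (number of supporting
datasets), printed LD arrow groups, and the curated conclusion with its
verdict genes. Conclusions are data, not computation: the original synthesis
was a manual judgment, and recomputing it would misrepresent the protocol. A
clearly labelled heuristic scorer (weighted source counting) exists for
synthetic runs only and is never compared to the curated conclusions.

Accounting conventions that the counts depend on: gene symbols are
normalized through the alias lists the table itself provides (e.g.
PLPP3 = PAP2B = PPAP2B, JCAD = KIAA1462); symbols the table keeps distinct
stay distinct (ABCG8 vs ABCG5, EIF6 vs ITGB4BP, C12ORF30 vs NAA25); the
uncharacterized probe HS.443185 counts as a candidate entity; verdict genes
appearing in two overlapping loci are deduplicated; the nearest gene is
positional information, not evidence. Under these conventions the fixture
reproduces every headline count: 51 loci, 36 with a causal or most-likely-
causal conclusion (27 + 10 = 37 distinct verdict genes), 18 well-known-gene
loci, 9 of those 18 genes also in the SMR/HEIDI column, 15 loci without
inference, 14 distinct candidates at the largest locus, and 37 loci with
more than one candidate.

The per-gene prioritized rsids and pairwise r² values from the original
supplementary material are not packaged; the fixture encodes the printed
arrow groups with synthetic placeholder SNP identifiers (`rsL<locus>g<group>`,
declared synthetic in the fixture header) so the grouping convention remains
reproducible and testable. Spearman score correlation between the two scored
studies is computed with average ranks for ties; the published correlations
are not re-asserted because they require the unpackaged supplementary score
tables.

## Synthetic data

The generator produces the statistical structure the tests assume, under
three architectures: **pleiotropy** (one SNP causal for trait and
expression — HEIDI's null), **linkage** (two distinct LD-correlated causal
SNPs — HEIDI's alternative), and **null** (no trait association — SMR's
null). Genotypes are latent AR(1) standard normals thresholded at
Hardy–Weinberg quantiles per SNP MAF, giving hard calls with decaying LD.
Summary statistics are drawn directly at the Z-score level,
z ~ MVN(Rλ, R) with R the panel LD matrix and λ the per-trait
non-centrality placed at the causal index; betas and SEs are back-filled
for a standardized phenotype (se = 1/√(2·maf·(1−maf)·n)), so Wald ratios
have an interpretable scale and the true expression-to-trait ratio under
pleiotropy is (λ_G/λ_E)·√(n_E/n_G). Simulating at the Z level gives exact
marginal control and is orders of magnitude faster than individual-level
regression; individual-level phenotypes, realistic human LD maps and
case/control liability modelling are out of scope, so passing tests
demonstrate correct statistical behaviour under the stated model, not
robustness to real-data pathologies (imputation error, allele-frequency
mismatch between studies, multi-signal loci).

Benchmark study conditions (`smrcoloc.calibration`): a 30-SNP locus with
latent AR(1) ρ = 0.8 and MAF ∈ [0.05, 0.5], a 2,000-individual reference
panel, n_GWAS = 200,000 and n_eQTL = 2,000, non-centrality 8 for
pleiotropy/null and 12 ("strong effects") for linkage, with the linkage
causal pair chosen at r² closest to 0.5. One panel is simulated per
benchmark; 1,000 replicates (2,000 for the null-uniformity check) redraw
the summary statistics. Under these conditions the suite verifies: null SMR
p-values near-uniform (KS < 0.05, instrument chosen by eQTL significance
with the z² ≥ 10 GWAS gate disabled, since conditioning on the GWAS trait
would bias the null); pleiotropy HEIDI rejection at α = 0.05 below 0.10
(near-calibrated or conservative); linkage HEIDI rejection above 0.5 at the
stringent 0.001 threshold; and Wald-ratio recovery within 3 SEs in ≥ 95% of
replicates.

## Numerical conventions

Floats in output files use fixed 6-significant-digit formatting so equal
seeds give byte-identical files. p-values are clamped at 1e-300. LD matrices
are symmetrized and can take a configurable diagonal ridge before
eigen-decomposition. Ties in top-SNP choice break by position then rsid;
ties in ranks use averages. Distance reporting rounds kb half-up to one
decimal. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

* The HEIDI candidate-selection details (r² window bounds, eQTL ranking)
  reconstruct the cited method's published practice rather than an exact
  specification; both bounds are config-exposed and recorded in the run
  manifest.
* The theta metric is a documented surrogate (see above).
* One BH family per run is the most conservative reproducible FDR scope;
  per-tissue adjustment changes which probes pass near the boundary.
* The curated conclusions and the arrow-group SNP identities are transcribed
  data; they cannot be recomputed from public inputs inside this package.
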