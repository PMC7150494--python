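# Methods

`aasig` implements a screening analysis for the aristolochic-acid (AA)
mutational process in urothelial carcinoma: somatic SNVs are post-filtered,
collapsed into 96-trinucleotide-context catalogs, attributed to reference
mutational signatures by non-negative least squares, and summarized as the
per-sample proportion of mutations attributable to the AA signature
(COSMIC signature 22). That proportion drives two subtype callers — cohort
hierarchical clustering for tumor panels, and fixed screening thresholds
for single samples such as urinary cell-free DNA (cfDNA) sequenced at low
coverage — and feeds the clinical association and survival comparisons
between the resulting AA Sig and No-AA Sig groups.

## Somatic SNV post-filtering

The filter engine consumes candidate SNVs already annotated with
read-level summary statistics; it does not run aligners or callers. A
candidate is removed when it fails any of eight read-level rules, each a
scalar cutoff (defaults in `FilterThresholds`):

1. median shortest distance of the variant position to either aligned read
   end < 10 bp (alignment-end artifacts);
2. median absolute deviation of that distance < 3 bp (stacked duplicates);
3. fraction of covering reads with mapping quality < 1 above 10%;
4. median mapping quality of variant reads < 40;
5. median base quality at the variant position < 20;
6. minority-strand fraction of variant reads < 0.02, unless the
   minority-strand fraction of all covering reads is also < 0.2 (a locus
   that is strand-skewed for every read is not evidence against the
   variant);
7. adjacent 1–4-mer repeat tract ≥ 12 bp;
8. more than 2 other variant positions in any surrounding 50-bp window.

Inequality directions are implemented exactly as stated above: "less than"
cutoffs are strict, the repeat rule is inclusive at 12, the
population-frequency cutoff below is inclusive at 0.001. Strand-bias
fields store the minority-strand fraction (in [0, 0.5]) so the 0.02 / 0.2
cutoffs act on the under-represented strand; this is a design choice where
the plain "fraction of reads in either direction" would be ambiguous.

Two cohort-level filters follow: an allele-frequency window retaining
0.25 < AF < 0.75 (above: germline-like; below: enriched for FFPE damage),
and removal of variants with frequency ≥ 0.001 in any population database
(1000 Genomes phase 3, ExAC, ESP6500, HRC, Kaviar, plus a local panel of
normals modeled as the database `panel`), with a rescue clause keeping
ClinVar-pathogenic or COSMIC urinary-annotated variants regardless of
population frequency. Caller intersection (`intersect_callsets`) keeps
records whose (chrom, pos, ref, alt) key is reported by both callers,
taking feature annotations from the first callset — one caller must be the
designated annotation source for determinism.

A variant failing several rules is removed under OR semantics but counted
under the lowest-numbered failing rule, so per-rule rejection counts
partition the removed set. The engine applies the eight rules before the
AF window and the population filter; since the retained set is a pure
conjunction the order does not change it, only the attribution of counts.
In low-coverage mode the AF window is the identity: per-variant AF is
meaningless at ~1× coverage.

## Catalogs and signature refitting

Each SNV maps to one of 96 classes (6 pyrimidine substitutions × 16 flank
pairs), strand-collapsing purine references by reverse complementation.
The canonical row order is substitution-major, then 5′ then 3′ flank,
alphabetical — the COSMIC v2 file order — so catalogs align with a
downloaded signature matrix without permutation; the loader validates and
reorders row labels in any case. Coordinates are 1-based; flanks are
pos−1/pos+1 from an indexed FASTA, with chromosome-name normalization
("chr1" vs "1") available because hg19 FASTA sources differ.

Refitting solves `min ||m − P e||₂ subject to e ≥ 0` per sample, where `m`
is the 96-vector of counts and `P` the column-stochastic signature matrix,
using Lawson–Hanson active-set NNLS (`scipy.optimize.nnls`). Exposures are
in mutation-count units; merging sums them by shared etiology into 10
groups. The default merge map is anchored by AA = {signature 22} — the
one documented identity — with the remaining groups assigned by the
signatures' standard proposed etiologies (clock {1, 5}, APOBEC {2, 13},
mismatch-repair deficiency {6, 15, 20, 21, 26}, tobacco {4, 29}, UV {7},
POLE {10}, alkylating {11}, aflatoxin {24}, `other` for the rest); it is
configuration, not code, and can be replaced from a `signature: group`
file. All 30 reference signatures are fit by default; a subset list is
accepted where an analysis wants to restrict the dictionary.

The screening statistic is the AA proportion: AA-group exposure divided by
total exposure.

### The reference signature matrix is synthetic

The genuine COSMIC v2 probabilities are an external download, so the
package generates a clearly-labeled synthetic stand-in
(`synthetic_signature_matrix`): 30 column-stochastic signatures from a
fixed seed, each mixing a sparse Dirichlet background with concentrated
mass on the field-known motif where one exists — signature 22 dominated by
T>A transversions peaking at C[T>A]G, signature 1 by C>T at NpCpG, the
APOBEC pair by C>T/C>G at TpCpN, UV by C>T at dipyrimidines, and so on.
This preserves what matters for validating the method (a distinctive,
sparse AA signature embedded among near-flat and motif-specific
companions) while making no claim to the real probabilities; analyses of
real cohorts should load a genuine COSMIC matrix via
`load_signature_matrix`, which accepts the standard download layout.

## Subtype assignment

Cohort mode: per-sample merged exposure vectors are log1p-transformed,
clustered with Ward linkage on Euclidean distances, and the tree is cut at
two clusters (the analysis is defined for exactly two subtypes); the
cluster with the larger mean AA exposure is labeled AA Sig. log1p on
attributed counts is the package's choice — raw counts let total mutation
burden dominate the geometry and proportions discard burden entirely;
both alternatives remain available (`transform="none"` / `"proportion"`,
and metric/linkage are parameters). Identical rows are rejected as a
degenerate dendrogram, and a single sample is directed to threshold mode.

Threshold mode: cfDNA calls AA Sig above 15% AA proportion and No-AA Sig
below 5%; the band between is labeled No-AA Sig with an `indeterminate`
flag because only the extremes are validated. Tumor mode uses a single
50% cutoff. All three cutoffs are strict inequalities.

## Clinical statistics

Covariate-by-subtype association uses Pearson chi-square without
continuity correction; this choice reproduces the published 2×2
stratification p-values (sex 0.034, multifocality 0.003, tumor size
0.009, T stage 0.005, location 0.027, smoking 0.092, architecture 0.361)
to the printed precision. Kruskal–Wallis on level codes is available for
ordered covariates (e.g. CKD stage). Three published rows (N stage,
postoperative chemotherapy, postoperative radiotherapy) do not reproduce
under Pearson, Yates-corrected, or Fisher tests on the printed counts;
whatever test produced them is undocumented, so the table builder renders
Pearson p-values for them and no claim is made. No multiple-testing
correction is applied, matching the source analysis. Percentages render
to 1 decimal place, p-values to 3, with values below 0.001 as "<0.001".

Survival uses the Kaplan–Meier product-limit estimator and the two-group
log-rank test (1 df), both via `lifelines`; ties between an event and a
censoring at the same time follow the standard convention (events first).

## Synthetic-data generators

All generators are seed-deterministic and return ground truth alongside
the data.

* `simulate_catalog`: multinomial draw of n mutations from a signature
  mixture. The default study condition for recovery experiments is
  n = 20,000 — the scale of a whole-genome tumor mutation count in this
  disease — with the AA weight on signature 22 and the remainder split
  evenly between the clock-like signatures 1 and 5, a realistic
  background for urothelial tumors without a dominant exogenous process.
* `simulate_tumor_cfdna_pair`: the cfDNA catalog is a binomial thinning
  (default fraction 0.05, emulating the ~20-fold mutation loss of
  low-coverage calling) of the tumor catalog. Thinning models reduced
  yield only; cfDNA-specific error modes (fragmentation bias, germline
  contamination of urine) are deliberately out of scope, so the
  recoverability results speak to counting noise, not to assay chemistry.
* `simulate_variant_records`: true records draw every read-level
  statistic comfortably inside its passing band; artifact records draw
  the designated statistic uniformly in a narrow band just beyond its
  threshold (and only that statistic), so strict-vs-inclusive boundary
  semantics are exercised and filter sensitivity/specificity against
  generator labels is exactly 1 when the bands are disjoint. Germline-het
  contaminants are modeled as population-database hits at AF ≈ 0.5;
  hom-germline and FFPE classes violate the AF window from above and
  below.
* `simulate_cohort`: binary covariates are Bernoulli per subtype with a
  configurable odds ratio against a 0.3 baseline prevalence; event times
  are exponential (AA-group hazard 0.02/month, No-AA hazard scaled by the
  hazard ratio, default 3 — the direction and rough magnitude of the
  published survival separation), and censoring is independent
  exponential with its rate set per group so the expected censored
  fraction equals `censor_rate`.
* `simulate_genome` / `simulate_wgs_sample`: a random genome and SNVs
  placed at positions whose trinucleotide matches the drawn class on
  either strand, so catalogs rebuilt from the emitted VCF + FASTA equal
  the generator's tally exactly.

What passing these tests shows — and does not. The generators establish
that the pipeline recovers what it is supposed to recover under its own
model (multinomial counting noise, exponential survival, clean feature
bands). They do not establish robustness to misspecified reference
signatures, signature collinearity beyond the synthetic set, cfDNA error
modes, or non-proportional hazards.

## Numerical choices and problem sizes

* NNLS: `scipy.optimize.nnls` active-set solver; degenerate/tied active
  sets resolve by the solver's deterministic ordering. Exposure vectors
  clip negatives below 1e−12 (solver round-off) to zero.
* Signature-weight recovery is validated on a grid of AA weights
  {0, 0.1, …, 0.9} at n = 20,000 with 100 seeds per cell (mean absolute
  error of the AA proportion ≤ 0.03); low-coverage recoverability on 200
  seeds of 5% thinning (±0.08 of truth for AA weight 0.6 in ≥95% of
  seeds; below the 5% screening floor for AA weight 0 in ≥95%).
* Log-rank calibration uses 500 replicates at n = 50 per group: type-I
  error within [0.03, 0.07] at hazard ratio 1, power ≥ 0.9 at hazard
  ratio 3.
* Zero-total catalogs are an error by default (`allow_zero` returns a
  zero exposure vector instead, with reconstruction cosine 0); zero
  marginals make chi-square expected counts undefined and are errors.

## Known limitations

* The reference matrix shipped for simulation is synthetic (above); real
  attributions require a genuine COSMIC matrix.
* The 23-signature subset and exact 10-group merge of the original
  analysis are unpublished; the default fits all 30 signatures and uses
  the etiology map above. Merged attributions other than AA may therefore
  differ from the original in detail; AA = signature 22 is exact.
* Whether the original cohort clustering used raw counts, proportions, or
  a transform is undocumented; log1p counts is this package's default and
  a parameter.
* Indel and doublet catalogs, transcription-strand-resolved (192-class)
  catalogs, de-novo signature extraction, driver discovery and Cox
  modeling are out of scope.
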