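# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Somatic filtering

Filtering operates at the variant level on precomputed evidence; read-level
preprocessing (base-quality trimming, alignment) belongs to the upstream
caller and is represented only through the ingested q-value. Thresholds
(`FilterParams` defaults):

| parameter | default | unit | role |
|---|---|---|---|
| `min_call_quality` | 12 | phred-like q | caller confidence floor (SNVs) |
| `min_tumour_depth_snv` | 50 | reads | tumour coverage floor |
| `min_germline_depth_snv` | 20 | reads | matched-normal coverage floor |
| `max_germline_mismatch` | 0.10 | fraction | germline contamination guard (strict `<`) |
| `min_vaf` | 0.10 | fraction | subclonal-noise floor (inclusive `>=`) |
| `min_indel_support` | 20 | reads | INDEL total support |
| `min_indel_interior_support` | 5 | reads | support with event >= 25 bp from both read ends |
| `min_germline_cover_indel` | 20 | reads | germline coverage at the site |
| `germline_indel_window_bp` | 20 | bp | exclusion window for germline INDELs |
| `max_local_mismatch_10bp` | 0.10 | fraction | local alignment-noise guard (strict `<`) |
| `max_adjacent_repeats` | 5 | regions | repeat-adjacency exclusion (`> 5` rejects) |

Boundary semantics follow the thresholds' wording: "at least"/"minimum" are
inclusive, "less/lower than" strict. Ties at the VAF cut are therefore kept
(VAF = 0.10 passes); a germline mismatch fraction of exactly 0.10 is
rejected. Two germline-INDEL conditions (none at the site; none within 20 bp)
collapse into one reason code because the at-site case is the window's
distance-zero case; they are not separately observable from the ingested
per-record counts. Rejected records carry *all* failing reasons, in a fixed
order, so audits of multiply-defective synthetic records are reproducible.
The unit of "repetitive regions" is ingested as a precomputed integer
annotation; the package does not define repeat discovery.

## Functional impact

An SNV is high functional impact (HFI) when at least 3 of the 6 predictor
verdicts are "deleterious". "Unknown" verdicts are non-votes: the denominator
stays six, which is the conservative reading (a variant with three tools
silent needs all three remaining tools to call it deleterious). All retained
INDELs are HFI by rule, independent of verdicts. The vote is monotone by
construction and is verified in the tests against exhaustive enumeration of
all 3^6 verdict combinations.

## Mutation burden

Callable bases are positions with depth >= 20 (inclusive). One Mb is 10^6
bases. Mode *all* counts every kept variant including synonymous, intronic
and intergenic SNVs; mode *nonsyn* counts missense, stop-gained and
splice-site SNVs plus INDELs, so `burden_nonsyn <= burden_all` always. Values
are carried raw; a two-significant-figure rounding helper matches the usual
reporting style. The demo analysis extrapolates a 200 kb simulated track to a
nominal 36 Mb exome for interpretable per-Mb numbers; the library itself
takes whatever callable-base count it is given.

## Mutational signatures

Catalog inclusion is deliberately different from the somatic filter: SNVs
with VAF > 10% (strict) and quality > 20 (strict), with *all* consequence
classes contributing. Substitutions are classed into the canonical 96
pyrimidine-centred trinucleotide categories; purine-reference calls are
reverse-complemented first.

Refitting minimises the squared error between the catalog's proportions and a
nonnegative mixture of reference rows by iterative forward selection: each
round line-searches every signature's weight on [0, 1] (golden-section, weight
tolerance 1e-6) with the others fixed, commits the single best improvement,
and re-optimises the active set by cyclic coordinate descent. Rounds stop when
the best improvement falls below `tol` (default 1e-3) *relative* to the
current SSE, so the stop rule tracks the attainable optimum rather than an
absolute scale. Weights below `min_contribution` (default 0.06) are then
pruned and the survivors re-optimised, repeated until every reported weight
clears the floor; `unexplained = 1 - sum(weights)` so the reported masses sum
to one. The fit is deterministic. No trinucleotide-opportunity rescaling is
applied by default (the catalog's raw proportions are fit directly); callers
wanting opportunity normalisation can rescale the matrix rows before fitting.
Known behaviour, quantified in the tests: at a few hundred mutations a small
spurious signature can survive the 0.06 floor; at n = 2000 a 0.7/0.3
two-signature mixture is recovered within ±0.05 in ≥ 95% of seeded
replicates. De novo extraction (NMF), INDEL/CNA signatures and composite
HRD classifiers are out of scope.

### The bundled reference matrix

The packaged 30-signature matrix is **synthetic** (`refdata.py`): a
deterministic stand-in with the shape, naming and row semantics of the widely
used 30-signature catalog — a CpG-deamination-like row, a near-flat
HR-deficiency-like row, a T>G-concentrated row, and sparse Dirichlet rows
elsewhere — built so refitting exercises are well-posed. Results on it say
nothing about real tumours; any matrix in the documented CSV schema (rows
summing to 1 over the 96 canonical columns) can be supplied instead.

## Pathway enrichment

The EASE score is the one-sided upper-tail Fisher p of the 2x2
query-vs-pathway table with one gene removed from the overlap cell:
P[X >= k-1] for X ~ Hypergeom(N, K, n). k <= 1 returns 1 by convention.
Removing a success always weakens the evidence, so EASE p >= classical
Fisher p; both are property-tested, and EASE is checked against exact
integer enumeration over every table with N <= 60. The background N defaults
to the collection's distinct-gene universe (the annotation service this
mirrors leaves its background implicit; the default is documented and
overridable). No multiple-testing correction is applied by default, matching
the per-pathway alpha = 0.05 convention; Benjamini–Hochberg is available but
off. Group comparisons report per-pathway counts of significant samples per
group and deliberately compute no pooled statistic — with a handful of
patients per group, "3 of 5 vs 0 of 6 samples significant" is the honest
resolution of the data.

## Clonal inference

Full cancer-exome clonality tools integrate copy number, purity and cohort
controls; this package deliberately replaces that machinery with a VAF-only
model under the assumption of diploid, copy-neutral sites, where a clone's
cellular fraction is proportional to its VAF. Each sample's variants
contribute (alt reads, depth) pairs modelled as a K-component binomial
mixture fit by EM (responsibility updates until the log-likelihood gain is
below 1e-8, at most 300 iterations). K runs from 1 to `k_max` (default 5) and
is chosen by BIC with 2K-1 free parameters. Initialisation uses the fixed
VAF-quantile grid ((j+0.5)/K quantiles), giving determinism; the seed only
drives two jitter restarts that guard against bad local optima at higher K.
Components left with fewer than two members after maximum-responsibility
assignment are dissolved into the nearest surviving cluster, so clusters
always have at least two defining variants.

Diagnostic and residual clusters are matched greedily by descending Jaccard
overlap of member variant loci (sample prefixes stripped), each cluster used
at most once; pairs with overlap >= 0.5 are *persistent*, unmatched residual
clusters *emergent*, unmatched diagnostic clusters *extinct*. Greedy matching
is deterministic and auditable, and at desk scale (a handful of clusters per
sample) is equivalent to optimal matching in all but contrived ties. Copy
number segmentation, phylogeny reconstruction and cohort-normalised error
models are explicitly not attempted, so inferences about real tumours should
treat these fates as VAF-cluster bookkeeping, not lineage proof.

## Trial statistics

The design is a single-stage exact binomial rule: n = 40, success iff >= 17
responders, p0 = 0.30, p1 = 0.50. Operating characteristics are the exact
tails P[X >= 17 | n, p] — 6.33% size and 86.6% power, i.e. the stated 6% and
87% after integer rounding. Response percentages are carried raw alongside
numerators; display rounding is left to callers (the reports print one
decimal where the underlying fraction needs it, e.g. 47.5%, and the TNBC
rate 7/15 is carried as 46.67 rather than asserting a rounding rule).
Disease-free survival uses the product-limit estimator with right censoring
(via lifelines); time origin is trial registration, primary progression
during treatment is flagged and excluded from events, and the median is the
smallest t with S(t) <= 0.5, reported as undefined while the curve stays
above 0.5. Relative dose intensity is delivered/planned dose; the
adverse-event table counts a patient once per term at the worst grade and
keeps terms with any-grade frequency >= 10% or any grade >= 3 event.

## Synthetic-data generator

The generator is the package's substitute for the trial's (undeposited)
sequence-level data; its defaults are the study's conditions.

* **Variant pairs**: intended-pass records clear every filter threshold with
  at least one unit of margin (quality drawn on [25, 60], tumour depth
  Poisson around 150× clamped >= 51, germline depth Poisson around 50×
  clamped >= 21, germline mismatch <= 0.08). Planted failures are pass
  records broken on exactly one condition into the failing range, so the
  filter audit must reproduce the planted reason codes and counts exactly.
  Alt reads are binomial at the record's clone VAF; for intended-pass records
  the draw is clamped up to VAF >= 0.11 (recorded in the ground truth), since
  an unclamped draw could legitimately fail the VAF cut.
* **Contexts**: each passing SNV draws its generating signature from the
  configured weights and its 96-class from that signature's row, so the
  sample catalog converges to the configured mixture (cosine similarity to a
  single generating signature > 0.99 by n = 5000 in the tests).
* **Two-timepoint clone structure**: persistent clones reuse the same loci at
  the residual timepoint with alt counts redrawn at the residual VAF;
  emergent clones introduce new loci; unmapped diagnostic clones are extinct.
  No VAF clamping is applied here — clone VAFs are the object under study.
* **Cohort**: the 40-patient table reproduces the trial's reported marginals
  exactly (22 breast pCR split 12/7/3 across subtypes; 18 breast+LN pCR split
  12/5/1; 13 ypT0 ypN0; 4 nCR; 19 breast-conserving; 7 DFS events assigned to
  non-pCR patients first; 35 patients at >= 85% dose intensity; the published
  adverse-event marginals). Joint distributions the reports do not constrain
  (which patients conserve the breast, event times, AE co-occurrence) are
  drawn from a seeded stream; censoring times span the reported 11.5–31.6
  month follow-up range.
* **Determinism**: one global seed; each component derives its own stream by
  a fixed offset, so adding a generator never perturbs another's draws. Fixed
  seed implies byte-identical outputs.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: read-level artefacts (FFPE damage, strand
bias, mapping error), overdispersed coverage, copy-number alteration and its
effect on VAFs, germline contamination structure, and correlated
predictor-verdict errors. The generator validates the *pipeline's logic*, not
the upstream caller.

## Problem sizes

Default test and demo sizes are chosen for desk-scale iteration: hundreds of
variants per sample, 200 kb depth tracks, 35–50 variants per clone at
200× depth, 100-replicate seeded simulations for signature recovery, and a
50-patient scenario sweep for clone-fate accuracy. These sizes are where the
methods' asymptotics already hold; the library itself has no scale
assumptions beyond memory.

## Known limitations

* The EASE background universe is a documented stand-in (distinct genes in
  the collection); enrichment p-values shift with the background choice.
* The binomial mixture ignores overdispersion; heavily overdispersed real
  data would fragment clones.
* Signature refitting on the synthetic reference matrix is a methods
  exercise; per-sample signature calls on real tumours require the real
  reference catalog and deposited data.
* The VCF dialect is a minimal subset (single-sample-pair, split
  multi-allelics upstream); BAM/CRAM access is out of scope.
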