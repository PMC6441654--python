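# Methods

## Experimental design assumed

All stages assume a factorial time-course: conditions {control (0 °C), LTC,
HT} × timepoints {1, 2, 4, 6, 8} days × replicates (default 3), with raw
integer read counts per gene (assembled transcript) and per-gene transcript
lengths.  Day 0 is not part of the series: treatments are contrasted with
the chilling control at matching days, so a pre-treatment baseline plays no
role in any statistic.  The timepoint series and replicate number are
configurable; every rule expressed as "k of 5" generalizes to the
configured series length.

## Differential expression

**Normalization.** RPKM (reads per kilobase of transcript per million
mapped reads) is used for reporting, ranking indicators and network
profiles.  DE testing operates on raw counts: RPKM is not variance-stable
and the exact test models counts directly.

**Exact test.** For one gene at one (treatment, timepoint) contrast with
replicate counts `a = (a_1..a_{n_a})` against control `b = (b_1..b_{n_b})`:

1. Each replicate is rescaled to the common effective library size
   `L* = round(geometric mean of the 2-group library sizes)` and rounded to
   an integer: `a_i ← round(a_i · L*/L_i)`.  Rounding keeps the NB support
   integral and is deterministic; two-sided alternatives defined by summed
   probability mass (below) avoid any tie-breaking ambiguity.
2. With group sums `S_a, S_b`, total `T = S_a + S_b` and pooled mean
   `μ̂ = T/(n_a+n_b)`, group sums are modelled as `S_g ~ NB(n_g μ̂, φ/n_g)`
   (a sum of `n_g` i.i.d. NB(μ̂, φ) variables).  The two-sided p-value is
   `p = Σ_{k: P(k, T−k) ≤ P(S_a, S_b)} P(k, T−k) / Σ_k P(k, T−k)`,
   i.e. the conditional probability of every split as or less probable than
   the observed one.  At φ = 0 this reduces to the conditional binomial
   `Bin(T, n_a/(n_a+n_b))` (Poisson limit).  A relative tolerance of 1e-10
   guards the "≤ observed" comparison against floating-point ties.
3. `log2FC = log2((mean(a*) + 0.5)/(mean(b*) + 0.5))` on the rescaled
   counts; the 0.5 pseudocount keeps fold changes finite for zero groups.

This is an exact-test workflow in the tradition of classic two-group count
DE analysis, defined in full here; no numerical identity with any external
package is claimed.  The suite verifies it against an independent
enumeration oracle to ~1e-9 relative error for totals ≤ 200.

**Dispersion.** φ (variance = μ + φμ²) is estimated per gene by the method
of moments: counts are rescaled to the mean library size (so depth
differences do not inflate variance), `(s² − m̄)/m̄²` is computed in every
(condition, timepoint) cell with ≥ 2 replicates, and the per-gene median
across cells is floored at 1e-4.  The floor handles constant replicates and
under-dispersed cells.  No empirical-Bayes shrinkage across genes is
applied; with 15 three-replicate cells the pooled median is serviceable,
and simulation tests show the resulting calls control the per-contrast
false-call rate well below the nominal 5 % at the default settings (the
fold-change ≥ 2 gate removes most borderline significance).

**Calls.** Benjamini–Hochberg FDR is computed across genes within each
(treatment, timepoint) contrast — matching the per-contrast way DEG counts
are reported in this design — and a gene is called up (down) iff
`log2FC ≥ 1` (`≤ −1`) and FDR ≤ 0.05.  Both thresholds are parameters.

## DEG-set filters

- **Same-trend filter (default min_support 2):** a gene is retained iff it
  is called in one direction at ≥ min_support timepoints.  A gene reaching
  the threshold in *both* directions has no coherent trend; it is excluded
  and logged.  Only significant calls count — fold-change signs at
  non-significant timepoints are ignored (a deliberate reading of
  "same trend"; the alternative would let noise votes decide direction).
- **Responder set:** the same rule at min_support 4.
- **Cross-treatment intersection** reports genes present in both
  treatments' sets with each direction; direction agreement is flagged, not
  required.
- **Strand filter:** a contig is discarded iff
  `sense_reads < 0.10 × antisense_reads` — strictly, so a contig exactly at
  10 % is kept; contigs with zero antisense reads are kept (no antisense
  evidence of a second-strand artifact).
- **Assembly stats:** N50 is the length at which the descending-sorted
  cumulative length first reaches ≥ half the total.

## Entropy-weight ranking

Indicators per gene (m = 10): the five per-timepoint replicate-mean RPKM
values under the treatment, and five linear fold changes `2^|log2FC|` vs
control.  The absolute value makes down-regulation count as strongly as
up-regulation and keeps all indicator values non-negative, which the
entropy normalization requires; whether the original formulation used
signed, absolute or log fold changes is not recoverable, so the choice is
made explicit here.

With column proportions `f_ij = r_ij / Σ_j r_ij` (0·ln 0 := 0):

- `H_i = −(1/ln n) Σ_j f_ij ln f_ij ∈ [0,1]` (conventional Shannon form),
- `w_i = (1 − H_i)/(m − Σ_i H_i)`, so Σ w_i = 1 algebraically
  (the package asserts it to 1e-12),
- composite score `s_j = Σ_i w_i f_ij`; genes rank by descending score,
  ties broken by ascending gene id.

Some published write-ups of the entropy-weight method print `H_i` without
the leading minus sign, which flips `H` into `[−1, 0]` and inverts which
indicators receive weight.  The package defaults to the conventional form —
it is the one under which discriminating indicators get high weight, the
method's stated purpose — and exposes `sign_convention="as_printed"` for
fidelity comparisons.  Both satisfy Σ w = 1.

The ranking is scale-free per indicator (rescaling a column leaves f, H, w
and all ranks unchanged), so mixing RPKM columns with fold-change columns
needs no unit harmonization.  The composite rule (weighted sum of the f
proportions) is the standard aggregation for this method; alternatives
(weighted sum of min-max-normalized values) would break scale invariance.
Annotation-based exclusion (e.g. dropping "heat shock" genes before reading
a top list) removes matches and re-weights and re-ranks the survivors from
scratch, which is equivalent to ranking the reduced panel directly.

## Coexpression networks

Profiles are log2(RPKM+1) per-timepoint replicate means under one treatment
(five points).  Log scale is the standard choice for expression
correlation; using the five means rather than 15 replicate samples matches
the profile-level question being asked (do two genes track each other over
the time course, not across replicate noise).  The network is bipartite:
every declared TF × structural-gene pair is tested and the edge kept iff
Pearson r ≥ 0.9 or ≤ −0.9.  With n = 5 points the null exceedance
P(|r| ≥ 0.9) under independence is ≈ 0.037 (t with 3 df), so single edges
are weak evidence; the stringent cutoff is retained deliberately, and users
should read edge *patterns* (many concordant TFs on one structural gene),
not single edges.  Constant profiles are skipped and counted.  The
shared-neighbor statistic between two structural genes (or one gene across
two treatments) is Jaccard, |∩|/|∪| of TF-neighbor sets, reading "of all
their connected TF nodes" as the union; an "own-neighbors" variant is
available.  Export formats: edge TSV (width = |r|) and GML.

## GO enrichment

One-sided hypergeometric upper tail `P(X ≥ k)` for k DEG genes carrying a
term, K background genes carrying it, n DEG genes and N background genes,
BH-corrected across all terms tested within one DEG set.  The background is
the annotated pool: genes with ≥ 1 GO assignment intersected with the
experiment's gene universe (matching the convention that only annotatable
genes can be drawn).  No GO-DAG ancestor propagation is applied by default
since no ontology file is a required input; `propagate()` accepts a
child → parents map when one is available.

## Synthetic-data generator

The generator emulates the *statistical* structure the downstream stages
assume; it is the test bed for every recovery claim.

| parameter | default | meaning |
|---|---|---|
| n_genes | 5000 | transcripts (kept small for seconds-scale runs) |
| n_tfs / n_structural | 100 / 10 | TF pool (~2 % of genes) and lignin-pathway structural genes |
| timepoints / replicates | (1,2,4,6,8) / 3 | the factorial design |
| baseline_log2_mean | (5.0, 1.5) | base-2 log-normal over expected counts (median ≈ 32) |
| dispersion φ | 0.05 | single global NB overdispersion, variance = μ + φμ² |
| frac_deg | 0.05 | fraction of genes planted as DEGs |
| planted_log2fc | 3.0 | effect size at perturbed (treatment, timepoint) cells |
| deg_support_distribution | uniform on {2,3,4,5} | perturbed-timepoint count per planted gene |
| planted_baseline_min | 50 | baseline-mean floor for planted DEGs and module members |
| n_coexpression_modules | 3 | planted TF ↔ structural modules |
| module_amplitude / module_profile_sd | 1.5 / 0.1 | latent-profile spread / member noise (log2) |
| frac_go_enriched | 0.6 | planted-term rate among true DEGs (background rate 0.05) |
| library_size_factor_sd | 0.15 | log-normal depth variation across libraries |

Planted DEGs multiply the NB mean by `2^±3` at their perturbed cells, in
LTC with probability 0.7 and HT with 0.45 (at least one), giving the
LTC-heavier DEG counts typical of this design; the control is never
perturbed.  Module members share a latent 5-point log2 profile that is
*standardized to realized sd = module_amplitude* (a raw Gaussian draw can
come out near-flat by chance, which would silently destroy the
by-construction guarantee that module pairs correlate at low noise);
per-gene deviations (sd module_profile_sd) are drawn once per gene and
shared across conditions, as is the profile itself, so modules create
within-treatment correlation without creating treatment-vs-control
differences.  Module members are excluded from DEG planting to keep both
ground truths clean.  Baselines of planted DEGs and module members are
floored at 50 expected counts so planted effects are detectable at the
default depth — the defaults describe a regime of strong, well-measured
effects.  The dispersion and depth defaults are generator choices, not
estimates of any real dataset.

What the generator does **not** emulate: per-gene dispersion variation,
length/GC bias, correlated library effects, batch structure, assembly
artifacts in the counts, annotation noise, weak effect sizes, or a day-0
baseline.  Passing recovery tests therefore demonstrates that the
implementation is correct under its stated model, not that real data of
this kind will yield 100 % sensitivity; on real data the same pipeline
applies, with performance governed by depth, dispersion and effect size.

The contig-summary generator separates artifact contigs (sense/antisense
drawn strictly below 0.095) from genuine ones (ratio ≥ 0.125 by
construction) so the strand filter recovers labels exactly — it is a
fixture for filter correctness, not a model of strand leakage rates.

## Numerical choices

- Dispersion floor 1e-4; log2FC pseudocount 0.5; exact-test tie tolerance
  1e-10 (relative); Σ w tolerance 1e-12; 0·ln 0 := 0 exactly.
- Common library size rounds the geometric mean; rescaled replicate counts
  round to nearest integer.
- Rank ties break by ascending gene id; enrichment rows sort by
  (corrected p, raw p, GO id); all table writers emit sorted,
  deterministic rows so fixed-seed runs are byte-identical.
- Degenerate inputs raise coded errors rather than warn-and-continue:
  empty libraries, zero-length genes, all-zero indicator columns,
  constant correlation profiles (skipped and counted at network level),
  inconsistent contingency counts.
- If every indicator is exactly uniform (m − ΣH = 0) the ranking falls
  back to equal weights with a logged warning.

## Problem sizes

Recovery and error-control checks in the test suite and the acceptance
script run on 2000-gene simulations (the planted run also drives the
network, ranking and enrichment checks); the end-to-end byte-reproducibility
check uses a 400-gene run; the full default (5000 genes, 45 samples)
pipeline completes in ~10 s on one CPU.  These sizes were chosen so the
whole suite runs in well under a minute of simulation time while leaving
hundreds of planted genes per check.

## Known limitations

- The exact test assumes a shared dispersion between the two groups of a
  contrast and conditions on a plug-in pooled mean; it is not an exhaustive
  re-derivation of any specific published implementation.
- Method-of-moments dispersion from 3-replicate cells is noisy per gene;
  no shrinkage is applied.
- With 5-point profiles the network stage cannot attach honest p-values;
  it reports thresholded correlations only.
- The enrichment stage treats GO terms independently (no DAG structure
  unless a parent map is supplied) and tests over-representation only.
- The headline counts of any real experiment depend on the raw reads,
  assembly and annotation stack, which sit outside this package's scope
  (counts in, results out).
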