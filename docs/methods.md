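# Methods

This note documents the models, rules, and conventions behind each stage
of the pipeline, the parameters that matter, what the synthetic data do and
do not emulate, and the numerical choices made where the procedure was
genuinely open.

## Binding calls (peak annotation)

Gene loci and ChIP-seq peaks are half-open, 0-based intervals (BED-native);
1-based TSV input is converted on read. The distance between a peak and a
gene is the edge-to-edge gap: 0 when the intervals intersect or touch,
otherwise the number of bases strictly between them. A TF is *bound* at a
gene when any of its peaks has gap ≤ `window_bp` to the gene body.

* `window_bp` — 50,000 bp by default, applied symmetrically (strand is
  ignored because the upstream and downstream windows are equal). The
  boundary is inclusive: gap = 50,000 counts as bound. Distances anchor on
  gene-body edges, not the TSS, because the binding rule accepts peaks
  anywhere in the transcribed sequence.
* Closest-gene annotation breaks ties by smaller gap, then smaller gene
  start, then lexicographic gene id, so results are order-independent.
* Candidate lookup uses an interval tree per chromosome (queries expanded
  by `window_bp + 1` to keep the inclusive boundary under strict half-open
  overlap); minimum gaps beyond the window come from sorted-edge bisection
  (nearest predecessor end / successor start). Both paths are exact; the
  test suite checks them against an O(n·m) all-pairs scan on 1,000 random
  genomes.
* Peaks on chromosomes absent from the gene set are dropped with a logged
  warning rather than an error, since assembly mismatches in peak files are
  common and non-fatal.

## Differential expression

Contrasts are two-group comparisons of probe-level log2 intensities,
oriented mutant-vs-control (or GFP⁺-vs-GFP⁻ for the lineage sort), so
log2FC = mean(group A) − mean(group B) and a positive value means *up in
the mutant* (or GFP⁺-enriched).

* Statistic: Welch two-sample t-test by default. When either group has
  fewer than 3 arrays (the Tbr2-cKO arm has 2), the test falls back to the
  pooled-variance Student's t with a logged notice; the method used is
  recorded per row. The exact statistic used on the original arrays is not
  recoverable, so this is a declared convention of the package.
* Significance: raw p < alpha (default 0.05), strict inequality. A
  Benjamini–Hochberg column is emitted for reference but never used for
  calls — the calling rule is deliberately the simple per-test threshold.
* Degenerate inputs: when both groups have zero variance (possible in
  noise-free simulations), p is 1 if the means agree and 0 otherwise, so
  planted effects remain decidable without noise.
* Gene aggregation: the minimum-p probe represents the gene (`best_log2fc`,
  `best_p`), ties broken by probe id. A gene is *conflicted* when at least
  two probes are significant with opposite log2FC signs; conflicted genes
  get direction "none" and are disqualified from cell-type calls. Whether
  the original analysis used a single probe or a summarized probeset per
  gene is unknown; minimum-p is the convention here and interacts with the
  conflicted-probe rule, which needs per-probe tests.

## Cell-type classification

A gene's *primary zones* are the zones (VZ, SVZ, IZ, CP, apical→pial) that
are detected (intensity ≥ `detect_floor`) and reach `dominance_frac`
(default 0.5) of the maximum zone intensity — a quantification of
"expressed mainly in", which was originally judged by eye on in situ
panels. The decision table (first match wins): conflicted → `conflicted`;
not significant or nothing detected → `none`; GFP⁻ with exactly {VZ} →
`RGP`, GFP⁻ otherwise → `mixed`; GFP⁺ with {VZ} → `aIP`, {SVZ} → `bIP`,
{VZ,SVZ} → `aIP+bIP`; GFP⁺ profiles touching IZ or CP → a neuron class
named by the earliest primary zone (`N-vz` … `N-cp`), with the `PN-`
prefix when the gene is annotated cortex-specific and the initial zone is
IZ or CP (the vocabulary has no PN-vz/PN-svz). Cortex specificity is an
input flag, not inferred: it depends on expression outside the cortex,
which is outside this data model. The table is total and mutually
exclusive over the whole input lattice (property-tested).

## Gradient calls

The statistic is the Spearman rank correlation of intensity against
rostrocaudal bin index (bin 0 = rostral); ties use average ranks. The
p-value is a two-sided permutation test over bin shuffles: exhaustive
enumeration when n_bins! ≤ `n_perm`, otherwise seeded Monte Carlo with the
add-one estimator (1 + hits)/(n_perm + 1). A direction is called only when
|rho| ≥ `rho_threshold` (default 0.8) *and* p < alpha: positive →
high-caudal, negative → high-rostral. Constant profiles return statistic 0
and direction none without error. Note the permutation test's granularity:
with 5 bins only |rho| = 1 can reach p < 0.05 two-sided, which motivates
the 8-bin default in the generator below. The original gradings were made
by visual inspection; this statistic is the package's declared substitute,
and thresholds are recorded in the output.

## Direct-target and synergy calling

For each (TF, gene) with the TF's mutant profiled: not bound → `not_bound`
regardless of expression; bound with no significant change on any covering
experiment → `bound_no_de`; bound and significant on *either* experiment →
`represses` if the gene is up in the mutant, `activates` if down, taking
the smallest-p experiment as primary evidence. If experiments disagree in
sign, the smaller p wins and a `sign_conflict` flag is raised (the flag
preserves the ambiguity; such cases are not silently resolved). An
exclusion list marks (TF, gene) pairs whose expression change is an
artifact of the mutant design — canonically the conditionally deleted TF's
own transcript — and forces `bound_no_de` with a note.

Synergy for a TF pair requires binding by both TFs, significance in the
double mutant on a covering experiment, and *no* significant change in
either single mutant on any experiment; direction comes from the
double-mutant sign. A gene therefore never carries both a single-TF edge
and a synergy edge. Exactly one mode is emitted per (TF, gene).

## Network and motifs

Qualifying calls become signed edges (synergy expands into two edges
sharing a `synergy_group` id, keeping per-TF tallies well-defined while
the summary reports synergy on its own line). Motifs are defined relative
to a user-declared TF ordering (the developmental order Pax6, Tbr2, Tbr1),
not inferred: feedforward chains are maximal all-positive paths respecting
the order (maximal = not a contiguous subpath of another reported chain),
feedback is any edge from a later TF to an earlier one, autoregulation is
a self-edge. The scan is verified against exhaustive enumeration on all
3-node signed digraphs and random 4–5-node digraphs. Summaries count
activated/repressed/synergistic targets per TF, genes per cell-type label,
gradients per direction, and the union of genes that are
cell-type-specific (label outside {none, conflicted, mixed}), graded, or
regulated. Exports: TSV (lossless round-trip), SIF (sign as the
interaction keyword), GraphML.

## Synthetic data: what is emulated

The generator plants a known truth and emits every input the pipeline
reads, with one `numpy.random.SeedSequence` child per sub-generator so a
fixed master seed gives byte-identical files.

* **Genome**: 5 chromosomes × 50 Mb; gene lengths uniform in 1–100 kb;
  same-chromosome neighbours separated by ≥ 150 kb so a peak planted
  within one gene's window cannot silently enter another's.
* **Peaks**: one peak per planted (TF, gene) binding, placed in the gene
  body or at a uniform gap in [0, 50 kb] and re-sampled until its window
  contains only its target, so binding calls round-trip the truth exactly;
  decoys re-sampled until > 50 kb from every gene.
* **Expression**: log2 intensity = 8.0 baseline + gene offset N(0,1) +
  probe offset N(0,0.25) + planted effect + N(0, `noise_sd`). Defaults:
  2 probes per gene (the minimum that exercises multi-probe aggregation
  and the conflicted rule), effect 0.75 log2 units, noise SD 0.25 — chosen
  once so recovery at the study's replicate counts is high but not
  saturated. Repressed targets gain the effect in every genotype whose
  lesions include the TF (so single-TF targets also shift in the dKO);
  activated targets lose it; synergistic targets shift only in the dKO.
  Lineage-sorted samples add ±0.75 to GFP⁺ arrays according to the planted
  label's enrichment sign; conflicted genes get alternating probe signs.
* **Design**: MA2 carries the study's 3/4/2/3 replicate counts (control,
  Tbr1-KO, Tbr2-cKO, Tbr1/2-dKO); MA1 is the earlier array round, with
  3/3/3 single-mutant counts (not documented for the original arrays;
  fixed here once) plus the Pax6-null dataset, so the either-experiment
  rule degenerates to one experiment for Pax6 exactly as in the study; the
  GFP sort is 4 vs 4. The dKO appears only on MA2.
* **Zonal profiles**: each label's canonical template (e.g. RGP → VZ;
  aIP+bIP → VZ+SVZ; N-iz → IZ+CP) at intensity 1.0 plus N(0, 0.1), clipped
  at 0, detection floor 0.2.
* **Gradient profiles**: 8 bins, total change (`slope`) 2.0 log-intensity
  units over the axis on a base of 2.0, noise SD 0.25; high-rostral
  profiles are the mirrored ramp, ungraded genes are flat.

What the generator does **not** emulate: probe-level cross-hybridization
and intensity-dependent variance of real arrays, read-level ChIP-seq noise
and peak-width structure, spatially correlated in situ backgrounds, and
indirect regulatory effects (every planted expression change is direct).
Passing recovery tests therefore certify the calling rules and their
implementation under the declared noise model, not performance on raw
data.

## Measured operating characteristics

At the default study conditions (20 seeds × 400 genes), the pipeline
recovers planted single-TF edges with sensitivity ≈ 0.95 and precision
≈ 0.94, cell-type labels ≈ 98% and gradient directions ≈ 98%; at zero
noise every planted label and edge is recovered exactly, and no synergy
call is ever significant in a single mutant (`scripts/acceptance.py`
recomputes all of these). Synergy sensitivity is ≈ 0.65–0.70, and this is
a property of the calling rule, not of the implementation: a planted
synergy gene must survive eight independent true-null tests at raw
α = 0.05 (two single mutants × two experiments × two probes under
minimum-p aggregation) *and* be detected in the 3-vs-3 double-mutant
contrast, which caps attainable sensitivity near
0.95⁸ × P(detect) ≈ 0.63–0.68 by noncentral-t power computation. Raising
it would require weakening the rule (multiplicity correction or probeset
averaging), which this package deliberately does not do.

## Known limitations

* The Welch/pooled t-test stands in for the original (uncited-in-detail)
  array statistics; absolute p-values on real data would differ.
* The dominance quantification of "mainly expressed in" and the
  Spearman-permutation gradient test are declared substitutes for visual
  ISH scoring; their thresholds (`dominance_frac` 0.5, `rho_threshold`
  0.8) are conventions, recorded in outputs, not biological constants.
* Gene-level aggregation by minimum-p probe inflates per-gene false
  positives roughly in proportion to probes per gene; precision figures
  are reported under the 2-probe default.
* The exclusion list must be supplied by the analyst; only the
  conditionally deleted TF's own transcript is excluded by default in the
  worked example.
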