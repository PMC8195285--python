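# Methods

This note documents the statistical procedures implemented in `tuftseq`,
the synthetic data they are exercised on, and the design decisions taken
where the underlying workflow left details open.

## Setting

Bulk RNA-seq of a FACS-enriched rare cell population (intestinal tuft
cells) contains reads from co-sorted contaminating cell types. The
pipeline uses a labelled single-cell reference of the surrounding tissue
(intestinal epithelium) to (i) estimate how much of each bulk sample is
target-derived, (ii) remove contaminating read contributions gene by
gene, and (iii) carry the purified matrix through differential
expression between two diet groups at two time points, gene-set and
orphan-gene annotation, and correlation networks against organism-level
phenotypes.

## Reference summaries

For every cell type `c` and gene `g` the reference yields the mean reads
per cell `μ_{c,g}` and the prevalence `π_{c,g}`: the fraction of cells of
type `c` with at least 3 reads of `g`. Prevalence at a 3-read floor is
deliberately insensitive to per-cell depth. Genes are partitioned as

* **non-target** — `π ≥ 0.2` in at least one non-target type and
  `π < 0.2` in the target (strict): contamination-only, removed;
* **target-only** — prevalent only in the target: passed through;
* **shared** — everything else, *including genes below threshold in every
  type*. The last choice is conservative: a gene with no prevalence
  evidence anywhere stays subject to decontamination rather than being
  silently trusted.

Marker sets are genes prevalent in exactly one type; they drive both
deconvolution and the removal of non-target markers.

**Mode and read-count cutoffs.** The pooled log10(count + 1) distribution
of the target type's *nonzero* gene–cell counts is summarized by the
argmax of a Gaussian KDE (Silverman bandwidth, 512-point grid) and by
one-sided counting quantiles: the lower cutoff is the largest observed
value L such that at least 95% of the observations at or below the mode
are ≥ L; the upper cutoff is symmetric above. Zeros are excluded from the
pooled sample because dropout pins the mode at 0 and degenerates both
cutoffs; whether the source distribution is per-gene, per-cell or pooled
was an open choice, and pooled-over-nonzero-counts is the reading
adopted here. The counting construction guarantees the contained
one-sided mass lies in [mass, mass + 1/n] by definition.

## Deconvolution and decontamination

Per-sample cell-type proportions solve a non-negative least squares of
the bulk CPM vector on the CPM-scaled type signatures over the union of
marker genes, renormalized to the simplex. NNLS is deterministic,
dependency-light, and a transparent stand-in for SVR-based deconvolution
methods; on negative-binomial mixtures of eight types it recovers the
target proportion with MAE below 0.01 (see `scripts/acceptance.py`).

The expected target share of gene `g` in sample `s` is

    share_{g,s} = p_t f_{t,g} / Σ_c p_c f_{c,g}

on depth-normalized profiles `f` (zero when the denominator vanishes:
the gene is unattributable to the target). The sample's target-read
fraction `f_s` is the share-weighted fraction of reads over genes
measured above the lower read-count cutoff; genes below it are too
weakly measured to apportion. Shared genes are corrected as

    corrected = raw × share × f_s / f̄,   clamped to ≤ raw,

where `f̄` is the cohort mean, so samples of poorer purity receive a
stronger correction. The exact mathematical role of the target-read
fraction as an "additional weight" was not fixed by the workflow this
implements; the multiplicative, cohort-centred, contraction-clamped form
above is this package's documented choice. Corrected counts never exceed
raw counts by construction.

## Gene-matrix cleanup

Three ordered steps: remove genes with zero reads everywhere; for each
duplicated symbol keep the row with the highest total count (ties: first
occurrence); keep genes with strictly more than 5 reads in at least 6
samples. "More than five" is read literally (a gene with exactly 5 reads
everywhere is removed). Duplicates are resolved before the expression
filter so totals are compared on full data. The `FilterReport` identity
`retained = input − unexpressed − duplicates − low-expression` is
validated on every run.

## Differential expression

The two-class test follows the SAM-seq recipe, re-implemented:

1. **Depth standardization** — each sample's counts are Poisson-resampled
   with mean `count × min(lib)/lib_s`, 20 independent resamples, so all
   samples are compared at the shallowest depth.
2. **Statistic** — per gene and resample, the standardized Wilcoxon
   rank-sum `(W − E[W]) / SD[W]` with average ranks and the tie-corrected
   permutation variance
   `Var = n_A n_B/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`,
   averaged over resamples. This closed form equals the exact enumeration
   over all group assignments (verified exhaustively for n ≤ 8).
3. **FDR** — for each threshold t (every observed |statistic|),
   `FDR(t) = median_perms #{permuted |stat| ≥ t} / #{observed |stat| ≥ t}`,
   clipped to [0, 1]; a step-up pass (running minimum from the least
   significant threshold) makes q monotone non-increasing in |t|.
   Permutations are complete group-label reshufflings; when fewer than
   200 distinct assignments exist they are enumerated exactly once, and
   below 20 the test refuses to run.
4. **Calls** — fold change is pseudo-counted mean CPM,
   `(CPM̄_num + 1)/(CPM̄_den + 1)`; a gene is up iff q < 0.05 and FC > 2,
   down iff q < 0.05 and FC < 0.5, all inequalities strict.

The pipeline runs DE per time point on the decontaminated matrix by
default (a `skip_decontamination` toggle bypasses purification), and
reports genes significant at both time points with a concordance flag.

## Gene sets and orphans

Pathway-level scoring aggregates gene-level statistics: a set's score is
the mean member statistic, its two-sided p-value the add-one rank of its
magnitude among 1000 size-matched random sets drawn from the measured
universe, and q-values are Benjamini–Hochberg across sets (direction from
the score's sign when q < 0.05). This competitive mean-statistic test is
a deliberate, simple stand-in: the originating workflow names its tool
but not its gene-set algorithm. Sets with fewer than 3 measured members
are skipped with a logged reason. DE genes in no loaded set are orphans;
they are flagged by exact membership of GO:0008152 (metabolic process)
and GO:0002376 (immune system process) in a precomputed two-column gene→
GO map — no ontology traversal is performed, so the map must already
contain ancestor closure.

## Correlations and networks

All-pairs Spearman correlations use pairwise-complete observations (≥ 5
required per pair), average ranks for ties, two-sided p-values from the
t-distribution approximation, and BH q-values over all pairs tested in
the batch; zero-variance variables are reported missing. Two regimes
mirror the two uses: the screen flags p < 0.05 ∧ q < 0.1 with
significance stars by p-value decade, the integration network keeps
|SCC| > 0.7 ∧ q < 0.05 (strict) and is exported as SIF and an
edge-attribute TSV. qPCR support computes ΔCt = Ct_target − Ct_reference
and relative expression 2^(−ΔCt).

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the study conditions:

* **Reference** — 8 intestinal epithelial types, 2,000 genes, 50
  cells/type; each type owns a disjoint 5% marker block expressed ~50×
  above its background elsewhere; other genes are expressed in random
  subsets of ≥ 2 types around lognormal base abundances; counts are
  negative binomial (dispersion 0.3 per cell).
* **Bulk cohort** — 2 diets × 2 time points × 6 replicates; per-sample
  target purity uniform on (0.6, 0.9); contaminant proportions uniform on
  the simplex over the 7 non-target types; library sizes log-uniform over
  a 2× range (5×10⁵–10⁶) to exercise depth standardization; counts
  negative binomial with dispersion 0.1 around
  `lib × Σ_c p_c × profile_c`.
* **Planted effects** — multiplicative 4-fold (log2 effect 2) changes on
  the HFD target profile only, random sign, half shared between time
  points; the modified profile is renormalized, so planting is
  compositional like real RNA-seq. Effects are planted only on genes with
  target mean ≥ 5 reads/cell: genes below the single-cell detection floor
  are removed by decontamination as unattributable, and planting there
  would measure the labelling rule rather than DE recovery.
* **Phenotypes** — a 12-variable panel (body mass, fat-to-lean ratio,
  tissue masses, immune-cell percentages, cytokines, glucose, tuft-cell
  density); linked phenotypes are affine transforms of a transcript's
  per-sample CPM rank plus Gaussian noise on the unit rank scale, so
  `noise_sd = 0` gives Spearman correlation exactly ±1.

Not emulated: read-level artifacts (mapping, duplicates), cage or batch
effects, repeated measures within animals, dropout structure beyond the
NB noise, and biologically correlated (rather than planted) gene
modules. Passing tests therefore show the *procedures* behave as
specified under a faithful generative model of the data's structure, not
that any biological conclusion transfers.

## Fixture sizes and numerical choices

Recovery experiments run at 2,000 genes × 24 samples (deconvolution,
decontamination, DE power/null at 10 replicates), a scale at which every
property is measurable in seconds. The decontamination-benefit fixture
uses 30% contamination with NB dispersion 0.01: at dispersion 0.1 the
corrected counts already sit at the counting-noise floor (CV ≈ 0.32),
so the benefit measurement would be noise-limited rather than
bias-limited; the low-noise fixture isolates the contamination bias the
procedure exists to remove. Degenerate inputs are handled explicitly:
zero-variance genes give statistic 0, zero denominators give share 0,
all-identical count distributions give mode = lower = upper, and
fold-change pseudo-counts floor 0/0 at 1.

## Known limitations

* NNLS deconvolution assumes the reference profiles span the bulk
  mixture; unmodelled cell types bias the proportions.
* The `f_s/f̄` weighting is a package-level interpretation; other
  readings (e.g. no cohort centring) would change corrected counts by a
  per-sample scalar.
* The permutation FDR is granular at small cohort sizes (≥ 20 distinct
  label assignments required) and, like SAM, can assign q = 0 to the top
  gene under a complete null in a minority of datasets.
* The gene-set test is competitive and directional; mixed up/down sets
  cancel toward a null score.
* BH q-values assume the PRDS-type dependence conditions under which the
  step-up procedure is valid; correlated transcripts can make them
  conservative or anti-conservative in edge cases.
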