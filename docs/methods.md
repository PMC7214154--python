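# Methods

This note documents the models, conventions and numerical choices behind
`mirpoc`, and what the synthetic-data generator does and does not emulate.

## Study design being modelled

Four experimental arms — Sham, ischaemia/reperfusion (I/R), ischaemic
pre-conditioning (IPC) and ischaemic post-conditioning (IPoC) — of
`n_per_arm = 20` rats each. Plasma troponin I (TnI, ng/mL) 60 minutes into
reperfusion serves as the infarct-size surrogate; the IPoC arm is bimodal,
splitting into responders (TnI near the IPC arm) and non-responders (TnI
near the I/R arm). Left-ventricular miRNA expression is observed as a
count matrix (miRs × animals); mRNA panels are observed as qPCR Ct values.

## Responder stratification

The study that motivates this package defines no numeric TnI cut, only the
observed bimodality, so both stratification methods here are declared
conventions rather than reconstructions:

- **mixture** (default): two-component Gaussian mixture on log TnI with
  free component variances, EM initialized deterministically at the
  25th/75th percentiles of the arm (no random restarts, so results are
  reproducible and scale-equivariant). The lower-mean component is the
  responder class; assignment is by posterior ≥ 0.5, with the tie assigned
  responder. If the fitted component means are closer than
  `min_separation = 0.5` pooled component standard deviations, or EM does
  not converge, the fit is declared degenerate and the threshold rule is
  applied with a flag. The guard catches collapsed/near-constant arms; it
  does not prevent a clearly unimodal arm from being split when the
  mixture finds two well-separated narrow components — the posterior and
  the flag are reported so the caller can judge.
- **threshold**: responder iff log TnI is below the midpoint of the median
  log TnI of the IPC and I/R reference arms (the geometric midpoint on the
  original scale). With reference medians 1 and 100 ng/mL the cut is
  10 ng/mL.

Group summaries report mean, sample SD (ddof = 1; a group of one reports
SD as NaN, never 0) and n for every numeric field. `relative_change`
reports 100·(treated − baseline)/baseline at one decimal; the package's
canonical example is cell shortening rising from 10.30% to 11.16% of
diastolic cell length, an 8.3% increase.

## Differential expression

A deliberately simplified negative-binomial Wald fit for pairwise
contrasts, adequate for raw-p screens on small groups; no Cook's-distance
outlier handling, independent filtering, multi-factor designs or
time-course models.

1. **Normalization** — median-of-ratios: the reference is the per-feature
   geometric mean over samples (features with any zero excluded); the
   size factor of a sample is the median of its count/reference ratios.
   If no feature is nonzero everywhere this is an error (a
   pseudo-reference is suggested, not silently applied).
2. **Dispersion** — per-feature method of moments on normalized counts,
   α̂ = max(0, (s² − μ)/μ²), pooled within groups (df-weighted) so real
   group differences do not inflate it, then shrunk with weight 0.3
   toward the mean dispersion of the feature's log10-mean decile and
   floored at 1e-8. The shrinkage weight stabilizes small groups (the
   motivating study sequenced 4–5 animals per group).
3. **Wald contrast** — for a two-group NB GLM with log link and known α,
   the group-mean MLE is the sample mean of normalized counts and the
   Fisher information gives Var(log μ̂) = (1 + αμ)/(nμ). The statistic is
   log2FC over its SE against a standard normal, two-sided. When either
   group mean is zero a pseudo-count of 0.5 is added to *both* means (and
   flagged), which keeps the estimate finite and preserves antisymmetry
   under swapping treated and reference. The closed form is verified in
   the tests against an independent IRLS NB GLM fit.

Calibration measured by the test suite at n = 20/group, dispersion 0.1:
null rejection ≈ 0.05–0.06 at p ≤ 0.05, planted unit log2FC recovered to
within ±0.1 on the 10-seed mean. Note that median-of-ratios absorbs part
of a globally one-sided effect: if most planted changes share one
direction the estimated fold changes attenuate (~0.09 log2 with 50 all-up
features of 600); recovery experiments therefore plant balanced up/down
effects.

BH adjustment is delegated to statsmodels and property-tested against the
step-up definition. Raw p drives the screens that mimic the motivating
analysis; adjusted p is always emitted.

**Two-sample cascade** (alpha = 0.05 throughout): Shapiro-Wilk on both
samples; both normal → Levene; equal variances → Student t (paired or
unpaired), unequal → Welch; any non-normal → Mann-Whitney (unpaired) or
Wilcoxon signed-rank (paired). The decision path is recorded. For ≥ 3
groups: one-way ANOVA gated Student-Newman-Keuls — ranges tested from
widest to narrowest on ordered means with studentized-range critical
values (span = number of means covered, error df from pooled
within-group variance, pairwise harmonic n for unequal sizes); a
non-significant range protects all its sub-ranges.

**qPCR** uses the delta-delta-Ct convention: ΔCt = Ct_target −
Ct_housekeeping per sample, ΔΔCt = group-mean difference vs the reference
group, fold = 2^(−ΔΔCt). The exact quantification of the original assay
is not reproduced; ΔΔCt is a declared stand-in.

## Regulation calls and the protective pattern

Calls: up iff p ≤ alpha and log2FC > lfc_min; down iff p ≤ alpha and
log2FC < −lfc_min; else unchanged (lfc_min defaults to 0; boundary
p = alpha is called; a significant feature with log2FC exactly 0 is
unchanged, since a direction-based rule gains nothing from directionless
significance).

A miR is *protective-pattern* selected iff (i) regulated by I/R vs Sham,
(ii) its IPoC-R vs I/R change is opposite to the I/R change, (iii) its
IPC vs I/R change is also opposite — required by default, switchable off
for the looser reading in which the responder reversal alone carries the
conditioned-arm requirement — and (iv) its IPoC-NR vs I/R change is *not*
opposite. "Not opposite" deliberately includes a significant
same-direction (further enhanced) change: both unchanged and enhanced
non-responder behaviour are non-protective. Both clause-(iii) modes are
exercised in the tests against an exhaustive 3⁴-combination oracle.

mRNA partition categories over the three "significant vs I/R" flags
(IPC, IPoC-R, IPoC-NR): ALL3, R_AND_NR, R_AND_IPC, R_ONLY, NR_ONLY,
IPC_ONLY, NONE, and OTHER (IPC ∧ NR without R) — mutually exclusive and
exhaustive. Applied to the transcribed significance markers of the
published mRNA panel this reproduces the printed block sizes 3 / 3 / 7;
the printed responder-only block is internally inconsistent in its source
(header n = 21, prose 23, marker count 22), so the package reports
computed counts and does not reconcile the discrepancy.

## Signed network and node strength

Thresholds are strict at the printed values: score-based predictions kept
iff score > 80.0, mirSVR-style kept iff score < −1.2, validated records
kept unconditionally. Duplicate (miR, target) pairs collapse to one edge
with the '+'-joined union of sources, so database redundancy cannot
inflate strength.

The weight convention is fixed as weight = −1 for an edge from an
up-regulated miR and +1 from a down-regulated one ("repression"
convention): node strength — the sum of incident weights — then predicts
the direction of the target's expression change under miR-mediated
repression. The opposite ("literal") mapping is available as a switch;
it flips every strength's sign and leaves the |strength| ranking
unchanged. Ranking is by |strength| descending, then strength descending,
then target id — fully deterministic. Exports: round-trip-safe edge-list
TSV, SIF (relation `pos`/`neg` encodes the weight sign) and GraphML.
Graph layout/visualization is out of scope.

## Mitochondrial filter

Identifier reconciliation follows a fixed cascade — Ensembl id, RGD id,
NCBI id, case-insensitive symbol, exact description — first hit wins.
Symbols shared by two or more annotation rows are excluded as ambiguous
rather than arbitrarily resolved (silent mis-mapping would corrupt the
subnetwork); description matching is exact-string, since descriptions do
not tolerate fuzz without inviting false matches. The annotation is
restricted to IMPI classes {known, predicted} before matching. A matched
target is mitochondrial iff its GO flag is set or its IMPI score is
strictly above 0.7. The subnetwork is induced by the kept targets plus
every miR with at least one edge to them; strengths are recomputed on the
subgraph.

## Synthetic-data generator

All generators draw from counter-keyed substreams
(`SeedSequence(seed, spawn_key=(k,))`) of one global seed, so outputs are
byte-reproducible and adding a generator never perturbs existing ones.
Counts of planted effects are *assigned* from the config, never sampled;
only their placement is random.

- **TnI**: log-normal per group; Sham 0.2, I/R 50, IPC 5 ng/mL locations,
  the IPoC arm a two-component mixture with the responder component at the
  IPC location and the non-responder component at the I/R location
  (10-fold apart). The log-spread 0.25 is a design property chosen so the
  planted mixture is cleanly separable (labels recoverable by any
  inter-component threshold) — tighter than a real TnI assay's biological
  spread, which means passing recovery tests demonstrates correctness of
  the stratification machinery, not its power on marginal real data.
  Echo/morphology fields are drawn per group around realistic means;
  LVESD is derived from LVEDD and FS so their consistency constraint holds
  by construction.
- **miR counts**: 627 features, NB noise with dispersion 0.1,
  per-sample library-size factors log-uniform on 0.5–2×, baseline means
  log-uniform on 10–1000. 286 planted differentially expressed: 82 up and
  77 down after I/R with |log2FC| uniform on 1–3, the remaining 127
  regulated in IPoC-R only (mirroring conditioning-only regulation).
  Conditioning arms revert a per-arm fraction of the I/R-regulated
  features to the Sham level: IPC 0.5, IPoC-R 0.28 (28% of up-miRs were
  modified in responders in the motivating study), IPoC-NR 0.05, plus a
  5% minority pushed *further* in the injury direction in non-responders.
  The truth table records per-contrast fold changes, reversal flags and
  the protective-pattern flag under both clause-(iii) modes.
- **qPCR**: Ct = housekeeping Ct + gene offset − log2(fold) + N(0, 0.15),
  so ΔΔCt recovery of the planted folds is unbiased; the default fold
  table emulates calcium-handling/remodelling magnitudes including one
  ~9.7-fold induction in responders. 5 samples per group.
- **Interactions**: three tables in the three source dialects with scores
  straddling the thresholds (uniform 0–100 and −2.5–0), vocabularies
  overlapping the simulated miRs/genes plus novel names, and mild
  rank-skew on target sampling to create hub targets.
- **Annotation**: per-gene identifiers in five columns, IMPI score, GO
  flag and class, constructed so that planted mitochondrial genes satisfy
  the keep-predicate and non-mitochondrial genes never do. An
  `alias_rate` fraction of rows is mutated through a deterministic cycle
  (drop Ensembl; drop to NCBI; symbol upper-cased with upstream ids
  blanked; description-only) to force the reconciliation cascade.

Not emulated: read-level sequencing artefacts (the pipeline starts at the
count matrix), echo time series, assay nonlinearity, correlated miRs, and
any real database content — real interaction/annotation releases are
bring-your-own-file inputs with the same column contracts.

## Pipeline and reproducibility

One YAML config drives stratify → DE (4 contrasts) → calls → protective
filter → network → mitochondrial subnetwork. Every output table carries a
comment line with the SHA-256-derived config hash; the manifest records
seed, config, per-stage input/output counts and thresholds. Re-running
the same config reproduces outputs (integer/graph stages exactly;
floating-point tables to writer precision). Any stage failure aborts with
the stage name. Exit codes: 0 ok, 1 user error, 2 internal.

The repository exposes the two genuinely model-like stages in a
model/results idiom (`TroponinMixture(...).fit()` and
`DifferentialExpression(...).fit()` returning results objects with
`summary()`); transform stages are plain functions behind stable module
surfaces.

## Problem sizes used in tests and the acceptance script

Recovery experiments use 600 features × 40 samples × 10 seeds (unit
log2FC), 2000 features × 3 seeds (null calibration) and 100 seeds of the
80-animal TnI study (label recovery); oracle suites use 200 random
bipartite graphs up to 50×50 and the exhaustive 81 direction
combinations. These sizes give stable averages for the properties being
checked while keeping the whole suite fast on a single CPU.

## Known limitations

- The NB Wald test relies on asymptotic normality; at very low counts or
  n ≤ 5 it is only a screen, like the raw-p usage it mirrors.
- Median-of-ratios assumes most features unchanged; strongly one-sided
  global regulation attenuates fold changes (quantified above).
- The mixture stratifier assumes exactly two log-normal components; the
  degeneracy guard is a heuristic, not a model-selection procedure.
- Symbol-level identifier matching is case-insensitive but not
  alias-table-aware; genes reachable only through description text with
  different wording stay unmatched by design.
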