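# mirpoc

Responder/non-responder analysis of ischaemic post-conditioning (IPoC) in
the rat heart, as a reusable, tested pipeline: troponin-based responder
stratification, miRNA differential expression from count matrices, the
protective-pattern filter, signed miR–target network construction with
node-strength scoring, and extraction of the mitochondria-related
subnetwork. A first-class synthetic-study generator with planted ground
truth makes every stage testable without any external download.

## The scientific problem

Brief cycles of reperfusion/re-occlusion at the end of an index ischaemia
(IPoC) protect some hearts and not others. With plasma cardiac troponin I
(TnI, a surrogate for infarct size) measured 60 min into reperfusion, a
post-conditioned arm splits into *responders* (TnI near the
pre-conditioned arm, IPoC-R) and *non-responders* (TnI indistinguishable
from untreated ischaemia/reperfusion, IPoC-NR). The question downstream is
which microRNAs show a *protective expression pattern* — changed by I/R
and reversed by the interventions that actually protected — and which
mitochondrial target genes those miRs converge on.

## Models and statistics at the core

- **Stratification.** A two-component Gaussian mixture on log TnI,
  deterministically initialized at the 25th/75th percentiles, assignment
  by posterior ≥ 0.5 (lower-mean component = responder), with a degeneracy
  guard (|Δμ| < 0.5 pooled component SD ⇒ fall back to the geometric
  midpoint of the IPC and I/R reference medians).
- **Differential expression.** Median-of-ratios size factors; per-feature
  method-of-moments NB dispersion α̂ = max(0, (s² − μ)/μ²) pooled within
  groups and shrunk toward a binned-trend; a two-group negative-binomial
  Wald test. For a saturated two-group design with known α the MLE group
  mean is the mean of normalized counts and Var(log μ̂) = (1 + αμ)/(nμ),
  so log2FC = log2(μ̂_t/μ̂_r) and z = log2FC/SE against N(0,1).
  Benjamini-Hochberg adjusted p-values are emitted alongside raw p.
- **Protective-pattern filter.** A miR is selected iff it is regulated by
  I/R vs Sham, its IPoC-R vs I/R change is opposite, the IPC change is
  opposite (optional clause), and the IPoC-NR change is *not* opposite
  (unchanged or further enhanced both count as non-protective).
- **Signed network.** Interactions merged from validated tables
  (kept unconditionally), score-based predictions (kept iff score > 80.0)
  and mirSVR-style predictions (kept iff score < −1.2); one edge per
  (miR, target) pair. Edge weight −1 from an up-regulated miR, +1 from a
  down-regulated one (repression convention), and node strength of a
  target is the sum of its incident weights — the predicted direction of
  its expression change.
- **Mitochondrial filter.** Target identifiers reconciled against an
  IMPI-style annotation through a fixed cascade (Ensembl → RGD → NCBI id →
  case-insensitive symbol → exact description); a target is mitochondrial
  iff matched and (GO mitochondrial flag or IMPI score > 0.7).

## Worked example

```bash
mirpoc simulate --seed 1 --outdir inputs
cat > config.yaml <<'YAML'
counts: inputs/counts.tsv
samples: inputs/samples.csv
interactions:
  - [inputs/interactions_validated.tsv, validated]
  - [inputs/interactions_score.tsv, predicted_score]
  - [inputs/interactions_mirsvr.tsv, predicted_mirsvr]
annotation: inputs/mito_annotation.tsv
outdir: run
seed: 1
YAML
mirpoc run --config config.yaml
mirpoc report run --top-k 5
```

prints (output of this exact command sequence):

```
Post-conditioning responder pipeline — run summary

Stratification (mixture): 8 responders, 12 non-responders of 20 post-conditioned animals
Differential expression: 627 miRs read; per-contrast hits: {'IPC_vs_IR': 107, 'IPoCNR_vs_IR': 50, 'IPoCR_vs_IR': 208, 'IR_vs_Sham': 186}
  350 miRs differentially expressed in any contrast; 87 up after I/R (24.9%), 99 down after I/R (28.3%)
Protective-pattern filter: 20 of 627 miRs selected (alpha=0.05)
Network: kept 3534/7500 interactions (score > 80.0, mirSVR < -1.2); 20 miRs, 78 targets, 99 edges
Mitochondrial filter: 19/78 targets kept (GO flag or IMPI > 0.7); subnetwork: 17 miRs, 22 edges

Top mitochondrial targets by |strength| (top 5):
  Gene0062: strength -2 (degree 2)
  Gene0014: strength 1 (degree 1)
  Gene0025: strength 1 (degree 1)
  Gene0052: strength 1 (degree 1)
  Gene0060: strength 1 (degree 1)
```

Reading the numbers: the synthetic IPoC arm planted 8 responders and the
mixture recovered all of them; 627 miRs were generated with 286 planted
differentially expressed, and the raw-p screen finds 350 across the four
contrasts (planted effects plus the expected false positives); 20 miRs
satisfy the protective pattern; their filtered interactions give a
78-target network whose mitochondrial slice ranks `Gene0062` first with
strength −2, i.e. two up-regulated protective miRs both predict its
down-regulation.

The same objects are available as a library: `SimulationConfig`/
`write_study`, `TroponinMixture(...).fit()`, `DifferentialExpression(
counts, groups).fit(contrasts)`, `protective_mir_filter`, `build_network`
/ `node_strength`, `reconcile_ids` / `mito_select` / `extract_subnetwork`,
and `run_pipeline(PipelineConfig(...))`.

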