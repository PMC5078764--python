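# Methods

## Model

The scorer treats miRNA–disease association prediction as a
network-consistency problem on three inputs: a binary association matrix
`AS` (n_m miRNAs × n_d diseases), a miRNA functional similarity matrix
`MM`, a disease semantic similarity matrix `DD`, and optionally a binary
same-family indicator `FAM` over miRNAs. All similarities are unitless
values in [0, 1]; `MM` and `DD` are consumed as precomputed inputs
(typically derived from disease-ontology structure), never recomputed
here.

Two internal similarity signals are derived from `AS` itself: the
Jaccard similarity of association profiles between miRNA pairs (`NCM`)
and between disease pairs (`NCD`),

    NCM(i,j) = D11 / (D11 + D10 + D01 + ε)

where D11 counts diseases associated with both miRNAs and D10/D01 the
one-sided ones; joint absences are ignored. The integrated networks are
weighted arithmetic means of the enabled components,

    SM = (w_mm·MM + w_ncm·NCM + w_fam·FAM) / (w_mm + w_ncm + w_fam)
    SD = (w_dd·DD + w_ncd·NCD) / (w_dd + w_ncd)

with all weights 1 by default. The mean is the simplest combiner that is
monotone in every component and strictly rewards same-family pairs, and
it makes each ablation (drop `NCM`/`NCD`, drop `FAM`) an exact special
case of the same formula. The rule is deliberately isolated behind
`IntegrationConfig`: substituting, e.g., a replace-by-max rule when
`FAM(i,j)=1` is a local change. Averaging a `FAM` zero into cross-family
pairs is likewise a choice; setting `weight_fam` asymmetrically or
disabling the component recovers the alternatives.

Zeros of `AS` are replaced by ε before projection, so every row and
column has strictly positive Euclidean norm. The scores are scalar
projections

    ncp_m(i,j) = ⟨SM_i, AS_·j⟩ / |AS_·j|
    ncp_d(i,j) = ⟨SD_·j, AS_i·⟩ / |AS_i·|
    ncp(i,j)   = (ncp_m + ncp_d) / (|SM_i| + |SD_j|)

For nonnegative vectors each scalar projection is bounded by the
projected vector's length (Cauchy–Schwarz), so `ncp ∈ [0, 1]`; the
single-space variants are exactly cosine similarities. No further
normalization is applied, and the scores carry no probabilistic
calibration — only their ranks are meaningful.

### Assumptions

- Functionally similar miRNAs associate with semantically similar
  diseases (the homophily assumption the projection exploits).
- `MM` and `DD` are informative and on a comparable [0, 1] scale to the
  Jaccard and family components; no per-component rescaling is done.
- An unobserved pair is unknown, not negative; ε substitution encodes
  exactly this ("absence of evidence") and is what allows scoring a
  disease with no known associations.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `epsilon` | 1e-30 | unitless smoothing constant in Jaccard denominators and the `AS` zero substitution; any value ≪ 1 gives indistinguishable scores (the suite asserts ≤1e-9 cell drift between 1e-30 and 1e-20) |
| `use_sn` / `use_family` | on | component switches; turning both off reduces scoring to cosine between the external similarities and `AS` |
| `weight_*` | 1 | nonnegative component weights of the integration means |
| `mode` | combined | `combined`, `mirna_only` or `disease_only` projection |

## Conventions and numerical choices

- Norms are Euclidean everywhere; the cosine identity for single-space
  scoring holds only under the Euclidean inner product.
- `NCM`/`NCD` diagonals follow the same Jaccard formula (≈1 for entities
  with at least one association, 0 otherwise); `SM`/`SD` diagonals are
  whatever the mean yields and are *not* forced to 1, since projections
  consume full rows including the self term.
- Jaccard similarities are always computed on the binary `AS` of the
  current training fold, never on the ε-substituted matrix; ε
  substitution is re-applied per scoring call, which under LOOCV means
  per fold.
- Similarity inputs are repaired only within floating-point round-off
  (asymmetry or range violations ≤ 1e-8, symmetrized by averaging /
  clamped); anything larger is rejected with the offending labels named.
- Ranking ties break by descending score, then lexicographic
  (disease, miRNA); LOOCV fold order is lexicographic by
  (disease label, miRNA label). Results are order-invariant; outputs and
  logs are deterministic.
- Label matching is exact after whitespace trimming, with no case
  folding: reconciling source-database spelling variants of miRNA names
  (and consolidating records of miRNA copies) is deliberately left to
  the user, since no universal rule exists.

## Evaluation protocol

LOOCV removes each known association in turn and recomputes *all*
derived quantities (`NCM`, `NCD`, `SM`, `SD`, scores) on the reduced
matrix — a disease whose only association is held out is scored through
the ε pathway, not skipped. The held-out pair's score is a positive;
negatives are all pairs unknown in the full data. Two negative-pool
conventions are provided:

- **per-fold (default):** negatives re-scored under each fold's model
  and pooled across folds — the faithful reading of "train on the
  remaining associations". Note its positive prevalence is
  ~1/(1+n_neg), which makes AUPR values much smaller than under a
  single-model pool; this is a property of the pooling, not a bug.
- **shared (`shared_negatives=True`):** negatives scored once under the
  full-data model — a labeled approximation, faster by a factor ~n_neg
  in memory traffic and with conventional AUPR prevalence.

ROC groups tied scores into one threshold step, making the trapezoidal
AUC equal the rank-sum estimator P(pos>neg) + 0.5·P(pos=neg); the PR
curve is anchored at recall 0 with the first group's precision. Both
identities are exploited as independent test oracles (plus
`sklearn.metrics.roc_auc_score` as a second, external cross-check).

The five ablation tags are: `full`, `no_family`, `no_sn`,
`mirna_space`, `disease_space`, with identical fold order.
Isolated-disease evaluation blinds the target's entire association
column *before* any similarity computation (total cold start) and
reports the average-rank percentile of the hidden true miRNAs, where
percentile (rank−0.5)/n has expectation 0.5 under random ranking.

## Synthetic data

The generator plants block structure: entities are assigned round-robin
to `n_blocks` blocks; similarities are `sim_in` within blocks and
`sim_out` across, plus clamped Gaussian noise (clamping to [0,1] rather
than resampling — the slight boundary bias is irrelevant to ranking);
associations are Bernoulli(`p_in`) on block-matched pairs and
Bernoulli(`p_out`) otherwise; a `family_frac` fraction of each miRNA
block (default 0.5 — enough for the family signal to matter without
making it redundant with the block similarity) shares one family. Each
matrix draws from its own seed-derived substream, so toggling family
generation does not shift the association draws. Degenerate draws
(isolated diseases, association-free miRNAs) are kept intentionally.

Default conditions are 100 miRNAs × 50 diseases, 5 blocks, `p_in=0.3`,
`p_out=0.01`, `sim_in=0.6`, `sim_out=0.2`, `sim_noise=0.1` (~340
associations per draw). The `benchmark_like_params` preset (99×51,
3 blocks, `p_in=0.115`, `p_out=0.01`) reproduces the degree regime of
small curated association collections (~2.3 associations per miRNA,
~4.5 per disease, ~227 expected links). Two further presets pin the
extremes: `separable_params` (all in/out contrasts maximal and
noise-free; LOOCV AUC is exactly 1 and every held-out pair ranks first)
and `null_params` (contrasts equal, i.e. constant similarity 0.5 and
i.i.d. Bernoulli links; LOOCV AUC calibrates to 0.5). Equal-contrast
settings are the reason the generator accepts `p_in == p_out` rather
than requiring strict inequality.

What the generator does *not* emulate: ontology-derived similarity
geometry (transitivity patterns of MeSH/DAG-based measures), realistic
degree heterogeneity (hub miRNAs), family structure that cuts across
functional blocks, and annotation biases of curated databases. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of homophilous structure — not expected performance on
any real curated dataset.

## Problem sizes used in checks

The automated checks run LOOCV at the default 100×50 generator scale
(5 seeds for signal recovery and isolated-disease recovery, 10 smaller
50×25 null draws for calibration), exact-recovery runs at 30×15, and
oracle comparisons on random instances up to 20×15. The signal-recovery
floor (mean full-model AUC ≥ 0.85 over the fixed seed set) was frozen
from a single pilot run at these conditions (pilot mean 0.861) and is
not tuned thereafter.

## Limitations

- Transductive only: entities unseen at fit time cannot be scored.
- The integration mean assumes components on comparable scales; a
  heavily skewed `MM` would implicitly down-weight the other signals.
- Per-fold LOOCV is O(n_assoc) full rescoring passes; fine at these
  scales (hundreds of folds in seconds), but quadratic-ish growth makes
  very large association sets a candidate for the shared-negative
  approximation.
- AUPR depends strongly on the negative-pool convention (see above);
  compare AUPRs only within one convention.
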