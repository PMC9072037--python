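# Methods

## Problem

A TCM medical case records four observed symptom fields — the engraving
(chief) symptoms, tongue body, tongue coating ("moss"), and pulse quality —
each a short list of phrase-level tokens, together with the physician's
syndrome elements: atomic diagnostic descriptors ("spleen", "deficiency",
"phlegm"; ~62 distinct values).  Because the number of elements is small
relative to symptoms but too large for reliable multilabel heads, the task
is cast as recommendation-style *ranking*: every (case, candidate element)
pair becomes one binary sample — label 1 iff the element belongs to the
case — and the model scores all candidates per case.  With a full
cross-product a corpus of `n` cases and `E` elements yields exactly `n×E`
samples (130,000 × 62 = 8.06 M at the reference scale).

## Model

**Main network (MMOE).**  Each field is embedded by mean-pooling its
tokens' embedding rows (the reserved padding/unknown id 0 is excluded; an
all-padding field contributes a zero vector).  The five field vectors
(four symptom fields plus the candidate element) are concatenated into
`E`.  A multi-gate mixture-of-experts applies `n_experts` shared two-layer
ReLU MLPs; for each task a softmax gate over `E` produces convex weights
that combine the expert outputs, and a per-task tower (one ReLU layer,
then a linear unit with sigmoid) yields the score ŷᵏ.  The study setting
is single-task; the code keeps the general per-task structure.

**Match network.**  An auxiliary two-tower network re-uses the same
embedding tables.  Two heads are supported: *concat* (the symptom-side and
element-side vectors concatenated, three ReLU layers, linear score), the
literal reading of the reference architecture; and *cosine* (a separate
tower per side ending in L2 normalization to unit vectors p_u, p_v, score
= sigmoid(w·⟨p_u, p_v⟩ + b)), required whenever per-side embeddings are
needed.  A zero vector reaching the normalization layer is passed through
unnormalized with a warning.

**Coupling (fusion modes).**
* `auxiliary_loss` — the match output gets its own binary cross-entropy on
  the same labels, weighted by λ₁.
* `match_as_feature` — the match probability ŷᵐ is appended to the main
  input features.  It is gradient-detached by default so the main loss
  cannot collapse the match net (joint flow is a config switch); the match
  BCE is kept so the match net retains a training signal.
* `mimic` — learned augmentation vectors a_u, a_v are concatenated to the
  tower inputs, and on positive pairs each is pulled toward the *opposing*
  tower's unit output by a squared-error loss with the tower
  stop-gradiented:  loss_u = (1/N) Σ yₖ‖a_u − p_v,ₖ‖²  (loss_v symmetric).
  Gradients of these terms therefore reach only a_u / a_v; the vectors
  inject cross-tower information through the tower inputs on the next
  forward pass.  a_u and a_v are single global vectors with the match
  tower's output width (per-element a_v is available behind a flag).
* `full` — all three simultaneously.

The total objective is
`Loss = loss_main + λ₁·loss_match + λu·loss_u + λv·loss_v`
with defaults λ₁ = 1.0, λu = λv = 0.5; all-zero weights reduce it to the
main cross-entropy exactly (asserted in tests).

**Why the mimic losses look different from their printed form.**  The
printed per-sample terms mix vectors and scalars and contain a
`(1−y)(p−p)` difference that is identically zero; they cannot evaluate to
a scalar.  They are resolved here as the positives-only squared-error form
above, following the dual-augmented two-tower mechanism the design cites,
with batch-size normalization.

**Implementation.**  The networks are plain NumPy with hand-written
analytic gradients (reverse-mode, assembled per architecture) and a
standard Adam optimizer.  Gradients are verified against central finite
differences at 1e-4 relative tolerance for every fusion mode whose
objective is an ordinary function of the parameters; stop-gradient paths
(detached fused feature, mimic targets) are checked by dedicated
closed-form tests, since a finite difference of the total loss cannot see
them by construction.  Initialization is truncated normal (±2σ, σ = 0.05
by default); embedding row 0 is frozen at zero.

## Hand-crafted statistics

For a token `zz` of one field and element `zs`, with case-level counts
(each case contributes at most 1 to any co-occurrence cell, computed per
field independently and on the training split only):

* `F1 = N/T_zz`, `F2 = N/T_zs` — association-rule confidence both ways,
* `L = F2 / (T_zs/T_total)` — lift; 1 under independence.  The printed
  formula carries a ×1e5 factor that contradicts the printed worked
  example (every printed F2/L ratio equals the element frequency 0.3056),
  so the scale defaults to 1 and remains a config knob,
* `TF-IDF = (N/S_zz)·log(Y_zz/(H_zs+1))`, natural log, where `S_zz` is the
  token's total co-occurrence mass over elements, `Y_zz` the distinct
  tokens of the field, and `H_zs` the number of *other* elements
  co-occurring with `zs`.  These are the only count-typed readings of the
  ambiguous prose that keep TF in [0,1] and IDF finite.

Zero denominators return 0 with a warning (rare tokens are expected, and
an exception would abort a whole featurization pass).

Per case and statistic, the token values of the four fields are aggregated
into a sum, an average, and a length-10 "padding" vector: the first 7
engraving values (−1-filled when short, truncated when long) followed by
the tongue, moss and pulse field averages.  An absent short field
contributes 0.0 to its padding slot: −1 is reserved for engraving slots
and the value should read as "no association evidence", for which 0 is the
statistics' natural null.  The feature order in a sample vector is
[sum, average] per statistic, then the padding blocks.

## Synthetic corpus generator

The reference corpus (150,000 physician-annotated records) is private, so
experiments use generated corpora that emulate its shape: 62 elements;
3–7 engraving symptoms from a 500-phrase vocabulary; 1–2 tokens each for
tongue (20), moss (20) and pulse (25); 1–4 elements per case, sampled
uniformly and independently (the real element co-occurrence structure is
unknown).  Each element owns a small characteristic token set per field
(6 engraving, 2 elsewhere), disjoint across elements where the vocabulary
permits.  Each emitted token is drawn: with probability `noise_rate`
(default 0.1) uniformly from the field vocabulary; otherwise via a
uniformly chosen case element, whose distribution puts `affinity_strength`
(default 0.8) mass on its characteristic set and the rest uniform.
Duplicates are rejected so field lengths land exactly in range; generation
is deterministic given the seed.

What the generator does *not* emulate: real TCM vocabulary semantics,
correlated elements, heavy-tailed symptom frequencies, annotation noise.
Passing tests therefore demonstrate that the pipeline recovers planted
co-occurrence structure at realistic shapes and rates — not clinical
performance.

## Evaluation

AUC is pooled over all samples (rank-sum with half credit for ties,
verified against a brute-force all-pairs oracle and scikit-learn).
Hits@10, MeanRank and MRR are computed per case after ranking all
candidate elements (ties broken by element id).  MeanRank uses the
piecewise penalty: with y = |true ∩ top-10|, s = |true| and i the rank of
the deepest true element found in the top 10 — y/s if i < 5, (y+i−3)/s if
5 ≤ i ≤ 10, (11−s)/s if none hit.  The published definition leaves `i`
underdetermined; "deepest found rank" is adopted so the penalty grows with
depth, and the formula is isolated in one function for easy substitution.
An alternative per-true-element reading (averaged per case) cannot be
ruled out from the published text.  MRR = 1/MeanRank within a run; across
runs every metric is averaged independently, which is why averaged
MRR·MeanRank need not equal 1 (the published per-model rows show the same
effect).  RelaImpr = ((AUC−0.5)/(AUC_base−0.5) − 1)·100%.

## Training protocol and problem sizes

Training follows the reference protocol — Adam, truncated-normal init,
5-run averaging with seeds `base_seed..base_seed+4` — with desk-scale
sizes chosen by this package: the default synthetic study corpus has
5,000 cases (4,000/1,000 case-level split, i.e. 248,000 / 62,000
cross-product samples).  At this scale the reference batch of 5,000 at
learning rate 5e-4 yields too few optimizer updates to learn the
symptom×element interaction, so the experiment configuration uses batches
of 1,024 at learning rate 1e-2 for 12 epochs (~2,900 updates), which
reaches the corpus's signal plateau, with a correspondingly scaled model
(embedding 16; 4 experts of 32/16; tower 16; match tower 32/16/16).  The
library defaults remain the reference values (batch 5,000, lr 5e-4,
8 experts of 256/128, embedding 64); batches are also scaled down
automatically (floor 64) whenever a corpus would yield fewer than 20
batches.  Epoch count is not stated in the reference protocol; the default
is 10 with optional early stopping on a held-out AUC.

**Where the fusion ablation runs.**  On the 5,000-case corpus at the
convergence protocol above, every fusion mode reaches the corpus's signal
ceiling and 5-run mean AUCs of `full` and `none` agree to within seed
noise (≈0.01 between runs): the planted associations are simple enough
for the plain MMOE to absorb fully.  The ablation comparison is therefore
run in an update-limited configuration (1,500 cases; batch 512; learning
rate 5e-3; 15 epochs) where representation learning is the bottleneck and
the match network's contribution — faster ID-embedding learning through
the auxiliary loss and the fused match feature — is measurable: there the
full model's 5-run mean AUC exceeds the uncoupled model's by ≈0.06, with
non-overlapping run ranges.  This mirrors the reference ablation as a
direction, not as effect sizes.

## Numerical choices and degenerate inputs

* Stable BCE from logits (`log1p`-style via `logaddexp`); probabilities
  clipped at 1e-12 in the reference-form loss.
* Softmax gates are max-shifted; gate weights sum to 1 by construction.
* Ranking ties broken by ascending element id (deterministic reports).
* Unknown tokens at inference encode as id 0 and drop out of field means;
  unknown *elements* in a case are an error at sample construction.
* Empty corpus, empty batch, all-empty aggregation input, single-class
  AUC, and baseline AUC of exactly 0.5 all raise with specific messages;
  an empty corpus file reads as an empty list with a warning.
* A non-finite training loss aborts with the epoch number.

## Known limitations

* The mimic mechanism at desk scale has a small effect: only two
  global vectors learn from the mimic losses, and on saturable synthetic
  corpora the fusion modes converge to similar AUC; the ablation
  comparison is a direction check, not an effect-size reproduction.
* Absolute published metric values (AUC 0.91132, Hits@10 0.77281, …)
  require the private corpus and are not reproducible here; only the
  arithmetic identities built on them are checked.
* Statistics use no smoothing; rare-token confidences are high-variance.
* The generator's independence of elements per case understates the
  correlation structure a real corpus would show.
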