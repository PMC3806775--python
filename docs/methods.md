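# Methods

`metaloc` integrates a heterogeneous panel of protein subcellular-
localization predictors for the ten plant compartments
(cytos, ER, extra, Golgi, membr, mito, nucl, pero, plast, vacu) into a
single meta-predictor, and provides the synthetic machinery needed to
study that integration without access to live predictor services.

## The node abstraction and partially labeled truth

Every predictor's output for a protein is split into *nodes* — one
(protein, location) pair per compartment the predictor scored, carrying
that predictor's raw confidence. Gold standards are positives-only:
experimental evidence can verify that a protein *is* in a compartment,
but absence of evidence never verifies absence. Two consequences run
through the whole package:

* a node's `judge` flag is 1 (verified) or 0 (unverified), never
  "negative";
* true-negative and false-negative counts are never read off raw labels.
  ROC and precision-recall curves are built by sweeping a cutoff k down
  the ranked node list — TPR(k) = TP(k)/P, FPR(k) = FP(k)/N,
  precision(k) = TP(k)/k, recall(k) = TP(k)/P — and the confusion table
  for F-score and MCC is anchored at the *intersection k\**, the
  smallest k with precision(k) ≤ recall(k). Precision starts high and
  falls while recall rises from zero, so this first crossing is unique
  on that monotone structure.

Train/test splits are drawn at the protein level (default one fifth to
test, `floor(n·fraction)` proteins, optional stratification by primary
compartment), so one protein's nodes never straddle the split.

## Group voting

Each predictor's *entire* node list (all proteins × covered locations)
is ranked by raw score, descending; ranking the whole list rather than
one protein at a time is what makes predictors with different coverage
and score scales comparable. Ties receive the mean of the tied rank
positions, which preserves the rank-sum identity Σranks = R(R+1)/2.
A node's group-voting score over the K predictors that actually scored
it is

    score(node) = 1 − (1/K) · Σ_k rank_k(node) / rank_range_k ,

the complement of its mean rank percentage: 1 is best, 0 is a node
ranked last by its only predictor. K counts only predictors that emitted
the node — a predictor that covers the location but skipped the protein
is excluded rather than imputed at some arbitrary rank, and K is
reported so downstream consumers can see how thin the support was.
Because only ranks enter, the vote is invariant under any monotone
rescaling of a predictor's raw scores.

## The network combiner and the combination model

The combiner is a feed-forward perceptron with logistic-sigmoid
(`logsig`) activations on every non-input layer and ten output units,
one per compartment, so multi-localized proteins are handled natively as
multi-label targets. Two integration modes use it:

* **network-only**: inputs are the concatenated per-predictor,
  per-location raw scores (min-max normalized to [0,1] per predictor;
  scores outside a predictor's coverage, or missed, are 0);
* **combination**: inputs are the ten group-voting scores of the
  protein, i.e. the vote acts as a rank-calibrated, coverage-aware
  front end and the network only re-weights and mixes ten numbers.

Training minimizes mean binary cross-entropy summed over the ten
outputs, by full-batch gradient descent with momentum 0.9 and an
accept/reject step control: a step that would increase the (optionally
L2-penalized) training loss is rejected, the velocity reset and the
learning rate halved; accepted steps grow the rate by 5%. The recorded
loss history is therefore non-increasing, and training is fully
deterministic given the initialisation seed. Optional L2 weight decay
(default 0) is exposed because, at these problem sizes, unregularized
nets show a large initialisation lottery (test-AUROC sd ≈ 0.01 across
restarts) that degrades model-selection protocols.

Because restarts land in different optima, every model-selection
protocol trains several times:

* **topology search** follows a grid of one or two hidden layers with
  5, 10 or 15 units each, trains each structure 10 times, summarises it
  by the median of its best 3 repeats, and returns the single best
  repeat as the deployable model. On vote-vector inputs the expected
  winner at these data sizes is one hidden layer of ten units; the test
  suite asserts the protocol, not the winner, since the winning
  structure is data-regime dependent.
* **stepwise predictor selection** adds candidates in descending order
  of individual AUROC and keeps one only if held-out AUROC improves.
  "Improves" is read against training noise: with the repeat spread of
  the incumbent and the candidate communities, a candidate is kept iff
  the mean gain exceeds max(1e-4, 2·SE of the mean difference). A fixed
  small tolerance alone is not usable here — step-to-step jitter from
  restart variability is ~1e-3 even with six repeats and shared repeat
  seeds, so a 1e-4 rule admits pure-noise predictors roughly a third of
  the time. Setting `se_factor=0` restores the plain fixed-tolerance
  rule for anyone who wants it.

At fit time the vote stage stores each predictor's full ranked score
list; a new protein's raw score is assigned the rank percentage it
would have received by insertion into that list (rank = #{stored > s} +
1), which is monotone, deterministic, and needs no re-ranking of the
training universe.

## Empirical P-values

Sequences that exist in no compartment define the null: random
amino-acid sequences (uniform residues, lengths uniform on 50–300) are
scored by the panel's negative-score model and pushed through the full
meta-predictor, giving one sorted null score array per compartment
(per-compartment nulls, because output scales differ by location). A
prediction's P-value is the add-one empirical tail

    p = (1 + #{null ≥ score}) / (M + 1) ∈ (0, 1],

strictly anti-monotone in the score, never exactly zero, and usable from
M = 100 up (M ≥ 1000 recommended; the package default for reports is
configurable). A similarity-filter hook is applied to the generated
sequences before scoring (for screening against a reference proteome);
the default is pass-through. P-values of fresh null draws are uniform on
(0,1] by the probability integral transform; the acceptance suite
checks this with a KS test at n = 1000.

## The synthetic ensemble generator

The generator emulates a curated plant localization gold standard and a
panel of live predictors. Each synthetic predictor is a **binormal**
scorer: for a covered location, a gold-positive node draws a latent
score from Normal(d, 1), any other node from Normal(0, 1), and the
latent value is squashed through `logsig` onto a (0,1) native scale
(AUROC is rank-based, so the squashing changes nothing). The separation
is set from a target AUROC by d = √2·Φ⁻¹(AUROC), so profiles are exactly
calibratable — the acceptance suite verifies the identity to ±0.02 at
2,000 nodes for d ∈ {0, 0.5, 1, 1.8, 2.5}.

Profiles add: a coverage mask (narrow-scope predictors score 1–3
compartments), a miss rate (probability of emitting nothing for a
covered protein), an optional loading on a shared latent noise factor
(for studying dependent panels), and optional cross-location
*confusions* — extra separation added to one compartment's score when
the protein is truly in another, e.g. a targeting-signal feature shared
by two organelles.

Gold standards default to one primary location per protein drawn from
imbalanced priors (plastid 0.18 … Golgi/vacuole/peroxisome 0.05 each —
the well-studied compartments dominate curated data), plus a second
distinct location with probability 0.1 (multiplicity capped at two; the
multi-localization literature gives no multiplicity distribution, so the
cap is the minimal choice). Default panel size is 2,000 proteins, which
keeps ≥100 expected positives in the rarest compartment while staying
desk-scale. An alternative label model draws every (protein, location)
positive as an independent Bernoulli and discards proteins with no
location; it exists because the default exclusivity coupling between
compartments is itself a learnable nonlinear signal (see below).

Named presets fix the study conditions:

* **paperlike-11** — eleven heterogeneous profiles: five wide-coverage
  tools of varying quality (per-location AUROC 0.58–0.86), three
  narrow targeting-signal tools, two single-compartment specialists and
  one weak generalist. Golgi and vacuole are deliberately poorly served
  (no profile above 0.66) while plastid and nucleus are well served.
* **three-community** — the first three wide profiles only.
* **noise-spiked** — five informative full-coverage profiles (uniform
  AUROC 0.80, 0.78, 0.76, 0.74, 0.72) plus two pure-noise profiles
  (0.5), for stepwise-selection studies. The informative profiles are
  deliberately close in strength so that even the weakest one carries a
  marginal gain (~0.01 AUROC) clearly above residual training noise.
* **additive** / **confounded** — a matched pair on independent
  per-location labels (Bernoulli 0.12). `additive` has five
  full-coverage profiles with no cross-location structure: the optimal
  score for a node is a monotone function of its own vote score, so the
  network has nothing to add and combination ≈ vote is the correct
  outcome. `confounded` is the same panel with one-way leakage —
  plastid positives inflate the mitochondrion score on four of the five
  members (d = 3.0), cytosol positives inflate the nucleus score on
  three — which a rank average cannot correct but a network seeing the
  whole vote vector can explain away via the cleanly predicted source
  compartment. One-way leakage is used because symmetric two-way
  leakage is largely destroyed by vote averaging and leaves almost no
  recoverable signal.

Everything is bit-reproducible under a master seed; per-predictor
sub-seeds are spawned deterministically.

## What the synthetic conditions do and do not show

Passing tests demonstrate the integration machinery behaves as the
theory predicts under calibrated binormal score models with known
coverage, independence and leakage structure. Real predictor panels
differ in ways the generator does not emulate: score distributions are
not Gaussian on any latent scale, errors correlate through shared
training data and shared features, per-location accuracies are only
estimable, and gold standards carry study-bias (well-studied
compartments contribute more diverse patterns). Results here say the
method extracts what the ensemble contains — not how much a particular
real ensemble contains.

## Numerical choices and degenerate inputs

* Ties in raw scores get mean (fractional) ranks; ranked-list order and
  every cutoff count are made reproducible by tie-breaking on node id.
* AUPR integrates precision linearly in recall, with an anchor at
  recall 0 carrying the k = 1 precision (interpolation convention moves
  AUPR in the third decimal, so it is fixed here).
* MCC is 0 by convention when any marginal of the confusion table is
  empty. F-score raises on an empty predicted-positive or positive set.
* Single-class ranked lists refuse to produce a ROC rather than
  fabricate one; per-location report rows for such compartments are
  marked unavailable.
* `logsig` is computed in the numerically stable split form; saturated
  inputs give exact 0/1 without overflow.
* SVD independence analysis column-centers the node × predictor rank
  matrix and reports the singular-value spectrum with variance
  fractions; a trailing near-zero value exposes a linearly redundant
  predictor, a dominant leading component a shared factor.
* Empirical P-values use the add-one rule, so p > 0 always and the
  anti-monotonicity in the score is strict across observed null values.

## Problem sizes

Default study sizes were chosen so the statistical claims are resolvable
at desk scale: 2,000 proteins (≈ 22,000 nodes for the 11-predictor
panel) for integration studies, 1,500 proteins for stepwise selection
(six training repeats per step), 2,000 labeled nodes per calibration
point, and M = 1,000 null sequences per P-value study. The end-to-end
pipeline and its byte-identity check run on smaller instances (a few
hundred proteins) since they verify plumbing and determinism, not
statistical effects.

## Known limitations

* The vote's insertion-percentile scoring of unseen proteins ignores
  that the stored list itself would shift by one rank; the discrepancy
  is O(1/rank_range).
* The stepwise and topology protocols select on the same held-out split
  they report, as the original selection protocols do; reported test
  AUROCs for selected models are therefore mildly optimistic.
* The network-only model's zero-fill for uncovered locations conflates
  "not covered" with "lowest score"; the combination model's K-aware
  vote front end is the recommended path for ragged panels.
* Dependence between predictors is modelled only as a shared Gaussian
  factor; real panels share training corpora, which induces structured,
  label-dependent correlation.
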