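# Methods

## Scope and model

`m6acall` estimates, for every RRACH centre A on every transcript
isoform, the fraction of reads carrying m⁶A (the site's stoichiometry).
The estimator is two-staged: a per-read binary classifier over
signal-level features of the RRACH 5-mer window, then a counting step,
rate = Nm/(Nm+Nu), thresholding the per-read probability at 0.5
("not less than 0.5" counts as modified).  The classifier ensemble is
motif-conditional: one independent sub-model per RRACH 5-mer, because
the baseline current of the window is dominated by its sequence and the
modification signal is a *shift* relative to that baseline.

Assumptions inherited from the study design:

* the event table comes from a re-squiggle step that aligned raw current
  segments to reference positions; mean/median/sd are in pA, dwell in
  arbitrary time units, quality Phred-like;
* training data exist as a *pair* of samples — one carrying m⁶A at the
  anchored sites (wild-type-like), one without (methyltransferase
  deficient) — while prediction needs only a single sample;
* mismatch-based read labeling is informative but noisy: its accuracy
  ceiling is a closed-form function of the per-position mismatch
  probabilities and the site stoichiometry
  (`m6acall.training.expected_label_accuracy`);
* reads are assigned to transcript isoforms upstream (the event table
  is keyed by transcript), which is what makes isoform-resolved calling
  possible.

## Thresholds and tunable parameters

| parameter | default | meaning |
|---|---|---|
| coverage filter | 50 reads | minimum spanning reads for a reported site |
| baseline rate | 0.1 | below: indistinguishable from unmodified background |
| high-confidence rate | > 0.2 | tier above the background band |
| low-confidence band | [0.1, 0.2] | closed interval; tiers partition [0, 1] |
| probability threshold | 0.5 | per-read modified/unmodified cut (0.5 → modified) |
| anchor distance | 5 nt | max |differential position − centre A| |
| labeling region | 11 nt | centre A ± 5 |
| feature window | 5 nt | the RRACH 5-mer (window width configurable) |
| train:test split | 7:3 | per motif, seeded shuffle |
| learning rate | 5e-4 | Adam, decayed ×0.1 every epoch |
| early stopping | patience 3 | best-validation checkpoint retained |

Tier boundaries are evaluated on exact fractions, never on the 3-decimal
rounded rate, so sites at exactly 0.1 or 0.2 land on the intended side.

## Classifier

Each sub-model is a 3-layer bidirectional LSTM (64 hidden units per
direction) over the 5 window positions (5 features per step), flattened
into a three-layer fully connected head (64, 32, 2) with softmax and
cross-entropy.  The implementation is a compact, dependency-free NumPy
network with hand-derived backpropagation, verified against central
finite differences in the test suite; it is single-threaded and strictly
deterministic under a fixed seed, which the test suite and the
acceptance script rely on.

Choices the published optimisation regime leaves open, and what this
package does:

* **Batch size 16, max 30 epochs.**  The ×0.1-per-epoch decay
  effectively confines learning to the first one or two epochs, so the
  number of gradient steps taken at a usable learning rate is
  `n_train / batch_size`.  At desk-scale per-motif datasets (10³–10⁴
  events) small batches are required for the optimiser to converge;
  batch 16 reaches the quality plateau.
* **Validation fraction 0.1** carved from the training partition drives
  early stopping ("verification set" size is not specified by the
  regime; recorded in model metadata).
* **Dwell is log-transformed** before z-scoring (`log_dwell=True`):
  dwell is approximately log-normal and the raw heavy tail wastes the
  channel.
* **Per-feature z-scoring** uses training-partition statistics stored
  with each sub-model, making prediction reproducible across runs; it
  can be disabled for raw-feature parity tests.
* **Level augmentation** (`level_augment_sd = 1.0` pA): during training
  each batch's mean/median columns receive a random per-event offset
  (a common-mode draw plus a half-weighted per-position draw).  Baseline
  current varies with flanking sequence context from site to site; a
  sub-model trained on a finite set of site contexts otherwise partially
  memorises their absolute baselines and mis-scores reads at unseen
  contexts.  The augmentation scale matches the context-induced
  variability of the level model and is far below the modification
  shift, so it enforces context invariance without erasing the signal.
* **Class imbalance** is left as-is by default (`class_balance="none"`),
  matching the original regime; downsampling is available.

## Synthetic data generator

`m6acall.synthetic` emulates the statistical structure of event-aligned
direct RNA-Seq around m⁶A sites:

* **Baseline level model**: a deterministic per-5-mer (mean, sd) table —
  centre base sets the level (92–104 pA), flanking bases add
  position-weighted offsets below ±1 pA, sd 1.5 pA.  This stands in for
  a measured pore model.
* **Modification effects** (defaults chosen once to make the classes
  separable but overlapping, not saturated): +4.5 pA at the modified
  centre with decaying neighbour fractions (0.5 at ±1, 0.25 at ±2);
  dwell log-mean +0.5 at the centre; quality −3.5 at the centre;
  per-position mismatch probability 0.12 inside the 11-nt region of a
  modified read versus 0.01 background.  Under a Gaussian approximation
  these defaults give a theoretical per-read Bayes accuracy near 0.97,
  so classifier targets are meaningful rather than trivially saturated.
* **Stoichiometry**: each read draws a latent modified flag
  Bernoulli(true_rate) per site; the flags are returned in a separate
  truth table, never in the event table, so tests cannot leak labels.
* **Nuisance processes**: deletion gaps (p = 0.004, features zeroed),
  5′-truncated reads (p = 0.05), median jitter, event-sd jitter.
* **References** contain *exactly* the planted RRACH sites: chance
  occurrences are scrubbed by iterated base flips outside planted
  footprints.  Without this, chance centres near planted sites acquire
  anchor status and contaminate training labels.

What the generator does **not** model: raw squiggle segmentation,
basecaller-specific error profiles (only per-position mismatch flags),
clustered multi-site signal interference, homopolymer artefacts,
coverage bias along transcripts.  Passing tests therefore demonstrate
the pipeline's correctness and its statistical behaviour under the
modelled effects — not performance on real flowcell data.

## Study designs used by the tests and the acceptance script

* **Recovery study** (`m6acall.harness.run_recovery_study`): training on
  16 sites per motif (96 transcripts × 2 sites, 200 nt), coverage
  125–175, stoichiometry 0.9 at training sites (anchor discovery is
  biased toward strongly modified sites, which this emulates) — about
  45k labeled events; evaluation on 40 fresh sites cycling the true-rate
  grid {0.0, …, 0.9} at coverage exactly 200, plus a second independent
  replicate (concordance) and a fully unmodified sample (background).
  Per-site recovery is judged against 0.05 + 3 Wald standard errors of
  the binomial estimate.
* **Null study** (`run_null_study`): a zero-effect configuration with
  every modified/unmodified parameter pair equalised and the mismatch
  probability set to 1 − 0.5^(1/11) ≈ 0.061 so the 11-nt labeling rule
  produces *balanced* classes — otherwise chance-level accuracy would be
  masked by class imbalance.  The differential-error test's type-I rate
  is measured over independent null transcript pairs.

Sizes were chosen so the full test suite and the acceptance script each
run in minutes on a single CPU; they are parameters of the harness
functions, not constants.

## Numerical and degenerate-case conventions

* Internal coordinates 0-based half-open; reported coordinates 1-based
  (site names carry the 1-based transcript position).  Both directions
  of the transcript↔genome map are explicit and strand-aware.
* Equidistant RRACH centres: anchoring ties break toward the 5′ centre.
* Substitutions and deletion gaps both count as basecall "errors" for
  labeling and for the differential test; the event table has no
  insertion rows.
* Undefined evaluation metrics (zero denominators) are reported as
  missing, never as 0.
* An empty probability vector has no defined rate and raises; sites with
  no spanning reads are simply not candidates.
* G-test cells with zero counts contribute 0 to the statistic;
  Benjamini–Hochberg is applied across all tested positions of a run.
* Sub-model training refuses single-class datasets and aborts on
  non-finite loss; motifs with a single-class partition are flagged
  untrainable and excluded from the ensemble (prediction then skips and
  tallies their events).

## Known limitations

* The per-read classifier's operating point (false-positive rate ~3–4%
  per read at the defaults) puts a floor under called rates at truly
  unmodified sites and a mild ceiling at fully modified ones; rates at
  the extremes are biased toward the centre by the per-read error rates.
* Site contexts far outside the training contexts' level range can
  still shift per-site error beyond the average, the residual of the
  context-invariance augmentation.
* Mismatch-based labels are impure at low-stoichiometry training sites;
  the harness trains at stoichiometry 0.9 where purity is ≈ 0.98.
* differr-style replicate-aware differential testing is out of scope;
  the G-test stand-in is only an anchor-site source.
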