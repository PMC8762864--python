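"""End-to-end study harnesses: parameter recovery, background control,
replicate concordance and null-regime behaviour.

These drive the whole pipeline on simulator output with known truth:

* **recovery study** — train the ensemble on a strongly modified
  synthetic wild-type vs an unmodified mutant, then quantify an
  independent evaluation sample whose sites span the stoichiometry grid
  {0.0, 0.1, ..., 0.9} at coverage 200, and measure how well the called
  rates recover the truth.  A second evaluation replicate gives the
  replicate-concordance estimate, and an evaluation sample simulated
  fully unmodified gives the false-positive background.
* **null study** — a zero-effect configuration (identical class
  parameters) checks that held-out accuracy collapses to chance and that
  the differential-error test controls its type-I rate.

Study sizes default to a desk-scale regime: 16 training sites per motif
at coverage 125-175 (about 45k labeled events over 192 site contexts) and
40 evaluation sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import (
    RRACH_MOTIFS,
    AnchoredSite,
    anchor_to_rrach,
    differential_error_test,
    enumerate_rrach,
)
from .metrics import replicate_concordance
from .model import EnsembleResults, ModelConfig, ModificationEnsemble
from .quantify import TIER_HIGH, call_isoforms, calls_to_frame
from .synthetic import SimConfig, make_reference, null_config, simulate_sample
from .training import build_datasets, extract_labeled_events

__all__ = ["RecoveryReport", "run_recovery_study", "run_null_study", "NullReport"]

RATE_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))


@dataclass
class RecoveryReport:
    """Everything the recovery study measured."""

    results: EnsembleResults
    site_estimates: pd.DataFrame  # truth vs called rate per evaluation site
    mae: float
    per_motif: pd.DataFrame  # held-out test metrics per motif
    background_median_rate: float
    background_high_conf_fraction: float
    background_n_sites: int
    replicate_correlation: float
    n_labeled_events: int
    n_anchored_sites: int
    n_planted_training_sites: int
    anchored_recall: float
    qc: dict = field(default_factory=dict)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_recovery_study(
    seed: int = 0,
    sites_per_motif: int = 16,
    train_rate: float = 0.9,
    train_coverage: tuple[int, int] = (125, 175),
    eval_rates: Sequence[float] = RATE_GRID,
    eval_sites_per_rate: int = 4,
    eval_coverage: int = 200,
    transcript_length: int = 200,
    sim_config: SimConfig | None = None,
    model_config: ModelConfig | None = None,
    verbose: bool = False,
) -> RecoveryReport:
    """Simulate, discover, extract, train, quantify, and score recovery.

    Training sites carry stoichiometry ``train_rate`` (anchor sites found
    by differential-error testing are biased toward strongly modified
    sites, which this emulates); evaluation sites cycle ``eval_rates``.
    """
    seeds = _spawn_seeds(seed, 8)
    cfg = sim_config or SimConfig(coverage_dist=train_coverage, seed=seeds[0])

    # --- training reference: sites_per_motif x 12 sites, 2 per transcript
    n_train_sites = sites_per_motif * len(RRACH_MOTIFS)
    n_train_tx = n_train_sites // 2
    reference, truth = make_reference(
        n_transcripts=n_train_tx,
        length=transcript_length,
        sites_per_transcript=2,
        seed=seeds[1],
        motifs=RRACH_MOTIFS,
        rates=[train_rate],
    )
    wt_events, _wt_latent = simulate_sample(
        reference, truth, cfg, seed=seeds[2], read_prefix="wt"
    )
    mut_events, _ = simulate_sample(
        reference, truth, cfg, modified_fraction_override=0.0,
        seed=seeds[3], read_prefix="mut",
    )

    # --- discovery: differential errors anchored to RRACH centres
    diff = differential_error_test(wt_events, mut_events, min_coverage=20)
    rrach_index = {tx: enumerate_rrach(seq) for tx, seq in reference.items()}
    anchored = anchor_to_rrach(diff, rrach_index)
    planted = {(t.transcript_id, t.position) for t in truth}
    recovered = {(a.transcript_id, a.position) for a in anchored} & planted
    anchored_recall = len(recovered) / len(planted)

    # --- labeled training data at anchored sites
    lengths = {tx: len(seq) for tx, seq in reference.items()}
    pos_events, qc_pos = extract_labeled_events(
        wt_events, anchored, "modified_sample", lengths
    )
    neg_events, qc_neg = extract_labeled_events(
        mut_events, anchored, "unmodified_sample", lengths
    )
    labeled = pd.concat([pos_events, neg_events], ignore_index=True)
    datasets = build_datasets(labeled, ratio=0.7, seed=seeds[4])

    # --- fit ensemble
    mcfg = model_config or ModelConfig(seed=seeds[5])
    results = ModificationEnsemble(datasets, mcfg).fit(verbose=verbose)
    per_motif = results.evaluate()

    # --- evaluation reference: rate grid, fixed coverage
    n_eval_sites = len(eval_rates) * eval_sites_per_rate
    eval_ref, eval_truth = make_reference(
        n_transcripts=n_eval_sites // 2,
        length=transcript_length,
        sites_per_transcript=2,
        seed=seeds[6],
        motifs=RRACH_MOTIFS,
        rates=list(eval_rates),
    )
    eval_cfg = SimConfig(
        **{**_config_kwargs(cfg), "coverage_dist": (eval_coverage, eval_coverage)}
    )
    rep_calls = []
    rep_seeds = _spawn_seeds(seeds[7], 3)
    for rep, rep_seed in enumerate(rep_seeds[:2]):
        ev, _ = simulate_sample(
            eval_ref, eval_truth, eval_cfg, seed=rep_seed, read_prefix=f"ev{rep}"
        )
        calls = call_isoforms(results, ev, eval_ref)
        rep_calls.append(calls_to_frame(calls))
    corr = replicate_concordance(rep_calls, min_coverage=50)
    replicate_correlation = float(corr.iloc[0, 1])

    est = rep_calls[0].set_index(["transcript_id", "position"])
    rows = []
    for t in eval_truth:
        key = (t.transcript_id, t.position)
        if key not in est.index:
            continue
        row = est.loc[key]
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "position": t.position,
                "motif": t.motif,
                "true_rate": t.true_rate,
                "called_rate": float(row["rate"]),
                "coverage": int(row["coverage"]),
                "error": float(row["rate"]) - t.true_rate,
            }
        )
    site_estimates = pd.DataFrame(rows)
    mae = float(site_estimates["error"].abs().mean())

    # --- background: same evaluation reference, fully unmodified
    bg_events, _ = simulate_sample(
        eval_ref, eval_truth, eval_cfg, modified_fraction_override=0.0,
        seed=rep_seeds[2], read_prefix="bg",
    )
    bg_calls = calls_to_frame(call_isoforms(results, bg_events, eval_ref))
    covered = bg_calls[bg_calls["coverage"] >= 50]
    background_median_rate = float(covered["rate"].median())
    background_high_conf_fraction = float((covered["tier"] == TIER_HIGH).mean())

    return RecoveryReport(
        results=results,
        site_estimates=site_estimates,
        mae=mae,
        per_motif=per_motif,
        background_median_rate=background_median_rate,
        background_high_conf_fraction=background_high_conf_fraction,
        background_n_sites=len(covered),
        replicate_correlation=replicate_correlation,
        n_labeled_events=len(labeled),
        n_anchored_sites=len(anchored),
        n_planted_training_sites=len(truth),
        anchored_recall=anchored_recall,
        qc={"positives": qc_pos, "negatives": qc_neg},
    )


def _config_kwargs(cfg: SimConfig) -> dict:
    return {
        "kmer_level_table": cfg.kmer_level_table,
        "mod_shift": cfg.mod_shift,
        "neighbor_fracs": cfg.neighbor_fracs,
        "dwell_params": cfg.dwell_params,
        "qual_params": cfg.qual_params,
        "mismatch_prob": cfg.mismatch_prob,
        "coverage_dist": cfg.coverage_dist,
        "gap_prob": cfg.gap_prob,
        "median_jitter": cfg.median_jitter,
        "sd_jitter": cfg.sd_jitter,
        "truncate_prob": cfg.truncate_prob,
        "region_flank": cfg.region_flank,
        "seed": cfg.seed,
    }


@dataclass
class NullReport:
    """Zero-effect regime: chance-level accuracy and type-I control."""

    per_motif_accuracy: pd.DataFrame  # motif, n_test, accuracy
    type_i_fraction: float  # transcripts with >= 1 anchored site under the null
    n_null_replicates: int
    nominal_level: float


def run_null_study(
    seed: int = 0,
    sites_per_motif: int = 2,
    coverage: tuple[int, int] = (140, 160),
    n_null_replicates: int = 200,
    null_coverage: int = 50,
    null_length: int = 200,
    alpha: float = 0.05,
    model_config: ModelConfig | None = None,
) -> NullReport:
    """Train on zero-effect data and probe the discovery test's null.

    The zero-effect configuration equalises every modified/unmodified
    parameter pair, with the per-position mismatch probability set so the
    11-nt labeling rule yields balanced classes (otherwise chance-level
    accuracy would be masked by class imbalance).
    """
    seeds = _spawn_seeds(seed, 4)
    cfg = null_config(seed=seeds[0], coverage_dist=coverage)

    n_tx = sites_per_motif * len(RRACH_MOTIFS) // 2
    reference, truth = make_reference(
        n_transcripts=n_tx, length=200, sites_per_transcript=2,
        seed=seeds[1], motifs=RRACH_MOTIFS, rates=[0.5],
    )
    wt, _ = simulate_sample(reference, truth, cfg, seed=seeds[2], read_prefix="wt")
    mut, _ = simulate_sample(
        reference, truth, cfg, modified_fraction_override=0.0,
        seed=seeds[3], read_prefix="mut",
    )
    lengths = {tx: len(s) for tx, s in reference.items()}
    sites = [
        AnchoredSite(t.transcript_id, t.position, t.motif) for t in truth
    ]
    pos, _ = extract_labeled_events(wt, sites, "modified_sample", lengths)
    neg, _ = extract_labeled_events(mut, sites, "unmodified_sample", lengths)
    labeled = pd.concat([pos, neg], ignore_index=True)
    datasets = build_datasets(labeled, seed=seeds[0])
    mcfg = model_config or ModelConfig(seed=seeds[0])
    results = ModificationEnsemble(datasets, mcfg).fit()
    per_motif = results.evaluate()[["n_test", "accuracy"]].reset_index()

    # --- type-I rate of the differential-error stand-in under the null
    rng_seeds = _spawn_seeds(seeds[0] + 1, n_null_replicates * 2)
    null_cfg = null_config(coverage_dist=(null_coverage, null_coverage))
    hits = 0
    for i in range(n_null_replicates):
        ref_i, truth_i = make_reference(
            1, null_length, 1, seed=rng_seeds[2 * i], rates=[0.0]
        )
        a, _ = simulate_sample(ref_i, truth_i, null_cfg, seed=rng_seeds[2 * i],
                               read_prefix="a")
        b, _ = simulate_sample(ref_i, truth_i, null_cfg, seed=rng_seeds[2 * i + 1],
                               read_prefix="b")
        diff = differential_error_test(a, b, min_coverage=20, alpha=alpha)
        idx = {tx: enumerate_rrach(s) for tx, s in ref_i.items()}
        if anchor_to_rrach(diff, idx):
            hits += 1
    return NullReport(
        per_motif_accuracy=per_motif,
        type_i_fraction=hits / n_null_replicates,
        n_null_replicates=n_null_replicates,
        nominal_level=alpha,
    )
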