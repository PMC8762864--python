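"""Site calling: Nm/Nu thresholding, filter tiers, scanning, pooling,
isoform-resolved calls with genome projection."""

import numpy as np
import pandas as pd
import pytest

from m6acall.discovery import AnchoredSite
from m6acall.event_io import TranscriptModel
from m6acall.model import ModelConfig, ModificationEnsemble
from m6acall.quantify import (
    TIER_BELOW,
    TIER_HIGH,
    TIER_INSUFFICIENT,
    TIER_LOW,
    call_isoforms,
    call_site,
    pool_replicates,
    scan_sites,
)
from m6acall.synthetic import SimConfig, make_reference, simulate_sample
from m6acall.training import build_datasets, extract_labeled_events


def brute_force_call(probs, min_coverage=50, baseline=0.1, high=0.2):
    """Independent oracle: explicit counting loop."""
    n_mod = sum(1 for p in probs if p >= 0.5)
    n_unmod = sum(1 for p in probs if p < 0.5)
    rate = n_mod / (n_mod + n_unmod)
    if n_mod + n_unmod < min_coverage:
        tier = TIER_INSUFFICIENT
    elif rate < baseline:
        tier = TIER_BELOW
    elif rate > high:
        tier = TIER_HIGH
    else:
        tier = TIER_LOW
    return n_mod, n_unmod, rate, tier


class TestCallSite:
    def test_worked_example(self):
        probs = [0.9] * 9 + [0.1] * 51
        assert call_site(probs) == (9, 51, 0.15, TIER_LOW)

    def test_rate_exactly_point_two_is_low_confidence(self):
        probs = [0.9] * 10 + [0.1] * 40
        n_mod, _, rate, tier = call_site(probs)
        assert rate == 0.2 and tier == TIER_LOW

    def test_probability_exactly_half_counts_as_modified(self):
        n_mod, n_unmod, _, _ = call_site([0.5] * 30 + [0.49] * 30)
        assert (n_mod, n_unmod) == (30, 30)

    def test_coverage_49_is_insufficient(self):
        assert call_site([0.9] * 49)[3] == TIER_INSUFFICIENT
        assert call_site([0.9] * 50)[3] == TIER_HIGH

    def test_empty_probabilities_raise(self):
        with pytest.raises(ValueError):
            call_site([])

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            call_site([0.5, 1.2])

    def test_matches_brute_force_oracle_on_fuzzed_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 120))
            probs = rng.random(n)
            if rng.random() < 0.3:  # salt exact-threshold values
                probs[rng.integers(0, n)] = 0.5
            assert call_site(probs) == brute_force_call(probs)

    def test_order_invariance(self, rng):
        probs = rng.random(80)
        assert call_site(probs) == call_site(probs[::-1])


class TestScanSites:
    @staticmethod
    def _frame(transcript, n_reads, length, start=0):
        rows = []
        for i in range(n_reads):
            rows.append(pd.DataFrame({
                "read_id": f"r{i}",
                "transcript_id": transcript,
                "position": np.arange(start, length),
                "event_mean": 100.0, "event_median": 100.0, "event_sd": 1.0,
                "dwell": 1.0, "base_quality": 12.0, "match_flag": "match",
            }))
        return pd.concat(rows, ignore_index=True)

    def test_uniform_coverage_all_candidates(self):
        ref = {"t": "CCCCGGACTCCCCCGGACACCCCCAGACTCCCC"}
        events = self._frame("t", 60, len(ref["t"]))
        cands = scan_sites(ref, events)
        assert len(cands) == 3
        assert all(c.coverage == 60 for c in cands)

    def test_overlapping_motifs_both_reported(self):
        ref = {"t": "CCCCGAACAAACTCCCC"}  # centres 6 and 10 share a base
        brute = [
            (i + 2, ref["t"][i : i + 5])
            for i in range(len(ref["t"]) - 4)
            if ref["t"][i] in "AG" and ref["t"][i + 1] in "AG"
            and ref["t"][i + 2] == "A" and ref["t"][i + 3] == "C"
            and ref["t"][i + 4] in "ACT"
        ]
        events = self._frame("t", 5, len(ref["t"]))
        cands = scan_sites(ref, events)
        assert [(c.position, c.motif) for c in cands] == brute
        assert len(brute) == 2

    def test_zero_reads_zero_candidates(self):
        ref = {"t": "CCCCGGACTCCCC"}
        events = self._frame("other", 5, 13)
        assert scan_sites(ref, events) == []

    def test_partial_spanning_reads_not_counted(self):
        ref = {"t": "CCCCGGACTCCCC"}  # centre 6, window [4, 9)
        full = self._frame("t", 3, 13)
        partial = self._frame("t", 2, 13, start=5)  # misses window start
        partial["read_id"] = partial["read_id"] + "p"
        cands = scan_sites(ref, pd.concat([full, partial], ignore_index=True))
        assert len(cands) == 1 and cands[0].coverage == 3


class TestPooling:
    @staticmethod
    def _tiny(n, prefix):
        return pd.DataFrame({
            "read_id": [f"{prefix}{i}" for i in range(n)],
            "transcript_id": "t", "position": 0,
            "event_mean": 1.0, "event_median": 1.0, "event_sd": 1.0,
            "dwell": 1.0, "base_quality": 10.0, "match_flag": "match",
        })

    def test_read_counts_sum(self):
        pooled = pool_replicates(self._tiny(100, "a"), self._tiny(150, "b"))
        assert pooled["read_id"].nunique() == 250

    def test_pooling_table_with_itself_doubles_coverage(self):
        t = self._tiny(40, "a")
        pooled = pool_replicates(t, t, labels=["rep1", "rep2"])
        assert len(pooled) == 80
        assert pooled["read_id"].nunique() == 80

    def test_duplicate_labels_rejected(self):
        t = self._tiny(5, "a")
        with pytest.raises(ValueError, match="unique"):
            pool_replicates(t, t, labels=["rep1", "rep1"])

    def test_site_passes_coverage_only_after_pooling(self):
        """Two replicates at 30 reads each: 50-read filter passes pooled."""
        probs_one = [0.6] * 30
        assert call_site(probs_one)[3] == TIER_INSUFFICIENT
        assert call_site(probs_one * 2)[3] == TIER_HIGH


@pytest.fixture(scope="module")
def mini_ensemble():
    """A small one-motif ensemble trained on simulated GGACT data."""
    ref, truth = make_reference(2, 200, 2, seed=21, motifs=["GGACT"], rates=[0.9])
    cfg = SimConfig(coverage_dist=(150, 150), seed=21)
    wt, _ = simulate_sample(ref, truth, cfg, seed=22, read_prefix="wt")
    mut, _ = simulate_sample(ref, truth, cfg, modified_fraction_override=0.0,
                             seed=23, read_prefix="mut")
    anchored = [AnchoredSite(t.transcript_id, t.position, t.motif) for t in truth]
    lengths = {tx: len(s) for tx, s in ref.items()}
    pos, _ = extract_labeled_events(wt, anchored, "modified_sample", lengths)
    neg, _ = extract_labeled_events(mut, anchored, "unmodified_sample", lengths)
    labeled = pd.concat([pos, neg], ignore_index=True)
    cfg_m = ModelConfig(hidden_size=16, fc_sizes=(16, 8), max_epochs=6, seed=0)
    return ModificationEnsemble(build_datasets(labeled, seed=0), cfg_m).fit()


class TestIsoformCalls:
    def test_shared_exon_site_reported_per_isoform(self, mini_ensemble):
        """Two isoforms share an exon carrying one site; calls stay
        separate per isoform but share the genomic key."""
        from m6acall.discovery import enumerate_rrach
        from m6acall.synthetic import SimTruth

        core, _ = make_reference(1, 200, 1, seed=31, motifs=["GGACT"], rates=[0.6])
        core_seq = core["tx0000"]
        (centre, motif), = enumerate_rrach(core_seq)
        ref = {"isoA": core_seq, "isoB": "C" * 100 + core_seq}
        truth = [SimTruth("isoA", centre, motif, 0.6),
                 SimTruth("isoB", centre + 100, motif, 0.4)]
        cfg = SimConfig(coverage_dist=(120, 120), seed=33)
        events, _ = simulate_sample(ref, truth, cfg, seed=34)
        annotation = {
            "isoA": TranscriptModel("isoA", "geneX", "chr5", "+",
                                    ((1100, 1300),)),
            "isoB": TranscriptModel("isoB", "geneX", "chr5", "+",
                                    ((1000, 1300),)),
        }
        calls = call_isoforms(mini_ensemble, events, ref, annotation=annotation,
                              min_coverage=50)
        at_site = {c.transcript_id: c for c in calls
                   if (c.transcript_id, c.position) in
                   {("isoA", centre), ("isoB", centre + 100)}}
        assert set(at_site) == {"isoA", "isoB"}
        assert at_site["isoA"].genomic_key == at_site["isoB"].genomic_key
        assert at_site["isoA"].rate > at_site["isoB"].rate  # 0.6 vs 0.4

    def test_transcript_missing_from_annotation_keeps_null_coordinate(
        self, mini_ensemble
    ):
        ref, truth = make_reference(1, 200, 1, seed=41, motifs=["GGACT"],
                                    rates=[0.5])
        cfg = SimConfig(coverage_dist=(80, 80), seed=41)
        events, _ = simulate_sample(ref, truth, cfg)
        calls = call_isoforms(mini_ensemble, events, ref, annotation={})
        assert calls and all(c.genome_pos is None for c in calls)

    def test_per_read_probabilities_returned(self, mini_ensemble):
        ref, truth = make_reference(1, 200, 1, seed=51, motifs=["GGACT"],
                                    rates=[1.0])
        cfg = SimConfig(coverage_dist=(60, 60), seed=51)
        events, _ = simulate_sample(ref, truth, cfg)
        calls, per_read = call_isoforms(mini_ensemble, events, ref,
                                        return_read_probabilities=True)
        assert {"read_id", "transcript_id", "position", "motif",
                "probability"} <= set(per_read.columns)
        assert per_read["probability"].between(0, 1).all()
        total = sum(c.coverage for c in calls)
        assert total == len(per_read)
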