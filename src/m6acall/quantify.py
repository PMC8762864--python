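"""Site-level m6A quantification from per-read probabilities.

At each RRACH centre A the per-read modification probabilities are
thresholded at 0.5 ("not less than 0.5" counts as modified), giving
Nm and Nu; the modification rate is Nm / (Nm + Nu).  Sites are tiered by
the published filter cascade:

* coverage < 50 reads            -> insufficient_coverage
* rate < 0.1                     -> below_baseline (background noise band)
* 0.1 <= rate <= 0.2             -> low_confidence
* rate > 0.2                     -> high_confidence

Tiers are computed from exact fractions, never from the rounded rate, so
boundary sites land on the intended side.  Sites are called independently
on each transcript isoform and projected to 1-based genome coordinates;
isoform calls sharing one genomic position stay separate rows sharing a
genomic key.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import enumerate_rrach
from .event_io import TranscriptModel, transcript_to_genome
from .model import EnsembleResults
from .training import WINDOW, extract_window_features

__all__ = [
    "TIER_HIGH",
    "TIER_LOW",
    "TIER_BELOW",
    "TIER_INSUFFICIENT",
    "SiteCall",
    "CandidateSite",
    "call_site",
    "scan_sites",
    "pool_replicates",
    "call_isoforms",
    "calls_to_frame",
    "tier_summary",
]

TIER_HIGH = "high_confidence"
TIER_LOW = "low_confidence"
TIER_BELOW = "below_baseline"
TIER_INSUFFICIENT = "insufficient_coverage"

MIN_COVERAGE = 50
BASELINE_RATE = 0.1
HIGH_CONF_RATE = 0.2
PROB_THRESHOLD = 0.5


@dataclass(frozen=True)
class CandidateSite:
    """An RRACH centre A with at least one window-spanning read."""

    transcript_id: str
    position: int
    motif: str
    coverage: int


@dataclass(frozen=True)
class SiteCall:
    """Per (isoform, position) modification call."""

    transcript_id: str
    position: int  # 0-based transcript coordinate of the centre A
    motif: str
    n_mod: int
    n_unmod: int
    rate: float
    tier: str
    chrom: str | None = None
    genome_pos: int | None = None  # 1-based
    strand: str | None = None
    gene_id: str | None = None

    @property
    def coverage(self) -> int:
        return self.n_mod + self.n_unmod

    @property
    def genomic_key(self) -> tuple[str, int, str] | None:
        if self.genome_pos is None:
            return None
        return (self.chrom, self.genome_pos, self.strand)


def call_site(
    probabilities: Sequence[float],
    min_coverage: int = MIN_COVERAGE,
    baseline: float = BASELINE_RATE,
    high_conf: float = HIGH_CONF_RATE,
    prob_threshold: float = PROB_THRESHOLD,
) -> tuple[int, int, float, str]:
    """Count Nm / Nu and tier one site.

    Nm counts probabilities >= ``prob_threshold`` (0.5 counted as
    modified), Nu the rest; rate = Nm / (Nm + Nu).  An empty probability
    vector has no defined rate and raises.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("cannot call a site from zero probabilities")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_mod = int((p >= prob_threshold).sum())
    n_unmod = int(p.size - n_mod)
    coverage = n_mod + n_unmod
    rate = n_mod / coverage
    if coverage < min_coverage:
        tier = TIER_INSUFFICIENT
    elif rate < baseline:
        tier = TIER_BELOW
    elif rate > high_conf:
        tier = TIER_HIGH
    else:
        tier = TIER_LOW
    return n_mod, n_unmod, rate, tier


def scan_sites(
    reference: Mapping[str, str],
    events: pd.DataFrame,
    window: int = WINDOW,
) -> list[CandidateSite]:
    """Every RRACH centre A with >= 1 read fully spanning the 5-mer window.

    Coverage counts reads whose event records cover all ``window``
    positions (gaps allowed here; gap-containing reads are excluded later
    at feature extraction).
    """
    half = window // 2
    candidates: list[CandidateSite] = []
    cov = (
        events.groupby(["transcript_id", "read_id"], observed=True)["position"]
        .agg(["min", "max"])
    )
    for tx, seq in reference.items():
        try:
            spans = cov.loc[tx]
        except KeyError:
            continue
        starts = spans["min"].to_numpy()
        ends = spans["max"].to_numpy()
        for centre, motif in enumerate_rrach(seq):
            n = int(((starts <= centre - half) & (ends >= centre + half)).sum())
            if n >= 1:
                candidates.append(CandidateSite(tx, centre, motif, n))
    return candidates


def pool_replicates(
    *event_tables: pd.DataFrame, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pool reads across replicates of one sample.

    Read ids are namespaced ``label:read_id`` so replicates cannot
    collide; a duplicated (label, read_id) pair raises.  The pooled total
    equals the sum of the inputs.
    """
    if labels is None:
        labels = [f"rep{i + 1}" for i in range(len(event_tables))]
    if len(labels) != len(event_tables):
        raise ValueError("one label per event table required")
    if len(set(labels)) != len(labels):
        raise ValueError("replicate labels must be unique")
    parts = []
    for label, tab in zip(labels, event_tables):
        t = tab.copy()
        t["read_id"] = label + ":" + t["read_id"].astype(str)
        parts.append(t)
    pooled = pd.concat(parts, ignore_index=True)
    dup = pooled.duplicated(subset=["read_id", "transcript_id", "position"])
    if dup.any():
        raise ValueError("duplicate (replicate, read_id) records after pooling")
    return pooled


def _project(
    call: SiteCall, annotation: Mapping[str, TranscriptModel] | None
) -> SiteCall:
    if annotation is None:
        return call
    tm = annotation.get(call.transcript_id)
    if tm is None:
        return call
    chrom, gpos, strand = transcript_to_genome(tm, call.position)
    return replace(call, chrom=chrom, genome_pos=gpos, strand=strand, gene_id=tm.gene_id)


def call_isoforms(
    results: EnsembleResults,
    events: pd.DataFrame,
    reference: Mapping[str, str],
    annotation: Mapping[str, TranscriptModel] | None = None,
    min_coverage: int = MIN_COVERAGE,
    baseline: float = BASELINE_RATE,
    high_conf: float = HIGH_CONF_RATE,
    prob_threshold: float = PROB_THRESHOLD,
    return_read_probabilities: bool = False,
):
    """Scan, predict and call every RRACH site independently per isoform.

    Sites whose motif has no sub-model are skipped (tallied via the
    prediction step).  With an annotation, calls are projected to 1-based
    genome coordinates; transcripts absent from the annotation keep a
    null genome coordinate rather than being dropped.

    Returns a list of :class:`SiteCall` (and, optionally, the per-read
    probability table with columns read_id, transcript_id, position,
    motif, probability).
    """
    candidates = scan_sites(reference, events, window=results.config_window())
    feats, _qc = extract_window_features(events, candidates, window=results.config_window())
    per_read = results.predict_events(feats)
    calls: list[SiteCall] = []
    for (tx, pos, motif), grp in per_read.groupby(
        ["transcript_id", "position", "motif"], observed=True, sort=True
    ):
        n_mod, n_unmod, rate, tier = call_site(
            grp["probability"].to_numpy(),
            min_coverage=min_coverage,
            baseline=baseline,
            high_conf=high_conf,
            prob_threshold=prob_threshold,
        )
        call = SiteCall(
            transcript_id=str(tx), position=int(pos), motif=str(motif),
            n_mod=n_mod, n_unmod=n_unmod, rate=rate, tier=tier,
        )
        calls.append(_project(call, annotation))
    if return_read_probabilities:
        cols = ["read_id", "transcript_id", "position", "motif", "probability"]
        return calls, per_read[cols]
    return calls


def calls_to_frame(calls: Iterable[SiteCall]) -> pd.DataFrame:
    """Site calls as a DataFrame (rates to full precision)."""
    rows = [
        {
            "transcript_id": c.transcript_id,
            "position": c.position,
            "motif": c.motif,
            "n_mod": c.n_mod,
            "n_unmod": c.n_unmod,
            "coverage": c.coverage,
            "rate": c.rate,
            "tier": c.tier,
            "chrom": c.chrom,
            "genome_pos": c.genome_pos,
            "strand": c.strand,
            "gene_id": c.gene_id,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)


def tier_summary(calls: Iterable[SiteCall]) -> dict[str, int]:
    """Counts per tier plus totals, for the run summary JSON."""
    summary = {
        "sites_called": 0,
        TIER_HIGH: 0,
        TIER_LOW: 0,
        TIER_BELOW: 0,
        TIER_INSUFFICIENT: 0,
    }
    for c in calls:
        summary["sites_called"] += 1
        summary[c.tier] += 1
    summary["passing_coverage"] = summary["sites_called"] - summary[TIER_INSUFFICIENT]
    summary["m6a_sites"] = summary[TIER_HIGH] + summary[TIER_LOW]
    return summary
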