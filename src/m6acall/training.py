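"""Construction of labeled training data from paired samples.

At each anchored candidate site the 11 nucleotides centred on the m6A
position (centre A +- 5 nt) form the *labeling region*.  Read fragments
fully spanning the region are labeled by their mismatch content:

* a fragment from the modified (wild-type-like) sample containing at
  least one mismatch anywhere in the region is a **modified** event;
* a fragment from the unmodified (methyltransferase-deficient) sample
  containing no mismatches is an **unmodified** event;
* every other combination is excluded from training.

For each labeled event the 5x5 feature matrix (window positions 5'->3' x
mean, median, sd, dwell, base quality) is taken from the RRACH 5-mer
window; fragments with a deletion gap inside the window are excluded and
tallied.  Events are partitioned by their RRACH 5-mer into at most 12
per-motif datasets and split 7:3 into training and testing partitions.

Deletion gaps count as mismatches for labeling: both are basecall-level
"errors" relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import AnchoredSite, RRACH_MOTIFS
from .event_io import EventRead

__all__ = [
    "REGION_FLANK",
    "WINDOW",
    "FEATURE_NAMES",
    "LabelingRegion",
    "MotifDataset",
    "BoundaryError",
    "extract_region",
    "label_fragment",
    "extract_features",
    "extract_labeled_events",
    "extract_window_features",
    "build_datasets",
    "expected_label_accuracy",
]

REGION_FLANK = 5  # nucleotides either side of the centre A
WINDOW = 5  # RRACH 5-mer window: centre A +- 2
FEATURE_NAMES = ("event_mean", "event_median", "event_sd", "dwell", "base_quality")

SampleSource = Literal["modified_sample", "unmodified_sample"]


class BoundaryError(ValueError):
    """Site too close to a transcript end for a full labeling region."""


@dataclass(frozen=True)
class LabelingRegion:
    """The 11-nt interval (centre A +- 5, half-open) used for labeling."""

    transcript_id: str
    center: int
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


def extract_region(
    transcript_id: str, center: int, transcript_length: int, flank: int = REGION_FLANK
) -> LabelingRegion:
    """Build the labeling region for a site, rejecting end-proximal sites.

    The centre must satisfy ``flank <= center <= length - flank - 1`` so
    the full region fits on the transcript.
    """
    if center < flank or center > transcript_length - flank - 1:
        raise BoundaryError(
            f"{transcript_id}:{center}: region [{center - flank}, {center + flank + 1}) "
            f"exceeds transcript of length {transcript_length}"
        )
    return LabelingRegion(transcript_id, center, center - flank, center + flank + 1)


def label_fragment(
    read: EventRead, region: LabelingRegion, source: SampleSource
) -> str | None:
    """Label one read fragment by mismatch content of the labeling region.

    Returns "modified", "unmodified", or None (excluded).  The read must
    fully span the region; substitutions and deletion gaps both count as
    mismatches.
    """
    s, e = read.span
    if read.transcript_id != region.transcript_id or s > region.start or e < region.end:
        return None
    flags = read.flags[region.start - s : region.end - s]
    n_err = int(np.isin(flags, ("mismatch", "gap")).sum())
    if source == "modified_sample":
        return "modified" if n_err >= 1 else None
    if source == "unmodified_sample":
        return "unmodified" if n_err == 0 else None
    raise ValueError(f"unknown sample source {source!r}")


def extract_features(read: EventRead, center: int, window: int = WINDOW) -> np.ndarray:
    """Copy the window feature matrix for one read at one site.

    Rows are window positions 5'->3' (centre A +- window//2), columns the
    fixed feature order (mean, median, sd, dwell, quality).  Raises
    ValueError when the read does not span the window or a gap falls
    inside it.
    """
    half = window // 2
    w0, w1 = center - half, center + half + 1
    s, e = read.span
    if s > w0 or e < w1:
        raise ValueError("read does not span the feature window")
    sl = slice(w0 - s, w1 - s)
    if (read.flags[sl] == "gap").any():
        raise ValueError("gap inside the feature window")
    return read.features[sl].copy()


def _feature_columns(window: int = WINDOW) -> list[str]:
    half = window // 2
    return [
        f"{feat}@{off:+d}"
        for off in range(-half, half + 1)
        for feat in FEATURE_NAMES
    ]


def extract_labeled_events(
    events: pd.DataFrame,
    sites: Sequence[AnchoredSite],
    source: SampleSource,
    transcript_lengths: Mapping[str, int],
    window: int = WINDOW,
    flank: int = REGION_FLANK,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorised labeling + feature extraction over an event table.

    Returns
    -------
    (table, qc)
        ``table``: one row per labeled event with columns transcript_id,
        position, motif, read_id, label and the 25 flattened feature
        columns (position-major, 5'->3').
        ``qc``: exclusion tallies; events in = events labeled + excluded.
    """
    qc = {
        "input_pairs": 0,
        "site_out_of_bounds": 0,
        "not_spanning_region": 0,
        "label_excluded": 0,
        "gap_in_window": 0,
        "labeled": 0,
    }
    half = window // 2
    by_tx: dict[str, pd.DataFrame] = {
        str(tx): grp for tx, grp in events.groupby("transcript_id", observed=True)
    }
    rows: list[pd.DataFrame] = []
    feat_cols = _feature_columns(window)
    for site in sites:
        length = transcript_lengths[site.transcript_id]
        try:
            region = extract_region(site.transcript_id, site.position, length, flank)
        except BoundaryError:
            qc["site_out_of_bounds"] += 1
            continue
        sub = by_tx.get(site.transcript_id)
        if sub is None:
            continue
        reg = sub[(sub["position"] >= region.start) & (sub["position"] < region.end)]
        if reg.empty:
            continue
        flag_piv = reg.pivot_table(
            index="read_id", columns="position", values="match_flag",
            aggfunc="first", observed=True,
        ).reindex(columns=range(region.start, region.end))
        n_reads_at_site = flag_piv.shape[0]
        qc["input_pairs"] += n_reads_at_site
        spanning = flag_piv.notna().all(axis=1)
        qc["not_spanning_region"] += int((~spanning).sum())
        flag_piv = flag_piv[spanning]
        if flag_piv.empty:
            continue
        is_err = flag_piv.isin(("mismatch", "gap")).to_numpy()
        n_err = is_err.sum(axis=1)
        if source == "modified_sample":
            keep_label = n_err >= 1
            label = "modified"
        else:
            keep_label = n_err == 0
            label = "unmodified"
        qc["label_excluded"] += int((~keep_label).sum())
        labeled_reads = flag_piv.index[keep_label]
        if len(labeled_reads) == 0:
            continue
        # feature window: no gaps allowed
        w0, w1 = site.position - half, site.position + half + 1
        win_flags = flag_piv.loc[labeled_reads, range(w0, w1)]
        no_gap = ~(win_flags == "gap").any(axis=1)
        qc["gap_in_window"] += int((~no_gap).sum())
        final_reads = labeled_reads[no_gap.to_numpy()]
        if len(final_reads) == 0:
            continue
        win = reg[(reg["position"] >= w0) & (reg["position"] < w1)]
        feat_piv = win.pivot_table(
            index="read_id", columns="position",
            values=list(FEATURE_NAMES), aggfunc="first", observed=True,
        ).reindex(index=final_reads)
        # arrange position-major, feature-minor
        mat = np.empty((len(final_reads), window * len(FEATURE_NAMES)))
        for i, pos in enumerate(range(w0, w1)):
            for j, feat in enumerate(FEATURE_NAMES):
                mat[:, i * len(FEATURE_NAMES) + j] = feat_piv[(feat, pos)].to_numpy()
        block = pd.DataFrame(mat, columns=feat_cols)
        block.insert(0, "label", label)
        block.insert(0, "read_id", np.asarray(final_reads))
        block.insert(0, "motif", site.motif)
        block.insert(0, "position", site.position)
        block.insert(0, "transcript_id", site.transcript_id)
        qc["labeled"] += len(block)
        rows.append(block)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["transcript_id", "position", "motif", "read_id", "label", *feat_cols]
        )
    return table, qc


def extract_window_features(
    events: pd.DataFrame,
    sites: Sequence,
    window: int = WINDOW,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Window feature matrices for *all* spanning reads at each site.

    Prediction-side counterpart of :func:`extract_labeled_events`: no
    mismatch labeling, only the spanning / gap-free requirements of the
    5-mer window.  ``sites`` need transcript_id, position and motif
    attributes.  Reads partially spanning the window, or with a gap in it,
    are excluded and tallied — they do not count toward site coverage.
    """
    qc = {"input_pairs": 0, "not_spanning_window": 0, "gap_in_window": 0, "kept": 0}
    half = window // 2
    by_tx: dict[str, pd.DataFrame] = {
        str(tx): grp for tx, grp in events.groupby("transcript_id", observed=True)
    }
    feat_cols = _feature_columns(window)
    rows: list[pd.DataFrame] = []
    for site in sites:
        sub = by_tx.get(site.transcript_id)
        if sub is None:
            continue
        w0, w1 = site.position - half, site.position + half + 1
        win = sub[(sub["position"] >= w0) & (sub["position"] < w1)]
        if win.empty:
            continue
        flag_piv = win.pivot_table(
            index="read_id", columns="position", values="match_flag",
            aggfunc="first", observed=True,
        ).reindex(columns=range(w0, w1))
        qc["input_pairs"] += flag_piv.shape[0]
        spanning = flag_piv.notna().all(axis=1)
        qc["not_spanning_window"] += int((~spanning).sum())
        no_gap = spanning & ~(flag_piv == "gap").any(axis=1)
        qc["gap_in_window"] += int((spanning & ~no_gap).sum())
        keep = flag_piv.index[no_gap]
        if len(keep) == 0:
            continue
        feat_piv = win.pivot_table(
            index="read_id", columns="position",
            values=list(FEATURE_NAMES), aggfunc="first", observed=True,
        ).reindex(index=keep)
        mat = np.empty((len(keep), window * len(FEATURE_NAMES)))
        for i, pos in enumerate(range(w0, w1)):
            for j, feat in enumerate(FEATURE_NAMES):
                mat[:, i * len(FEATURE_NAMES) + j] = feat_piv[(feat, pos)].to_numpy()
        block = pd.DataFrame(mat, columns=feat_cols)
        block.insert(0, "read_id", np.asarray(keep))
        block.insert(0, "motif", site.motif)
        block.insert(0, "position", site.position)
        block.insert(0, "transcript_id", site.transcript_id)
        qc["kept"] += len(block)
        rows.append(block)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["transcript_id", "position", "motif", "read_id", *feat_cols]
        )
    return table, qc


@dataclass
class MotifDataset:
    """Train/test partitions of labeled events for one RRACH 5-mer.

    ``X_*`` are (n, window, 5) feature tensors, ``y_*`` binary labels
    (1 = modified).  ``trainable`` is False when either partition lacks a
    class.
    """

    motif: str
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    ratio: float
    trainable: bool

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    @property
    def n_test(self) -> int:
        return len(self.y_test)


def build_datasets(
    labeled: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    window: int = WINDOW,
) -> dict[str, MotifDataset]:
    """Partition labeled events by motif and split 7:3 within each.

    Events are shuffled with a per-motif child seed before the split, so
    the same seed reproduces identical partitions.  Event counts are
    conserved: per motif, n_train + n_test equals the input count.
    Motifs outside the 12-pattern consensus raise (upstream bug).
    """
    bad = set(labeled["motif"].unique()) - set(RRACH_MOTIFS)
    if bad:
        raise ValueError(f"motif(s) outside the RRACH consensus: {sorted(bad)}")
    feat_cols = _feature_columns(window)
    datasets: dict[str, MotifDataset] = {}
    ss = np.random.SeedSequence(seed)
    motifs = sorted(labeled["motif"].unique())
    children = ss.spawn(len(motifs))
    for motif, child in zip(motifs, children):
        grp = labeled[labeled["motif"] == motif]
        X = grp[feat_cols].to_numpy(dtype=float).reshape(-1, window, len(FEATURE_NAMES))
        y = (grp["label"] == "modified").to_numpy(dtype=np.int64)
        rng = np.random.default_rng(child)
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        n_train = int(round(ratio * len(y)))
        ds = MotifDataset(
            motif=motif,
            X_train=X[:n_train],
            y_train=y[:n_train],
            X_test=X[n_train:],
            y_test=y[n_train:],
            ratio=ratio,
            trainable=(len(np.unique(y[:n_train])) == 2 and len(np.unique(y[n_train:])) == 2),
        )
        datasets[motif] = ds
    return datasets


def expected_label_accuracy(
    true_rate: float,
    mismatch_prob_modified: float,
    mismatch_prob_unmodified: float,
    region_width: int = 2 * REGION_FLANK + 1,
) -> float:
    """Closed-form agreement between mismatch labels and latent status.

    For a modified-sample read the positive label fires when >=1 of the
    ``region_width`` positions mismatches.  Among reads that *are* labeled
    positive, the probability the read is truly modified follows from the
    two Bernoulli mismatch rates and the site stoichiometry — this is the
    accuracy ceiling of mismatch-based labeling.
    """
    p_pos_mod = 1.0 - (1.0 - mismatch_prob_modified) ** region_width
    p_pos_unmod = 1.0 - (1.0 - mismatch_prob_unmodified) ** region_width
    num = true_rate * p_pos_mod
    den = num + (1.0 - true_rate) * p_pos_unmod
    return num / den if den > 0 else float("nan")
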