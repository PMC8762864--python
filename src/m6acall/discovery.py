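"""Candidate m6A site discovery from differential base-calling errors.

Methyltransferase-deficient samples lose the systematic base-calling
"errors" that m6A induces in direct RNA-Seq reads.  Comparing per-position
mismatch rates between a modified and an unmodified sample therefore
highlights positions near modified bases; those positions are then anchored
to the centre A of the nearest RRACH 5-mer (R = A/G, H = A/C/U), the
substrate consensus of the plant and metazoan m6A writer complex.

The differential test here is a per-position 2x2 G-test with
Benjamini-Hochberg correction.  It is a deliberately simple stand-in for
replicate-aware differential-error tools; it exists so the downstream
pipeline has an anchor-site source that runs on the in-repo event tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RRACH_MOTIFS",
    "rrach_motifs",
    "is_rrach",
    "enumerate_rrach",
    "differential_error_test",
    "anchor_to_rrach",
    "AnchoredSite",
]

_R = "AG"
_H = "ACT"
_RRACH_RE = re.compile(r"(?=([AG][AG]AC[ACT]))")

#: The 12 five-mers matching the RRACH consensus (T written for U).
RRACH_MOTIFS: tuple[str, ...] = tuple(
    sorted(f"{r1}{r2}AC{h}" for r1, r2, h in product(_R, _R, _H))
)


def rrach_motifs() -> tuple[str, ...]:
    """Return the 12 five-mers matching the RRACH consensus."""
    return RRACH_MOTIFS


def is_rrach(kmer: str) -> bool:
    """True when a 5-mer matches the RRACH consensus (U accepted for T)."""
    return _RRACH_RE.match(kmer.upper().replace("U", "T")) is not None and len(kmer) == 5


def enumerate_rrach(sequence: str) -> list[tuple[int, str]]:
    """Find every RRACH occurrence in ``sequence``.

    Parameters
    ----------
    sequence
        Transcript sequence over {A, C, G, U/T}; case-insensitive.

    Returns
    -------
    list of (center_position, motif)
        0-based position of the centre A (motif start + 2) and the 5-mer
        written with T.  Overlapping occurrences are all reported.
    """
    seq = sequence.upper().replace("U", "T")
    return [(m.start() + 2, m.group(1)) for m in _RRACH_RE.finditer(seq)]


@dataclass(frozen=True)
class AnchoredSite:
    """A candidate m6A site: an RRACH centre A supported by nearby
    differential-error positions (all within the anchoring distance)."""

    transcript_id: str
    position: int  # 0-based centre A
    motif: str
    supports: tuple[int, ...] = field(default_factory=tuple)  # diff positions
    distances: tuple[int, ...] = field(default_factory=tuple)  # support - centre

    def __post_init__(self) -> None:
        if not is_rrach(self.motif):
            raise ValueError(f"motif {self.motif!r} does not match RRACH")


def _mismatch_match_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Per (transcript, position) mismatch/match counts.

    Substitutions and deletion gaps both count as mismatches; the event
    table has no insertion rows.
    """
    mm = events["match_flag"].isin(("mismatch", "gap"))
    tab = (
        pd.DataFrame(
            {
                "transcript_id": events["transcript_id"].to_numpy(),
                "position": events["position"].to_numpy(),
                "mismatch": mm.to_numpy().astype(np.int64),
            }
        )
        .groupby(["transcript_id", "position"], observed=True)["mismatch"]
        .agg(["sum", "count"])
    )
    tab.columns = ["mismatch", "total"]
    tab["match"] = tab["total"] - tab["mismatch"]
    return tab


def _g_statistic(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorised 2x2 log-likelihood-ratio (G) statistic.

    Cells: [[a, b], [c, d]] with zero cells contributing 0 to the sum.
    """
    cells = np.stack([a, b, c, d], axis=0).astype(float)
    n = cells.sum(axis=0)
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    expected = np.stack(
        [row1 * col1, row1 * col2, row2 * col1, row2 * col2], axis=0
    ) / np.where(n > 0, n, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = cells * np.log(cells / expected)
    terms[cells == 0] = 0.0
    terms[~np.isfinite(terms)] = 0.0
    return 2.0 * terms.sum(axis=0)


def differential_error_test(
    modified_events: pd.DataFrame,
    unmodified_events: pd.DataFrame,
    min_coverage: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each reference position for excess mismatches in the modified sample.

    Positions covered by at least ``min_coverage`` reads in *both* samples
    enter a 2x2 G-test (mismatch vs match x sample); p-values are
    Benjamini-Hochberg adjusted across all tested positions.  Only positions
    with q < ``alpha`` and a *higher* mismatch rate in the modified sample
    are returned.

    Returns
    -------
    pandas.DataFrame
        Columns: transcript_id, position, mismatch_mod, match_mod,
        mismatch_unmod, match_unmod, g_stat, p_value, q_value; sorted by
        (transcript_id, position).
    """
    mod = _mismatch_match_counts(modified_events)
    unm = _mismatch_match_counts(unmodified_events)
    joined = mod.join(unm, how="inner", lsuffix="_mod", rsuffix="_unmod")
    joined = joined[
        (joined["total_mod"] >= min_coverage) & (joined["total_unmod"] >= min_coverage)
    ]
    if joined.empty:
        warnings.warn("no positions met the coverage requirement in both samples")
        return pd.DataFrame(
            columns=[
                "transcript_id", "position", "mismatch_mod", "match_mod",
                "mismatch_unmod", "match_unmod", "g_stat", "p_value", "q_value",
            ]
        )
    a = joined["mismatch_mod"].to_numpy()
    b = joined["match_mod"].to_numpy()
    c = joined["mismatch_unmod"].to_numpy()
    d = joined["match_unmod"].to_numpy()
    g = _g_statistic(a, b, c, d)
    p = stats.chi2.sf(g, df=1)
    q = stats.false_discovery_control(p, method="bh")
    rate_mod = a / (a + b)
    rate_unmod = c / (c + d)
    keep = (q < alpha) & (rate_mod > rate_unmod)
    out = joined.reset_index()[
        ["transcript_id", "position", "mismatch_mod", "match_mod",
         "mismatch_unmod", "match_unmod"]
    ].copy()
    out["g_stat"] = g
    out["p_value"] = p
    out["q_value"] = q
    out = out[keep].sort_values(["transcript_id", "position"]).reset_index(drop=True)
    return out


def anchor_to_rrach(
    diff_sites: pd.DataFrame | Iterable[tuple[str, int]],
    rrach_index: Mapping[str, Sequence[tuple[int, str]]],
    max_distance: int = 5,
) -> list[AnchoredSite]:
    """Assign differential-error positions to the nearest RRACH centre A.

    Each differential position is paired with the nearest centre A on its
    transcript (ties broken toward the 5' centre); assignments farther than
    ``max_distance`` nucleotides are discarded.  Positions anchored to the
    same centre are merged into one :class:`AnchoredSite`.

    Parameters
    ----------
    diff_sites
        Output of :func:`differential_error_test`, or an iterable of
        (transcript_id, position) pairs.
    rrach_index
        Mapping transcript_id -> list of (centre position, motif) from
        :func:`enumerate_rrach` on the same reference.
    """
    if isinstance(diff_sites, pd.DataFrame):
        pairs = list(zip(diff_sites["transcript_id"], diff_sites["position"]))
    else:
        pairs = [(t, int(p)) for t, p in diff_sites]

    grouped: dict[tuple[str, int], tuple[str, list[int]]] = {}
    for transcript_id, pos in pairs:
        centres = rrach_index.get(transcript_id)
        if not centres:
            continue
        # nearest centre; ties -> smaller (5') position
        best = min(centres, key=lambda cm: (abs(cm[0] - pos), cm[0]))
        centre, motif = best
        if abs(centre - pos) > max_distance:
            continue
        key = (transcript_id, centre)
        grouped.setdefault(key, (motif, []))[1].append(int(pos))

    sites = []
    for (transcript_id, centre), (motif, supports) in sorted(grouped.items()):
        supports = sorted(set(supports))
        sites.append(
            AnchoredSite(
                transcript_id=transcript_id,
                position=centre,
                motif=motif,
                supports=tuple(supports),
                distances=tuple(s - centre for s in supports),
            )
        )
    return sites
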