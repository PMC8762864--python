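"""Synthetic direct RNA-Seq event-table generator with known stoichiometry.

Emulates the phenomenology that makes m6A visible in nanopore direct
RNA-Seq: at a modified RRACH centre A the ionic-current level shifts by a
few pA (with a decaying effect on immediate neighbours), dwell time
lengthens, base quality drops, and basecalls within ~5 nt of the site are
enriched for mismatches.  Unmodified reads follow the baseline 5-mer level
model.  Per-read latent modification flags are drawn Bernoulli(true_rate)
per site and returned in a separate truth table, never written into the
event table the pipeline consumes.

The generator emulates the *statistical structure* of in vivo data
(per-site stoichiometry, modification-conditional signal and mismatch
distributions, coverage ranges); it does not model raw squiggles,
basecaller error profiles beyond per-position mismatch flags, or clustered
multi-site interference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import RRACH_MOTIFS, is_rrach
from .event_io import EVENT_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlacementError",
    "default_kmer_level",
    "make_reference",
    "simulate_sample",
    "null_config",
]

_BASES = "ACGT"
_CENTER_LEVEL = {"A": 100.0, "C": 96.0, "G": 104.0, "T": 92.0}
_CTX_VALUE = {"A": 0.3, "C": -0.3, "G": 0.5, "T": -0.5}
_CTX_WEIGHT = {-2: 0.3, -1: 0.6, 1: 0.6, 2: 0.3}
_BASE_SD = 1.5

#: Mismatch probability per position (equal in both classes) that makes a
#: >=1-mismatch label over an 11-nt region a fair coin: 1 - 0.5**(1/11).
_NULL_MISMATCH = 1.0 - 0.5 ** (1.0 / 11.0)


class PlacementError(ValueError):
    """Too many sites requested for the transcript length."""


def default_kmer_level(kmer: str) -> tuple[float, float]:
    """Baseline (current mean pA, sd pA) for a 5-mer.

    Deterministic: the centre base sets the level, flanking bases add small
    position-weighted offsets (< ~1 pA total), emulating sequence-dependent
    pore current without a measured pore model.
    """
    centre = kmer[2]
    level = _CENTER_LEVEL[centre]
    for off, w in _CTX_WEIGHT.items():
        level += w * _CTX_VALUE[kmer[2 + off]]
    return (level, _BASE_SD)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one planted site: location, motif, stoichiometry."""

    transcript_id: str
    position: int  # 0-based centre A
    motif: str
    true_rate: float

    def __post_init__(self) -> None:
        if not is_rrach(self.motif):
            raise ValueError(f"motif {self.motif!r} does not match RRACH")
        if not 0.0 <= self.true_rate <= 1.0:
            raise ValueError("true_rate outside [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated sample.

    Modified/unmodified parameter pairs are ordered (modified, unmodified).
    Dwell is log-normal in arbitrary time units; quality is a clipped
    normal on a Phred-like scale; ``mismatch_prob`` applies per position
    within the 11-nt labeling region of a modified read (unmodified
    probability applies everywhere else and to unmodified reads).
    """

    kmer_level_table: Mapping[str, tuple[float, float]] | None = None
    mod_shift: float = 4.5  # pA added at a modified centre A
    neighbor_fracs: tuple[float, float] = (0.5, 0.25)  # fraction of shift at +-1, +-2
    dwell_params: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 0.35), (0.0, 0.35))
    qual_params: tuple[tuple[float, float], tuple[float, float]] = ((8.5, 2.5), (12.0, 2.5))
    mismatch_prob: tuple[float, float] = (0.12, 0.01)
    coverage_dist: tuple[int, int] = (180, 260)
    gap_prob: float = 0.004
    median_jitter: float = 0.4
    sd_jitter: float = 0.15
    truncate_prob: float = 0.05
    region_flank: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for mu, sigma in self.dwell_params:
            if sigma <= 0:
                raise ValueError("dwell sigma must be > 0")
        for mean, sd in self.qual_params:
            if sd <= 0:
                raise ValueError("quality sd must be > 0")
        for p in (*self.mismatch_prob, self.gap_prob, self.truncate_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.coverage_dist
        if not (0 <= lo <= hi):
            raise ValueError("invalid coverage_dist")

    def levels_for(self, kmer: str) -> tuple[float, float]:
        if self.kmer_level_table is not None:
            return self.kmer_level_table[kmer]
        return default_kmer_level(kmer)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A zero-effect configuration: modified and unmodified classes share
    every parameter, and the per-position mismatch probability makes the
    11-nt >=1-mismatch label a fair coin."""
    base = dict(
        mod_shift=0.0,
        dwell_params=((0.0, 0.35), (0.0, 0.35)),
        qual_params=((12.0, 2.5), (12.0, 2.5)),
        mismatch_prob=(_NULL_MISMATCH, _NULL_MISMATCH),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def make_reference(
    n_transcripts: int,
    length: int,
    sites_per_transcript: int,
    seed: int,
    motifs: Sequence[str] | None = None,
    rates: Sequence[float] | None = None,
) -> tuple[dict[str, str], list[SimTruth]]:
    """Generate random transcript sequences with planted RRACH sites.

    Sites are placed on an even grid with >= 11 nt separation and at least
    5 nt clearance from both transcript ends.  ``motifs`` and ``rates``
    cycle over the global site index when given; otherwise the motif is
    drawn uniformly from the 12 RRACH 5-mers and the rate uniformly from
    the grid {0.0, 0.1, ..., 0.9}.

    Deterministic under a fixed seed.
    """
    if n_transcripts == 0:
        return {}, []
    if length < 200:
        raise ValueError("transcript length must be >= 200")
    if sites_per_transcript < 1:
        raise ValueError("sites_per_transcript must be >= 1")
    margin = 20
    spacing = (length - 2 * margin) / sites_per_transcript
    if spacing < 16:
        raise PlacementError(
            f"cannot place {sites_per_transcript} sites >=11 nt apart on "
            f"{length} nt with {margin} nt end margins"
        )
    rng = np.random.default_rng(seed)
    rate_grid = np.round(np.arange(0.0, 1.0, 0.1), 1)
    sequences: dict[str, str] = {}
    truth: list[SimTruth] = []
    site_index = 0
    for t in range(n_transcripts):
        name = f"tx{t:04d}"
        seq = rng.choice(list(_BASES), size=length)
        for j in range(sites_per_transcript):
            centre = int(margin + spacing * (j + 0.5))
            if motifs is not None:
                motif = motifs[site_index % len(motifs)]
            else:
                motif = RRACH_MOTIFS[rng.integers(len(RRACH_MOTIFS))]
            if rates is not None:
                rate = float(rates[site_index % len(rates)])
            else:
                rate = float(rate_grid[rng.integers(len(rate_grid))])
            seq[centre - 2 : centre + 3] = list(motif)
            truth.append(SimTruth(name, centre, motif, rate))
            site_index += 1
        planted = {t.position for t in truth if t.transcript_id == name}
        _scrub_chance_rrach(seq, planted, rng)
        sequences[name] = "".join(seq)
    return sequences, truth


def _scrub_chance_rrach(seq: np.ndarray, planted_centres: set[int],
                        rng: np.random.Generator, max_rounds: int = 50) -> None:
    """Mutate away RRACH occurrences that were not planted, in place.

    The reference contract is that transcripts contain *exactly* the
    planted sites, so chance occurrences (which would contaminate anchor
    sets and background scans) are disrupted by flipping one base outside
    every planted 5-mer footprint.  Iterates because a flip can create a
    new occurrence.
    """
    from .discovery import enumerate_rrach

    protected = set()
    for c in planted_centres:
        protected.update(range(c - 2, c + 3))
    for _ in range(max_rounds):
        chance = [
            c for c, _m in enumerate_rrach("".join(seq))
            if c not in planted_centres
        ]
        if not chance:
            return
        for c in chance:
            candidates = [p for p in range(c - 2, c + 3) if p not in protected]
            if not candidates:  # fully inside a planted footprint: impossible
                continue
            p = candidates[rng.integers(len(candidates))]
            # C breaks both R slots and the centre A; keeps composition simple
            seq[p] = "C" if seq[p] != "C" else "T"
    raise RuntimeError("failed to scrub chance RRACH occurrences")


def _position_levels(seq: str, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    padded = "AA" + seq + "AA"
    means = np.empty(len(seq))
    sds = np.empty(len(seq))
    for i in range(len(seq)):
        means[i], sds[i] = cfg.levels_for(padded[i : i + 5])
    return means, sds


def simulate_sample(
    reference: Mapping[str, str],
    truth: Sequence[SimTruth],
    cfg: SimConfig,
    modified_fraction_override: float | None = None,
    seed: int | None = None,
    read_prefix: str = "r",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one sample's event table over a reference.

    For every read and every planted site the read spans, a latent
    modified flag is drawn Bernoulli(true_rate) (or the override).
    Modified reads receive the configured signal shift (decaying into
    +-2 neighbours), centre-position dwell and quality effects, and
    elevated mismatch probability within centre +- ``region_flank``.

    Returns
    -------
    (events, latent)
        ``events``: long event-table DataFrame (dialect columns).
        ``latent``: per (read, site) truth with columns read_id,
        transcript_id, site_position, modified — kept separate from the
        event table to avoid label leakage.
    """
    for site in truth:
        if site.transcript_id not in reference:
            raise ValueError(f"truth site on unknown transcript {site.transcript_id!r}")
        seq = reference[site.transcript_id]
        if not 0 <= site.position < len(seq):
            raise ValueError(f"truth site position {site.position} outside transcript")

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    (dw_mu_m, dw_sig_m), (dw_mu_u, dw_sig_u) = cfg.dwell_params
    (q_mean_m, q_sd_m), (q_mean_u, q_sd_u) = cfg.qual_params
    mm_m, mm_u = cfg.mismatch_prob
    fracs = np.array([cfg.neighbor_fracs[1], cfg.neighbor_fracs[0], 1.0,
                      cfg.neighbor_fracs[0], cfg.neighbor_fracs[1]])

    sites_by_tx: dict[str, list[SimTruth]] = {}
    for site in truth:
        sites_by_tx.setdefault(site.transcript_id, []).append(site)

    event_parts: list[pd.DataFrame] = []
    latent_parts: list[pd.DataFrame] = []
    for tx, seq in reference.items():
        L = len(seq)
        base_mean, base_sd = _position_levels(seq, cfg)
        lo, hi = cfg.coverage_dist
        n_reads = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        if n_reads == 0:
            continue
        read_ids = np.array([f"{read_prefix}_{tx}_{i:05d}" for i in range(n_reads)])
        starts = np.zeros(n_reads, dtype=int)
        truncated = rng.random(n_reads) < cfg.truncate_prob
        if truncated.any():
            starts[truncated] = rng.integers(1, max(2, L // 2), size=truncated.sum())

        tx_sites = sites_by_tx.get(tx, [])
        shift = np.zeros((n_reads, L))
        mism_p = np.full((n_reads, L), mm_u)
        latent_flags = np.zeros((n_reads, len(tx_sites)), dtype=bool)
        for j, site in enumerate(tx_sites):
            p = site.true_rate if modified_fraction_override is None else modified_fraction_override
            flags = rng.random(n_reads) < p
            latent_flags[:, j] = flags
            c = site.position
            w0, w1 = max(0, c - 2), min(L, c + 3)
            prof = fracs[(w0 - (c - 2)) : (w0 - (c - 2)) + (w1 - w0)] * cfg.mod_shift
            shift[flags, w0:w1] += prof
            r0, r1 = max(0, c - cfg.region_flank), min(L, c + cfg.region_flank + 1)
            mism_p[flags, r0:r1] = mm_m

        latent_level = base_mean + shift + rng.normal(0.0, base_sd, size=(n_reads, L))
        means = latent_level
        medians = latent_level + rng.normal(0.0, cfg.median_jitter, size=(n_reads, L))
        sds = np.abs(rng.normal(base_sd, cfg.sd_jitter, size=(n_reads, L)))
        dwell = rng.lognormal(dw_mu_u, dw_sig_u, size=(n_reads, L))
        quality = rng.normal(q_mean_u, q_sd_u, size=(n_reads, L))
        for j, site in enumerate(tx_sites):
            rows = latent_flags[:, j]
            k = int(rows.sum())
            if k:
                c = site.position
                dwell[rows, c] = rng.lognormal(dw_mu_m, dw_sig_m, size=k)
                quality[rows, c] = rng.normal(q_mean_m, q_sd_m, size=k)
        quality = np.clip(quality, 1.0, 40.0)
        mismatch = rng.random((n_reads, L)) < mism_p
        gap = rng.random((n_reads, L)) < cfg.gap_prob

        flags_arr = np.where(gap, "gap", np.where(mismatch, "mismatch", "match"))
        for arr in (means, medians, sds, dwell, quality):
            arr[gap] = 0.0

        covered = np.arange(L)[None, :] >= starts[:, None]
        n_per_read = covered.sum(axis=1)
        rows_read = np.repeat(read_ids, n_per_read)
        pos_grid = np.broadcast_to(np.arange(L), (n_reads, L))
        event_parts.append(
            pd.DataFrame(
                {
                    "read_id": rows_read,
                    "transcript_id": np.repeat(tx, n_per_read.sum()),
                    "position": pos_grid[covered],
                    "event_mean": means[covered],
                    "event_median": medians[covered],
                    "event_sd": sds[covered],
                    "dwell": dwell[covered],
                    "base_quality": quality[covered],
                    "match_flag": flags_arr[covered],
                }
            )
        )
        if tx_sites:
            latent_parts.append(
                pd.DataFrame(
                    {
                        "read_id": np.tile(read_ids, len(tx_sites)),
                        "transcript_id": tx,
                        "site_position": np.repeat(
                            [s.position for s in tx_sites], n_reads
                        ),
                        "modified": latent_flags.T.ravel(),
                    }
                )
            )

    if event_parts:
        events = pd.concat(event_parts, ignore_index=True)
    else:
        events = pd.DataFrame(columns=list(EVENT_COLUMNS))
    if latent_parts:
        latent = pd.concat(latent_parts, ignore_index=True)
    else:
        latent = pd.DataFrame(columns=["read_id", "transcript_id", "site_position", "modified"])
    return events, latent
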