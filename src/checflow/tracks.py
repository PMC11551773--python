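"""Per-base signal tracks: BedGraph I/O, normalization, z-scoring, meta-profiles.

Tracks are dense per-base float arrays (yeast-scale genomes fit trivially in
memory).  BedGraph runs are expanded on read and re-compressed on write;
values round-trip at full precision via ``repr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_TRACK_TOTAL = 1e7  # counts per 10 million (CPtM)


@dataclass
class SignalTrack:
    """Per-chromosome, per-base signal with a declared normalization total."""

    data: dict[str, np.ndarray]
    declared_total: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def copy(self) -> "SignalTrack":
        return SignalTrack({c: v.copy() for c, v in self.data.items()},
                           self.declared_total, dict(self.metadata))

    def scaled(self, factor: float) -> "SignalTrack":
        out = self.copy()
        for v in out.data.values():
            v *= factor
        if out.declared_total is not None:
            out.declared_total *= factor
        return out


def normalize_track(track: SignalTrack, total: float = DEFAULT_TRACK_TOTAL) -> SignalTrack:
    """Scale the track so its genome-wide sum equals ``total``.

    The convention is counts per 10 million (total = 1e7) for cut-site
    tracks.  Raises on an all-zero track (empty sample).
    """
    s = track.total()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero track (empty sample?)")
    out = track.scaled(total / s)
    out.declared_total = float(total)
    return out


def genomewide_zscore(track: SignalTrack) -> SignalTrack:
    """Z-score the signal across the entire genome (sample SD, ddof=1)."""
    flat = np.concatenate([v for v in track.data.values()])
    mu = flat.mean()
    sd = flat.std(ddof=1)
    if sd == 0:
        raise ValueError("constant track: genome-wide z-score undefined")
    out = track.copy()
    for c in out.data:
        out.data[c] = (out.data[c] - mu) / sd
    out.declared_total = None
    out.metadata["zscored"] = True
    return out


def rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with truncated windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(values)
    half_l = (window - 1) // 2
    half_r = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class MetaProfile:
    """Mean signal around a set of anchors, symmetric about offset 0."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_anchors: int
    smooth_window: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# offset_bp\tmean_signal\n")
            for o, m in zip(self.offsets, self.mean_signal):
                fh.write(f"{o}\t{m!r}\n")


def meta_profile(
    track: SignalTrack,
    anchors: Sequence[Mapping],
    flank: int,
    smooth_window: int = 5,
) -> MetaProfile:
    """Average the signal in ±``flank`` bp around anchors, then smooth.

    Anchors are mappings with keys ``chrom``, ``center`` and ``strand``;
    minus-strand anchors are reversed so that positive offsets point
    downstream of the anchor.  Anchors within ``flank`` of a chromosome
    end are dropped (logged).  The per-offset mean is smoothed with a
    centered rolling mean of width ``smooth_window``.
    """
    rows = []
    dropped = 0
    for a in anchors:
        chrom, center, strand = a["chrom"], int(a["center"]), a.get("strand", "+")
        arr = track.data[chrom]
        if center - flank < 0 or center + flank + 1 > len(arr):
            dropped += 1
            continue
        window = arr[center - flank: center + flank + 1]
        rows.append(window[::-1] if strand == "-" else window)
    if dropped:
        log.info("meta_profile: dropped %d/%d anchors near chromosome bounds", dropped, len(anchors))
    if not rows:
        raise ValueError("no usable anchors for meta profile")
    mean = np.vstack(rows).mean(axis=0)
    smoothed = rolling_mean(mean, smooth_window)
    offsets = np.arange(-flank, flank + 1)
    return MetaProfile(offsets, smoothed, n_anchors=len(rows), smooth_window=smooth_window)


# ---------------------------------------------------------------------------
# BedGraph I/O (0-based half-open)


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> SignalTrack:
    data = {c: np.zeros(L, dtype=float) for c, L in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            chrom, start, end, value = line.split()
            data[chrom][int(start):int(end)] = float(value)
    return SignalTrack(data)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write as run-length-merged BedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                v = float(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_bigwig(path, chrom_lengths: Mapping[str, int] | None = None) -> SignalTrack:
    """Read a bigWig file into a dense track (requires pyBigWig at runtime)."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    try:
        lengths = chrom_lengths or bw.chroms()
        data = {}
        for chrom, L in lengths.items():
            vals = np.array(bw.values(chrom, 0, int(L)), dtype=float)
            vals[np.isnan(vals)] = 0.0
            data[chrom] = vals
    finally:
        bw.close()
    return SignalTrack(data)
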