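"""Canonical k-mer scoring of ChEC cut-site signal and score-weighted PWMs.

Every x-mer and its reverse complement share one canonical index (4^x / 2
classes for odd x, where no x-mer is its own reverse complement).  Each
occurrence of an x-mer starting inside a promoter is scored by the mean
cut-site signal in a 20 bp window centered on the occurrence midpoint; the
class score is the mean over all its promoter occurrences.  The top-scoring
classes are aligned to the best one by an exhaustive ungapped
offset-and-orientation search and combined, weighted by score, into a
position weight matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import PromoterSet
from .tracks import SignalTrack

log = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def _encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0 C=1 G=2 T=3, other = -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for b, c in _CODE.items():
        out[arr == ord(b)] = c
    return out


def _rc_codes(codes: np.ndarray, x: int) -> np.ndarray:
    """Reverse-complement of base-4 integer x-mer codes, vectorized."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(x):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


@dataclass
class CanonicalIndex:
    """Bijection between canonical x-mer classes and dense integer indices."""

    x: int
    canon_of_code: np.ndarray  # 4^x -> canonical code (min of pair)
    index_of_canon: np.ndarray  # 4^x -> dense class index
    representatives: list[str]  # class index -> lexicographically smaller form

    @property
    def n_classes(self) -> int:
        return len(self.representatives)

    def index_of(self, seq: str) -> int:
        code = 0
        for b in seq.upper():
            code = code * 4 + _CODE[b]
        return int(self.index_of_canon[self.canon_of_code[code]])


def _decode(code: int, x: int) -> str:
    out = []
    for _ in range(x):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def canonical_index(x: int) -> CanonicalIndex:
    """Build the canonical index for all x-mers.

    For odd x the class count is exactly 4^x / 2 (no odd-length DNA word
    equals its own reverse complement).  Even x is allowed but yields
    (4^x + #palindromes) / 2 classes, logged as deviating from the odd-x
    formula.
    """
    if not 1 <= x <= 12:
        raise ValueError("x must be between 1 and 12")
    codes = np.arange(4 ** x, dtype=np.int64)
    rc = _rc_codes(codes, x)
    canon = np.minimum(codes, rc)
    uniq = np.unique(canon)
    index_of_canon = np.full(4 ** x, -1, dtype=np.int64)
    index_of_canon[uniq] = np.arange(len(uniq))
    reps = [_decode(int(c), x) for c in uniq]
    if x % 2 == 0:
        n_pal = int((codes == rc).sum())
        log.info("even x=%d: %d palindromic x-mers; %d classes (odd-x formula 4^x/2 "
                 "does not apply)", x, n_pal, len(uniq))
    return CanonicalIndex(x, canon, index_of_canon, reps)


@dataclass
class XmerScoreTable:
    """Per-canonical-class mean ChEC signal over promoter occurrences."""

    x: int
    table: pd.DataFrame  # index: class index; columns: representative, mean_signal, n_occurrences
    n_skipped: int = 0  # occurrences whose window left chromosome bounds

    def top(self, n: int) -> pd.DataFrame:
        scored = self.table[self.table["n_occurrences"] > 0]
        return scored.sort_values(["mean_signal", "representative"],
                                  ascending=[False, True]).head(n)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# canonical {self.x}-mer classes; mean_signal = mean cut-site "
                     f"signal in 20 bp window over promoter occurrences\n")
            self.table.rename_axis("class_index").to_csv(fh, sep="\t")


def score_xmers(
    genome: dict[str, str],
    track: SignalTrack,
    promoters: PromoterSet,
    x: int = 7,
    window: int = 20,
    index: CanonicalIndex | None = None,
    genome_wide: bool = False,
) -> XmerScoreTable:
    """Score every canonical x-mer class by mean signal at its occurrences.

    An occurrence is an x-mer whose start lies inside a promoter (or
    anywhere, with ``genome_wide=True``); its score is the mean signal in
    ``[mid - window//2, mid + window//2)`` with mid = start + x//2.
    Occurrences whose window leaves the chromosome are skipped and
    counted; occurrences containing non-ACGT bases are ignored.
    """
    if index is None:
        index = canonical_index(x)
    for chrom, seq in genome.items():
        if chrom in track.data and len(seq) != len(track.data[chrom]):
            raise ValueError(f"{chrom}: sequence length {len(seq)} != track length "
                             f"{len(track.data[chrom])}")
    if track.declared_total is None:
        raise ValueError("track must be depth-normalized (run normalize_track)")

    sums = np.zeros(index.n_classes)
    counts = np.zeros(index.n_classes, dtype=np.int64)
    n_skipped = 0
    half = window // 2
    mid_off = x // 2

    # per-chromosome occurrence codes and window means, computed once
    for chrom, seq in genome.items():
        if chrom not in track.data:
            continue
        enc = _encode(seq)
        n = len(enc)
        if n < x:
            continue
        n_pos = n - x + 1
        codes = np.zeros(n_pos, dtype=np.int64)
        valid = np.ones(n_pos, dtype=bool)
        for j in range(x):
            col = enc[j:n_pos + j]
            valid &= col >= 0
            codes = codes * 4 + np.maximum(col, 0)
        cls = index.index_of_canon[index.canon_of_code[codes]]
        csum = np.concatenate([[0.0], np.cumsum(track.data[chrom])])

        if genome_wide:
            starts = np.arange(n_pos)
        else:
            proms = [p for p in promoters if p.chrom == chrom]
            if not proms:
                continue
            starts = np.concatenate([
                np.arange(p.start, min(p.end, n_pos)) for p in proms
            ]) if proms else np.array([], dtype=int)
        if len(starts) == 0:
            continue
        mids = starts + mid_off
        lo = mids - half
        hi = lo + window
        in_bounds = (lo >= 0) & (hi <= n)
        n_skipped += int((~in_bounds).sum())
        use = in_bounds & valid[starts]
        starts, lo, hi = starts[use], lo[use], hi[use]
        wmeans = (csum[hi] - csum[lo]) / window
        occ_cls = cls[starts]
        np.add.at(sums, occ_cls, wmeans)
        np.add.at(counts, occ_cls, 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame({
        "representative": index.representatives,
        "mean_signal": means,
        "n_occurrences": counts,
    })
    return XmerScoreTable(x, table, n_skipped)


@dataclass
class PWM:
    """Position probability matrix with per-position total weight."""

    probs: pd.DataFrame  # positions x [A, C, G, T]
    total_weight: np.ndarray

    def __len__(self) -> int:
        return len(self.probs)

    def consensus(self) -> str:
        return "".join(self.probs.idxmax(axis=1))

    def to_tsv(self, path) -> None:
        out = self.probs.copy()
        out["total_weight"] = self.total_weight
        with open(path, "w") as fh:
            fh.write("# PWM: per-position base probabilities weighted by k-mer binding score\n")
            out.rename_axis("position").to_csv(fh, sep="\t")

    def to_meme(self, path, name: str = "motif") -> None:
        """Minimal MEME motif format."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(self.probs)}\n")
            for _, row in self.probs.iterrows():
                fh.write(" ".join(f"{row[b]:.6f}" for b in "ACGT") + "\n")


def _align_to_anchor(anchor: str, motif: str, max_shift: int) -> tuple[str, int]:
    """Best ungapped placement of ``motif`` (either orientation) on ``anchor``.

    Maximizes the number of matching bases in the overlap; ties prefer the
    smaller |offset|, then the forward orientation.  Returns the oriented
    sequence and its offset relative to the anchor start.
    """
    best = (-1, None, None)
    offsets = sorted(range(-max_shift, max_shift + 1), key=lambda d: (abs(d), d < 0))
    for oriented in (motif, revcomp(motif)):
        for d in offsets:
            matches = sum(
                1 for i in range(len(oriented))
                if 0 <= i + d < len(anchor) and oriented[i] == anchor[i + d]
            )
            if matches > best[0]:
                best = (matches, oriented, d)
    return best[1], best[2]


def build_pwm(table: XmerScoreTable, top_n: int = 10, trim_frac: float = 0.5) -> PWM:
    """Score-weighted PWM from the top-scoring canonical x-mer classes.

    The highest-scoring class anchors the alignment; every other top class
    is placed on it by an exhaustive ungapped offset/orientation search
    (offsets up to ±(x−1)) and contributes its mean signal as weight to
    the per-position base counts.  Columns are normalized to probabilities
    and the matrix trimmed to positions whose total weight is at least
    ``trim_frac`` of the maximum.
    """
    top = table.top(top_n)
    if len(top) < top_n:
        raise ValueError(f"need {top_n} scored classes, have {len(top)}")
    if (top["mean_signal"] <= 0).all():
        raise ValueError("top classes carry no signal")
    x = table.x
    anchor = top.iloc[0]["representative"]
    span = 3 * x - 2  # anchor at [x-1, 2x-2]; offsets within ±(x-1)
    origin = x - 1
    counts = pd.DataFrame(0.0, index=range(span), columns=list("ACGT"))
    for _, row in top.iterrows():
        oriented, off = _align_to_anchor(anchor, row["representative"], x - 1)
        w = float(row["mean_signal"])
        for i, base in enumerate(oriented):
            counts.loc[origin + off + i, base] += w
    total = counts.sum(axis=1).to_numpy()
    keep = total >= trim_frac * total.max()
    counts = counts.loc[keep]
    total = total[keep]
    probs = counts.div(counts.sum(axis=1), axis=0)
    probs.index = range(len(probs))
    return PWM(probs, total)


# ---------------------------------------------------------------------------
# FASTA I/O (via Biopython)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
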