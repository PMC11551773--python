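"""Promoter-level TF binding: quantification, target calling, spike-in calibration.

The binding strength of a TF at a promoter is the sum of depth-normalized
cut-site signal over the promoter interval, rescaled to the maximal promoter
length (700 bp) so that truncated promoters are comparable:

    binding = sum(signal on promoter) / len(promoter) * 700

Promoters with binding z-score >= 3 (computed across all promoters of a
sample, sample SD) are called targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import Promoter, PromoterSet
from .tracks import SignalTrack, rolling_mean

log = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.0
SPIKE_GENES = ("ARO9", "ARO10", "NAF1")  # Aro80-MNase spike-in promoters


@dataclass
class PromoterBindingVector:
    """Length-normalized promoter binding sums and their z-scores for one sample."""

    sample_id: str
    binding: pd.Series  # gene_id -> binding
    z: pd.Series  # gene_id -> z-score

    def to_frame(self, z_thresh: float = DEFAULT_Z_THRESHOLD) -> pd.DataFrame:
        return pd.DataFrame({
            "binding": self.binding,
            "z": self.z,
            "is_target": self.z >= z_thresh,
        })

    def to_tsv(self, path, z_thresh: float = DEFAULT_Z_THRESHOLD) -> None:
        df = self.to_frame(z_thresh)
        df.index.name = "gene_id"
        with open(path, "w") as fh:
            fh.write(f"# sample {self.sample_id}; binding in normalized counts per 700 bp; z over promoters\n")
            df.to_csv(fh, sep="\t")


@dataclass
class TargetSet:
    sample_id: str
    genes: set[str]
    threshold: float = DEFAULT_Z_THRESHOLD

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def newly_acquired(self, reference: "TargetSet") -> set[str]:
        """Targets of this sample not bound in the reference sample.

        Used to ask which promoters a minimal DBD-AD fusion acquires beyond
        the full-length TF's native repertoire.
        """
        return self.genes - reference.genes


def _zscore(values: pd.Series) -> pd.Series:
    sd = values.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return pd.Series(np.nan, index=values.index)
    return (values - values.mean()) / sd


def promoter_binding(
    track: SignalTrack,
    promoters: PromoterSet,
    sample_id: str | None = None,
    exclude_from_z: set[str] | frozenset[str] = frozenset(),
) -> PromoterBindingVector:
    """Quantify binding per promoter and z-score across promoters.

    The track must be depth-normalized (``declared_total`` set).  Genes in
    ``exclude_from_z`` (e.g. spike-in promoters in calibrated samples) keep
    their binding value but do not enter the z-score statistics; their own
    z is computed against the remaining promoters' mean/SD.
    """
    if track.declared_total is None:
        raise ValueError("track must be depth-normalized before promoter binding "
                         "(run normalize_track)")
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    values = {}
    for p in promoters:
        arr = track.data.get(p.chrom)
        if arr is None or p.end > len(arr):
            raise ValueError(f"promoter {p.gene_id} outside track bounds "
                             f"(annotation/track mismatch on {p.chrom})")
        values[p.gene_id] = float(arr[p.start:p.end].sum()) / p.length * promoters.max_len
    binding = pd.Series(values, name="binding")
    core = binding.drop(index=[g for g in exclude_from_z if g in binding.index])
    sd = core.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        z = pd.Series(np.nan, index=binding.index)
    else:
        z = (binding - core.mean()) / sd
    sid = sample_id or track.metadata.get("sample_id", "sample")
    return PromoterBindingVector(sid, binding, z)


def call_targets(binding: PromoterBindingVector, z_thresh: float = DEFAULT_Z_THRESHOLD) -> TargetSet:
    """Promoters with binding z-score >= ``z_thresh`` for this sample."""
    if len(binding.binding) < 2:
        raise ValueError("need at least 2 promoters to call targets")
    if binding.z.isna().all():
        log.warning("sample %s: zero-variance binding vector; no targets called",
                    binding.sample_id)
        return TargetSet(binding.sample_id, set(), z_thresh)
    genes = set(binding.z.index[binding.z >= z_thresh])
    return TargetSet(binding.sample_id, genes, z_thresh)


def calibrate_binding(
    binding: PromoterBindingVector,
    spike_targets: set[str] | tuple[str, ...] = SPIKE_GENES,
) -> float:
    """Total binding strength relative to the spike-in signal.

    Returns the ratio of summed binding over all non-spike promoters to the
    summed binding over the spike-in TF's target promoters (ARO9, ARO10,
    NAF1 for the Aro80-MNase spike-in).  The ratio cancels sequencing-depth
    normalization, making binding strengths comparable across samples.
    """
    spike = set(spike_targets)
    missing = spike - set(binding.binding.index)
    if missing:
        raise ValueError(f"spike-in promoters missing from binding vector: {sorted(missing)}")
    spike_sum = binding.binding[sorted(spike)].sum()
    if spike_sum <= 0:
        raise ValueError("zero spike-in signal: spike-in failed")
    other_sum = binding.binding.drop(index=sorted(spike)).sum()
    return float(other_sum / spike_sum)


@dataclass
class TssDistance:
    distance: int
    flat: bool = False


def binding_distance_from_tss(
    track: SignalTrack, promoter: Promoter, window: int = 50
) -> TssDistance:
    """Distance (bp) from the TSS to the peak of smoothed promoter signal.

    The promoter signal is smoothed with a centered rolling mean of width
    ``window``; the distance is from the TSS to the argmax, ties broken
    toward the TSS.  A flat profile returns distance 0 with ``flat=True``.
    """
    if promoter.length < window:
        raise ValueError(f"promoter {promoter.gene_id} shorter than smoothing window")
    arr = track.data[promoter.chrom][promoter.start:promoter.end]
    smoothed = rolling_mean(arr, window)
    if np.allclose(smoothed, smoothed[0]):
        return TssDistance(0, flat=True)
    # distance from the TSS base; upstream is leftward for '+' genes
    if promoter.strand == "+":
        dist = promoter.length - np.arange(len(smoothed))
    else:
        dist = np.arange(len(smoothed)) + 1
    order = np.lexsort((dist, -smoothed))  # max signal first, ties toward TSS
    return TssDistance(int(dist[order[0]]))


def binding_similarity(
    vectors: list[PromoterBindingVector], on: str = "all",
    z_thresh: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of promoter binding preferences.

    ``on='union_targets'`` restricts to promoters that are a target
    (z >= ``z_thresh``) of at least one input sample.  Constant vectors
    yield NaN correlations (reported missing).
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 binding vectors")
    mat = pd.DataFrame({v.sample_id: v.binding for v in vectors})
    if mat.isna().any().any():
        raise ValueError("binding vectors must share a common gene set")
    if on == "union_targets":
        keep = pd.DataFrame({v.sample_id: v.z for v in vectors}).ge(z_thresh).any(axis=1)
        mat = mat.loc[keep]
    elif on != "all":
        raise ValueError(f"unknown restriction {on!r}")
    return mat.corr(method="pearson")
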