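"""Per-promoter scalar features and sorted rolling-mean ± SEM profiles.

The OPN ("occupied proximal nucleosome") score captures promoter nucleosome
architecture: log2 of the mean nucleosome occupancy 200-400 bp upstream of
the TSS (distal) minus log2 of the mean occupancy in the 150 bp directly
upstream (proximal).  High OPN marks a fuzzy or depleted proximal
nucleosome; low OPN a well-occupied one.

Other features (expression flexibility, STM class membership, number of
bound TFs, basal expression) reduce to per-gene scalars that downstream
figures summarize as rolling mean ± SEM along a sorted axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import PromoterSet
from .tracks import SignalTrack

log = logging.getLogger(__name__)

OPN_PROXIMAL = (0, 150)  # bp upstream of TSS, half-open
OPN_DISTAL = (200, 400)


@dataclass
class FeatureVector:
    name: str
    values: pd.Series
    units: str = ""

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# feature {self.name}" + (f" [{self.units}]" if self.units else "") + "\n")
            self.values.rename(self.name).rename_axis("gene_id").to_csv(fh, sep="\t")


def _upstream_interval(prom, lo: int, hi: int) -> tuple[int, int]:
    """Genomic half-open interval [TSS-hi, TSS-lo) in the gene's orientation."""
    if prom.strand == "+":
        tss = prom.end
        return tss - hi, tss - lo
    tss = prom.start - 1
    return tss + 1 + lo, tss + 1 + hi


def opn_score(
    occupancy: SignalTrack,
    promoters: PromoterSet,
    pseudocount: float = 0.0,
) -> FeatureVector:
    """OPN score: log2(distal occupancy) - log2(proximal occupancy) per promoter.

    Proximal = mean occupancy over [TSS-150, TSS); distal = mean over
    [TSS-400, TSS-200), strand-aware.  Promoters shorter than 400 bp, or
    with zero mean in either region (unless a pseudocount is given), get a
    missing value and are counted in the log.
    """
    need = OPN_DISTAL[1]
    values: dict[str, float] = {}
    n_short = n_zero = 0
    for p in promoters:
        if p.length < need:
            values[p.gene_id] = np.nan
            n_short += 1
            continue
        arr = occupancy.data[p.chrom]
        ps, pe = _upstream_interval(p, *OPN_PROXIMAL)
        ds, de = _upstream_interval(p, *OPN_DISTAL)
        prox = float(arr[ps:pe].mean()) + pseudocount
        dist = float(arr[ds:de].mean()) + pseudocount
        if prox <= 0 or dist <= 0:
            values[p.gene_id] = np.nan
            n_zero += 1
            continue
        values[p.gene_id] = float(np.log2(dist) - np.log2(prox))
    if n_short or n_zero:
        log.info("opn_score: %d promoters < %d bp, %d with zero-occupancy region",
                 n_short, need, n_zero)
    return FeatureVector("opn", pd.Series(values), units="log2 distal/proximal occupancy")


def expression_flexibility(fc: pd.DataFrame,
                           lo_pct: float = 0.05, hi_pct: float = 99.95) -> FeatureVector:
    """Extreme-percentile spread of log2 fold-changes across conditions.

    Per gene, the value at percentile ``hi_pct`` minus that at ``lo_pct``
    (linear-interpolation convention; with few conditions this collapses
    to max - min).  All-missing genes stay missing.
    """
    def spread(row: np.ndarray) -> float:
        vals = row[~np.isnan(row)]
        if len(vals) < 2:
            return np.nan
        lo, hi = np.percentile(vals, [lo_pct, hi_pct])
        return float(hi - lo)

    values = fc.apply(lambda r: spread(r.to_numpy()), axis=1)
    return FeatureVector("flexibility", values, units="log2 fold-change spread")


def count_bound_tfs(binding_z: pd.DataFrame, z_thresh: float = 3.0) -> FeatureVector:
    """Number of TFs binding each promoter with z-score >= ``z_thresh``.

    ``binding_z`` is a promoters x TFs matrix of per-TF z-scored binding.
    """
    counts = (binding_z >= z_thresh).sum(axis=1).astype(float)
    return FeatureVector("n_bound_tfs", counts, units="TFs at z>=%g" % z_thresh)


def binary_fraction_feature(labels: pd.Series, positive_class: str,
                            name: str = "fraction") -> FeatureVector:
    """Indicator vector for membership in ``positive_class``.

    Its sorted rolling profile is the class-fraction curve used for e.g.
    the STM (SAGA/Tup1/Mediator) promoter class.
    """
    values = (labels == positive_class).astype(float)
    return FeatureVector(name, values, units="indicator")


@dataclass
class RollingProfile:
    """Rolling mean ± SEM of a value along an ascending sort axis."""

    sort_values: np.ndarray
    window_mean: np.ndarray
    window_sem: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.sort_values)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# rolling profile, window={self.window} genes; sem = SD/sqrt(n)\n")
            fh.write("sort_value\tmean\tsem\n")
            for s, m, e in zip(self.sort_values, self.window_mean, self.window_sem):
                fh.write(f"{s!r}\t{m!r}\t{e!r}\n")


def sorted_rolling_profile(
    sort_by: pd.Series,
    values: pd.Series,
    window: int,
) -> RollingProfile:
    """Sort genes by ``sort_by`` and take centered rolling mean and SEM of ``values``.

    SEM = sample SD / sqrt(window size); edge windows are truncated.
    Genes missing a sort key are dropped (logged); ties in the sort key
    are broken by gene id for determinism.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    common = sort_by.index.intersection(values.index)
    sort_by = sort_by.loc[common]
    missing = sort_by.isna()
    if missing.any():
        log.info("sorted_rolling_profile: dropped %d genes without sort key", int(missing.sum()))
        sort_by = sort_by[~missing]
    if window > len(sort_by):
        raise ValueError(f"window {window} exceeds {len(sort_by)} usable genes")
    perm = np.lexsort((sort_by.index.to_numpy(), sort_by.to_numpy()))
    order = sort_by.index[perm]
    v = values.loc[order]
    roll = v.rolling(window, min_periods=2, center=True)
    mean = roll.mean().to_numpy()
    sd = roll.std(ddof=1).to_numpy()
    n = v.rolling(window, min_periods=2, center=True).count().to_numpy()
    sem = sd / np.sqrt(n)
    return RollingProfile(sort_by.loc[order].to_numpy(), mean, sem, window)
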