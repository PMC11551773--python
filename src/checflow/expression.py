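"""Expression matrices: normalization, gene filtering, binned differential expression.

Raw gene-by-sample counts are scaled per sample to 1e6 (CPM) and
log2(x + 1)-transformed.  Samples with fewer than 200 000 total reads are
discarded to avoid artificial enrichment for highly expressed genes.

Differential expression of overexpression strains is assessed against a
steady-state reference (per-gene median over wild-type samples) by a
binned-z procedure: genes are split into 10 equal-size bins by reference
expression level, and each gene's log2 fold-change is z-scored against its
bin; |z| > 2 flags a gene as differentially expressed.  A per-bin t-test
of bound vs unbound genes is reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_READ_FLOOR = 200_000
DEFAULT_CPM_TOTAL = 1e6
DEFAULT_MIN_LOG2 = 4.5
DEFAULT_MIN_FRAC = 0.025
DEFAULT_N_BINS = 10
DEFAULT_DE_Z = 2.0


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with explicit normalization state."""

    values: pd.DataFrame
    state: str  # 'raw' | 'cpm_1e6' | 'log2'
    raw_totals: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# expression matrix, state={self.state}\n")
            self.values.rename_axis("gene_id").to_csv(fh, sep="\t")


def normalize_counts(
    raw: pd.DataFrame,
    read_floor: int = DEFAULT_READ_FLOOR,
    total: float = DEFAULT_CPM_TOTAL,
) -> ExpressionMatrix:
    """Per-sample CPM scaling to ``total`` followed by log2(x + 1).

    Samples whose raw totals fall below ``read_floor`` are dropped with a
    warning.  Raises on an empty matrix or when no sample survives.
    """
    if raw.size == 0:
        raise ValueError("empty count matrix")
    totals = raw.sum(axis=0)
    low = totals.index[totals < read_floor]
    if len(low):
        log.warning("dropping %d sample(s) below %d reads: %s",
                    len(low), read_floor, ", ".join(map(str, low[:10])))
    kept = raw.drop(columns=low)
    if kept.shape[1] == 0:
        raise ValueError("no sample passes the read floor")
    totals = totals.drop(index=low)
    cpm = kept * (total / totals)
    return ExpressionMatrix(np.log2(cpm + 1.0), state="log2", raw_totals=totals)


def required_sample_count(n_samples: int, min_frac: float = DEFAULT_MIN_FRAC) -> int:
    """Minimum number of samples a gene must be expressed in: ceil(frac * n)."""
    return math.ceil(min_frac * n_samples)


def filter_genes(
    mat: ExpressionMatrix,
    min_log2: float = DEFAULT_MIN_LOG2,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> set[str]:
    """Genes with >= ``min_log2`` normalized log2 reads in >= ceil(frac * n) samples."""
    if mat.state != "log2":
        raise ValueError("filter_genes expects a log2-normalized matrix")
    need = required_sample_count(mat.values.shape[1], min_frac)
    counts = (mat.values >= min_log2).sum(axis=1)
    return set(counts.index[counts >= need])


def steady_state_reference(wt: ExpressionMatrix) -> pd.Series:
    """Per-gene median log2 expression over wild-type samples."""
    if wt.state != "log2":
        raise ValueError("reference expects a log2-normalized matrix")
    return wt.values.median(axis=1)


@dataclass
class DEResult:
    """Binned-z differential expression of one overexpression sample."""

    sample_id: str
    table: pd.DataFrame  # gene_id -> log2fc, bin, z, de_flag
    bound_set: set[str]
    bin_tests: pd.DataFrame  # per-bin t-statistic and p for bound vs unbound
    frac_bound_up: float
    frac_bound_down: float

    def flagged(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["de_flag"] == direction])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sample {self.sample_id}; log2fc vs steady-state reference; "
                     f"z within reference-level bins\n")
            self.table.rename_axis("gene_id").to_csv(fh, sep="\t")


def _quantile_bins(reference: pd.Series, n_bins: int) -> pd.Series:
    """Equal-size bins by reference level; remainder genes go to the lowest
    bins; ties in level broken by gene_id for determinism."""
    # stable sort: ties in level keep the caller's (gene_id-sorted) order
    order = reference.sort_values(kind="mergesort").index
    n = len(reference)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    labels = np.repeat(np.arange(1, n_bins + 1), sizes)
    return pd.Series(labels, index=order)


def overexpression_de(
    sample: pd.Series,
    reference: pd.Series,
    bound: set[str],
    n_bins: int = DEFAULT_N_BINS,
    z_thresh: float = DEFAULT_DE_Z,
    sample_id: str = "sample",
) -> DEResult:
    """Binned-z differential expression against a steady-state reference.

    log2fc = sample - reference.  Genes are split into ``n_bins``
    equal-size bins by reference level; per-bin mean/SD of log2fc yield a
    per-gene z; |z| > ``z_thresh`` flags DE.  A two-sample t-test of bound
    vs unbound log2fc is reported per bin, and the fractions of bound
    genes flagged up/down are returned.
    """
    common = sample.index.intersection(reference.index)
    if len(common) != len(sample) or len(common) != len(reference):
        raise ValueError("sample and reference must share the same gene set")
    if len(common) < n_bins:
        raise ValueError("fewer genes than bins")
    sample = sample.loc[common]
    reference = reference.loc[common]
    # deterministic tie-break: pre-sort genes by id so the stable bin sort
    # resolves equal reference levels by gene_id
    gid_order = sorted(common)
    reference = reference.loc[gid_order]
    sample = sample.loc[gid_order]
    log2fc = sample - reference
    bins = _quantile_bins(reference, n_bins)

    z = pd.Series(np.nan, index=log2fc.index)
    tests = []
    for b in range(1, n_bins + 1):
        idx = bins.index[bins == b]
        if len(idx) < 2:
            raise ValueError(f"bin {b} has fewer than 2 genes")
        fc = log2fc.loc[idx]
        sd = fc.std(ddof=1)
        z.loc[idx] = 0.0 if sd == 0 else (fc - fc.mean()) / sd
        in_bound = fc.index.isin(bound)
        if in_bound.any() and (~in_bound).any() and in_bound.sum() >= 2 and (~in_bound).sum() >= 2:
            t, p = stats.ttest_ind(fc[in_bound], fc[~in_bound], equal_var=False)
        else:
            t, p = np.nan, np.nan
        tests.append({"bin": b, "n": len(idx), "n_bound": int(in_bound.sum()),
                      "t": t, "p": p})

    de_flag = pd.Series("none", index=log2fc.index)
    de_flag[z > z_thresh] = "up"
    de_flag[z < -z_thresh] = "down"
    table = pd.DataFrame({"log2fc": log2fc, "bin": bins.loc[log2fc.index],
                          "z": z, "de_flag": de_flag})
    bound_in = table.index.isin(bound)
    n_bound = int(bound_in.sum())
    frac_up = float((de_flag[bound_in] == "up").sum() / n_bound) if n_bound else 0.0
    frac_down = float((de_flag[bound_in] == "down").sum() / n_bound) if n_bound else 0.0
    return DEResult(sample_id, table, set(bound), pd.DataFrame(tests),
                    frac_up, frac_down)


def library_fold_change(
    lib: ExpressionMatrix,
    abundances: pd.Series,
    k: int = 5,
    smooth_strains: int = 3,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene fold-change between extreme-abundance strains, plus display matrix.

    Delta = mean expression over the ``k`` highest-abundance strains minus
    the mean over the ``k`` lowest.  The display matrix is per-gene
    mean-centered, shifted so the ``k`` lowest-abundance strains sit near
    zero, ordered by abundance and smoothed with a rolling window of
    ``smooth_strains`` strains.  Abundance ties at the k-boundary are
    broken by sample id (logged).
    """
    common = lib.samples.intersection(abundances.index)
    if len(common) < 2 * k:
        raise ValueError(f"need at least {2 * k} strains with abundances")
    ab = abundances.loc[common]
    perm = np.lexsort((ab.index.to_numpy(), ab.to_numpy()))
    ordered = list(ab.index[perm])
    if ab.duplicated(keep=False).any():
        log.info("abundance ties present; broken by sample id order")
    low, high = ordered[:k], ordered[-k:]
    vals = lib.values[ordered]
    delta = vals[high].mean(axis=1) - vals[low].mean(axis=1)
    display = vals.sub(vals.mean(axis=1), axis=0)
    display = display.sub(display[low].mean(axis=1), axis=0)
    display = display.T.rolling(smooth_strains, min_periods=1, center=True).mean().T
    return delta, display
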