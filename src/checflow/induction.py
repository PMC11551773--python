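"""Dose-response induction scores from TF-abundance strain libraries.

A library is a set of strains expressing one TF at graded abundance
(quantified by flow cytometry of a YFP fusion).  The *induction score* of a
gene is the Spearman rank correlation between its expression across strains
and the TF abundance; p-values are Benjamini-Hochberg adjusted within the
library, and genes with q < alpha count as significantly induced (r > 0) or
repressed (r < 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .chec_binding import TargetSet
from .expression import ExpressionMatrix, library_fold_change

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class AbundanceEntry:
    """Background-subtracted log2 median fluorescence of one strain."""

    sample_id: str
    abundance: float
    n_cells: int
    qc_pass: bool = True
    gmm_fallback: bool = False


@dataclass
class AbundanceTable:
    entries: dict[str, AbundanceEntry]

    def series(self, qc_only: bool = True) -> pd.Series:
        items = {sid: e.abundance for sid, e in self.entries.items()
                 if e.qc_pass or not qc_only}
        return pd.Series(items, name="abundance")

    @classmethod
    def from_series(cls, s: pd.Series, n_cells: int = 0) -> "AbundanceTable":
        return cls({sid: AbundanceEntry(sid, float(v), n_cells) for sid, v in s.items()})


def estimate_abundance(
    cells: np.ndarray,
    background_runs: list[np.ndarray],
    sample_id: str = "strain",
    min_cells: int = 100,
    sd_cut: float = 2.0,
) -> AbundanceEntry:
    """TF abundance from per-cell fluorescence, debris-filtered by a GMM.

    Log2 fluorescence is clustered into two Gaussian components (cells vs
    debris/noise); the component with more members is taken as the cell
    population and cells within ``sd_cut`` standard deviations of its mean
    are kept.  If the two components are indistinguishable (means within
    0.1 log2 units) all cells are kept and the entry is flagged.  The
    abundance is median(log2 kept) minus the median over background runs
    of each run's median log2 fluorescence.
    """
    cells = np.asarray(cells, dtype=float)
    if len(cells) < min_cells:
        raise ValueError(f"{sample_id}: need >= {min_cells} cells, got {len(cells)}")
    if not background_runs:
        raise ValueError("at least one background (non-fluorescent) run required")
    logf = np.log2(np.maximum(cells, 1e-12))
    gmm = GaussianMixture(n_components=2, random_state=0, n_init=1,
                          means_init=np.percentile(logf, [25, 75]).reshape(-1, 1))
    labels = gmm.fit_predict(logf.reshape(-1, 1))
    means = gmm.means_.ravel()
    fallback = abs(means[0] - means[1]) < 0.1
    if fallback:
        kept = logf
    else:
        cell_comp = int(np.bincount(labels, minlength=2).argmax())
        mu = means[cell_comp]
        sd = float(np.sqrt(gmm.covariances_.ravel()[cell_comp]))
        member = logf[labels == cell_comp]
        kept = member[np.abs(member - mu) <= sd_cut * sd]
        if len(kept) == 0:
            kept, fallback = logf, True
    bg = float(np.median([np.median(np.log2(np.maximum(np.asarray(b, float), 1e-12)))
                          for b in background_runs]))
    return AbundanceEntry(sample_id, float(np.median(kept)) - bg,
                          n_cells=len(cells), gmm_fallback=fallback)


@dataclass
class InductionScoreTable:
    """Per-gene Spearman r / p / BH-q against TF abundance for one library."""

    library_id: str
    table: pd.DataFrame  # gene_id -> r, p, q, significant
    alpha: float = DEFAULT_ALPHA

    @property
    def r(self) -> pd.Series:
        return self.table["r"]

    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# library {self.library_id}; r = Spearman rho vs TF abundance; "
                     f"q = BH-adjusted p; alpha = {self.alpha}\n")
            self.table.rename_axis("gene_id").to_csv(fh, sep="\t")


def _spearman_vs_vector(values: pd.DataFrame, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided p of a matrix against one vector.

    Average ranks on ties; p from the t approximation (as scipy uses for
    n > 2).  Constant rows give NaN.
    """
    n = values.shape[1]
    rt = stats.rankdata(target)
    rv = np.apply_along_axis(stats.rankdata, 1, values.to_numpy())
    rt_c = rt - rt.mean()
    rv_c = rv - rv.mean(axis=1, keepdims=True)
    denom = np.sqrt((rv_c ** 2).sum(axis=1) * (rt_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rv_c @ rt_c) / denom
    r = np.where(denom == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, p


def induction_scores(
    lib: ExpressionMatrix,
    abundances: AbundanceTable | pd.Series,
    alpha: float = DEFAULT_ALPHA,
    library_id: str = "library",
    min_samples: int = 10,
) -> InductionScoreTable:
    """Spearman induction score, p and BH-q per gene for one library.

    Expression should already be log2-normalized and gene-filtered.  The
    BH correction runs over all scored (non-constant) genes of the
    library; ``significant`` means q < ``alpha``.
    """
    ab = abundances.series() if isinstance(abundances, AbundanceTable) else abundances
    common = lib.samples.intersection(ab.index)
    if len(common) < 4:
        raise ValueError("need at least 4 strains with abundance measurements")
    if len(common) < min_samples:
        log.warning("library %s: only %d strains pass QC (recommended >= %d)",
                    library_id, len(common), min_samples)
    vals = lib.values[common]
    target = ab.loc[common].to_numpy()
    r, p = _spearman_vs_vector(vals, target)
    table = pd.DataFrame({"r": r, "p": p}, index=vals.index)
    scored = table["p"].notna()
    q = pd.Series(np.nan, index=table.index)
    if scored.any():
        q.loc[scored] = multipletests(table.loc[scored, "p"], method="fdr_bh")[1]
    table["q"] = q
    table["significant"] = (table["q"] < alpha).fillna(False)
    return InductionScoreTable(library_id, table, alpha)


def define_induced_targets(
    scores: InductionScoreTable,
    native_targets: TargetSet,
    direction: str = "up",
    lib: ExpressionMatrix | None = None,
    abundances: pd.Series | None = None,
) -> tuple[set[str], float, float | None]:
    """Significantly induced (or repressed) genes among the native TF's targets.

    Returns (induced_targets, fraction of native targets induced, mean
    log2 fold-change of induced targets).  The fold-change — the mean of
    the extreme-abundance-strain delta — is only computed when ``lib`` and
    ``abundances`` are supplied.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(native_targets) == 0:
        log.warning("empty native target set for %s", scores.library_id)
        return set(), 0.0, None
    sig = scores.table[scores.table["significant"]]
    oriented = sig.index[sig["r"] > 0] if direction == "up" else sig.index[sig["r"] < 0]
    induced = set(oriented) & native_targets.genes
    frac = len(induced) / len(native_targets)
    mean_fc = None
    if lib is not None and abundances is not None and induced:
        delta, _ = library_fold_change(lib, abundances)
        mean_fc = float(delta.loc[sorted(induced)].mean())
    return induced, frac, mean_fc


def cross_library_correlation(
    score_tables: list[InductionScoreTable],
    gene_union: set[str],
) -> pd.DataFrame:
    """Pearson correlation of induction-score vectors between libraries.

    ``gene_union`` is the caller-supplied comparison set (genes significant
    in at least one full-TF library, intersected with native targets).
    Missing r values are pairwise-deleted.
    """
    if len(score_tables) < 2:
        raise ValueError("need at least 2 libraries")
    genes = sorted(gene_union)
    mat = pd.DataFrame({t.library_id: t.r.reindex(genes) for t in score_tables})
    n_missing = int(mat.isna().sum().sum())
    if n_missing:
        log.info("cross-library correlation: %d missing r values pairwise-deleted", n_missing)
    return mat.corr(method="pearson")
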