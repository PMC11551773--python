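"""Seeded synthetic worlds: genome, ChEC/MNase tracks and expression libraries.

The generators emulate the study design end to end with known ground truth:
a compact yeast-like genome (default ~600 kb, 300 genes on both strands),
per-TF target promoters carrying a planted consensus motif, Poisson
cut-site tracks with Gaussian promoter enrichment and an optional
Aro80-like spike-in confined to three designated promoters, MNase-like
nucleosome occupancy with a planted high/low OPN split, and 35-40-strain
TF-abundance expression libraries with monotone (Hill-type) dose-response
target genes, multiplicative lognormal noise and multinomial count
sampling.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotations import GenomeAnnotation, Transcript
from .induction import AbundanceEntry, AbundanceTable
from .tracks import SignalTrack

DEFAULT_N_GENES = 300
DEFAULT_CHROM_LEN = 600_000
DEFAULT_N_TFS = 3
DEFAULT_TARGETS_PER_TF = 20
DEFAULT_ENRICHMENT = 10.0
DEFAULT_DEPTH = 1_000_000
DEFAULT_N_STRAINS = 38
DEFAULT_AMPLITUDE = 2.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_HALF_MAX = 8.0
MOTIF_LEN = 7
PEAK_SD = 25.0  # bp; width of the cut-site enrichment around a planted motif
MOTIF_OFFSET = 200  # planted motif center, bp upstream of the TSS


@dataclass
class GroundTruth:
    """What was planted, for verifying every downstream stage."""

    planted_targets: dict[str, set[str]]  # TF -> target gene ids
    enrichment: float
    motifs: dict[str, str]  # TF -> consensus motif sequence
    motif_sites: dict[str, list[tuple[str, int]]]  # TF -> (chrom, center)
    responders: dict[str, dict[str, dict[str, float]]]  # TF -> gene -> {amplitude, half_max}
    opn_assignment: dict[str, str]  # gene -> 'high' | 'low'
    spike_genes: tuple[str, str, str] = ("ARO9", "ARO10", "NAF1")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["planted_targets"] = {tf: sorted(g) for tf, g in self.planted_targets.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome(
    n_genes: int = DEFAULT_N_GENES,
    chrom_len: int = DEFAULT_CHROM_LEN,
    seed: int = 0,
    n_tfs: int = DEFAULT_N_TFS,
    targets_per_tf: int = DEFAULT_TARGETS_PER_TF,
    enrichment: float = DEFAULT_ENRICHMENT,
    n_close_pairs: int = 3,
) -> tuple[GenomeAnnotation, dict[str, str], GroundTruth]:
    """Random genome with planted TF targets, spike promoters and OPN classes.

    Genes are laid out in uniform slots on alternating strands with
    upstream gaps wide enough for full 700 bp promoters; ``n_close_pairs``
    genes get a neighboring transcript extended to truncate their promoter
    (exercising the promoter-truncation rule).  Each TF gets a random
    7-bp consensus motif planted (written into the sequence) ~200 bp
    upstream of the TSS of each of its targets.  Three genes, disjoint
    from all TF targets, are designated spike-in (Aro80-like) promoters.
    """
    if n_genes < 20:
        raise ValueError("need at least 20 genes")
    slot = chrom_len // n_genes
    if slot < 2000:
        raise ValueError("overcrowded layout: need >= 2000 bp per gene")
    rng = np.random.default_rng(seed)
    chrom = "chrI"
    seq = _random_sequence(rng, chrom_len)

    transcripts: list[Transcript] = []
    tss_of: dict[str, int] = {}
    strand_of: dict[str, str] = {}
    for i in range(n_genes):
        gid = f"G{i:04d}"
        base = i * slot
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = base + 800, base + 1800
            tss, stop = start, end - 4
        else:
            start, end = base + 100, base + 1100
            tss, stop = end - 1, start + 3
        transcripts.append(Transcript(gid, chrom, strand, tss, stop, start, end))
        tss_of[gid], strand_of[gid] = tss, strand

    # rename three non-target genes as spike promoters, chosen from the end
    spike_ids = ("ARO9", "ARO10", "NAF1")
    renames = {f"G{n_genes - 1 - j:04d}": spike_ids[j] for j in range(3)}
    transcripts = [
        Transcript(renames.get(t.gene_id, t.gene_id), t.chrom, t.strand,
                   t.tss, t.stop_codon, t.start, t.end)
        for t in transcripts
    ]
    for old, new in renames.items():
        tss_of[new] = tss_of.pop(old)
        strand_of[new] = strand_of.pop(old)

    # close-neighbor pairs: insert a short neighbor transcript ending 400 bp
    # upstream of a + strand gene's TSS so its promoter truncates to 400 bp
    eligible = [t for t in transcripts if t.strand == "+"
                and t.gene_id.startswith("G") and t.gene_id != "G0000"]
    truncated: list[str] = []
    neighbors: list[Transcript] = []
    for i, t in enumerate(eligible[:n_close_pairs]):
        ns, ne = t.tss - 550, t.tss - 400
        neighbors.append(Transcript(f"N{i:03d}", t.chrom, "+", ns, ne - 5, ns, ne))
        truncated.append(t.gene_id)
    transcripts = transcripts + neighbors

    # assign disjoint target sets per TF, excluding spikes, truncated genes
    # and the inserted neighbors
    skip = set(spike_ids) | set(truncated) | {n.gene_id for n in neighbors}
    pool = [t.gene_id for t in transcripts if t.gene_id not in skip]
    if len(pool) < n_tfs * targets_per_tf:
        raise ValueError(f"too few genes ({len(pool)} eligible) for "
                         f"{n_tfs} x {targets_per_tf} planted targets")
    chosen = rng.choice(len(pool), size=n_tfs * targets_per_tf, replace=False)
    planted: dict[str, set[str]] = {}
    motifs: dict[str, str] = {}
    sites: dict[str, list[tuple[str, int]]] = {}
    for k in range(n_tfs):
        tf = f"TF{k + 1}"
        motif = _to_str(_random_sequence(rng, MOTIF_LEN))
        motifs[tf] = motif
        genes = {pool[j] for j in chosen[k * targets_per_tf:(k + 1) * targets_per_tf]}
        planted[tf] = genes
        sites[tf] = []
        motif_codes = np.frombuffer(motif.encode(), dtype=np.uint8)
        codes = np.zeros(MOTIF_LEN, dtype=np.int8)
        for b, c in zip(b"ACGT", range(4)):
            codes[motif_codes == b] = c
        for g in sorted(genes):
            tss, strand = tss_of[g], strand_of[g]
            center = tss - MOTIF_OFFSET if strand == "+" else tss + MOTIF_OFFSET
            start = center - MOTIF_LEN // 2
            seq[start:start + MOTIF_LEN] = codes
            sites[tf].append((chrom, center))

    # OPN classes: alternate high/low over the gene list for balance
    opn = {t.gene_id: ("high" if i % 2 == 0 else "low")
           for i, t in enumerate(sorted(transcripts, key=lambda t: t.gene_id))}

    # responders: all planted targets respond, Hill-type, uniform amplitude
    responders = {
        tf: {g: {"amplitude": DEFAULT_AMPLITUDE, "half_max": DEFAULT_HALF_MAX}
             for g in sorted(genes)}
        for tf, genes in planted.items()
    }

    annotation = GenomeAnnotation({chrom: chrom_len}, transcripts)
    truth = GroundTruth(planted, enrichment, motifs, sites, responders, opn,
                        spike_genes=spike_ids)
    return annotation, {chrom: _to_str(seq)}, truth


def _promoter_center(t: Transcript) -> int:
    return t.tss - MOTIF_OFFSET if t.strand == "+" else t.tss + MOTIF_OFFSET


def simulate_chec_track(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    tf: str,
    depth: int = DEFAULT_DEPTH,
    enrichment: float | None = None,
    spike_fraction: float = 0.0,
    seed: int = 0,
) -> SignalTrack:
    """Poisson cut-site track with enrichment at the TF's planted motifs.

    Background is uniform Poisson; each planted motif site receives a
    Gaussian bump (SD 25 bp) sized so the 700 bp promoter sum is
    ``enrichment``-fold the background expectation.  With
    ``spike_fraction > 0`` that fraction of the expected read mass is
    concentrated at the three spike promoters (Aro80-like signal) and the
    rest scaled down accordingly.
    """
    if depth < 1e5:
        raise ValueError("depth must be >= 1e5 reads")
    fold = truth.enrichment if enrichment is None else enrichment
    rng = np.random.default_rng(seed)
    genome_len = sum(annotation.chromosomes.values())
    rate = {c: np.ones(L, dtype=float) for c, L in annotation.chromosomes.items()}

    def add_bump(chrom: str, center: int, mass: float) -> None:
        lo = max(center - 150, 0)
        hi = min(center + 151, len(rate[chrom]))
        xs = np.arange(lo, hi)
        kernel = np.exp(-0.5 * ((xs - center) / PEAK_SD) ** 2)
        rate[chrom][lo:hi] += mass * kernel / kernel.sum()

    per_site = (fold - 1.0) * 700.0  # background rate is 1/bp over a 700 bp promoter
    for chrom, center in truth.motif_sites.get(tf, []):
        if per_site > 0:
            add_bump(chrom, center, per_site)

    if spike_fraction > 0:
        # spike read mass as a fraction of the non-spike mass, so that
        # doubling spike_fraction doubles the spike signal at fixed
        # non-spike signal (and halves the calibration ratio)
        nonspike_mass = sum(v.sum() for v in rate.values())
        spike_mass = nonspike_mass * spike_fraction
        by_id = {t.gene_id: t for t in annotation}
        for g in truth.spike_genes:
            add_bump(by_id[g].chrom, _promoter_center(by_id[g]), spike_mass / 3.0)

    total_rate = sum(v.sum() for v in rate.values())
    scale = depth / total_rate
    data = {c: rng.poisson(v * scale).astype(float) for c, v in rate.items()}
    return SignalTrack(data, metadata={"sample_id": f"{tf}_chec_seed{seed}", "kind": "chec"})


def simulate_nucleosome_track(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    seed: int = 0,
    effect_size: float = 1.0,
    noise_sd: float = 0.2,
) -> SignalTrack:
    """MNase-like occupancy with a planted proximal-nucleosome dichotomy.

    Baseline occupancy 1.0 with multiplicative lognormal noise.  Low-OPN
    genes get an occupied, well-positioned proximal nucleosome (occupancy
    raised by ``effect_size`` in [TSS-150, TSS)); high-OPN genes get a
    depleted/fuzzy proximal region (occupancy reduced toward
    1/(1+effect_size)).  ``effect_size = 0`` removes the dichotomy.
    """
    rng = np.random.default_rng(seed)
    data = {}
    for chrom, L in annotation.chromosomes.items():
        base = np.exp(rng.normal(0.0, noise_sd, size=L))
        data[chrom] = base
    for t in annotation:
        cls = truth.opn_assignment.get(t.gene_id)
        if cls is None:
            continue
        if t.strand == "+":
            ps, pe = t.tss - 150, t.tss
        else:
            ps, pe = t.tss + 1, t.tss + 151
        ps = max(ps, 0)
        pe = min(pe, annotation.chromosomes[t.chrom])
        if cls == "low":
            data[t.chrom][ps:pe] *= 1.0 + effect_size
        else:
            data[t.chrom][ps:pe] /= 1.0 + effect_size
    return SignalTrack(data, metadata={"sample_id": f"mnase_seed{seed}", "kind": "mnase"})


def _simulate_library(
    genes: list[str],
    responders: dict[str, dict[str, float]],
    prefix: str,
    n_strains: int,
    noise_sd: float,
    depth: int,
    n_cells: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, AbundanceTable, dict[str, np.ndarray], list[np.ndarray]]:
    strains = [f"{prefix}_s{i:02d}" for i in range(n_strains)]
    abundance = np.exp2(np.linspace(0.0, 6.0, n_strains))  # 1 .. 64

    base = rng.normal(6.0, 1.5, size=len(genes))
    amp = np.zeros(len(genes))
    half = np.ones(len(genes))
    for i, g in enumerate(genes):
        if g in responders:
            amp[i] = responders[g]["amplitude"]
            half[i] = responders[g]["half_max"]

    counts = np.zeros((len(genes), n_strains), dtype=np.int64)
    for j, a in enumerate(abundance):
        mu = base + amp * (a / (a + half))
        log2_expr = mu + rng.normal(0.0, noise_sd, size=len(genes))
        props = np.exp2(log2_expr)
        props /= props.sum()
        counts[:, j] = rng.multinomial(depth, props)
    raw = pd.DataFrame(counts, index=genes, columns=strains)

    entries = {}
    fluor: dict[str, np.ndarray] = {}
    bg_level = 50.0  # autofluorescence, arbitrary units
    for sid, a in zip(strains, abundance):
        n_debris = int(0.1 * n_cells)
        cell_f = np.exp2(np.log2(bg_level * a) + rng.normal(0.0, 0.3, size=n_cells - n_debris))
        debris_f = np.exp2(np.log2(bg_level / 8) + rng.normal(0.0, 0.3, size=n_debris))
        fluor[sid] = np.concatenate([cell_f, debris_f])
        entries[sid] = AbundanceEntry(sid, float(np.log2(a)), n_cells=n_cells)
    background = [np.exp2(np.log2(bg_level) + rng.normal(0.0, 0.3, size=n_cells))
                  for _ in range(4)]
    return raw, AbundanceTable(entries), fluor, background


def simulate_expression_library(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    tf: str,
    n_strains: int = DEFAULT_N_STRAINS,
    noise_sd: float = DEFAULT_NOISE_SD,
    depth: int = 2_000_000,
    n_cells: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, AbundanceTable, dict[str, np.ndarray], list[np.ndarray]]:
    """A TF-abundance strain library with Hill-type responder genes.

    Strain abundances are log-spaced over [1, 16] (log2 fluorescence units
    over background).  A responder gene's mean log2 expression is
    base + amplitude * a / (a + half_max); non-responders are flat.
    Per-strain counts are multinomial at ``depth`` reads on expression
    proportions, after per-gene-per-strain N(0, noise_sd) log2 noise.
    Per-cell fluorescence is lognormal around each strain's abundance with
    a 10% low-fluorescence debris component; four non-fluorescent
    background runs are also returned.
    """
    if n_strains < 10:
        raise ValueError("need at least 10 strains")
    rng = np.random.default_rng(seed)
    genes = sorted(t.gene_id for t in annotation)
    return _simulate_library(genes, truth.responders.get(tf, {}), tf,
                             n_strains, noise_sd, depth, n_cells, rng)


def simulate_null_library(
    n_genes: int = 2000,
    n_strains: int = DEFAULT_N_STRAINS,
    noise_sd: float = DEFAULT_NOISE_SD,
    depth: int = 2_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, AbundanceTable]:
    """Library of pure-noise genes (no responders), for FDR calibration."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    raw, abundances, _, _ = _simulate_library(genes, {}, "null", n_strains,
                                              noise_sd, depth, n_cells=200, rng=rng)
    return raw, abundances
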