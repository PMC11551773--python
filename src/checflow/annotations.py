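"""Genome annotation model, promoter intervals and gene quantification windows.

All coordinates are 0-based half-open internally.  GFF3 input (1-based,
inclusive) is converted on read; BED/BedGraph-style TSV input is native.

A *promoter* extends upstream from a gene's transcription start site (TSS)
for at most ``max_len`` bp (default 700), stopping early where it meets the
span of any other transcript (on either strand) or the chromosome boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_PROMOTER_LEN = 700


@dataclass(frozen=True)
class Transcript:
    """A transcript with strand-aware TSS and stop-codon coordinates.

    ``tss`` and ``stop_codon`` are genomic positions of the respective
    bases (0-based).  ``start``/``end`` delimit the transcript span as a
    half-open interval.  For a ``+`` strand transcript ``tss == start``;
    for ``-`` strand ``tss == end - 1``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    stop_codon: int | None
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start <= self.tss < self.end:
            raise ValueError(f"{self.gene_id}: TSS {self.tss} outside span [{self.start},{self.end})")


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus a set of transcripts with unique gene ids."""

    chromosomes: dict[str, int]
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.transcripts:
            if t.gene_id in seen:
                raise ValueError(f"duplicate gene_id {t.gene_id!r}")
            seen.add(t.gene_id)
            if t.chrom not in self.chromosomes:
                raise ValueError(f"{t.gene_id}: unknown chromosome {t.chrom!r}")
            L = self.chromosomes[t.chrom]
            if not (0 <= t.start < t.end <= L):
                raise ValueError(f"{t.gene_id}: span [{t.start},{t.end}) outside chromosome (len {L})")
            if t.stop_codon is not None and not (0 <= t.stop_codon < L):
                raise ValueError(f"{t.gene_id}: stop codon {t.stop_codon} outside chromosome")

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.transcripts]


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PromoterSet:
    """gene_id -> promoter interval, each abutting the gene's TSS upstream."""

    promoters: dict[str, Promoter]
    max_len: int = DEFAULT_PROMOTER_LEN

    def __getitem__(self, gene_id: str) -> Promoter:
        return self.promoters[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.promoters

    def __iter__(self) -> Iterator[Promoter]:
        return iter(self.promoters.values())

    def __len__(self) -> int:
        return len(self.promoters)

    def gene_ids(self) -> list[str]:
        return list(self.promoters)

    def to_bed(self, path) -> None:
        """Write as 6-column BED (chrom, start, end, gene_id, score, strand)."""
        with open(path, "w") as fh:
            for p in self.promoters.values():
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n")


def define_promoters(annotation: GenomeAnnotation, max_len: int = DEFAULT_PROMOTER_LEN) -> PromoterSet:
    """Derive promoter intervals upstream of every annotated TSS.

    Each promoter extends from the TSS upstream until the first of:
    ``max_len`` bp, the span of another transcript (either strand), or the
    chromosome boundary.  Genes whose TSS is covered by another transcript
    get a zero-length promoter and are excluded with a warning.
    """
    by_chrom: dict[str, list[Transcript]] = {}
    for t in annotation:
        by_chrom.setdefault(t.chrom, []).append(t)

    promoters: dict[str, Promoter] = {}
    for t in sorted(annotation, key=lambda t: t.gene_id):
        others = [o for o in by_chrom[t.chrom] if o.gene_id != t.gene_id]
        if t.strand == "+":
            cand_start, cand_end = max(t.tss - max_len, 0), t.tss
            for o in others:
                if o.start < cand_end and o.end > cand_start:
                    cand_start = max(cand_start, min(o.end, cand_end))
        else:
            cand_start, cand_end = t.tss + 1, min(t.tss + 1 + max_len, annotation.chromosomes[t.chrom])
            for o in others:
                if o.start < cand_end and o.end > cand_start:
                    cand_end = min(cand_end, max(o.start, cand_start))
        if cand_end <= cand_start:
            log.warning("gene %s: TSS covered by another transcript; promoter excluded", t.gene_id)
            continue
        promoters[t.gene_id] = Promoter(t.gene_id, t.chrom, t.strand, cand_start, cand_end)
    return PromoterSet(promoters, max_len=max_len)


def gene_quant_window(
    annotation: GenomeAnnotation, up: int = 400, down: int = 200
) -> dict[str, tuple[str, int, int]]:
    """Strand-aware expression quantification window around each stop codon.

    Covers ``up`` bp upstream of the stop codon through ``down`` bp
    downstream of it (3'-UTR inclusive), clipped to chromosome bounds.
    Returns gene_id -> (chrom, start, end).  Genes lacking a stop-codon
    coordinate are skipped with a warning.
    """
    windows: dict[str, tuple[str, int, int]] = {}
    for t in annotation:
        if t.stop_codon is None:
            log.warning("gene %s: no stop codon annotated; quantification window skipped", t.gene_id)
            continue
        L = annotation.chromosomes[t.chrom]
        if t.strand == "+":
            start, end = t.stop_codon - up, t.stop_codon + down
        else:
            start, end = t.stop_codon - down, t.stop_codon + up
        windows[t.gene_id] = (t.chrom, max(start, 0), min(end, L))
    return windows


# ---------------------------------------------------------------------------
# I/O


def read_annotation_tsv(path) -> GenomeAnnotation:
    """Read a transcript table: gene_id, chrom, strand, tss, stop, start, end.

    Coordinates in the TSV are 0-based half-open (start/end) with tss/stop
    as 0-based base positions.  Chromosome lengths are taken from a header
    comment line ``# chrom <name> <length>`` (one per chromosome); if
    absent they default to the max observed end per chromosome.
    """
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# chrom"):
                _, _, name, length = line.split()
                chroms[name] = int(length)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "chrom", "strand", "tss", "stop", "start", "end"])
    transcripts = [
        Transcript(r.gene_id, r.chrom, r.strand, int(r.tss),
                   None if pd.isna(r.stop) else int(r.stop), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    if not chroms:
        for t in transcripts:
            chroms[t.chrom] = max(chroms.get(t.chrom, 0), t.end)
    return GenomeAnnotation(chroms, transcripts)


def write_annotation_tsv(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for name, length in annotation.chromosomes.items():
            fh.write(f"# chrom {name} {length}\n")
        for t in annotation:
            stop = "" if t.stop_codon is None else t.stop_codon
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.strand}\t{t.tss}\t{stop}\t{t.start}\t{t.end}\n")


def read_gff3(path, chromosomes: dict[str, int] | None = None,
              feature: str = "mRNA") -> GenomeAnnotation:
    """Read transcripts from GFF3 (1-based inclusive coordinates).

    The TSS is the strand-aware 5' end of the feature and the stop codon
    the 3' end.  ``##sequence-region`` pragmas supply chromosome lengths
    unless ``chromosomes`` is given.  Attributes must carry ``ID=`` or
    ``gene_id=``.
    """
    chroms: dict[str, int] = dict(chromosomes or {})
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                chroms.setdefault(parts[1], int(parts[3]))
                continue
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            chrom, start1, end1, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for kv in attrs.split(";"):
                k, _, v = kv.partition("=")
                if k.strip() in ("ID", "gene_id", "Name"):
                    gene_id = v.strip()
                    break
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID/gene_id attribute: {line!r}")
            start, end = start1 - 1, end1  # to 0-based half-open
            tss = start if strand == "+" else end - 1
            stop = end - 1 if strand == "+" else start
            transcripts.append(Transcript(gene_id, chrom, strand, tss, stop, start, end))
    if not chroms:
        for t in transcripts:
            chroms[t.chrom] = max(chroms.get(t.chrom, 0), t.end)
    return GenomeAnnotation(chroms, transcripts)


def write_gff3(annotation: GenomeAnnotation, path, feature: str = "mRNA") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.chromosomes.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for t in annotation:
            fh.write(f"{t.chrom}\tchecflow\t{feature}\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\tID={t.gene_id}\n")
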