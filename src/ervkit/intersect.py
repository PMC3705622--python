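"""Orientation-aware intersection of repeat loci with gene models.

A locus is *intragenic* when it overlaps the transcribed span of at least
one gene by >= 1 nt (configurable), otherwise *intergenic*.  Orientation is
``same`` iff the locus and feature strands are equal; a locus under two
genes transcribed in opposite directions contributes one orientation count
per gene.  Strandless loci are counted under ``same`` by convention and
flagged.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .core import FormatError, GenomeInterval

FEATURE_KINDS = ("gene", "exon", "intron", "utr5", "utr3", "cds")

_GTF_KIND_MAP = {
    "gene": "gene",
    "transcript": None,  # ignored
    "exon": "exon",
    "intron": "intron",
    "CDS": "cds",
    "five_prime_utr": "utr5",
    "5UTR": "utr5",
    "three_prime_utr": "utr3",
    "3UTR": "utr3",
}


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    kind: str
    interval: GenomeInterval
    coding: bool = True

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene features must be stranded")


@dataclass(frozen=True)
class OverlapRecord:
    locus_id: str
    gene_id: str
    feature_kind: str
    orientation: str  # same | opposite
    overlap_bp: int
    strandless_locus: bool = False


@dataclass
class ContextSummary:
    """Counts shaped like a per-feature-kind, per-orientation summary table."""

    n_loci: int
    intergenic: int
    intragenic: int
    cells: dict[tuple[str, bool, str], int]  # (kind, coding, orientation) -> count

    @property
    def pct_intragenic(self) -> float:
        return 100.0 * self.intragenic / self.n_loci if self.n_loci else 0.0


def parse_gtf(stream: TextIO, derive_introns: bool = True) -> list[GeneFeature]:
    """Parse gene/exon/CDS/UTR features from GTF.

    ``coding`` is taken from a ``gene_biotype``/``gene_type`` attribute when
    present (protein_coding => True), else defaults to True.  When
    ``derive_introns`` is set and a gene has exons but no explicit introns,
    introns are computed as gene minus exons.
    """
    feats: list[GeneFeature] = []
    exons: dict[str, list[GenomeInterval]] = {}
    genes: dict[str, GeneFeature] = {}
    has_introns: set[str] = set()

    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise FormatError(f"GTF line {lineno}: expected 9 columns")
        chrom, _, ftype, start1, end1, _, strand, _, attrs = f[:9]
        kind = _GTF_KIND_MAP.get(ftype)
        if ftype not in _GTF_KIND_MAP or kind is None:
            continue
        gene_id = _gtf_attr(attrs, "gene_id")
        if gene_id is None:
            raise FormatError(f"GTF line {lineno}: missing gene_id attribute")
        biotype = _gtf_attr(attrs, "gene_biotype") or _gtf_attr(attrs, "gene_type")
        coding = True if biotype is None else biotype == "protein_coding"
        iv = GenomeInterval(chrom, int(start1) - 1, int(end1), strand)
        feat = GeneFeature(gene_id=gene_id, kind=kind, interval=iv, coding=coding)
        feats.append(feat)
        if kind == "gene":
            genes[gene_id] = feat
        elif kind == "exon":
            exons.setdefault(gene_id, []).append(iv)
        elif kind == "intron":
            has_introns.add(gene_id)

    if derive_introns:
        for gene_id, gene in genes.items():
            if gene_id in has_introns or gene_id not in exons:
                continue
            feats.extend(
                GeneFeature(gene_id=gene_id, kind="intron", interval=iv, coding=gene.coding)
                for iv in _complement_within(gene.interval, exons[gene_id])
            )
    return feats


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key) :].strip().strip('"')
    return None


def _complement_within(span: GenomeInterval, blocks: Sequence[GenomeInterval]) -> list[GenomeInterval]:
    """Intervals inside *span* not covered by *blocks* (gene minus exons)."""
    out = []
    pos = span.start
    for b in sorted(blocks, key=lambda iv: iv.start):
        s, e = max(b.start, span.start), min(b.end, span.end)
        if s > pos:
            out.append(GenomeInterval(span.chrom, pos, s, span.strand))
        pos = max(pos, e)
    if pos < span.end:
        out.append(GenomeInterval(span.chrom, pos, span.end, span.strand))
    return out


def read_bed6(stream: TextIO) -> list[tuple[str, GenomeInterval]]:
    """Read BED6 loci as (name, interval) pairs."""
    loci = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 4:
            raise FormatError(f"BED line {lineno}: need >= 4 columns")
        strand = f[5] if len(f) >= 6 else "."
        loci.append((f[3], GenomeInterval(f[0], int(f[1]), int(f[2]), strand)))
    return loci


def intersect(
    loci: Sequence[tuple[str, GenomeInterval]],
    features: Sequence[GeneFeature],
    min_overlap: int = 1,
) -> list[OverlapRecord]:
    """All (locus, feature) overlaps of >= min_overlap bp, via a sorted sweep.

    Orientation is computed from strands; strandless loci are flagged and
    counted as ``same``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[GeneFeature]] = {}
    for feat in features:
        by_chrom.setdefault(feat.interval.chrom, []).append(feat)
    starts: dict[str, list[int]] = {}
    for chrom, feats in by_chrom.items():
        feats.sort(key=lambda ft: ft.interval.start)
        starts[chrom] = [ft.interval.start for ft in feats]

    records: list[OverlapRecord] = []
    for locus_id, iv in loci:
        feats = by_chrom.get(iv.chrom, [])
        if not feats:
            continue
        # any feature with start < locus end can overlap; scan those
        hi = bisect.bisect_left(starts[iv.chrom], iv.end)
        for feat in feats[:hi]:
            ov = iv.overlap(feat.interval)
            if ov >= min_overlap:
                strandless = iv.strand == "."
                orientation = (
                    "same" if strandless or iv.strand == feat.interval.strand else "opposite"
                )
                records.append(
                    OverlapRecord(
                        locus_id=locus_id,
                        gene_id=feat.gene_id,
                        feature_kind=feat.kind,
                        orientation=orientation,
                        overlap_bp=ov,
                        strandless_locus=strandless,
                    )
                )
    return records


def intersect_bruteforce(
    loci: Sequence[tuple[str, GenomeInterval]],
    features: Sequence[GeneFeature],
    min_overlap: int = 1,
) -> list[OverlapRecord]:
    """Quadratic all-pairs reference implementation (kept as a test oracle)."""
    records = []
    for locus_id, iv in loci:
        for feat in features:
            ov = iv.overlap(feat.interval)
            if ov >= min_overlap:
                strandless = iv.strand == "."
                records.append(
                    OverlapRecord(
                        locus_id=locus_id,
                        gene_id=feat.gene_id,
                        feature_kind=feat.kind,
                        orientation=(
                            "same" if strandless or iv.strand == feat.interval.strand else "opposite"
                        ),
                        overlap_bp=ov,
                        strandless_locus=strandless,
                    )
                )
    return records


def classify_context(
    locus_id: str,
    locus: GenomeInterval,
    features: Sequence[GeneFeature],
    min_overlap: int = 1,
) -> tuple[str, list[OverlapRecord]]:
    """Classify one locus as intergenic/intragenic against gene spans.

    Returns the class plus one gene-span overlap record per overlapping
    gene, so a locus beneath two genes on opposite strands yields two
    orientation counts.
    """
    gene_feats = [ft for ft in features if ft.kind == "gene"]
    recs = intersect([(locus_id, locus)], gene_feats, min_overlap=min_overlap)
    return ("intragenic" if recs else "intergenic"), recs


def summarize(
    records: Sequence[OverlapRecord],
    loci: Sequence[tuple[str, GenomeInterval]],
    coding_by_gene: dict[str, bool] | None = None,
) -> ContextSummary:
    """Aggregate overlap records into the per-kind/orientation summary.

    Intragenic status is decided by gene-span records only; feature-kind
    cells count every record of that kind independently.
    """
    intragenic_loci = {r.locus_id for r in records if r.feature_kind == "gene"}
    n_loci = len(loci)
    intragenic = sum(1 for locus_id, _ in loci if locus_id in intragenic_loci)
    cells: dict[tuple[str, bool, str], int] = {}
    for r in records:
        coding = coding_by_gene.get(r.gene_id, True) if coding_by_gene else True
        key = (r.feature_kind, coding, r.orientation)
        cells[key] = cells.get(key, 0) + 1
    return ContextSummary(
        n_loci=n_loci,
        intergenic=n_loci - intragenic,
        intragenic=intragenic,
        cells=cells,
    )


def write_records_tsv(records: Iterable[OverlapRecord], stream: TextIO) -> None:
    stream.write("locus_id\tgene_id\tfeature_kind\torientation\toverlap_bp\tstrandless\n")
    for r in records:
        stream.write(
            f"{r.locus_id}\t{r.gene_id}\t{r.feature_kind}\t{r.orientation}"
            f"\t{r.overlap_bp}\t{int(r.strandless_locus)}\n"
        )


def write_summary_tsv(summary: ContextSummary, stream: TextIO) -> None:
    stream.write("metric\tvalue\n")
    stream.write(f"n_loci\t{summary.n_loci}\n")
    stream.write(f"intergenic\t{summary.intergenic}\n")
    stream.write(f"intragenic\t{summary.intragenic}\n")
    stream.write(f"pct_intragenic\t{summary.pct_intragenic:.1f}\n")
    for (kind, coding, orientation), count in sorted(summary.cells.items()):
        label = "coding" if coding else "noncoding"
        stream.write(f"{kind}.{label}.{orientation}\t{count}\n")
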