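"""Repeat-table parsing, name filtering, size histograms, fragment statistics,
and solo-LTR / provirus element classification.

Fragment-level accounting is the default reporting granularity: annotation
tools report one row per contiguous masked segment, and a single element
disrupted by deletions or insertions appears as several rows.  Element-level
calls are produced separately by :func:`classify_elements`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .core import FormatError, GenomeInterval

logger = logging.getLogger(__name__)

#: Default repeat names for the targeted retroelement family: three LTR
#: subfamily names plus the internal-genome name.
LTR_NAMES = frozenset({"LTR5_Hs", "LTR5A", "LTR5B"})
INTERNAL_NAMES = frozenset({"HERVK-int"})
DEFAULT_NAMES = LTR_NAMES | INTERNAL_NAMES

#: Full-length reference sizes (bp) used for percent-of-full statistics.
LTR_FULL_BP = 968
INTERNAL_FULL_BP = 7500


@dataclass(frozen=True)
class RepeatFragment:
    """One masker-reported repeat interval."""

    interval: GenomeInterval
    rep_name: str
    rep_class: str = ""
    element_id: int | None = None

    def __post_init__(self) -> None:
        if not self.rep_name:
            raise ValueError("empty rep_name")

    @property
    def length(self) -> int:
        return self.interval.length()


@dataclass(frozen=True)
class SizeHistogram:
    """Fragment-length histogram over fixed windows of ``window_bp``."""

    window_bp: int
    bins: dict[int, int]

    @property
    def n(self) -> int:
        return sum(self.bins.values())

    def count(self, bin_index: int) -> int:
        return self.bins.get(bin_index, 0)

    def to_rows(self) -> list[tuple[int, int, int]]:
        """(bin_start, bin_end, count) rows in ascending bin order."""
        return [
            (k * self.window_bp, (k + 1) * self.window_bp, v)
            for k, v in sorted(self.bins.items())
        ]


@dataclass(frozen=True)
class CatalogStats:
    """Aggregate fragment statistics relative to a full-length reference."""

    n_fragments: int
    total_bp: int
    full_length_bp: int

    @property
    def mean_len(self) -> float:
        return self.total_bp / self.n_fragments

    @property
    def mean_len_int(self) -> int:
        # truncation, not nearest-integer: published means are rendered
        # this way (e.g. 487,441/255 = 1911.53 printed as 1,911)
        return int(self.mean_len)

    @property
    def pct_of_full(self) -> float:
        return 100.0 * self.mean_len / self.full_length_bp

    @property
    def pct_of_full_int(self) -> int:
        return round(self.pct_of_full)

    @property
    def frags_per_element(self) -> float:
        return self.full_length_bp / self.mean_len


@dataclass(frozen=True)
class ElementCall:
    """A cluster of fragments interpreted as one genomic element."""

    span: GenomeInterval
    kind: str  # solo_ltr | provirus | internal_only | ltr_fragment
    fragments: tuple[RepeatFragment, ...]


_UCSC_COLUMNS = ("genoName", "genoStart", "genoEnd", "strand", "repName")


def parse_repeat_table(stream: TextIO, dialect: str = "ucsc_rmsk_tsv") -> list[RepeatFragment]:
    """Parse a repeat annotation table into internal coordinates.

    Dialects:

    ``ucsc_rmsk_tsv``
        Tab-separated with a header naming at least genoName, genoStart,
        genoEnd, strand, repName (repClass and id optional).  Coordinates
        are 0-based half-open already.
    ``rm_out``
        Native masker ``.out``: whitespace-separated, 1-based inclusive
        begin/end in columns 6-7, strand in column 9 (``C`` = minus),
        name in column 10, class in column 11, joining id in column 15.
    """
    if dialect == "ucsc_rmsk_tsv":
        return _parse_ucsc(stream)
    if dialect == "rm_out":
        return _parse_rm_out(stream)
    raise FormatError(f"unknown repeat-table dialect: {dialect!r}")


def _parse_ucsc(stream: TextIO) -> list[RepeatFragment]:
    header_line = stream.readline()
    if not header_line.strip():
        return []
    header = header_line.lstrip("#").rstrip("\n").split("\t")
    try:
        idx = {c: header.index(c) for c in _UCSC_COLUMNS}
    except ValueError as exc:
        raise FormatError(f"rmsk TSV header missing column: {exc}") from exc
    cls_i = header.index("repClass") if "repClass" in header else None
    id_i = header.index("id") if "id" in header else None

    fragments = []
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        try:
            start, end = int(f[idx["genoStart"]]), int(f[idx["genoEnd"]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinate ({exc})") from exc
        fragments.append(
            RepeatFragment(
                interval=GenomeInterval(f[idx["genoName"]], start, end, f[idx["strand"]]),
                rep_name=f[idx["repName"]],
                rep_class=f[cls_i] if cls_i is not None else "",
                element_id=int(f[id_i]) if id_i is not None and f[id_i] else None,
            )
        )
    return fragments


def _parse_rm_out(stream: TextIO) -> list[RepeatFragment]:
    fragments = []
    for lineno, line in enumerate(stream, start=1):
        f = line.split()
        if not f:
            continue
        # .out preamble: "SW" header rows and the blank-score header
        if f[0] in ("SW", "score") or not f[0][0].isdigit():
            continue
        if len(f) < 11:
            raise FormatError(f"rm_out line {lineno}: too few columns")
        try:
            begin1, end1 = int(f[5]), int(f[6])
        except ValueError as exc:
            raise FormatError(f"rm_out line {lineno}: non-integer coordinate ({exc})") from exc
        strand = "-" if f[8] == "C" else "+"
        element_id = int(f[14]) if len(f) > 14 and f[14].isdigit() else None
        fragments.append(
            RepeatFragment(
                interval=GenomeInterval(f[4], begin1 - 1, end1, strand),
                rep_name=f[9],
                rep_class=f[10],
                element_id=element_id,
            )
        )
    return fragments


def filter_family(
    fragments: Iterable[RepeatFragment],
    ltr_names: frozenset[str] = LTR_NAMES,
    internal_names: frozenset[str] = INTERNAL_NAMES,
) -> tuple[list[RepeatFragment], list[RepeatFragment]]:
    """Partition fragments into (LTR, internal) by repeat name; other names
    are dropped."""
    ltrs, internals = [], []
    for frag in fragments:
        if frag.rep_name in ltr_names:
            ltrs.append(frag)
        elif frag.rep_name in internal_names:
            internals.append(frag)
    return ltrs, internals


def size_histogram(fragments: Sequence[RepeatFragment], window_bp: int) -> SizeHistogram:
    """Histogram of fragment lengths; bin k counts lengths in [k*w, (k+1)*w)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    bins: dict[int, int] = {}
    for frag in fragments:
        k = frag.length // window_bp
        bins[k] = bins.get(k, 0) + 1
    return SizeHistogram(window_bp=window_bp, bins=bins)


def catalog_stats(fragments: Sequence[RepeatFragment], full_length_bp: int) -> CatalogStats:
    if not fragments:
        raise ValueError("catalog_stats requires at least one fragment")
    if full_length_bp <= 0:
        raise ValueError("full_length_bp must be positive")
    total = sum(f.length for f in fragments)
    return CatalogStats(
        n_fragments=len(fragments), total_bp=total, full_length_bp=full_length_bp
    )


def stats_from_totals(n_fragments: int, total_bp: int, full_length_bp: int) -> CatalogStats:
    """Build stats directly from published totals (no fragment list needed)."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    return CatalogStats(n_fragments=n_fragments, total_bp=total_bp, full_length_bp=full_length_bp)


def classify_elements(
    ltr_fragments: Sequence[RepeatFragment],
    internal_fragments: Sequence[RepeatFragment],
    gap_tol_bp: int = 2000,
    ltr_full_bp: int = LTR_FULL_BP,
) -> list[ElementCall]:
    """Cluster same-strand fragments into elements and classify them.

    Fragments on the same chrom+strand whose gaps are <= ``gap_tol_bp``
    form one element.  When every member of a run carries a masker joining
    id, clustering follows the id; otherwise positional clustering is used.

    Classification: cluster with >=1 internal fragment and >=1 LTR fragment
    -> provirus; LTR-only cluster -> solo_ltr if total LTR length >= 50% of
    ``ltr_full_bp`` else ltr_fragment; internal-only -> internal_only.
    """
    tagged = [(f, "ltr") for f in ltr_fragments] + [(f, "int") for f in internal_fragments]
    by_group: dict[tuple[str, str], list[tuple[RepeatFragment, str]]] = {}
    for frag, role in tagged:
        by_group.setdefault((frag.interval.chrom, frag.interval.strand), []).append((frag, role))

    calls: list[ElementCall] = []
    for (chrom, strand), members in sorted(by_group.items()):
        members.sort(key=lambda m: (m[0].interval.start, m[0].interval.end))
        clusters: list[list[tuple[RepeatFragment, str]]] = []
        use_ids = all(f.element_id is not None for f, _ in members)
        if use_ids:
            by_id: dict[int, list[tuple[RepeatFragment, str]]] = {}
            for m in members:
                by_id.setdefault(m[0].element_id, []).append(m)  # type: ignore[arg-type]
            clusters = [by_id[k] for k in sorted(by_id)]
        else:
            current: list[tuple[RepeatFragment, str]] = []
            prev_end = None
            for m in members:
                iv = m[0].interval
                if prev_end is not None and iv.start < prev_end:
                    logger.warning(
                        "overlapping fragments on %s%s at %d; merging", chrom, strand, iv.start
                    )
                if prev_end is None or iv.start - prev_end <= gap_tol_bp:
                    current.append(m)
                else:
                    clusters.append(current)
                    current = [m]
                prev_end = max(prev_end or 0, iv.end)
            if current:
                clusters.append(current)

        for cluster in clusters:
            frags = tuple(f for f, _ in cluster)
            roles = {role for _, role in cluster}
            span = GenomeInterval(
                chrom,
                min(f.interval.start for f in frags),
                max(f.interval.end for f in frags),
                strand,
            )
            if "int" in roles and "ltr" in roles:
                kind = "provirus"
            elif roles == {"int"}:
                kind = "internal_only"
            else:
                ltr_bp = sum(f.length for f in frags)
                kind = "solo_ltr" if ltr_bp >= 0.5 * ltr_full_bp else "ltr_fragment"
            calls.append(ElementCall(span=span, kind=kind, fragments=frags))
    return calls


def write_fragment_bed(fragments: Iterable[RepeatFragment], stream: TextIO) -> None:
    """BED6 output: name column carries the repeat name, score is length."""
    for frag in fragments:
        iv = frag.interval
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag.rep_name}\t{frag.length}\t{iv.strand}\n"
        )


def write_histogram_tsv(hist: SizeHistogram, stream: TextIO) -> None:
    stream.write("bin_start\tbin_end\tcount\n")
    for start, end, count in hist.to_rows():
        stream.write(f"{start}\t{end}\t{count}\n")


def write_stats_tsv(stats_by_name: dict[str, CatalogStats], stream: TextIO) -> None:
    stream.write(
        "set\tn_fragments\ttotal_bp\tmean_len\tmean_len_int\tpct_of_full\tpct_of_full_int\tfrags_per_element\n"
    )
    for name, s in stats_by_name.items():
        stream.write(
            f"{name}\t{s.n_fragments}\t{s.total_bp}\t{s.mean_len:.2f}\t{s.mean_len_int}"
            f"\t{s.pct_of_full:.2f}\t{s.pct_of_full_int}\t{s.frags_per_element:.2f}\n"
        )
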