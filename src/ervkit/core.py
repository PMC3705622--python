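"""Shared coordinate conventions, sequence types, and plain-text format IO.

Internal coordinates are 0-based half-open everywhere.  The 1-based
inclusive convention appears only in two places: UCSC-style display spans
(``parse_ucsc_span`` / ``format_ucsc_span``) and RepeatMasker ``.out``
parsing (handled in :mod:`ervkit.catalog`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

VALID_STRANDS = ("+", "-", ".")
_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# en-dash, em-dash, minus sign, hyphen all accepted as span separators
_SPAN_RE = re.compile(
    r"^\s*(?:(?P<chrom>[\w.]+):)?(?P<start>[\d,]+)\s*[–—−-]\s*(?P<end>[\d,]+)\s*$"
)


class FormatError(ValueError):
    """Raised on malformed input text (FASTA, spans, tables)."""


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval, 0-based.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name ("" allowed for bare spans).
    start, end : int
        0-based half-open bounds, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval bounds {self.start}..{self.end} (need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Overlap in bp with *other* (0 if different chrom or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"invalid bases in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair.

    ``fwd`` is read 5'->3' on the sense strand; ``rev`` is read 5'->3' on
    the antisense strand (i.e. it matches the sense strand as
    ``revcomp(rev)``).
    """

    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for label, primer in (("fwd", self.fwd), ("rev", self.rev)):
            if len(primer) < 15:
                raise ValueError(
                    f"primer {self.name}/{label} shorter than 15 nt: {primer!r}"
                )
            bad = set(primer) - _ALPHABET
            if bad:
                raise ValueError(f"invalid bases in primer {self.name}/{label}")


def parse_ucsc_span(text: str) -> GenomeInterval:
    """Parse a UCSC-style display span into an internal interval.

    Display spans are 1-based inclusive, e.g. ``chr1:155,596,457–155,605,636``
    or bare ``5–5`` (a single base).  En-dash and ASCII hyphen are both
    accepted; thousands separators are stripped.
    """
    m = _SPAN_RE.match(text)
    if m is None:
        raise FormatError(f"malformed coordinate span: {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise FormatError(f"non-positive or inverted span: {text!r}")
    return GenomeInterval(chrom=m.group("chrom") or "", start=start1 - 1, end=end1)


def format_ucsc_span(interval: GenomeInterval, thousands: bool = True) -> str:
    """Render an internal interval back to 1-based inclusive display form."""
    fmt = "{:,d}" if thousands else "{:d}"
    span = fmt.format(interval.start + 1) + "–" + fmt.format(interval.end)
    return f"{interval.chrom}:{span}" if interval.chrom else span


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement bases {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(stream: TextIO) -> list[SequenceRecord]:
    """Read FASTA records (wrapped or unwrapped); sequences are upper-cased.

    Raises :class:`FormatError` on empty record bodies or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    rec_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if rec_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"empty sequence body for record {rec_id!r}")
        seen[rec_id] = seen.get(rec_id, 0) + 1
        records.append(SequenceRecord(id=rec_id, seq=seq))

    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            rec_id = line[1:].split()[0] if line[1:].split() else ""
            if not rec_id:
                raise FormatError("FASTA header with empty id")
            chunks = []
        else:
            if rec_id is None:
                raise FormatError(f"sequence data before first header: {line[:30]!r}")
            chunks.append(line)
    _flush()

    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"duplicate FASTA ids: {dups}")
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: TextIO, width: int = 70) -> None:
    for rec in records:
        stream.write(f">{rec.id}\n")
        for i in range(0, len(rec.seq), width):
            stream.write(rec.seq[i : i + width] + "\n")


def read_primer_tsv(stream: TextIO) -> list[PrimerPair]:
    """Read a primer table: TSV with header columns name, fwd, rev."""
    header = stream.readline().rstrip("\n").split("\t")
    try:
        idx = {k: header.index(k) for k in ("name", "fwd", "rev")}
    except ValueError as exc:
        raise FormatError(f"primer TSV missing column: {exc}") from exc
    pairs = []
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            pairs.append(
                PrimerPair(
                    name=fields[idx["name"]],
                    fwd=fields[idx["fwd"]].upper(),
                    rev=fields[idx["rev"]].upper(),
                )
            )
        except (IndexError, ValueError) as exc:
            raise FormatError(f"primer TSV line {lineno}: {exc}") from exc
    return pairs


def find_primer_sites(template: str, primer: str, max_mismatch: int = 1) -> list[int]:
    """Start positions where *primer* matches *template* with <= max_mismatch
    substitutions (no indels).  N never counts as a match."""
    n, k = len(template), len(primer)
    hits = []
    for i in range(n - k + 1):
        mm = 0
        window = template[i : i + k]
        for a, b in zip(window, primer):
            if a != b or a == "N":
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            hits.append(i)
    return hits
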