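"""Splice-junction inference against a proviral model, donor/acceptor
classification (major vs minor spliceosome), and type I/II classification
via presence/absence of the 292-bp segment spanning the pol-env boundary.

Junction coordinates follow the "first intron base / first exon base after
the intron" convention.  Offsets from the canonical sites are signed with
downstream positive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .core import revcomp
from .assign import make_aligner

#: U12-type donor consensus used to label minor-spliceosome donors.  The
#: exact consensus is a configurable modelling choice, not a measured value.
MINOR_DONOR_PATTERN = "[GA]TATCC"

#: A spliced placement must beat the best contiguous placement by at least
#: this many matches before a junction is reported (guards against
#: spurious micro-introns).
DEFAULT_MIN_MARGIN = 8

TYPE2_SEGMENT_LEN = 292


@dataclass(frozen=True)
class ProvirusModel:
    """A proviral sequence with landmark coordinates (all 0-based on seq).

    ``canonical_5ss`` is the first intronic base of the canonical intron;
    ``canonical_3ss`` is the first exonic base after it.  ``type2_segment``
    is the 292-bp stretch spanning the pol-env boundary (None for a type I
    model that lacks it).
    """

    seq: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    canonical_5ss: int
    canonical_3ss: int
    type2_segment: tuple[int, int] | None
    provirus_type: str  # "I" | "II"

    def __post_init__(self) -> None:
        if not (self.ltr5[0] < self.ltr5[1] <= self.ltr3[0] < self.ltr3[1] <= len(self.seq)):
            raise ValueError("LTR intervals out of order")
        if not (0 <= self.canonical_5ss < self.canonical_3ss <= len(self.seq)):
            raise ValueError("canonical splice sites out of order")
        if self.type2_segment is not None:
            s, e = self.type2_segment
            if e - s != TYPE2_SEGMENT_LEN:
                raise ValueError(
                    f"type2_segment must be {TYPE2_SEGMENT_LEN} bp, got {e - s}"
                )
        if self.provirus_type not in ("I", "II"):
            raise ValueError("provirus_type must be 'I' or 'II'")

    def to_landmarks_json(self) -> str:
        d = {
            "ltr5": list(self.ltr5),
            "ltr3": list(self.ltr3),
            "canonical_5ss": self.canonical_5ss,
            "canonical_3ss": self.canonical_3ss,
            "type2_segment": list(self.type2_segment) if self.type2_segment else None,
            "provirus_type": self.provirus_type,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_landmarks(cls, seq: str, landmarks: dict) -> "ProvirusModel":
        seg = landmarks.get("type2_segment")
        return cls(
            seq=seq,
            ltr5=tuple(landmarks["ltr5"]),
            ltr3=tuple(landmarks["ltr3"]),
            canonical_5ss=landmarks["canonical_5ss"],
            canonical_3ss=landmarks["canonical_3ss"],
            type2_segment=tuple(seg) if seg else None,
            provirus_type=landmarks["provirus_type"],
        )


@dataclass(frozen=True)
class SpliceJunction:
    donor_pos: int
    acceptor_pos: int
    donor_offset: int
    acceptor_offset: int
    donor_dinuc: str
    acceptor_dinuc: str
    ss_class: str  # canonical | alt_major | alt_minor | non_canonical
    matches: int


def _to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _offset_cumsum(q: np.ndarray, t: np.ndarray, off_lo: int, off_hi: int) -> tuple[np.ndarray, np.ndarray]:
    """Ungapped match counts of query *q* against target *t* at every
    diagonal offset in [off_lo, off_hi].

    Returns (offsets, C) with C[r, i] = number of matching positions among
    q[0:i] placed at t[offsets[r]:offsets[r]+i]; out-of-range target
    positions and N bases never match.
    """
    n, m = len(q), len(t)
    offsets = np.arange(off_lo, off_hi + 1)
    pos = offsets[:, None] + np.arange(n)[None, :]
    valid = (pos >= 0) & (pos < m)
    tvals = t[np.clip(pos, 0, m - 1)]
    match = (tvals == q[None, :]) & valid & (q != ord("N"))[None, :]
    c = np.zeros((len(offsets), n + 1), dtype=np.int32)
    np.cumsum(match, axis=1, out=c[:, 1:])
    return offsets, c


def find_junction(
    cdna: str,
    model: ProvirusModel,
    search_window: int = 1000,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> SpliceJunction | None:
    """Infer a single splice junction by best split placement of the cDNA.

    Over all split points of the cDNA and all (donor, acceptor) positions
    within ``search_window`` of the canonical sites, the placement
    maximizing total ungapped matches of prefix (ending at the donor) plus
    suffix (starting at the acceptor) is chosen.  Ties are broken by intron
    boundary class (GT..AG > AT..AC > other), then smallest
    |donor_offset| + |acceptor_offset|, then leftmost donor.  Returns None
    when the best spliced placement does not beat the best contiguous
    placement by >= ``min_margin`` matches.
    """
    if len(cdna) < 60:
        raise ValueError("cDNA shorter than 60 nt")
    if model.canonical_5ss is None or model.canonical_3ss is None:
        raise ValueError("model lacks canonical splice sites")

    q, t = _to_u8(cdna), _to_u8(model.seq)
    n, m = len(q), len(t)
    c5, c3 = model.canonical_5ss, model.canonical_3ss
    d_lo, d_hi = max(0, c5 - search_window), min(m, c5 + search_window)
    a_lo, a_hi = max(0, c3 - search_window), min(m, c3 + search_window)

    # prefix: split i, diagonal offset o => donor d = o + i
    off5, cum5 = _offset_cumsum(q, t, d_lo - n + 1, d_hi - 1)
    # suffix: acceptor c = o + i; suffix matches = row total - prefix
    off3, cum3 = _offset_cumsum(q, t, a_lo - n + 1, a_hi - 1)
    suf3 = cum3[:, -1:] - cum3

    i_arr = np.arange(n + 1)[None, :]
    d_mat = off5[:, None] + i_arr  # donor position per (row, split)
    a_mat = off3[:, None] + i_arr
    valid5 = (d_mat >= d_lo) & (d_mat <= d_hi) & (i_arr >= 1)
    valid3 = (a_mat >= a_lo) & (a_mat <= a_hi) & (i_arr <= n - 1)

    neg = np.int32(-1)
    p5 = np.where(valid5, cum5, neg)
    p3 = np.where(valid3, suf3, neg)
    best5 = p5.max(axis=0)  # per split i
    best3 = p3.max(axis=0)

    usable = (best5 >= 0) & (best3 >= 0)
    if not usable.any():
        return None
    totals = np.where(usable, best5 + best3, -1)
    best_total = int(totals.max())

    # contiguous (unspliced) placement over the whole model
    _, cum_all = _offset_cumsum(q, t, -n + 1, m - 1)
    contiguous_best = int(cum_all[:, -1].max())
    if best_total < contiguous_best + min_margin:
        return None

    # enumerate optimal (split, donor, acceptor) triples for tie-breaking
    candidates: list[tuple[tuple[int, int, int], int, int, int]] = []
    for i in np.nonzero(totals == best_total)[0]:
        i = int(i)
        rows5 = np.nonzero(p5[:, i] == best5[i])[0]
        rows3 = np.nonzero(p3[:, i] == best3[i])[0]
        for r5 in rows5:
            d = int(off5[r5]) + i
            for r3 in rows3:
                a = int(off3[r3]) + i
                if d >= a:
                    continue
                intron = (model.seq[d : d + 2], model.seq[a - 2 : a])
                if intron == ("GT", "AG"):
                    cls_rank = 0
                elif intron == ("AT", "AC"):
                    cls_rank = 1
                else:
                    cls_rank = 2
                key = (cls_rank, abs(d - c5) + abs(a - c3), d)
                candidates.append((key, i, d, a))
    if not candidates:
        return None
    _, _, d, a = min(candidates, key=lambda x: x[0])

    junction = SpliceJunction(
        donor_pos=d,
        acceptor_pos=a,
        donor_offset=d - c5,
        acceptor_offset=a - c3,
        donor_dinuc=model.seq[d : d + 2],
        acceptor_dinuc=model.seq[a - 2 : a],
        ss_class="",
        matches=best_total,
    )
    return SpliceJunction(
        **{**junction.__dict__, "ss_class": classify_sites(model, junction)}
    )


def classify_sites(
    model: ProvirusModel,
    junction: SpliceJunction,
    minor_donor_pattern: str = MINOR_DONOR_PATTERN,
) -> str:
    """Label a junction: canonical (both offsets 0), alt_major (GT donor),
    alt_minor (donor context matching the minor-spliceosome consensus), or
    non_canonical.  Donor class takes labelling precedence; the acceptor
    dinucleotide is carried on the junction record for inspection."""
    if not (0 <= junction.donor_pos < len(model.seq)):
        raise ValueError("junction donor outside model")
    if junction.donor_offset == 0 and junction.acceptor_offset == 0:
        return "canonical"
    if junction.donor_dinuc == "GT":
        return "alt_major"
    donor_ctx = model.seq[junction.donor_pos : junction.donor_pos + 6]
    if re.fullmatch(minor_donor_pattern, donor_ctx):
        return "alt_minor"
    return "non_canonical"


def find_deletions(
    query: str,
    reference: str,
    min_len: int = 50,
) -> list[tuple[int, int]]:
    """Deletions in *query* relative to *reference* of >= min_len bp,
    found by global alignment.  Returned as half-open intervals in
    reference coordinates."""
    aligner = make_aligner(mode="global")
    # long indels should stay as single gaps
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.2
    aln = aligner.align(reference, query)[0]
    r_blocks, q_blocks = aln.aligned
    deletions = []
    for k in range(1, len(r_blocks)):
        r_gap = int(r_blocks[k][0]) - int(r_blocks[k - 1][1])
        q_gap = int(q_blocks[k][0]) - int(q_blocks[k - 1][1])
        if r_gap - q_gap >= min_len:
            deletions.append((int(r_blocks[k - 1][1]) + q_gap, int(r_blocks[k][0])))
    return deletions


def detect_type(
    locus_seq: str,
    reference: ProvirusModel,
    tolerance: int = 10,
    flank: int = 600,
) -> tuple[str, int, tuple[int, int] | None]:
    """Classify a locus as type I/II by aligning it around the pol-env
    boundary of a type II reference.

    A deletion of ``292 +/- tolerance`` bp overlapping the reference's
    type2_segment yields type I; the deletion length is reported exactly.
    """
    if reference.type2_segment is None:
        raise ValueError("reference model must carry a type2_segment")
    seg_s, seg_e = reference.type2_segment
    win_s, win_e = max(0, seg_s - flank), min(len(reference.seq), seg_e + flank)
    ref_win = reference.seq[win_s:win_e]
    # the locus region homologous to the window sits near the same
    # coordinates, shifted left by at most the deletion length
    loc_s = max(0, win_s - TYPE2_SEGMENT_LEN - tolerance)
    loc_e = min(len(locus_seq), win_e + tolerance)
    loc_win = locus_seq[loc_s:loc_e]

    best: tuple[int, tuple[int, int]] | None = None
    for rs, re_ in find_deletions(loc_win, ref_win, min_len=100):
        abs_iv = (rs + win_s, re_ + win_s)
        if abs_iv[0] < seg_e and abs_iv[1] > seg_s:  # overlaps the segment
            dlen = re_ - rs
            if best is None or dlen > best[0]:
                best = (dlen, abs_iv)
    if best is not None and abs(best[0] - TYPE2_SEGMENT_LEN) <= tolerance:
        return "I", best[0], best[1]
    return "II", (best[0] if best else 0), (best[1] if best else None)


def predict_amplicon_sizes(
    template: str,
    fwd: str,
    rev: str,
    max_mismatch: int = 1,
    max_len: int = 5000,
) -> list[int]:
    """Expected PCR product length(s) on a template (primers included).

    The reverse primer is matched as its reverse complement downstream of
    each forward-primer site; products longer than ``max_len`` are dropped.
    """
    from .core import find_primer_sites

    fwd_sites = find_primer_sites(template, fwd, max_mismatch)
    rev_sites = find_primer_sites(template, revcomp(rev), max_mismatch)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            length = r + len(rev) - f
            if r >= f + len(fwd) and length <= max_len:
                products.append(length)
    return sorted(products)


def write_junctions_tsv(
    rows: Sequence[tuple[str, SpliceJunction | None]], stream: TextIO
) -> None:
    stream.write(
        "query\tdonor_pos\tacceptor_pos\tdonor_offset\tacceptor_offset"
        "\tdonor_dinuc\tacceptor_dinuc\tss_class\tmatches\n"
    )
    for name, j in rows:
        if j is None:
            stream.write(f"{name}\t-\t-\t-\t-\t-\t-\tunspliced\t-\n")
        else:
            stream.write(
                f"{name}\t{j.donor_pos}\t{j.acceptor_pos}\t{j.donor_offset}"
                f"\t{j.acceptor_offset}\t{j.donor_dinuc}\t{j.acceptor_dinuc}"
                f"\t{j.ss_class}\t{j.matches}\n"
            )
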