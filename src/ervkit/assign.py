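"""Assignment of cDNA clones to their locus of origin among near-identical
paralogous candidates.

Paralogous loci of a recently expanded element family are ~99% identical,
so a clone can only be placed by exact accounting of the handful of
single-nucleotide differences among candidates.  The score is defined with
two keys: the integer count of matching aligned columns (primary) and the
percent identity over alignment columns (secondary).  A query whose best
score is tied across >= 2 candidates on BOTH keys is *ambiguous* — integer
comparison on the primary key avoids floating-point tie fragility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core import GenomeInterval, SequenceRecord, revcomp

#: Local-alignment scoring: unit match/mismatch, affine gaps
#: (first gap column -2, each further column -1).  N never matches.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
OPEN_GAP_SCORE = -2.0
EXTEND_GAP_SCORE = -1.0

_ALPHA = "ACGTN"


def _substitution_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_ALPHA, dims=2)
    for a in _ALPHA:
        for b in _ALPHA:
            if a == b and a != "N":
                m[a, b] = MATCH_SCORE
            else:
                m[a, b] = MISMATCH_SCORE
    return m


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix()
    aligner.open_gap_score = OPEN_GAP_SCORE
    aligner.extend_gap_score = EXTEND_GAP_SCORE
    return aligner


@dataclass(frozen=True)
class CandidateLocus:
    locus_id: str
    seq: str
    interval: GenomeInterval | None = None


@dataclass(frozen=True)
class IdentityResult:
    """Best local alignment of a query against one target."""

    identity_pct: float
    match_count: int
    columns: int
    score: float
    mismatches: tuple[tuple[int, str, str], ...]  # (query pos, query base, target base)
    query_span: tuple[int, int]
    target_span: tuple[int, int]


@dataclass(frozen=True)
class Assignment:
    query_id: str
    status: str  # assigned | ambiguous | below_threshold
    best_locus: str | None
    identity_pct: float
    match_count: int
    tied_loci: tuple[str, ...]
    mismatches: tuple[tuple[int, str, str], ...]
    orientation: str = "+"


def identity_score(
    query: str,
    target: str,
    aligner: Align.PairwiseAligner | None = None,
    seed_window: bool = True,
) -> IdentityResult:
    """Score the best local alignment of *query* against *target*.

    identity_pct = 100 * matches / alignment columns (gap columns included).
    When the target is much longer than the query, a 16-mer seed restricts
    the alignment to a window around the seed hits; pass
    ``seed_window=False`` for exhaustive alignment.
    """
    if not query or not target:
        raise ValueError("empty sequence passed to identity_score")
    if aligner is None:
        aligner = make_aligner()

    offset = 0
    window = target
    if seed_window and len(target) > 2 * len(query) + 400:
        lo, hi = _seed_window(query, target)
        if lo is None:
            # no shared 16-mer: nowhere near the identity range of interest
            return IdentityResult(0.0, 0, 0, 0.0, (), (0, 0), (0, 0))
        offset, window = lo, target[lo:hi]

    alignments = aligner.align(window, query)
    if len(alignments) == 0:
        return IdentityResult(0.0, 0, 0, 0.0, (), (0, 0), (0, 0))
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return IdentityResult(0.0, 0, 0, float(aln.score), (), (0, 0), (0, 0))

    matches = 0
    mismatches: list[tuple[int, str, str]] = []
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_len += te - ts
        for i in range(te - ts):
            tb, qb = window[ts + i], query[qs + i]
            if tb == qb and tb != "N":
                matches += 1
            else:
                mismatches.append((qs + i, qb, tb))
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    gap_cols = (t_span[1] - t_span[0] - aligned_len) + (q_span[1] - q_span[0] - aligned_len)
    columns = aligned_len + gap_cols
    identity = 100.0 * matches / columns if columns else 0.0
    return IdentityResult(
        identity_pct=identity,
        match_count=matches,
        columns=columns,
        score=float(aln.score),
        mismatches=tuple(mismatches),
        query_span=q_span,
        target_span=(t_span[0] + offset, t_span[1] + offset),
    )


def _seed_window(query: str, target: str, k: int = 16, pad: int = 200) -> tuple[int | None, int | None]:
    """Window of *target* covering the diagonals implied by exact k-mer hits
    of *query*, padded by ``pad``; (None, None) when there is no seed hit."""
    step = max(1, (len(query) - k + 1) // 64)  # sample seeds, cap the set size
    seeds: dict[str, int] = {}
    for i in range(0, len(query) - k + 1, step):
        seeds.setdefault(query[i : i + k], i)
    if not seeds:
        return None, None
    diags = []
    for i in range(len(target) - k + 1):
        q_off = seeds.get(target[i : i + k])
        if q_off is not None:
            diags.append(i - q_off)
    if not diags:
        return None, None
    lo = max(0, min(diags) - pad)
    hi = min(len(target), max(diags) + len(query) + pad)
    return lo, hi


def assign_locus(
    query: SequenceRecord | str,
    candidates: Sequence[CandidateLocus],
    min_identity_pct: float = 99.0,
    try_revcomp: bool = True,
    seed_window: bool = True,
) -> Assignment:
    """Assign a query to the candidate with the highest identity score.

    Both orientations of the query are tried and the better one kept per
    candidate.  The best candidate is the argmax of
    (match_count, identity_pct); an exact tie on both keys across several
    candidates yields status ``ambiguous`` with the tied set.  A best
    identity below ``min_identity_pct`` yields ``below_threshold``.
    """
    if not candidates:
        raise ValueError("assign_locus requires at least one candidate")
    if isinstance(query, str):
        query = SequenceRecord(id="query", seq=query)
    ids = [c.locus_id for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus_id in candidate set")

    aligner = make_aligner()
    orientations = [("+", query.seq)]
    if try_revcomp:
        orientations.append(("-", revcomp(query.seq)))

    best_per_candidate: list[tuple[CandidateLocus, IdentityResult, str]] = []
    for cand in candidates:
        best: tuple[IdentityResult, str] | None = None
        for orient, qseq in orientations:
            res = identity_score(qseq, cand.seq, aligner=aligner, seed_window=seed_window)
            key = (res.match_count, res.identity_pct)
            if best is None or key > (best[0].match_count, best[0].identity_pct):
                best = (res, orient)
        assert best is not None
        best_per_candidate.append((cand, best[0], best[1]))

    best_key = max((r.match_count, r.identity_pct) for _, r, _ in best_per_candidate)
    tied = [
        (cand, res, orient)
        for cand, res, orient in best_per_candidate
        if (res.match_count, res.identity_pct) == best_key
    ]
    top_cand, top_res, top_orient = tied[0]

    if top_res.identity_pct < min_identity_pct:
        status, best_locus = "below_threshold", None
    elif len(tied) >= 2:
        status, best_locus = "ambiguous", None
    else:
        status, best_locus = "assigned", top_cand.locus_id

    return Assignment(
        query_id=query.id,
        status=status,
        best_locus=best_locus,
        identity_pct=top_res.identity_pct,
        match_count=top_res.match_count,
        tied_loci=tuple(c.locus_id for c, _, _ in tied) if len(tied) >= 2 else (),
        mismatches=top_res.mismatches,
        orientation=top_orient,
    )


def diagnostic_sites(
    candidates: Sequence[CandidateLocus],
) -> list[tuple[int, dict[str, tuple[int, str]]]]:
    """Columns distinguishing near-identical candidates.

    A star alignment against the first candidate projects every candidate
    onto reference columns; returned are the reference columns where not
    all aligned bases agree, as ``(ref_column, {locus_id: (own_pos, base)})``.
    Bases are reported in each candidate's own coordinates; candidates with
    a gap at a column are omitted from that column's mapping.
    """
    if len(candidates) < 2:
        raise ValueError("diagnostic_sites requires >= 2 candidates")
    ref = candidates[0]
    n = len(ref.seq)
    aligner = make_aligner(mode="global")

    # per candidate: base and own position at each reference column
    per_cand: dict[str, list[tuple[int, str] | None]] = {}
    per_cand[ref.locus_id] = [(i, ref.seq[i]) for i in range(n)]
    for cand in candidates[1:]:
        col: list[tuple[int, str] | None] = [None] * n
        aln = aligner.align(ref.seq, cand.seq)[0]
        r_blocks, c_blocks = aln.aligned
        for (rs, re_), (cs, _) in zip(r_blocks, c_blocks):
            for i in range(re_ - rs):
                col[rs + i] = (cs + i, cand.seq[cs + i])
        per_cand[cand.locus_id] = col

    sites = []
    for col_i in range(n):
        bases = {
            locus: entry
            for locus, entries in per_cand.items()
            if (entry := entries[col_i]) is not None
        }
        if len({b for _, b in bases.values()}) >= 2:
            sites.append((col_i, bases))
    return sites


def write_assignments_tsv(assignments: Iterable[Assignment], stream: TextIO) -> None:
    stream.write("query_id\tstatus\tbest_locus\tidentity_pct\ttied_loci\tmismatches\torientation\n")
    for a in assignments:
        mm = ";".join(f"{pos}:{qb}>{tb}" for pos, qb, tb in a.mismatches)
        stream.write(
            f"{a.query_id}\t{a.status}\t{a.best_locus or '-'}\t{a.identity_pct:.2f}"
            f"\t{','.join(a.tied_loci) or '-'}\t{mm or '-'}\t{a.orientation}\n"
        )
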