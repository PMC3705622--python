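"""Threshold-cycle (Ct) arithmetic: delta-Ct fold changes, housekeeping
normalization, and R-region copy correction for estimating the excess of
solo-LTR transcripts over what full-length proviral transcripts explain.

An unspliced or once-spliced proviral transcript carries two copies of the
LTR R region per copy of the internal target, so the raw LTR/internal fold
difference is divided by the R copy number (default 2) before being read
as solo-LTR excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

DEFAULT_EFFICIENCY = 2.0
DEFAULT_R_COPIES = 2


@dataclass(frozen=True)
class CtMeasurement:
    sample: str
    amplicon: str
    replicate_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.replicate_cts:
            raise ValueError("at least one Ct replicate required")
        for ct in self.replicate_cts:
            if not (0.0 < ct < 60.0):
                raise ValueError(f"Ct value out of range: {ct}")

    @property
    def mean_ct(self) -> float:
        return sum(self.replicate_cts) / len(self.replicate_cts)


@dataclass(frozen=True)
class FoldEstimate:
    delta_ct: float
    efficiency: float
    r_copies: int

    @property
    def fold(self) -> float:
        return self.efficiency**self.delta_ct

    @property
    def solo_ltr_excess(self) -> float:
        return self.fold / self.r_copies

    @property
    def is_deficit(self) -> bool:
        """True when the corrected ratio falls below 1 (no excess signal)."""
        return self.solo_ltr_excess < 1.0


def delta_ct(reference: CtMeasurement, target: CtMeasurement) -> float:
    """mean(reference Ct) - mean(target Ct).

    Positive when the target amplicon is more abundant (lower Ct) than the
    reference; both measurements must come from the same sample.
    """
    if reference.sample != target.sample:
        raise ValueError(
            f"delta_ct across samples: {reference.sample!r} vs {target.sample!r}"
        )
    return reference.mean_ct - target.mean_ct


def fold_change(dct: float, efficiency: float = DEFAULT_EFFICIENCY) -> float:
    """efficiency ** delta_ct; strictly monotone in delta_ct."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency must be in (1, 2]")
    return efficiency**dct

def solo_ltr_excess(fold: float, r_copies: int = DEFAULT_R_COPIES) -> float:
    """Fold change corrected for R-region copies per proviral transcript.
    Values > 1 indicate LTR signal beyond what proviral transcripts explain."""
    if r_copies < 1:
        raise ValueError("r_copies must be >= 1")
    return fold / r_copies


def normalize_to_housekeeping(
    target: CtMeasurement, controls: Sequence[CtMeasurement]
) -> dict[str, float]:
    """Per-control delta-Ct normalization: target mean Ct minus each
    housekeeping mean Ct, reported separately per control (never averaged)."""
    if not controls:
        raise ValueError("at least one housekeeping control required")
    out = {}
    for ctrl in controls:
        if ctrl.sample != target.sample:
            raise ValueError(
                f"control {ctrl.amplicon!r} from sample {ctrl.sample!r} "
                f"does not match target sample {target.sample!r}"
            )
        out[ctrl.amplicon] = target.mean_ct - ctrl.mean_ct
    return out


def delta_delta_ct(
    dct_sample: float, dct_calibrator: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Cross-sample relative quantification: efficiency^-(ddCt)."""
    return fold_change(-(dct_sample - dct_calibrator), efficiency)


def read_ct_tsv(stream: TextIO) -> list[CtMeasurement]:
    """TSV with header sample/amplicon/ct, one replicate per row."""
    header = stream.readline().rstrip("\n").split("\t")
    idx = {k: header.index(k) for k in ("sample", "amplicon", "ct")}
    reps: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for line in stream:
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        key = (f[idx["sample"]], f[idx["amplicon"]])
        if key not in reps:
            reps[key] = []
            order.append(key)
        reps[key].append(float(f[idx["ct"]]))
    return [
        CtMeasurement(sample=s, amplicon=a, replicate_cts=tuple(reps[(s, a)]))
        for s, a in order
    ]


def write_fold_tsv(
    rows: Iterable[tuple[str, FoldEstimate]], stream: TextIO
) -> None:
    stream.write("sample\tdelta_ct\tfold\tsolo_ltr_excess\tdeficit\n")
    for sample, est in rows:
        stream.write(
            f"{sample}\t{est.delta_ct:.3f}\t{est.fold:.2f}"
            f"\t{est.solo_ltr_excess:.2f}\t{int(est.is_deficit)}\n"
        )
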