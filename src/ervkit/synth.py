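"""Synthetic-data generator: a toy genome carrying near-identical paralogous
proviruses and solo LTRs with target-site duplications, a masker-style
fragment table, gene models, strand-specific transcripts, in-silico PCR,
clone sampling, and Ct values — all with full ground truth for recovery
testing.

Every operation is driven by the seed in :class:`SimConfig`; the same seed
reproduces identical output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .catalog import RepeatFragment
from .core import GenomeInterval, PrimerPair, SequenceRecord, find_primer_sites, revcomp
from .intersect import GeneFeature
from .quant import CtMeasurement
from .splice import ProvirusModel, TYPE2_SEGMENT_LEN

# --- ancestral element geometry -------------------------------------------
LTR_LEN = 968
U3_LEN = 700
R_LEN = 100  # R region: [700, 800) within each LTR
INTERNAL_LEN = 7514  # type II total = 2*968 + 7514 = 9450
ANCESTOR_LEN = 2 * LTR_LEN + INTERNAL_LEN
CANONICAL_5SS = LTR_LEN + 100  # first intron base, in the leader
CANONICAL_3SS = 6560  # first exon base after the intron, upstream of env
TYPE2_SEG = (6570, 6570 + TYPE2_SEGMENT_LEN)
#: alternative junction planted in the ancestor: a minor-spliceosome donor
#: downstream of the canonical donor, and a nearby alternative acceptor
ALT_DONOR_OFFSET = 435
ALT_ACCEPTOR_OFFSET = 6

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FragmentationConfig:
    """Per-provirus breakage-style fragmentation of the internal segment."""

    deletion_rate: float = 0.0
    deletion_size: tuple[int, int] = (200, 1200)
    insertion_rate: float = 0.0
    insertion_size: tuple[int, int] = (100, 400)


@dataclass(frozen=True)
class TranscriptSpec:
    locus_id: str
    strand: str = "+"
    spliced: bool = False
    donor_offset: int = 0
    acceptor_offset: int = 0
    abundance: float = 1.0


@dataclass
class SimConfig:
    seed: int = 0
    genome_len: int = 400_000
    n_proviruses: int = 5
    n_solo_ltrs: int = 10
    pairwise_divergence: float = 0.01
    type1_fraction: float = 0.4
    tsd_len: int = 6
    min_intergap: int = 5000
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    #: locus_id -> intronic_same | intronic_opposite | exonic_same | exonic_opposite
    gene_program: dict[str, str] = field(default_factory=dict)
    transcript_program: list[TranscriptSpec] = field(default_factory=list)
    clones_per_amplicon: int = 10
    ct_noise_sd: float = 0.0


@dataclass
class Landmarks:
    """Per-locus coordinates in the element's own (edited) sequence."""

    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    c5ss: int
    c3ss: int
    r5: tuple[int, int]
    r3: tuple[int, int]
    type2: tuple[int, int] | None


@dataclass
class LocusTruth:
    locus_id: str
    kind: str  # provirus | solo_ltr
    provirus_type: str | None  # I | II | None for solo LTRs
    seq: str
    landmarks: Landmarks | None
    interval: GenomeInterval | None = None  # set at planting
    tsd: str = ""
    mask_segments: list[tuple[int, int, str]] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)
    gene_context: str = "intergenic"


@dataclass
class TranscriptTruth:
    transcript_id: str
    locus_id: str
    strand: str
    spliced: bool
    donor_offset: int
    acceptor_offset: int
    abundance: float
    seq: str


@dataclass
class CloneTruth:
    clone_id: str
    locus_id: str
    transcript_id: str
    amplicon: str
    strand: str
    seq: str


@dataclass
class TruthTable:
    loci: list[LocusTruth] = field(default_factory=list)
    transcripts: list[TranscriptTruth] = field(default_factory=list)
    clones: list[CloneTruth] = field(default_factory=list)

    def locus(self, locus_id: str) -> LocusTruth:
        for lt in self.loci:
            if lt.locus_id == locus_id:
                return lt
        raise KeyError(locus_id)

    def to_json(self) -> str:
        def _convert(obj):
            if isinstance(obj, GenomeInterval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end, "strand": obj.strand}
            return obj

        payload = {
            "loci": [
                {**asdict(lt), "interval": _convert(lt.interval), "landmarks": asdict(lt.landmarks) if lt.landmarks else None}
                for lt in self.loci
            ],
            "transcripts": [asdict(t) for t in self.transcripts],
            "clones": [asdict(c) for c in self.clones],
        }
        return json.dumps(payload, indent=1)


@dataclass
class Simulation:
    config: SimConfig
    ancestor: ProvirusModel
    genome: SequenceRecord
    fragments: list[RepeatFragment]
    features: list[GeneFeature]
    truth: TruthTable


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _plant(seq: str, pos: int, motif: str) -> str:
    return seq[:pos] + motif + seq[pos + len(motif) :]


def build_ancestor(config: SimConfig) -> ProvirusModel:
    """Deterministic pseudo-random ancestral type II element.

    Identical 968-bp 5' and 3' LTRs, an internal segment sized so the full
    element is ~9.45 kb, GT/AG planted at the canonical splice sites, a
    minor-spliceosome donor motif planted at the +435 alternative donor,
    and the 292-bp type-II segment at the pol-env boundary.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11CE]))
    ltr = _random_seq(rng, LTR_LEN)
    internal = _random_seq(rng, INTERNAL_LEN)
    seq = ltr + internal + ltr
    seq = _plant(seq, CANONICAL_5SS, "GTAAGT")
    seq = _plant(seq, CANONICAL_3SS - 2, "AG")
    seq = _plant(seq, CANONICAL_5SS + ALT_DONOR_OFFSET, "ATATCC")
    # distinct context on each side of the alternative junction, so no
    # shifted placement is match-equivalent to the planted one
    seq = _plant(seq, CANONICAL_5SS + ALT_DONOR_OFFSET - 3, "GGG")
    seq = _plant(seq, CANONICAL_3SS + ALT_ACCEPTOR_OFFSET - 3, "CCC")
    return ProvirusModel(
        seq=seq,
        ltr5=(0, LTR_LEN),
        ltr3=(LTR_LEN + INTERNAL_LEN, ANCESTOR_LEN),
        canonical_5ss=CANONICAL_5SS,
        canonical_3ss=CANONICAL_3SS,
        type2_segment=TYPE2_SEG,
        provirus_type="II",
    )


def _ancestor_landmarks() -> Landmarks:
    ltr3_start = LTR_LEN + INTERNAL_LEN
    return Landmarks(
        ltr5=(0, LTR_LEN),
        ltr3=(ltr3_start, ANCESTOR_LEN),
        c5ss=CANONICAL_5SS,
        c3ss=CANONICAL_3SS,
        r5=(U3_LEN, U3_LEN + R_LEN),
        r3=(ltr3_start + U3_LEN, ltr3_start + U3_LEN + R_LEN),
        type2=TYPE2_SEG,
    )


def _shift_point(p: int, pos: int, delta: int) -> int:
    return p if p <= pos else p + delta


def _shift_iv(iv: tuple[int, int], pos: int, delta: int) -> tuple[int, int]:
    return (_shift_point(iv[0], pos, delta), _shift_point(iv[1], pos, delta))


def _shift_landmarks(lm: Landmarks, pos: int, delta: int) -> Landmarks:
    return Landmarks(
        ltr5=_shift_iv(lm.ltr5, pos, delta),
        ltr3=_shift_iv(lm.ltr3, pos, delta),
        c5ss=_shift_point(lm.c5ss, pos, delta),
        c3ss=_shift_point(lm.c3ss, pos, delta),
        r5=_shift_iv(lm.r5, pos, delta),
        r3=_shift_iv(lm.r3, pos, delta),
        type2=_shift_iv(lm.type2, pos, delta) if lm.type2 else None,
    )


def _apply_deletion(truth: LocusTruth, pos: int, length: int) -> None:
    """Delete element seq[pos:pos+length]; the mask segment containing the
    deletion is split at the junction (adjacent rows, emulating a
    consensus-coordinate jump)."""
    truth.seq = truth.seq[:pos] + truth.seq[pos + length :]
    truth.landmarks = _shift_landmarks(truth.landmarks, pos, -length)
    new_segments = []
    for s, e, role in truth.mask_segments:
        if e <= pos:
            new_segments.append((s, e, role))
        elif s < pos < pos + length < e:
            new_segments.append((s, pos, role))
            new_segments.append((pos, e - length, role))
        elif s >= pos + length:
            new_segments.append((s - length, e - length, role))
        else:
            raise ValueError("deletion not contained in a single mask segment")
    truth.mask_segments = new_segments
    truth.breakpoints.append(pos)


def _apply_insertion(truth: LocusTruth, pos: int, ins: str) -> None:
    """Insert foreign sequence at pos; the containing mask segment splits
    around a genuine gap."""
    length = len(ins)
    truth.seq = truth.seq[:pos] + ins + truth.seq[pos:]
    truth.landmarks = _shift_landmarks(truth.landmarks, pos, length)
    new_segments = []
    for s, e, role in truth.mask_segments:
        if e <= pos:
            new_segments.append((s, e, role))
        elif s < pos < e:
            new_segments.append((s, pos, role))
            new_segments.append((pos + length, e + length, role))
        else:
            new_segments.append((s + length, e + length, role))
    truth.mask_segments = new_segments
    truth.breakpoints.append(pos)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with probability *rate*."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def _make_locus(
    rng: np.random.Generator,
    ancestor: ProvirusModel,
    locus_id: str,
    kind: str,
    provirus_type: str | None,
    divergence: float,
) -> LocusTruth:
    """Derive one locus from the ancestor at divergence/2 substitutions per
    site, with the two LTRs kept byte-identical within the locus."""
    per_locus_rate = divergence / 2.0
    if kind == "solo_ltr":
        seq = _mutate(rng, ancestor.seq[: LTR_LEN], per_locus_rate)
        return LocusTruth(
            locus_id=locus_id,
            kind="solo_ltr",
            provirus_type=None,
            seq=seq,
            landmarks=None,
            mask_segments=[(0, LTR_LEN, "ltr")],
        )
    seq = _mutate(rng, ancestor.seq, per_locus_rate)
    # homogenize the LTR pair (freshly inserted elements have identical
    # LTRs; keeping them identical also keeps the two R copies identical)
    ltr3_start = LTR_LEN + INTERNAL_LEN
    seq = seq[:ltr3_start] + seq[:LTR_LEN]
    truth = LocusTruth(
        locus_id=locus_id,
        kind="provirus",
        provirus_type=provirus_type,
        seq=seq,
        landmarks=_ancestor_landmarks(),
        mask_segments=[
            (0, LTR_LEN, "ltr"),
            (LTR_LEN, ltr3_start, "int"),
            (ltr3_start, ANCESTOR_LEN, "ltr"),
        ],
    )
    if provirus_type == "I":
        seg = truth.landmarks.type2
        truth.landmarks.type2 = None
        _apply_deletion(truth, seg[0], seg[1] - seg[0])
    return truth


def _fragment_locus(rng: np.random.Generator, truth: LocusTruth, frag: FragmentationConfig) -> None:
    """Apply breakage-style deletion/insertion events inside the internal
    segment, away from splice-site and boundary landmarks."""
    lm = truth.landmarks
    lo = lm.c5ss + 300
    if rng.random() < frag.deletion_rate:
        size = int(rng.integers(*frag.deletion_size))
        hi = lm.c3ss - 300 - size
        if hi > lo:
            _apply_deletion(truth, int(rng.integers(lo, hi)), size)
    if rng.random() < frag.insertion_rate:
        size = int(rng.integers(*frag.insertion_size))
        hi = truth.landmarks.c3ss - 300
        if hi > lo:
            _apply_insertion(truth, int(rng.integers(lo, hi)), _random_seq(rng, size))


def plant_loci(config: SimConfig) -> Simulation:
    """Generate the genome, plant loci with TSDs, and emit the fragment
    table, gene models and truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB10C5]))
    ancestor = build_ancestor(config)

    programmed = {spec.locus_id for spec in config.transcript_program}
    loci: list[LocusTruth] = []
    n_type1 = round(config.n_proviruses * config.type1_fraction)
    for i in range(config.n_proviruses):
        ptype = "I" if i < n_type1 else "II"
        loci.append(
            _make_locus(rng, ancestor, f"prov{i + 1}", "provirus", ptype, config.pairwise_divergence)
        )
    for i in range(config.n_solo_ltrs):
        loci.append(
            _make_locus(rng, ancestor, f"solo{i + 1}", "solo_ltr", None, config.pairwise_divergence)
        )
    for lt in loci:
        # transcribed loci stay structurally intact; fragmentation is
        # applied only to silent proviruses
        if lt.kind == "provirus" and lt.locus_id not in programmed:
            _fragment_locus(rng, lt, config.fragmentation)

    total_element = sum(len(lt.seq) + 2 * config.tsd_len for lt in loci)
    n_gaps = len(loci) + 1
    host_total = config.genome_len - total_element
    if host_total < n_gaps * config.min_intergap:
        raise ValueError(
            f"genome_len {config.genome_len} too small for non-overlapping placement"
        )
    extra = host_total - n_gaps * config.min_intergap
    weights = rng.dirichlet(np.ones(n_gaps))
    gap_lens = [config.min_intergap + int(w * extra) for w in weights]

    order = list(range(len(loci)))
    rng.shuffle(order)
    chunks: list[str] = []
    pos = 0
    fragments: list[RepeatFragment] = []
    chrom = "chrS"
    for gi, li in enumerate(order):
        host = _random_seq(rng, gap_lens[gi])
        chunks.append(host)
        pos += len(host)
        lt = loci[li]
        tsd = _random_seq(rng, config.tsd_len)
        strand = "+" if rng.random() < 0.5 else "-"
        element = lt.seq if strand == "+" else revcomp(lt.seq)
        chunks.append(tsd + element + tsd)
        start = pos + config.tsd_len
        end = start + len(lt.seq)
        lt.interval = GenomeInterval(chrom, start, end, strand)
        lt.tsd = tsd
        pos = end + config.tsd_len
        elen = len(lt.seq)
        for seg_i, (s, e, role) in enumerate(lt.mask_segments):
            if strand == "+":
                g_iv = GenomeInterval(chrom, start + s, start + e, strand)
            else:
                g_iv = GenomeInterval(chrom, start + elen - e, start + elen - s, strand)
            name = "LTR5_Hs" if role == "ltr" else "HERVK-int"
            fragments.append(
                RepeatFragment(interval=g_iv, rep_name=name, rep_class="LTR", element_id=li + 1)
            )
    chunks.append(_random_seq(rng, gap_lens[-1]))
    genome = SequenceRecord(id=chrom, seq="".join(chunks))
    fragments.sort(key=lambda f: f.interval.start)

    features = _place_genes(config, loci, genome)
    truth = TruthTable(loci=loci)
    return Simulation(
        config=config,
        ancestor=ancestor,
        genome=genome,
        fragments=fragments,
        features=features,
        truth=truth,
    )


def _place_genes(config: SimConfig, loci: list[LocusTruth], genome: SequenceRecord) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    for lt in loci:
        program = config.gene_program.get(lt.locus_id)
        if program is None or lt.interval is None:
            continue
        placement, orientation = program.rsplit("_", 1)
        locus_strand = lt.interval.strand if lt.interval.strand in "+-" else "+"
        gene_strand = locus_strand if orientation == "same" else ("-" if locus_strand == "+" else "+")
        gs = max(0, lt.interval.start - 2000)
        ge = min(len(genome.seq), lt.interval.end + 2000)
        gene_id = f"gene_{lt.locus_id}"
        chrom = lt.interval.chrom
        features.append(
            GeneFeature(gene_id, "gene", GenomeInterval(chrom, gs, ge, gene_strand))
        )
        if placement == "intronic":
            exons = [(gs, gs + 200), (ge - 200, ge)]
        elif placement == "exonic":
            exons = [(gs, gs + 200), (lt.interval.start - 100, lt.interval.start + 100), (ge - 200, ge)]
        else:
            raise ValueError(f"unknown gene program {program!r}")
        for es, ee in exons:
            features.append(
                GeneFeature(gene_id, "exon", GenomeInterval(chrom, es, ee, gene_strand))
            )
        lt.gene_context = program
    return features


def write_gtf(features: Sequence[GeneFeature], stream) -> None:
    kind_map = {"gene": "gene", "exon": "exon", "cds": "CDS", "utr5": "five_prime_utr", "utr3": "three_prime_utr", "intron": "intron"}
    for ft in features:
        iv = ft.interval
        biotype = "protein_coding" if ft.coding else "lincRNA"
        stream.write(
            f"{iv.chrom}\tsynth\t{kind_map[ft.kind]}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
            f'gene_id "{ft.gene_id}"; gene_biotype "{biotype}";\n'
        )


def transcribe(truth: TruthTable, program: Sequence[TranscriptSpec]) -> list[TranscriptTruth]:
    """Realize the transcript program against the planted loci.

    Unspliced proviral transcripts run from the R start of the 5' LTR to
    the R end of the 3' LTR (two R copies per env copy); spliced ones
    excise [c5ss+donor_offset, c3ss+acceptor_offset).  Solo-LTR
    transcripts run from the R start to the LTR end (one R copy).
    Antisense transcripts are reverse complements.
    """
    transcripts = []
    for k, spec in enumerate(program):
        lt = truth.locus(spec.locus_id)
        if lt.kind == "solo_ltr":
            seq = lt.seq[U3_LEN:]
        else:
            lm = lt.landmarks
            if spec.spliced:
                donor = lm.c5ss + spec.donor_offset
                acceptor = lm.c3ss + spec.acceptor_offset
                if not (lm.r5[0] < donor < acceptor < lm.r3[1]):
                    raise ValueError(f"splice sites outside transcript for {spec.locus_id}")
                seq = lt.seq[lm.r5[0] : donor] + lt.seq[acceptor : lm.r3[1]]
            else:
                seq = lt.seq[lm.r5[0] : lm.r3[1]]
        if spec.strand == "-":
            seq = revcomp(seq)
        transcripts.append(
            TranscriptTruth(
                transcript_id=f"tx{k + 1}_{spec.locus_id}",
                locus_id=spec.locus_id,
                strand=spec.strand,
                spliced=spec.spliced,
                donor_offset=spec.donor_offset,
                acceptor_offset=spec.acceptor_offset,
                abundance=spec.abundance,
                seq=seq,
            )
        )
    truth.transcripts = transcripts
    return transcripts


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    locus_id: str
    start: int
    end: int
    seq: str
    abundance: float
    strand: str = "+"


def in_silico_pcr(
    templates: Sequence[TranscriptTruth],
    pair: PrimerPair,
    max_mismatch: int = 1,
    max_len: int = 5000,
) -> list[Amplicon]:
    """All PCR products of a primer pair across templates.

    Both template orientations are scanned (PCR products are double
    stranded); products are reported in forward-primer orientation and
    capped at ``max_len``."""
    products = []
    for tpl in templates:
        for oriented, label in ((tpl.seq, "+"), (revcomp(tpl.seq), "-")):
            fwd_sites = find_primer_sites(oriented, pair.fwd, max_mismatch)
            rev_sites = find_primer_sites(oriented, revcomp(pair.rev), max_mismatch)
            for f in fwd_sites:
                for r in rev_sites:
                    end = r + len(pair.rev)
                    if r >= f + len(pair.fwd) and end - f <= max_len:
                        products.append(
                            Amplicon(
                                template_id=tpl.transcript_id,
                                locus_id=tpl.locus_id,
                                start=f,
                                end=end,
                                seq=oriented[f:end],
                                abundance=tpl.abundance,
                                strand=label,
                            )
                        )
            if products and products[-1].template_id == tpl.transcript_id:
                break  # found on this orientation; don't double-report
    return products


def sample_clones(
    pool: Sequence[Amplicon], n: int, seed: int, amplicon_name: str = "amp"
) -> list[CloneTruth]:
    """Multinomial clone sampling proportional to template abundance."""
    if not pool:
        raise ValueError("empty amplicon pool")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC104E]))
    weights = np.array([a.abundance for a in pool], dtype=float)
    picks = rng.choice(len(pool), size=n, p=weights / weights.sum())
    clones = []
    for j, idx in enumerate(picks):
        amp = pool[int(idx)]
        clones.append(
            CloneTruth(
                clone_id=f"{amplicon_name}_clone{j + 1}",
                locus_id=amp.locus_id,
                transcript_id=amp.template_id,
                amplicon=amplicon_name,
                strand=amp.strand,
                seq=amp.seq,
            )
        )
    return clones


def simulate_ct(
    proviral_abundance: float,
    solo_abundance: float,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample: str = "sim",
    baseline: float = 36.0,
    n_replicates: int = 3,
) -> dict[str, CtMeasurement]:
    """Ct values for the LTR and internal amplicons implied by transcript
    abundances.

    The LTR amplicon sees two R copies per proviral transcript plus one per
    solo-LTR transcript; the internal amplicon sees proviral transcripts
    only.  Ct = baseline - log_E(abundance) + Normal(0, noise_sd).
    """
    if proviral_abundance <= 0:
        raise ValueError("proviral abundance must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC7]))
    abundances = {
        "q-ltr": 2.0 * proviral_abundance + solo_abundance,
        "q-int": proviral_abundance,
    }
    out = {}
    logE = np.log(efficiency)
    for amplicon, ab in abundances.items():
        base_ct = baseline - float(np.log(ab) / logE)
        reps = tuple(base_ct + float(rng.normal(0.0, noise_sd)) for _ in range(n_replicates)) if noise_sd > 0 else tuple([base_ct] * n_replicates)
        out[amplicon] = CtMeasurement(sample=sample, amplicon=amplicon, replicate_cts=reps)
    return out


def design_primers(ancestor: ProvirusModel) -> dict[str, PrimerPair]:
    """Primer pairs on the ancestral consensus mirroring the assay design:
    an 'unspliced' pair flanking the type-II segment, a '1x-env' pair
    crossing the canonical intron, three short internal 'env' pairs, a
    'pro' pair, and an 'ltr' pair inside the R region."""
    seq = ancestor.seq
    seg_s, seg_e = ancestor.type2_segment
    c5, c3 = ancestor.canonical_5ss, ancestor.canonical_3ss

    def pair(name: str, f_start: int, r_end: int, plen: int = 20) -> PrimerPair:
        return PrimerPair(
            name=name,
            fwd=seq[f_start : f_start + plen],
            rev=revcomp(seq[r_end - plen : r_end]),
        )

    r5s = U3_LEN
    return {
        "unspliced": pair("unspliced", seg_s - 300, seg_e + 250),
        "1x-env": pair("1x-env", c5 - 70, c3 + 350),
        "pro": pair("pro", c5 + 1200, c5 + 1650),
        "env-1": pair("env-1", seg_e + 100, seg_e + 550),
        "env-2": pair("env-2", seg_e + 600, seg_e + 1050),
        "env-3": pair("env-3", seg_e + 1100, seg_e + 1550),
        "ltr": pair("ltr", r5s + 2, r5s + R_LEN - 2),
    }
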