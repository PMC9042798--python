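"""Synthetic Circle-Seq data generator.

Produces seed-reproducible toy genomes with planted annotation elements,
eccDNA-like circles whose sizes follow a four-component mixture peaked at
207/358/553/732 bp (the single/di/tri/tetra-nucleosome ladder seen in
cell-free circle sequencing), GC-biased circle origins, junction direct
repeats and trinucleotide palindromic units written into the reference, and
already-aligned paired-end reads from a circular template: junction-crossing
reads become split alignments (primary + supplementary with SA tags),
junction-straddling pairs become discordant pairs, and linear background
reads cover the rest of the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from .genome import ReferenceGenome, AnnotationSet, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TrueCircle",
    "ReadSet",
    "SimulatedSample",
    "generate_reference",
    "sample_true_circles",
    "simulate_reads",
    "simulate_cohort",
    "write_truth_table",
]

# size-mixture defaults: the 358 bp (di-nucleosome) peak carries ~10x the
# weight of the other three peaks
DEFAULT_SIZE_PEAKS: tuple[tuple[float, float, float], ...] = (
    (207.0, 20.0, 0.06),
    (358.0, 20.0, 0.82),
    (553.0, 20.0, 0.06),
    (732.0, 20.0, 0.06),
)

DEFAULT_ELEMENT_PLAN: tuple[tuple[str, float, int], ...] = (
    ("gene", 0.40, 15_000),
    ("CpG", 0.02, 800),
    ("SINE", 0.10, 300),
    ("LINE", 0.05, 1_000),
    ("Simple_repeat", 0.02, 200),
    ("miRNA", 0.002, 80),
)

GENE_FLANK = 2_000  # bp, up/downstream gene flank width
_PLANT_MARGIN = 20  # bp kept clear of chromosome ends for motif planting


@dataclass
class SimulationConfig:
    """All knobs of the synthetic Circle-Seq study.

    Defaults describe a small but realistic study: human-like background GC
    (0.41), genes covering 40% of the genome, a SINE/LINE/simple-repeat
    landscape, the nucleosome-ladder size mixture, a GC-biased circle origin,
    direct repeats planted at two thirds of junctions (4-18 bp) and
    palindromic units at a third, PE150 reads with 400 bp fragments.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 500_000
    gc_background: float = 0.41
    element_plan: Sequence[tuple[str, float, int]] = DEFAULT_ELEMENT_PLAN
    n_circles: int = 1_000
    size_peaks: Sequence[tuple[float, float, float]] = DEFAULT_SIZE_PEAKS
    gc_bias_beta: float = 4.0
    p_direct_repeat: float = 0.66
    dr_length_range: tuple[int, int] = (4, 18)
    p_palindrome: float = 0.33
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    circle_depth: float = 30.0
    background_depth: float = 1.0
    mapq_unique: int = 60
    # extras
    cpg_gc: float = 0.65
    size_min: int = 50
    size_max: int = 2_000
    background_mapq0_frac: float = 0.05

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1_000:
            raise ValueError("need at least one chromosome of >= 1 kb")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0, 1)")
        weights = [w for _, _, w in self.size_peaks]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"size-peak weights must sum to 1, got {sum(weights)}")
        lo, hi = self.dr_length_range
        if not (4 <= lo <= hi <= 18):
            raise ValueError("dr_length_range must be within [4, 18]")
        for p, name in [
            (self.p_direct_repeat, "p_direct_repeat"),
            (self.p_palindrome, "p_palindrome"),
            (self.background_mapq0_frac, "background_mapq0_frac"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gc_bias_beta < 0:
            raise ValueError("gc_bias_beta must be >= 0")
        total_frac = sum(f for _, f, _ in self.element_plan)
        if total_frac > 1:
            raise ValueError(f"element plan fractions sum to {total_frac} > 1")
        if self.n_circles < 1:
            raise ValueError("n_circles must be >= 1")
        if not self.size_min < self.size_max:
            raise ValueError("size_min must be < size_max")

    # YAML round trip --------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["element_plan"] = [list(e) for e in self.element_plan]
        d["size_peaks"] = [list(p) for p in self.size_peaks]
        d["dr_length_range"] = list(self.dr_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["element_plan"] = tuple(tuple(e) for e in d.get("element_plan", DEFAULT_ELEMENT_PLAN))
        d["size_peaks"] = tuple(tuple(p) for p in d.get("size_peaks", DEFAULT_SIZE_PEAKS))
        d["dr_length_range"] = tuple(d.get("dr_length_range", (4, 18)))
        return cls(**d)


@dataclass
class TrueCircle:
    """A planted circle: ground truth for caller evaluation."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    planted_dr_length: int | None = None
    planted_palindrome: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# reference + annotation generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _place_intervals(
    rng: np.random.Generator,
    lengths_by_chrom: dict[str, int],
    target_bases: int,
    draw_length,
    occupied: dict[str, list[tuple[int, int]]],
    element_class: str,
    margin: int = 0,
    max_tries: int = 500,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping (within `occupied`) intervals until target reached."""
    chroms = list(lengths_by_chrom)
    lens = np.array([lengths_by_chrom[c] for c in chroms], dtype=float)
    pchrom = lens / lens.sum()
    placed: list[tuple[str, int, int]] = []
    placed_bases = 0
    while placed_bases < target_bases:
        length = int(draw_length())
        ok = False
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=pchrom)]
            L = lengths_by_chrom[chrom]
            if L - length - 2 * margin <= 0:
                continue
            start = int(rng.integers(margin, L - length - margin))
            end = start + length
            conflict = any(
                s < end + margin and start - margin < e for s, e in occupied[chrom]
            )
            if not conflict:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"element plan exceeds genome capacity for class {element_class!r}"
            )
        occupied[chrom].append((start, end))
        placed.append((chrom, start, end))
        placed_bases += length
    return placed


def _gene_features(
    rng: np.random.Generator, chrom: str, start: int, end: int, chrom_len: int, idx: int
) -> list[tuple]:
    """Decompose a gene interval into exons/introns/UTRs/2-kb flanks."""
    strand = "+" if rng.random() < 0.5 else "-"
    gid = f"gene{idx}"
    L = end - start
    n_exons = int(rng.integers(3, 9))
    exon_lens = rng.integers(120, 301, size=n_exons)
    while exon_lens.sum() > 0.6 * L and n_exons > 2:
        n_exons -= 1
        exon_lens = exon_lens[:n_exons]
    intron_total = L - int(exon_lens.sum())
    cuts = np.sort(rng.choice(np.arange(1, intron_total), size=n_exons - 1, replace=False))
    intron_lens = np.diff(np.concatenate([[0], cuts, [intron_total]]))
    # genes start and end with an exon; interior gaps are the introns
    rows = [(chrom, start, end, strand, "gene", gid)]
    pos = start
    exon_bounds = []
    for i in range(n_exons):
        if i > 0:
            ilen = int(intron_lens[i])
            rows.append((chrom, pos, pos + ilen, strand, "intron", f"{gid}.i{i}"))
            pos += ilen
        elen = int(exon_lens[i])
        exon_bounds.append((pos, pos + elen))
        rows.append((chrom, pos, pos + elen, strand, "exon", f"{gid}.e{i + 1}"))
        pos += elen
    # UTRs: leading/trailing slice of the terminal exons, strand-aware
    first, last = exon_bounds[0], exon_bounds[-1]
    u5 = (first[0], min(first[1], first[0] + 150))
    u3 = (max(last[0], last[1] - 150), last[1])
    if strand == "-":
        u5, u3 = (max(last[0], last[1] - 150), last[1]), (first[0], min(first[1], first[0] + 150))
    rows.append((chrom, u5[0], u5[1], strand, "5UTR", f"{gid}.5utr"))
    rows.append((chrom, u3[0], u3[1], strand, "3UTR", f"{gid}.3utr"))
    # 2-kb flanks, strand-aware (upstream = 5' side)
    left = (max(0, start - GENE_FLANK), start)
    right = (end, min(chrom_len, end + GENE_FLANK))
    up, down = (left, right) if strand == "+" else (right, left)
    if up[1] > up[0]:
        rows.append((chrom, up[0], up[1], strand, "gene2kbU", f"{gid}.up2kb"))
    if down[1] > down[0]:
        rows.append((chrom, down[0], down[1], strand, "gene2kbD", f"{gid}.down2kb"))
    return rows


def generate_reference(config: SimulationConfig) -> tuple[ReferenceGenome, AnnotationSet]:
    """Build a toy genome plus annotations per the element plan.

    Background bases are i.i.d. at ``gc_background``; CpG-island blocks are
    rewritten at ``cpg_gc``. Genes (with exon/intron/UTR substructure and
    derived 2-kb flanks), repeat-class intervals and miRNA genes (60-100 bp,
    placed both inside and outside genes) are planted non-overlapping within
    their own class. Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {
        c: _random_sequence(rng, config.chrom_length, config.gc_background)
        for c in chrom_names
    }
    lengths = {c: config.chrom_length for c in chrom_names}
    total = config.n_chroms * config.chrom_length

    rows: list[tuple] = []
    gene_intervals: list[tuple[str, int, int]] = []
    plan = {name: (frac, mlen) for name, frac, mlen in config.element_plan}

    # genes first (other classes may overlap them, as in a real genome)
    if "gene" in plan:
        frac, mlen = plan["gene"]
        occupied = {c: [] for c in chrom_names}
        placed = _place_intervals(
            rng,
            lengths,
            int(frac * total),
            lambda: max(2_000, int(rng.normal(mlen, 0.2 * mlen))),
            occupied,
            "gene",
            margin=GENE_FLANK,
        )
        for i, (chrom, s, e) in enumerate(placed):
            gene_intervals.append((chrom, s, e))
            rows.extend(_gene_features(rng, chrom, s, e, lengths[chrom], i))

    for name, frac, mlen in config.element_plan:
        if name == "gene":
            continue
        occupied = {c: [] for c in chrom_names}
        if name == "miRNA":
            draw = lambda: int(rng.integers(60, 101))
        else:
            draw = lambda m=mlen: max(20, int(rng.normal(m, 0.2 * m)))
        placed = _place_intervals(rng, lengths, int(frac * total), draw, occupied, name)
        for i, (chrom, s, e) in enumerate(placed):
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, s, e, strand, name, f"{name}{i}"))
            if name == "CpG":  # CpG islands carry elevated GC in sequence
                seqs[chrom][s:e] = _random_sequence(rng, e - s, config.cpg_gc)

    genome = ReferenceGenome({c: seqs[c].tobytes() for c in chrom_names})
    annotations = AnnotationSet.from_records(rows)
    return genome, annotations


# ---------------------------------------------------------------------------
# circle sampling + motif planting
# ---------------------------------------------------------------------------

_GC_WINDOW = 200  # bp window whose GC drives origin bias


def _draw_sizes(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    """Truncated-normal mixture draw of circle sizes."""
    means = np.array([m for m, _, _ in config.size_peaks])
    sds = np.array([s for _, s, _ in config.size_peaks])
    weights = np.array([w for _, _, w in config.size_peaks])
    comp = rng.choice(len(means), size=n, p=weights / weights.sum())
    sizes = rng.normal(means[comp], sds[comp])
    bad = (sizes < config.size_min) | (sizes > config.size_max)
    while bad.any():  # redraw out-of-range sizes within their component
        sizes[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = (sizes < config.size_min) | (sizes > config.size_max)
    return np.round(sizes).astype(np.int64)


def sample_true_circles(
    config: SimulationConfig,
    genome: ReferenceGenome,
    annotations: AnnotationSet | None = None,
    n_circles: int | None = None,
) -> list[TrueCircle]:
    """Draw circles and plant junction motifs into the genome (in place).

    Origin positions are drawn with weight proportional to
    ``exp(gc_bias_beta * GC)`` of the 200-bp window at the circle start.
    With probability ``p_palindrome`` a 10-bp unit (triplet + 4-base spacer +
    reverse-complement triplet) is written straddling the start junction;
    with probability ``p_direct_repeat`` the sequence beginning at ``end`` is
    rewritten to copy the one at ``start`` so the junction carries a direct
    repeat. Overlapping rewrites resolve last-wins and are logged; a repair
    pass re-asserts clobbered direct repeats.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_circles if n_circles is None else n_circles
    if n < 1:
        raise ValueError("need n_circles >= 1")

    chroms = genome.chrom_names
    cum_weights: dict[str, np.ndarray] = {}
    for c in chroms:
        cs = genome.gc_cumsum(c)
        L = genome.lengths[c]
        win_gc = (cs[_GC_WINDOW:] - cs[: L - _GC_WINDOW + 1]) / _GC_WINDOW
        w = np.exp(config.gc_bias_beta * win_gc)
        cum_weights[c] = np.concatenate([[0.0], np.cumsum(w)])

    sizes = _draw_sizes(rng, config, n)
    circles: list[TrueCircle] = []
    for size in sizes:
        placed = False
        for _ in range(200):
            lo = {}
            hi = {}
            mass = np.empty(len(chroms))
            for i, c in enumerate(chroms):
                a = _PLANT_MARGIN
                b = min(genome.lengths[c] - int(size) - _PLANT_MARGIN,
                        len(cum_weights[c]) - 2)
                lo[c], hi[c] = a, b
                mass[i] = cum_weights[c][b + 1] - cum_weights[c][a] if b >= a else 0.0
            if mass.sum() <= 0:
                break
            c = chroms[rng.choice(len(chroms), p=mass / mass.sum())]
            u = rng.uniform(cum_weights[c][lo[c]], cum_weights[c][hi[c] + 1])
            start = int(np.searchsorted(cum_weights[c], u, side="left") - 1)
            start = max(lo[c], min(start, hi[c]))
            circles.append(TrueCircle(c, start, start + int(size)))
            placed = True
            break
        if not placed:
            raise ValueError(f"cannot place a circle of size {size} on this genome")

    # motif planting (palindrome first so the DR copy wins at the junction)
    written: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    conflicts = 0

    def _log_write(chrom: str, s: int, e: int) -> None:
        nonlocal conflicts
        if any(a < e and s < b for a, b in written[chrom]):
            conflicts += 1
        written[chrom].append((s, e))

    dr_lo, dr_hi = config.dr_length_range
    for circ in circles:
        if rng.random() < config.p_palindrome:
            t1 = "".join(rng.choice(list("ACGT"), size=3))
            spacer = "".join(rng.choice(list("ACGT"), size=4))
            unit = t1 + spacer + revcomp(t1)
            pos = circ.start - 5  # unit straddles the start junction
            _log_write(circ.chrom, pos, pos + 10)
            genome.write(circ.chrom, pos, unit)
            circ.planted_palindrome = True
        if rng.random() < config.p_direct_repeat:
            s_len = int(rng.integers(dr_lo, dr_hi + 1))
            circ.planted_dr_length = s_len

    # DR writes + repair passes (a later write can clobber an earlier copy)
    for _ in range(10):
        dirty = False
        for circ in circles:
            s_len = circ.planted_dr_length
            if s_len is None:
                continue
            src = genome.sequence(circ.chrom, circ.start, circ.start + s_len)
            dst = genome.sequence(circ.chrom, circ.end, circ.end + s_len)
            if src != dst:
                _log_write(circ.chrom, circ.end, circ.end + s_len)
                genome.write(circ.chrom, circ.end, src)
                dirty = True
        if not dirty:
            break
    else:
        logger.warning("direct-repeat planting did not converge after 10 passes")
    if conflicts:
        logger.info("motif planting: %d overlapping rewrites (last-wins)", conflicts)
    return circles


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Coordinate-sorted aligned reads plus the mapped-read count."""

    records: list[pysam.AlignedSegment]
    header: pysam.AlignmentHeader
    mapped_read_count: int

    def write_sam(self, path: str | Path) -> None:
        with pysam.AlignmentFile(str(path), "wh", header=self.header) as out:
            for rec in self.records:
                out.write(rec)

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path) -> None:
        """Original-orientation FASTQ of primary records (integration testing)."""
        with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
            for rec in self.records:
                if rec.is_supplementary or rec.is_secondary:
                    continue
                seq = rec.query_sequence
                if rec.is_reverse:
                    seq = revcomp(seq)
                out = f1 if rec.is_read1 else f2
                out.write(f"@{rec.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")


def _sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": genome.lengths[c]} for c in genome.chrom_names],
        }
    )


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    pos: int,
    cigar: str,
    seq: str,
    mapq: int,
    *,
    reverse: bool,
    read1: bool,
    supplementary: bool = False,
    mate: tuple[str, int, bool] | None = None,
    sa: str | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = chrom
    a.reference_start = pos
    a.cigarstring = cigar
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    a.mapping_quality = mapq
    flag = 1  # paired
    flag |= 64 if read1 else 128
    if reverse:
        flag |= 16
    if supplementary:
        flag |= 2048
    a.flag = flag
    if mate is not None:
        mchrom, mpos, mrev = mate
        a.next_reference_name = mchrom
        a.next_reference_start = mpos
        if mrev:
            a.flag |= 32
    if sa is not None:
        a.set_tag("SA", sa, "Z")
    a.set_tag("NM", 0, "i")
    return a


def _circular_read_segments(
    offset: int, read_len: int, circ: TrueCircle
) -> list[tuple[int, str]]:
    """Alignment segments (ref pos, cigar) for a read at circular ``offset``.

    The stored SEQ is reference-oriented; a junction-crossing read yields a
    matched-then-clipped segment at the high-coordinate side and a
    clipped-then-matched segment starting at the circle start.
    """
    L = circ.length
    o = offset % L
    if o + read_len <= L:
        return [(circ.start + o, f"{read_len}M")]
    k1 = L - o
    rem = read_len - k1
    k2 = min(rem, L)  # a read wrapping more than once is clipped past one lap
    segs = [(circ.start + o, f"{k1}M{read_len - k1}S")]
    tail = f"{rem - k2}S" if rem > k2 else ""
    segs.append((circ.start, f"{k1}S{k2}M{tail}"))
    return segs


def _matched(cigar: str) -> int:
    total, cur = 0, ""
    for ch in cigar:
        if ch.isdigit():
            cur += ch
        else:
            if ch == "M":
                total += int(cur)
            cur = ""
    return total


def simulate_reads(
    circles: Sequence[TrueCircle],
    genome: ReferenceGenome,
    config: SimulationConfig,
) -> ReadSet:
    """Simulate aligned PE reads from circular templates plus linear background.

    Fragment positions on a circle are taken modulo circle length (rolling-
    circle concatemers); junction-crossing reads are emitted as split
    alignments with SA tags, junction-straddling pairs as discordant pairs.
    Output is coordinate-sorted and deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    header = _sam_header(genome)
    RL = config.read_length
    records: list[pysam.AlignedSegment] = []
    n_reads = 0

    def emit_read(name, circ, offset, read1, reverse, mapq):
        """Emit one read (possibly split) of a circular fragment; returns primary."""
        segs = _circular_read_segments(offset, RL, circ)
        L = circ.length
        o = offset % L
        cseq = genome.sequence(circ.chrom, circ.start, circ.end)
        reps = cseq * (2 + RL // L)
        seq = reps[o : o + RL]
        if len(segs) == 1:
            pos, cig = segs[0]
            rec = _make_segment(header, name, circ.chrom, pos, cig, seq, mapq,
                                reverse=reverse, read1=read1)
            return [rec], rec
        # split: primary = segment with more matched bases
        prim_i = 0 if _matched(segs[0][1]) >= _matched(segs[1][1]) else 1
        strand = "-" if reverse else "+"
        recs = []
        for i, (pos, cig) in enumerate(segs):
            j = 1 - i
            sa = f"{circ.chrom},{segs[j][0] + 1},{strand},{segs[j][1]},{mapq},0;"
            recs.append(
                _make_segment(header, name, circ.chrom, pos, cig, seq, mapq,
                              reverse=reverse, read1=read1,
                              supplementary=(i != prim_i), sa=sa)
            )
        return recs, recs[prim_i]

    # --- circle-derived fragments ------------------------------------------
    for ci, circ in enumerate(circles):
        L = circ.length
        n_frag = max(1, round(config.circle_depth * L / (2 * RL)))
        for j in range(n_frag):
            o = int(rng.integers(0, L))
            F = max(RL, int(rng.normal(config.fragment_mean, config.fragment_sd)))
            o2 = (o + F - RL) % L
            name = f"circ{ci}_frag{j}"
            recs1, prim1 = emit_read(name, circ, o, True, False, config.mapq_unique)
            recs2, prim2 = emit_read(name, circ, o2, False, True, config.mapq_unique)
            for r in recs1:
                r.next_reference_name = prim2.reference_name
                r.next_reference_start = prim2.reference_start
                r.flag |= 32  # mate reverse
            for r in recs2:
                r.next_reference_name = prim1.reference_name
                r.next_reference_start = prim1.reference_start
            records.extend(recs1 + recs2)
            n_reads += 2

    # --- linear background ---------------------------------------------------
    chroms = genome.chrom_names
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    n_bg = int(round(config.background_depth * lens.sum() / (2 * RL)))
    for j in range(n_bg):
        c = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
        Lc = genome.lengths[c]
        F = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd), RL, Lc))
        s = int(rng.integers(0, Lc - F + 1))
        mapq = 0 if rng.random() < config.background_mapq0_frac else config.mapq_unique
        name = f"bg_frag{j}"
        p1, p2 = s, s + F - RL
        r1 = _make_segment(header, name, c, p1, f"{RL}M",
                           genome.sequence(c, p1, p1 + RL), mapq,
                           reverse=False, read1=True, mate=(c, p2, True))
        r2 = _make_segment(header, name, c, p2, f"{RL}M",
                           genome.sequence(c, p2, p2 + RL), mapq,
                           reverse=True, read1=False, mate=(c, p1, False))
        r1.flag |= 2
        r2.flag |= 2
        records.extend([r1, r2])
        n_reads += 2

    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    return ReadSet(records=records, header=header, mapped_read_count=n_reads)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    reads: ReadSet
    truth: list[TrueCircle]


@dataclass
class CohortResult:
    samples: list[SimulatedSample]
    genome: ReferenceGenome
    annotations: AnnotationSet
    recurrent_mirna_ids: list[str]

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.samples, self.genome, self.annotations))


def simulate_cohort(
    config_healthy: SimulationConfig,
    config_disease: SimulationConfig,
    n_h: int,
    n_d: int,
    n_recurrent_mirna: int = 3,
    mirna_flank: int = 100,
) -> CohortResult:
    """Simulate a two-group cohort on a shared reference.

    Disease samples carry a higher circle rate (``config_disease.n_circles``,
    treated as a Poisson rate per sample), any size shift encoded in
    ``config_disease.size_peaks``, and ``n_recurrent_mirna`` planted circles
    that fully contain the same miRNA genes in every disease sample.
    Per-sample seeds derive from the healthy config's master seed.
    """
    config_healthy.validate()
    config_disease.validate()
    if n_h < 3 or n_d < 3:
        raise ValueError("need at least 3 samples per group")
    genome, annotations = generate_reference(config_healthy)
    master = np.random.default_rng([config_healthy.seed, 3])

    mirnas = annotations.by_class("miRNA")
    if n_recurrent_mirna > 0 and len(mirnas) < n_recurrent_mirna:
        raise ValueError("not enough miRNA genes annotated for recurrence planting")
    chosen = mirnas.sort_values(["chrom", "start"]).head(n_recurrent_mirna)

    samples: list[SimulatedSample] = []
    for i in range(n_h + n_d):
        disease = i >= n_h
        base = config_disease if disease else config_healthy
        seed_i = int(master.integers(0, 2**31 - 1))
        cfg = replace(base, seed=seed_i)
        rng = np.random.default_rng([seed_i, 4])
        n_circ = max(1, int(rng.poisson(cfg.n_circles)))
        truth = sample_true_circles(cfg, genome, annotations, n_circles=n_circ)
        if disease:
            for row in chosen.itertuples(index=False):
                s = max(_PLANT_MARGIN, int(row.start) - mirna_flank)
                e = min(genome.lengths[row.chrom] - _PLANT_MARGIN,
                        int(row.end) + mirna_flank)
                truth.append(TrueCircle(str(row.chrom), s, e))
        reads = simulate_reads(truth, genome, cfg)
        group = "disease" if disease else "healthy"
        sid = f"{'D' if disease else 'H'}{(i - n_h if disease else i) + 1:02d}"
        samples.append(SimulatedSample(sid, group, reads, truth))
    return CohortResult(
        samples, genome, annotations, [str(r.name) for r in chosen.itertuples(index=False)]
    )


def write_truth_table(circles: Sequence[TrueCircle], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tplanted_dr_length\tplanted_palindrome\n")
        for c in circles:
            dr = "" if c.planted_dr_length is None else str(c.planted_dr_length)
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{dr}\t{int(c.planted_palindrome)}\n")
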