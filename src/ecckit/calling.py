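"""Junction-evidence circle calling, filtering, deduplication and EPM.

Candidates are detected from split alignments in back-to-junction
configuration, scored with documented surrogates of the Circle-Map-style
support metrics, and filtered by six criteria: split reads >= 2,
circle score >= 20, coverage increase at start and end >= 0.33,
coverage continuity <= 0.1, and SD of coverage < mean coverage.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import ReferenceGenome
from .simulate import ReadSet

logger = logging.getLogger(__name__)

__all__ = [
    "CircleCandidate",
    "FilterThresholds",
    "SampleCircleSet",
    "read_circle_table",
    "call_candidates",
    "apply_filters",
    "deduplicate",
    "epm",
    "write_circle_bed",
    "write_sample_summary",
]

CLUSTER_TOL = 5  # bp, breakpoint clustering tolerance
COV_WINDOW = 50  # bp, coverage-increase window
MAPQ_CAP = 10  # per-split-read score contribution cap


@dataclass
class CircleCandidate:
    """A candidate circle with its junction-support metrics."""

    chrom: str
    start: int
    end: int
    discordant_count: int = 0
    split_count: int = 0
    circle_score: float = 0.0
    mean_cov: float = 0.0
    sd_cov: float = 0.0
    cov_inc_start: float = 0.0
    cov_inc_end: float = 0.0
    cov_continuity: float = 0.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterThresholds:
    """The six filter settings; defaults are the standard stringent set."""

    min_split: int = 2
    min_score: float = 20.0
    min_inc_start: float = 0.33
    min_inc_end: float = 0.33
    max_continuity: float = 0.1
    require_sd_lt_mean: bool = True

    def __post_init__(self):
        for name in ("min_split", "min_score", "min_inc_start", "min_inc_end",
                     "max_continuity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SampleCircleSet:
    """Per-sample deduplicated circles + read depth; unit of EPM and cohort stats."""

    sample_id: str
    group: str
    circles: list[CircleCandidate]
    mapped_read_count: int
    sex: str = "unknown"
    age: float | None = None

    def __post_init__(self):
        if self.mapped_read_count <= 0:
            raise ValueError("mapped_read_count must be > 0")
        keys = [(c.chrom, c.start, c.end) for c in self.circles]
        if len(set(keys)) != len(keys):
            raise ValueError("circles must be unique by (chrom, start, end)")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "chrom", "start", "end", "discordant", "split", "score",
    "mean_cov", "sd_cov", "inc_start", "inc_end", "continuity",
]


def read_circle_table(path: str | Path) -> list[CircleCandidate]:
    """Read a Circle-Map-dialect 11-column TSV of candidates.

    Coordinates are taken as 0-based half-open. Malformed rows raise with
    their line number.
    """
    out: list[CircleCandidate] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected 11 columns, got {len(fields)}"
                )
            try:
                out.append(
                    CircleCandidate(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        discordant_count=int(fields[3]),
                        split_count=int(fields[4]),
                        circle_score=float(fields[5]),
                        mean_cov=float(fields[6]),
                        sd_cov=float(fields[7]),
                        cov_inc_start=float(fields[8]),
                        cov_inc_end=float(fields[9]),
                        cov_continuity=float(fields[10]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not out:
        logger.warning("%s: empty circle table", path)
    return out


def write_circle_bed(circles: Sequence[CircleCandidate], path: str | Path) -> None:
    """BED3+ with the metric columns."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TABLE_COLUMNS) + "\n")
        for c in circles:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.discordant_count}\t{c.split_count}\t"
                f"{c.circle_score:g}\t{c.mean_cov:g}\t{c.sd_cov:g}\t"
                f"{c.cov_inc_start:g}\t{c.cov_inc_end:g}\t{c.cov_continuity:g}\n"
            )


def write_sample_summary(samples: Sequence[SampleCircleSet], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "n_unique": len(s.circles),
            "mapped_reads": s.mapped_read_count,
            "EPM": epm(s),
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate calling from aligned reads
# ---------------------------------------------------------------------------


def _cigar_clips(cigartuples) -> tuple[int, int, int, int]:
    """(leading clip, trailing clip, ref span, matched bases) of a CIGAR."""
    lead = trail = ref = matched = 0
    if not cigartuples:
        return 0, 0, 0, 0
    ops = list(cigartuples)
    if ops[0][0] in (4, 5):  # S/H
        lead = ops[0][1]
    if ops[-1][0] in (4, 5):
        trail = ops[-1][1]
    for op, ln in ops:
        if op in (0, 7, 8, 2, 3):  # M/=/X/D/N consume reference
            ref += ln
        if op in (0, 7, 8):
            matched += ln
    return lead, trail, ref, matched


_CIGAR_OP = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}


def _parse_cigar_string(cig: str):
    out, cur = [], ""
    for ch in cig:
        if ch.isdigit():
            cur += ch
        else:
            out.append((_CIGAR_OP[ch], int(cur)))
            cur = ""
    return out


def _junction_from_split(read: pysam.AlignedSegment) -> tuple[str, int, int, int] | None:
    """Reconstruct a circle junction from a primary split alignment.

    Returns (chrom, start, end, mapq) when the primary and its SA partner sit
    on the same chromosome and strand in back-to-junction configuration: the
    matched-then-clipped segment maps downstream of the clipped-then-matched
    one, so the junction joins the downstream segment's reference end back to
    the upstream segment's reference start.
    """
    sa = read.get_tag("SA")
    first = sa.split(";")[0].split(",")
    sa_chrom, sa_pos, sa_strand = first[0], int(first[1]) - 1, first[2]
    sa_cigar = first[3]
    if sa_chrom != read.reference_name:
        return None
    strand = "-" if read.is_reverse else "+"
    if sa_strand != strand:
        return None
    lead1, trail1, _, m1 = _cigar_clips(read.cigartuples)
    ct2 = _parse_cigar_string(sa_cigar)
    lead2, trail2, ref2, m2 = _cigar_clips(ct2)
    seg1 = (read.reference_start, read.reference_end, lead1, trail1)
    seg2 = (sa_pos, sa_pos + ref2, lead2, trail2)
    m_first = [s for s in (seg1, seg2) if s[3] > s[2]]  # trailing clip dominates
    s_first = [s for s in (seg1, seg2) if s[2] > s[3]]
    if len(m_first) != 1 or len(s_first) != 1:
        return None
    mf, sf = m_first[0], s_first[0]
    if mf[1] <= sf[0]:  # reference order same as clip order: linear split
        return None
    start, end = sf[0], mf[1]
    if end <= start:
        return None
    return read.reference_name, start, end, read.mapping_quality


def _mode_smallest(values: Iterable[int]) -> int:
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def call_candidates(
    reads: ReadSet | str | Path,
    genome: ReferenceGenome,
) -> list[CircleCandidate]:
    """Detect circle candidates from coordinate-sorted aligned reads.

    Split alignments in back-to-junction configuration are clustered by
    breakpoint pair (tolerance +/- 5 bp, consensus = modal breakpoint, ties
    toward the smaller coordinate). Discordant outward-facing pairs
    consistent with the interval are counted. Coverage metrics come from
    primary alignments only; ``circle_score`` is the sum over supporting
    split reads of ``min(MAPQ, 10)``.
    """
    if isinstance(reads, (str, Path)):
        with pysam.AlignmentFile(str(reads), "r") as fh:
            records = list(fh)
            header = fh.header
    else:
        records, header = reads.records, reads.header

    lengths = genome.lengths
    for sq in header.to_dict().get("SQ", []):
        if sq["SN"] not in lengths:
            raise ValueError(f"reads reference unknown chromosome {sq['SN']!r}")

    coverage = {c: np.zeros(l, dtype=np.int32) for c, l in lengths.items()}
    junctions: list[tuple[str, int, int, int]] = []
    pair_first: dict[str, pysam.AlignedSegment] = {}
    discordant: list[tuple[str, int, int]] = []  # (chrom, low pos, high end)

    last_key = (-1, -1)
    for read in records:
        if read.is_unmapped or read.is_secondary:
            continue
        if read.reference_name not in lengths:
            raise ValueError(f"read references unknown chromosome {read.reference_name!r}")
        key = (read.reference_id, read.reference_start)
        if key < last_key:
            raise ValueError("input reads are not coordinate-sorted")
        last_key = key
        if read.is_supplementary:
            continue
        if read.is_duplicate or read.is_qcfail:
            continue
        # primary alignments drive coverage
        coverage[read.reference_name][read.reference_start : read.reference_end] += 1
        if read.has_tag("SA"):
            j = _junction_from_split(read)
            if j is not None:
                junctions.append(j)
            continue
        # discordant outward pair: reverse mate at the lower coordinate
        if read.is_paired and read.reference_name == read.next_reference_name:
            other = pair_first.pop(read.query_name, None)
            if other is None:
                pair_first[read.query_name] = read
            else:
                lo, hi = sorted([other, read], key=lambda r: r.reference_start)
                if lo.is_reverse and not hi.is_reverse:
                    discordant.append(
                        (lo.reference_name, lo.reference_start, hi.reference_end)
                    )

    # cluster junctions by breakpoint pair
    junctions.sort(key=lambda j: (j[0], j[1], j[2]))
    candidates: list[CircleCandidate] = []
    cluster: list[tuple[str, int, int, int]] = []

    def flush():
        if not cluster:
            return
        chrom = cluster[0][0]
        start = _mode_smallest([c[1] for c in cluster])
        end = _mode_smallest([c[2] for c in cluster])
        mapqs = [c[3] for c in cluster]
        cov = coverage[chrom]
        inner = cov[start:end]
        mean_cov = float(inner.mean())
        sd_cov = float(inner.std())
        continuity = float((inner == 0).mean())

        def cov_inc(inside: np.ndarray, outside: np.ndarray) -> float:
            c_in = inside.mean() if len(inside) else 0.0
            c_out = outside.mean() if len(outside) else 0.0
            return float((c_in - c_out) / c_in) if c_in > 0 else 0.0

        inc_start = cov_inc(cov[start : start + COV_WINDOW],
                            cov[max(0, start - COV_WINDOW) : start])
        inc_end = cov_inc(cov[max(start, end - COV_WINDOW) : end],
                          cov[end : end + COV_WINDOW])
        n_disc = sum(
            1
            for c, lo, hi in discordant
            if c == chrom and lo >= start - CLUSTER_TOL and hi <= end + CLUSTER_TOL
        )
        candidates.append(
            CircleCandidate(
                chrom=chrom,
                start=start,
                end=end,
                discordant_count=n_disc,
                split_count=len(cluster),
                circle_score=float(sum(min(q, MAPQ_CAP) for q in mapqs)),
                mean_cov=mean_cov,
                sd_cov=sd_cov,
                cov_inc_start=inc_start,
                cov_inc_end=inc_end,
                cov_continuity=continuity,
            )
        )
        cluster.clear()

    for j in junctions:
        if cluster and (
            j[0] != cluster[0][0]
            or abs(j[1] - _mode_smallest([c[1] for c in cluster])) > CLUSTER_TOL
            or abs(j[2] - _mode_smallest([c[2] for c in cluster])) > CLUSTER_TOL
        ):
            flush()
        cluster.append(j)
    flush()
    candidates.sort(key=lambda c: (c.chrom, c.start, c.end))
    return candidates


# ---------------------------------------------------------------------------
# filtering / dedup / EPM
# ---------------------------------------------------------------------------


def apply_filters(
    candidates: Sequence[CircleCandidate],
    thresholds: FilterThresholds | None = None,
) -> list[CircleCandidate]:
    """Keep candidates passing all six criteria (order preserved).

    Numeric comparisons are inclusive as written (>= / <=) except the SD
    criterion, which is strict (SD < mean).
    """
    t = thresholds or FilterThresholds()
    out = []
    for c in candidates:
        if (
            c.split_count >= t.min_split
            and c.circle_score >= t.min_score
            and c.cov_inc_start >= t.min_inc_start
            and c.cov_inc_end >= t.min_inc_end
            and c.cov_continuity <= t.max_continuity
            and (not t.require_sd_lt_mean or c.sd_cov < c.mean_cov)
        ):
            out.append(c)
    return out


def deduplicate(candidates: Sequence[CircleCandidate]) -> list[CircleCandidate]:
    """Unique by exact (chrom, start, end); highest circle_score wins."""
    best: dict[tuple[str, int, int], CircleCandidate] = {}
    order: list[tuple[str, int, int]] = []
    for c in candidates:
        key = (c.chrom, c.start, c.end)
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.circle_score > best[key].circle_score:
            best[key] = c
    return [best[k] for k in order]


def epm(sample: SampleCircleSet) -> float:
    """Circles per million mapped reads."""
    if sample.mapped_read_count <= 0:
        raise ValueError("mapped_read_count must be positive")
    return len(sample.circles) / (sample.mapped_read_count / 1_000_000)
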