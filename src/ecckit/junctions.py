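"""Junction-flank sequence analysis: base-frequency matrices, direct repeats
and trinucleotide palindromic units.

The junction context of a circle is the +/- w bp (default 10) reference
window around each junction coordinate, read from the + strand. Direct
repeats are exact longest common substrings (4-18 bp) shared by the two
windows, a microhomology signature; palindromic units are 10-bp motifs
(triplet + 4-base spacer + reverse-complement triplet) straddling a junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, revcomp
from .characterize import as_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionContext",
    "DirectRepeatHit",
    "extract_junction_flanks",
    "base_frequency_matrix",
    "find_direct_repeats",
    "find_palindromic_pairs",
    "size_binned_motifs",
]

BASES = "ACGT"
DEFAULT_PEAK_MEANS = (207, 358, 553, 732)


@dataclass
class JunctionContext:
    circle_id: str
    start_window: str  # genome[start-w : start+w], + strand
    end_window: str  # genome[end-w : end+w], + strand
    w: int = 10
    length: int | None = None  # circle length, for size binning

    def __post_init__(self):
        if len(self.start_window) != 2 * self.w or len(self.end_window) != 2 * self.w:
            raise ValueError("junction windows must have length 2w")


@dataclass
class DirectRepeatHit:
    length: int
    sequence: str
    offset_start: int  # signed, relative to the start junction coordinate
    offset_end: int  # signed, relative to the end junction coordinate


def extract_junction_flanks(
    circles, genome: ReferenceGenome, w: int = 10
) -> tuple[list[JunctionContext], list[str]]:
    """Extract the +/- w bp windows around each circle's junctions.

    Circles whose windows do not fit on the chromosome are flagged (returned
    in the second list by id) and excluded.
    """
    df = as_intervals(circles)
    contexts: list[JunctionContext] = []
    flagged: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        cid = f"{row.chrom}:{row.start}-{row.end}"
        chrom_len = genome.lengths[row.chrom]
        if row.start < w or row.end + w > chrom_len:
            flagged.append(cid)
            continue
        contexts.append(
            JunctionContext(
                circle_id=cid,
                start_window=genome.sequence(row.chrom, row.start - w, row.start + w),
                end_window=genome.sequence(row.chrom, row.end - w, row.end + w),
                w=w,
                length=int(row.end - row.start),
            )
        )
    return contexts, flagged


def base_frequency_matrix(
    contexts: Sequence[JunctionContext], site: str = "start"
) -> pd.DataFrame:
    """4 x 2w per-position base frequency matrix around one junction site.

    Column labels are positions relative to the junction (-w .. w-1);
    frequencies are over non-ambiguous bases so columns sum to 1. The table
    is directly renderable as a sequence logo.
    """
    if not contexts:
        raise ValueError("need at least one junction context")
    if site not in ("start", "end"):
        raise ValueError("site must be 'start' or 'end'")
    w = contexts[0].w
    windows = [c.start_window if site == "start" else c.end_window for c in contexts]
    arr = np.array([list(win) for win in windows])
    counts = np.zeros((4, 2 * w))
    for bi, b in enumerate(BASES):
        counts[bi] = (arr == b).sum(axis=0)
    col_tot = counts.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    freq = counts / col_tot
    return pd.DataFrame(freq, index=list(BASES), columns=np.arange(-w, w))


def find_direct_repeats(
    context: JunctionContext, min_len: int = 4, max_len: int = 18
) -> DirectRepeatHit | None:
    """Longest common substring of the two junction windows.

    Returns the longest substring shared by ``start_window`` and
    ``end_window`` with length in [min_len, min(max_len, 2w)]; ties resolve
    to the smallest ``offset_start`` then the smallest ``offset_end``.
    Offsets are reported relative to the junction coordinates. None when no
    common substring reaches ``min_len``.
    """
    a, b = context.start_window, context.end_window
    w = context.w
    cap = min(max_len, 2 * w)
    n, m = len(a), len(b)
    # classic O(nm) longest-common-substring DP; dp[j] = match length ending
    # at a[i-1], b[j-1]
    best_len = 0
    best: tuple[int, int] | None = None  # (end_i, end_j) in a/b
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai in BASES:
                cur[j] = prev[j - 1] + 1
                length = min(cur[j], cap)
                start_i = i - length
                start_j = j - length
                if length > best_len:
                    best_len, best = length, (start_i, start_j)
                elif length == best_len and best is not None:
                    if (start_i, start_j) < best:
                        best = (start_i, start_j)
        prev = cur
    if best_len < min_len or best is None:
        return None
    si, sj = best
    return DirectRepeatHit(
        length=best_len,
        sequence=a[si : si + best_len],
        offset_start=si - w,
        offset_end=sj - w,
    )


def find_palindromic_pairs(
    context: JunctionContext, require_straddle: bool = True
) -> tuple[bool, list[dict]]:
    """Detect 10-bp trinucleotide palindromic units in the junction windows.

    A unit is t1 + spacer + t2 with |t1| = |t2| = 3, |spacer| = 4 and
    t2 = reverse-complement(t1). By default the unit must straddle the
    junction coordinate (unit start < w <= unit end). All matches in either
    window are reported.
    """
    w = context.w
    hits: list[dict] = []
    for site, win in (("start", context.start_window), ("end", context.end_window)):
        for u in range(0, len(win) - 10 + 1):
            if require_straddle and not (u < w <= u + 10):
                continue
            t1 = win[u : u + 3]
            t2 = win[u + 7 : u + 10]
            if any(ch not in BASES for ch in t1 + t2):
                continue
            if t2 == revcomp(t1):
                hits.append({"site": site, "offset": u - w, "unit": win[u : u + 10]})
    return bool(hits), hits


def size_binned_motifs(
    circles,
    contexts: Sequence[JunctionContext],
    peak_means: Sequence[float] = DEFAULT_PEAK_MEANS,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-size-bin base-frequency matrices (start and end junctions).

    Bin edges sit at the midpoints between consecutive peak means; circles
    are assigned to bins by length. Empty bins are noted (absent from the
    result) with a log message.
    """
    means = sorted(peak_means)
    edges = [(means[i] + means[i + 1]) / 2 for i in range(len(means) - 1)]
    bins: dict[str, list[JunctionContext]] = {f"peak_{int(m)}": [] for m in means}
    labels = list(bins)
    for ctx in contexts:
        if ctx.length is None:
            raise ValueError("contexts need circle lengths for size binning")
        k = int(np.searchsorted(edges, ctx.length, side="right"))
        bins[labels[k]].append(ctx)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for label, ctxs in bins.items():
        if not ctxs:
            logger.info("size bin %s is empty; matrix absent", label)
            continue
        out[label] = {
            "start": base_frequency_matrix(ctxs, "start"),
            "end": base_frequency_matrix(ctxs, "end"),
        }
    return out


def junction_table(
    contexts: Sequence[JunctionContext],
    min_len: int = 4,
    max_len: int = 18,
) -> pd.DataFrame:
    """Per-circle junction summary: DR length/sequence and palindrome flag."""
    rows = []
    for ctx in contexts:
        dr = find_direct_repeats(ctx, min_len, max_len)
        pal, _ = find_palindromic_pairs(ctx)
        rows.append(
            {
                "circle_id": ctx.circle_id,
                "dr_length": dr.length if dr else 0,
                "dr_sequence": dr.sequence if dr else "",
                "palindrome": pal,
            }
        )
    return pd.DataFrame(rows)
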