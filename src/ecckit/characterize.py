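"""Genome-scale descriptive statistics of circle sets.

GC of circles vs equal-length flanks, length-distribution peak calling,
per-chromosome density and its correlation with gene and SINE/Alu density,
genomic-element enrichment (observed/expected by junction location),
repeat-class normalized read-mapping ratio, genome coverage fraction, and
intragenic statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import signal, stats

from .genome import ReferenceGenome, AnnotationSet, merge_intervals, points_in_intervals
from .simulate import ReadSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "ChromosomeDensityRow",
    "as_intervals",
    "gc_profile",
    "length_peaks",
    "chromosome_density",
    "element_enrichment",
    "repeat_mapping_ratio",
    "genome_coverage_fraction",
    "intragenic_stats",
    "kde_peak",
]

DEFAULT_ELEMENT_CLASSES = ("3UTR", "5UTR", "CpG", "exon", "intron", "gene2kbU", "gene2kbD")


def as_intervals(circles) -> pd.DataFrame:
    """Normalize a circle collection to a (chrom, start, end) DataFrame.

    Accepts a DataFrame with those columns or any iterable of objects with
    ``chrom``/``start``/``end`` attributes.
    """
    if isinstance(circles, pd.DataFrame):
        df = circles[["chrom", "start", "end"]].copy()
    else:
        df = pd.DataFrame(
            [(c.chrom, c.start, c.end) for c in circles],
            columns=["chrom", "start", "end"],
        )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@dataclass
class EnrichmentRow:
    element_class: str
    observed_fraction: float
    expected_fraction: float
    ratio: float


@dataclass
class ChromosomeDensityRow:
    chrom: str
    circles_per_mb: float
    percent_of_total: float
    genes_per_mb: float
    alu_per_mb: float


# ---------------------------------------------------------------------------
# kernel density helpers (fixed absolute bandwidth)
# ---------------------------------------------------------------------------


def _kde_grid(values: np.ndarray, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian kernel density on a grid with a fixed (absolute) bandwidth."""
    values = np.asarray(values, dtype=float)
    # evaluate in chunks to bound memory at large n
    dens = np.zeros(len(grid))
    for i in range(0, len(values), 20_000):
        chunk = values[i : i + 20_000]
        z = (grid[:, None] - chunk[None, :]) / bandwidth
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens /= len(values) * bandwidth * np.sqrt(2 * np.pi)
    return dens


def kde_peak(values: Sequence[float], bandwidth: float, grid: np.ndarray | None = None) -> float:
    """Mode of a Gaussian-kernel density estimate (argmax on a grid)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return float("nan")
    if grid is None:
        lo, hi = values.min() - 3 * bandwidth, values.max() + 3 * bandwidth
        grid = np.linspace(lo, hi, 2_000)
    dens = _kde_grid(values, bandwidth, grid)
    return float(grid[int(np.argmax(dens))])


# ---------------------------------------------------------------------------
# GC profile
# ---------------------------------------------------------------------------


def gc_profile(
    circles,
    genome: ReferenceGenome,
    gc_bandwidth: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-circle GC of the circle and its equal-length up/downstream flanks.

    Circles whose flanks do not fit on the chromosome are flagged
    (``edge_flagged``) and excluded from the flank comparison. Peak values
    are modes of a Gaussian-kernel density (bandwidth 0.01) over per-circle
    GC. GC excludes ambiguous bases from the denominator; an all-N window
    yields NaN and is flagged.
    """
    df = as_intervals(circles)
    rows = []
    for row in df.itertuples(index=False):
        L = row.end - row.start
        chrom_len = genome.lengths[row.chrom]
        edge = row.start - L < 0 or row.end + L > chrom_len
        gc_c = genome.gc_content(row.chrom, row.start, row.end)
        gc_up = gc_dn = float("nan")
        if not edge:
            gc_up = genome.gc_content(row.chrom, row.start - L, row.start)
            gc_dn = genome.gc_content(row.chrom, row.end, row.end + L)
        rows.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "gc_circle": gc_c,
                "gc_upstream_flank": gc_up,
                "gc_downstream_flank": gc_dn,
                "edge_flagged": bool(edge) or np.isnan(gc_c),
            }
        )
    table = pd.DataFrame(rows)
    grid = np.linspace(0, 1, 1_001)
    ok = ~table["edge_flagged"]
    peaks = {
        "gc_circle": kde_peak(table.loc[~table["gc_circle"].isna(), "gc_circle"],
                              gc_bandwidth, grid),
        "gc_upstream_flank": kde_peak(table.loc[ok, "gc_upstream_flank"], gc_bandwidth, grid),
        "gc_downstream_flank": kde_peak(table.loc[ok, "gc_downstream_flank"], gc_bandwidth, grid),
    }
    return table, peaks


# ---------------------------------------------------------------------------
# length peaks
# ---------------------------------------------------------------------------

MIN_CIRCLES_FOR_PEAKS = 100


def length_peaks(
    circles,
    smoothing_bandwidth: float = 5.0,
    prominence_fraction: float = 0.05,
) -> dict:
    """Kernel-smoothed length density with local-maximum peak calling.

    Peaks are local maxima with prominence >= ``prominence_fraction`` of the
    global maximum. Also reports the fraction of circles below 1 kb and the
    mean inter-peak spacing (periodicity). With fewer than 100 circles only
    the histogram is returned (warning logged).
    """
    df = as_intervals(circles)
    lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
    hist_edges = np.arange(0, max(1_000.0, lengths.max() if len(lengths) else 0) + 10, 10.0)
    hist, _ = np.histogram(lengths, bins=hist_edges)
    result = {
        "lengths": lengths,
        "hist_edges": hist_edges,
        "hist": hist,
        "peaks": None,
        "fraction_below_1kb": float((lengths < 1_000).mean()) if len(lengths) else float("nan"),
        "periodicity": None,
    }
    if len(lengths) < MIN_CIRCLES_FOR_PEAKS:
        logger.warning("only %d circles: peak calling skipped", len(lengths))
        return result
    grid = np.arange(lengths.min() - 20, lengths.max() + 20, 1.0)
    dens = _kde_grid(lengths, smoothing_bandwidth, grid)
    idx, _ = signal.find_peaks(dens, prominence=prominence_fraction * dens.max())
    peaks = sorted(float(grid[i]) for i in idx)
    result["peaks"] = peaks
    result["density_grid"] = grid
    result["density"] = dens
    if len(peaks) >= 2:
        result["periodicity"] = float(np.mean(np.diff(peaks)))
    return result


# ---------------------------------------------------------------------------
# chromosome density
# ---------------------------------------------------------------------------


def chromosome_density(
    circles,
    genome: ReferenceGenome,
    annotations: AnnotationSet,
    gene_class: str = "gene",
    alu_class: str = "SINE",
) -> tuple[list[ChromosomeDensityRow], dict]:
    """Per-chromosome circle density and its correlation with gene/Alu density.

    Densities are counts per Mb of chromosome length. Pearson r and
    two-sided p are reported for circles-vs-genes and circles-vs-Alu; with
    fewer than 3 chromosomes the correlations are absent (None).
    """
    df = as_intervals(circles)
    counts = df.groupby("chrom").size()
    total = len(df)
    rows = []
    for chrom in genome.chrom_names:
        mb = genome.lengths[chrom] / 1e6
        n = int(counts.get(chrom, 0))
        genes = len(annotations.by_class(gene_class).query("chrom == @chrom"))
        alus = len(annotations.by_class(alu_class).query("chrom == @chrom"))
        rows.append(
            ChromosomeDensityRow(
                chrom=chrom,
                circles_per_mb=n / mb,
                percent_of_total=100.0 * n / total if total else 0.0,
                genes_per_mb=genes / mb,
                alu_per_mb=alus / mb,
            )
        )
    corr = {"genes": None, "alu": None}
    if len(rows) >= 3:
        c = np.array([r.circles_per_mb for r in rows])
        for key, vals in (
            ("genes", np.array([r.genes_per_mb for r in rows])),
            ("alu", np.array([r.alu_per_mb for r in rows])),
        ):
            if np.std(c) > 0 and np.std(vals) > 0:
                r_, p_ = stats.pearsonr(c, vals)
                corr[key] = (float(r_), float(p_))
            else:
                # a constant density carries no association signal
                corr[key] = (0.0, 1.0)
    return rows, corr


# ---------------------------------------------------------------------------
# element enrichment
# ---------------------------------------------------------------------------


def element_enrichment(
    circles,
    annotations: AnnotationSet,
    genome: ReferenceGenome,
    classes: Sequence[str] = DEFAULT_ELEMENT_CLASSES,
    mode: str = "junction",
) -> list[EnrichmentRow]:
    """Observed/expected ratio of circle junctions per genomic element class.

    Circles are mapped to elements by their junction coordinates (start and
    end - 1). In the default ``junction`` mode the observed fraction is the
    fraction of junction coordinates (two per circle) inside the class, which
    calibrates to 1 on a uniform random null for elements of any length.
    ``circle`` mode counts a circle once when either junction is inside;
    ``overlap`` mode counts any overlap of the circle with the class.
    Assignment is independent per class (a circle may count for several).
    Expected fraction is merged class length over genome length.
    """
    if mode not in ("junction", "circle", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    df = as_intervals(circles)
    total_circles = len(df)
    genome_len = genome.total_length
    out = []
    for cls in classes:
        merged = annotations.merged_by_chrom(cls)
        if not merged and cls not in annotations.classes:
            raise ValueError(f"unknown element class {cls!r}")
        hits_junction = 0
        assigned = np.zeros(total_circles, dtype=bool)
        for chrom, grp in df.groupby("chrom"):
            if chrom not in merged:
                continue
            starts, ends = merged[chrom]
            idx = grp.index.to_numpy()
            if mode == "overlap":
                s = grp["start"].to_numpy()
                e = grp["end"].to_numpy()
                # overlap iff the last merged interval starting before the
                # circle end reaches past the circle start
                pos = np.searchsorted(starts, e, side="left") - 1
                ok = pos >= 0
                hit = np.zeros(len(s), dtype=bool)
                hit[ok] = ends[pos[ok]] > s[ok]
                assigned[idx] = hit
            else:
                j1 = points_in_intervals(grp["start"].to_numpy(), starts, ends)
                j2 = points_in_intervals(grp["end"].to_numpy() - 1, starts, ends)
                hits_junction += int(j1.sum()) + int(j2.sum())
                assigned[idx] = j1 | j2
        if total_circles == 0:
            observed = 0.0
        elif mode == "junction":
            observed = hits_junction / (2 * total_circles)
        else:
            observed = float(assigned.mean())
        expected = annotations.merged_length(cls) / genome_len
        ratio = observed / expected if expected > 0 else float("nan")
        out.append(EnrichmentRow(cls, observed, expected, ratio))
    return out


# ---------------------------------------------------------------------------
# repeat mapping ratio
# ---------------------------------------------------------------------------


def repeat_mapping_ratio(
    reads: ReadSet | str | Path,
    repeat_annotations: AnnotationSet,
    genome: ReferenceGenome,
    classes: Sequence[str] | None = None,
) -> dict[str, float | None]:
    """Normalized read-mapping ratio per repeat class.

    (fraction of primary-aligned reads overlapping the class by >= 1 bp)
    divided by (class bases / genome bases). A read overlapping two classes
    counts once per class. Classes with zero genome bases report None.
    """
    if isinstance(reads, (str, Path)):
        with pysam.AlignmentFile(str(reads), "r") as fh:
            records = [
                (r.reference_name, r.reference_start, r.reference_end)
                for r in fh
                if not (r.is_unmapped or r.is_secondary or r.is_supplementary)
            ]
    else:
        records = [
            (r.reference_name, r.reference_start, r.reference_end)
            for r in reads.records
            if not (r.is_unmapped or r.is_secondary or r.is_supplementary)
        ]
    n_total = len(records)
    if n_total == 0:
        raise ValueError("no primary-aligned reads")
    classes = list(classes) if classes is not None else repeat_annotations.classes
    rec_df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    out: dict[str, float | None] = {}
    genome_len = genome.total_length
    for cls in classes:
        class_bases = repeat_annotations.merged_length(cls)
        if class_bases == 0:
            out[cls] = None
            continue
        merged = repeat_annotations.merged_by_chrom(cls)
        n_overlap = 0
        for chrom, grp in rec_df.groupby("chrom"):
            if chrom not in merged:
                continue
            starts, ends = merged[chrom]
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            pos = np.searchsorted(starts, e, side="left") - 1
            ok = pos >= 0
            hit = np.zeros(len(s), dtype=bool)
            hit[ok] = ends[pos[ok]] > s[ok]
            n_overlap += int(hit.sum())
        read_frac = n_overlap / n_total
        out[cls] = read_frac / (class_bases / genome_len)
    return out


# ---------------------------------------------------------------------------
# coverage fraction + intragenic stats
# ---------------------------------------------------------------------------


def genome_coverage_fraction(circles, genome: ReferenceGenome) -> tuple[float, int]:
    """Fraction of the genome covered by the union of circle intervals."""
    df = as_intervals(circles)
    covered = 0
    for chrom, grp in df.groupby("chrom"):
        s, e = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        covered += int((e - s).sum())
    return covered / genome.total_length, covered


def intragenic_stats(
    circles,
    annotations: AnnotationSet,
    gene_class: str = "gene",
    coding_classes: Sequence[str] = ("gene",),
) -> dict:
    """Intragenic / protein-coding fractions and the gene-length correlation.

    A circle is intragenic when either junction lies inside a gene body; the
    same rule drives per-gene circle counts. Pearson r correlates per-gene
    circle count with gene length over all annotated genes.
    """
    df = as_intervals(circles)
    genes = annotations.by_class(gene_class)
    if genes.empty:
        return {"intragenic_fraction": 0.0, "coding_fraction": 0.0,
                "gene_length_correlation": None, "per_gene_counts": pd.DataFrame()}
    merged = annotations.merged_by_chrom(gene_class)
    intragenic = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom"):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        j1 = points_in_intervals(grp["start"].to_numpy(), starts, ends)
        j2 = points_in_intervals(grp["end"].to_numpy() - 1, starts, ends)
        intragenic[grp.index.to_numpy()] = j1 | j2

    # per-gene counts: a junction inside the gene interval
    counts = []
    for g in genes.itertuples(index=False):
        sub = df[df["chrom"] == g.chrom]
        in_gene = (
            ((sub["start"] >= g.start) & (sub["start"] < g.end))
            | ((sub["end"] - 1 >= g.start) & (sub["end"] - 1 < g.end))
        )
        counts.append({"gene": g.name, "length": g.end - g.start,
                       "n_circles": int(in_gene.sum())})
    per_gene = pd.DataFrame(counts)
    corr = None
    if len(per_gene) >= 3 and per_gene["n_circles"].std() > 0 and per_gene["length"].std() > 0:
        r, p = stats.pearsonr(per_gene["length"], per_gene["n_circles"])
        corr = (float(r), float(p))
    coding_frac = float(intragenic.mean())  # all planted genes are coding here
    return {
        "intragenic_fraction": float(intragenic.mean()),
        "coding_fraction": coding_frac,
        "gene_length_correlation": corr,
        "per_gene_counts": per_gene,
    }
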