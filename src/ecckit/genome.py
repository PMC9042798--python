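"""Reference genome and annotation containers.

All coordinates throughout the package are 0-based, half-open
``[start, end)``; interval length is always ``end - start``.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ReferenceGenome", "AnnotationSet", "merge_intervals", "points_in_intervals"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """Named chromosome sequences; the coordinate source of truth.

    Sequences are stored mutably (``bytearray``) so that the simulator can
    plant junction motifs in place; analysis code only reads from it.
    """

    def __init__(self, chroms: Mapping[str, str | bytes | bytearray]):
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs: dict[str, bytearray] = {}
        for name, seq in chroms.items():
            if isinstance(seq, str):
                seq = seq.encode("ascii")
            self._seqs[str(name)] = bytearray(seq.upper())
        self._gc_cumsum: dict[str, np.ndarray] = {}

    # -- basic accessors -------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        """Return the + strand sequence of ``chrom[start:end]``."""
        seq = self._seqs[chrom]
        if end is None:
            end = len(seq)
        if start < 0 or end > len(seq) or end < start:
            raise ValueError(
                f"window [{start}, {end}) out of bounds for {chrom} (length {len(seq)})"
            )
        return self._seqs[chrom][start:end].decode("ascii")

    def write(self, chrom: str, pos: int, seq: str) -> None:
        """Overwrite genome sequence at ``pos`` (simulator planting only)."""
        b = seq.encode("ascii")
        if pos < 0 or pos + len(b) > len(self._seqs[chrom]):
            raise ValueError(f"write of {len(b)} bp at {chrom}:{pos} is out of bounds")
        self._seqs[chrom][pos : pos + len(b)] = b
        self._gc_cumsum.pop(chrom, None)

    # -- GC helpers ------------------------------------------------------
    def gc_cumsum(self, chrom: str) -> np.ndarray:
        """Cumulative count of G/C bases; entry i = #GC in [0, i)."""
        if chrom not in self._gc_cumsum:
            arr = np.frombuffer(bytes(self._seqs[chrom]), dtype=np.uint8)
            gc = (arr == ord("G")) | (arr == ord("C"))
            self._gc_cumsum[chrom] = np.concatenate(
                [[0], np.cumsum(gc, dtype=np.int64)]
            )
        return self._gc_cumsum[chrom]

    def gc_content(self, chrom: str, start: int, end: int) -> float:
        """GC fraction of a window, ambiguous bases excluded from denominator.

        Returns ``nan`` for an all-N window.
        """
        window = self.sequence(chrom, start, end)
        acgt = sum(window.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        return (window.count("G") + window.count("C")) / acgt

    def global_gc(self) -> float:
        num = sum(int(self.gc_cumsum(c)[-1]) for c in self._seqs)
        return num / self.total_length

    # -- I/O ---------------------------------------------------------------
    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                s = seq.decode("ascii")
                for i in range(0, len(s), line_width):
                    fh.write(s[i : i + line_width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals into a disjoint sorted set."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts = np.asarray(starts, dtype=np.int64)[order]
    ends = np.asarray(ends, dtype=np.int64)[order]
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def points_in_intervals(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: does each point fall inside any merged (disjoint, sorted) interval."""
    points = np.asarray(points, dtype=np.int64)
    if len(starts) == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(points), dtype=bool)
    hit[ok] = points[ok] < ends[idx[ok]]
    return hit


_GFF3_SOURCE = "ecckit"


class AnnotationSet:
    """Strand-aware labeled genomic intervals (genes, exons, repeats, miRNAs...).

    Backed by a DataFrame with columns chrom, start, end, strand,
    feature_class, name. Coordinates half-open 0-based.
    """

    COLUMNS = ["chrom", "start", "end", "strand", "feature_class", "name"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("annotation intervals must satisfy end > start")
        self.df = df.reset_index(drop=True)
        self._merged_cache: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "AnnotationSet":
        return cls(pd.DataFrame(list(records), columns=cls.COLUMNS))

    @property
    def classes(self) -> list[str]:
        return sorted(self.df["feature_class"].unique())

    def by_class(self, feature_class: str) -> pd.DataFrame:
        return self.df[self.df["feature_class"] == feature_class]

    def merged_by_chrom(self, feature_class: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (disjoint, sorted) intervals of one class."""
        if feature_class not in self._merged_cache:
            sub = self.by_class(feature_class)
            merged = {}
            for chrom, grp in sub.groupby("chrom"):
                merged[str(chrom)] = merge_intervals(
                    grp["start"].to_numpy(), grp["end"].to_numpy()
                )
            self._merged_cache[feature_class] = merged
        return self._merged_cache[feature_class]

    def merged_length(self, feature_class: str) -> int:
        total = 0
        for starts, ends in self.merged_by_chrom(feature_class).values():
            total += int((ends - starts).sum())
        return total

    # -- I/O ---------------------------------------------------------------
    def write_bed(self, path: str | Path) -> None:
        out = self.df.copy()
        out["score"] = 0
        out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.df.itertuples(index=False):
                attrs = f"ID={row.name};Name={row.name}"
                fh.write(
                    f"{row.chrom}\t{_GFF3_SOURCE}\t{row.feature_class}\t"
                    f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                name = ""
                for field in f[8].split(";"):
                    if field.startswith("ID="):
                        name = field[3:]
                rows.append((f[0], int(f[3]) - 1, int(f[4]), f[6], f[2], name))
        return cls.from_records(rows)

    @classmethod
    def from_bed(cls, path: str | Path, feature_class: str) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        n = df.shape[1]
        rows = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1],
                "end": df[2],
                "strand": df[5] if n > 5 else "+",
                "feature_class": feature_class,
                "name": df[3] if n > 3 else "",
            }
        )
        return cls(rows)

    def __len__(self) -> int:
        return len(self.df)
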