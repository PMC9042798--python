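"""Chromosome-length-weighted random circle null datasets.

The expectation baseline for enrichment statistics: each in-silico circle's
chromosome is drawn with probability proportional to chromosome length, its
start uniformly on the chromosome, and its size uniformly on
[size_min, size_max] (150-850 bp by default). Circles extending past the
chromosome end are resampled, preserving the size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceGenome

__all__ = ["NullConfig", "generate_insilico"]


@dataclass
class NullConfig:
    n_per_dataset: Sequence[int]
    size_min: int = 150
    size_max: int = 850
    seed: int = 0

    @property
    def n_datasets(self) -> int:
        return len(self.n_per_dataset)

    def validate(self) -> None:
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be < size_max")
        if len(self.n_per_dataset) == 0 or any(n < 1 for n in self.n_per_dataset):
            raise ValueError("each dataset needs at least one circle")


def generate_insilico(
    config: NullConfig, genome: ReferenceGenome
) -> list[pd.DataFrame]:
    """Generate matched random circle datasets; deterministic per seed.

    Returns one (chrom, start, end) DataFrame per dataset.
    """
    config.validate()
    for chrom, L in genome.lengths.items():
        if config.size_max > L:
            raise ValueError(
                f"size_max {config.size_max} exceeds length of chromosome {chrom!r} ({L})"
            )
    rng = np.random.default_rng(config.seed)
    chroms = genome.chrom_names
    lens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    p = lens / lens.sum()
    datasets = []
    for n in config.n_per_dataset:
        ci = rng.choice(len(chroms), size=n, p=p)
        sizes = rng.integers(config.size_min, config.size_max + 1, size=n)
        starts = (rng.random(n) * lens[ci]).astype(np.int64)
        # resample circles running off the chromosome end
        bad = starts + sizes > lens[ci]
        while bad.any():
            starts[bad] = (rng.random(bad.sum()) * lens[ci[bad]]).astype(np.int64)
            bad = starts + sizes > lens[ci]
        datasets.append(
            pd.DataFrame(
                {
                    "chrom": [chroms[i] for i in ci],
                    "start": starts,
                    "end": starts + sizes,
                }
            )
        )
    return datasets


def write_null_datasets(
    datasets: Sequence[pd.DataFrame], outdir: str | Path, prefix: str = "insilico"
) -> Path:
    """One BED3 per dataset plus a manifest TSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, df in enumerate(datasets):
        path = outdir / f"{prefix}_{i + 1:02d}.bed"
        df.to_csv(path, sep="\t", header=False, index=False)
        manifest.append({"dataset": i + 1, "n_circles": len(df), "path": path.name})
    mpath = outdir / f"{prefix}_manifest.tsv"
    pd.DataFrame(manifest).to_csv(mpath, sep="\t", index=False)
    return mpath
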