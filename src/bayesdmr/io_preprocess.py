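"""Count-table input/output, coverage filtering and genome chunking.

WGBS methylation calls arrive as per-sample tables of methylated / total
read counts at CpG coordinates.  This module merges per-sample files into a
single :class:`MethylationTable`, drops CpGs observed in too few samples,
and splits the genome into independent chunks at large CpG gaps so that the
latent-field model factorizes into small block problems.

Coordinates are 1-based inclusive throughout (bismark coverage convention);
BED output converts to 0-based half-open on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationTable",
    "Chunk",
    "ParseError",
    "ValidationError",
    "read_counts",
    "read_sample_sheet",
    "write_counts",
    "filter_sites",
    "chunk_genome",
    "write_site_table",
    "write_dmr_bed",
]


class ParseError(ValueError):
    """A count file could not be parsed; message carries file and line."""


class ValidationError(ValueError):
    """Counts violate an invariant (y > n, duplicate coordinates, ...)."""


@dataclass
class MethylationTable:
    """Per-CpG, per-sample methylated/total counts for two groups.

    Missing observations (sample has no reads at a site) are stored as NaN
    in both ``meth`` and ``total``.  Sites are sorted by (chrom, pos) with
    unique positions per chromosome.

    Parameters
    ----------
    chrom, pos : arrays of shape (n_sites,)
        Chromosome name and 1-based coordinate of each CpG.
    meth, total : float arrays of shape (n_sites, n_samples)
        Methylated and total read counts; NaN marks a missing sample.
    groups : int array of shape (n_samples,)
        Group index (0 or 1) of each sample column.
    samples : list of sample names.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    groups: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.atleast_2d(np.asarray(self.meth, dtype=float))
        self.total = np.atleast_2d(np.asarray(self.total, dtype=float))
        self.groups = np.asarray(self.groups, dtype=np.int64)
        if not self.samples:
            self.samples = [f"s{j}" for j in range(self.meth.shape[1])]
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.meth.shape != self.total.shape:
            raise ValidationError("meth/total shape mismatch")
        if self.meth.shape[0] != self.pos.shape[0]:
            raise ValidationError("site count mismatch between pos and counts")
        if self.groups.shape[0] != self.meth.shape[1]:
            raise ValidationError("one group label per sample column required")
        if self.n_sites and self.pos.min() < 1:
            raise ValidationError("positions must be >= 1 (1-based)")
        obs = np.isfinite(self.total)
        if np.any(self.meth[obs] > self.total[obs]):
            i, j = np.argwhere(self.meth > self.total)[0]
            raise ValidationError(
                f"methylated > total at {self.chrom[i]}:{self.pos[i]} "
                f"sample {self.samples[j]}"
            )
        if np.any(np.isfinite(self.meth) & (self.meth < 0)):
            raise ValidationError("negative methylated counts")
        # strictly increasing pos within each chromosome, blocks contiguous
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on {c}"
                )
        for g in (0, 1):
            if self.n_samples and not np.any(self.groups == g):
                raise ValidationError(f"group {g + 1} has no samples")

    # -- basic accessors ------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.pos.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    @property
    def chromosomes(self) -> list:
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def group_columns(self, group: int) -> np.ndarray:
        """Column indices of samples in ``group`` (0 or 1)."""
        return np.flatnonzero(self.groups == group)

    @property
    def replicates(self) -> tuple:
        """(R1, R2): number of samples per group."""
        return (len(self.group_columns(0)), len(self.group_columns(1)))

    def islice(self, start: int, stop: int) -> "MethylationTable":
        """Row slice [start, stop) as a new table (views where possible)."""
        return MethylationTable(
            self.chrom[start:stop],
            self.pos[start:stop],
            self.meth[start:stop],
            self.total[start:stop],
            self.groups,
            self.samples,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "pos": self.pos}
        for j, name in enumerate(self.samples):
            data[f"meth_{name}"] = self.meth[:, j]
            data[f"total_{name}"] = self.total[:, j]
        return pd.DataFrame(data)


@dataclass
class Chunk:
    """A contiguous run of CpGs analyzed as one independent block.

    Gaps between consecutive CpGs inside the chunk never exceed the chunking
    threshold, and the gaps to the neighbouring chunks exceed it; each chunk
    is one block of the block-diagonal latent-field precision.
    """

    chrom: str
    table: MethylationTable
    index: int
    start: int  # row offset of the first member site in the parent table
    stop: int

    @property
    def n_sites(self) -> int:
        return self.table.n_sites

    @property
    def pos(self) -> np.ndarray:
        return self.table.pos


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_COVERAGE_COLS = ["chrom", "start", "end", "pct", "meth", "unmeth"]
_GENERIC_COLS = ["chrom", "pos", "meth", "total"]


def read_sample_sheet(path) -> list:
    """Read a two-column whitespace-separated sheet ``file<TAB>group``."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'file group'")
            entries.append((parts[0], parts[1]))
    return entries


def _read_one(path, dialect: str) -> pd.DataFrame:
    names = _COVERAGE_COLS if dialect == "coverage" else _GENERIC_COLS
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=names,
                         comment="#", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise ParseError(f"{path}: cannot parse: {exc}") from exc
    numeric = [c for c in names if c != "chrom"]
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ParseError(f"{path}:{lineno}: non-numeric value in '{c}'")
        if coerced.isna().any():
            lineno = int(coerced.isna().idxmax()) + 1
            raise ParseError(f"{path}:{lineno}: missing value in '{c}'")
        df[c] = coerced
    if dialect == "coverage":
        df = pd.DataFrame({
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "meth": df["meth"].astype(float),
            "total": (df["meth"] + df["unmeth"]).astype(float),
        })
    else:
        df["pos"] = df["pos"].astype(np.int64)
    if (df["meth"] > df["total"]).any():
        i = int((df["meth"] > df["total"]).idxmax())
        raise ValidationError(
            f"{path}:{i + 1}: methylated count exceeds total"
        )
    if df.duplicated(["chrom", "pos"]).any():
        i = int(df.duplicated(["chrom", "pos"]).idxmax())
        raise ValidationError(f"{path}:{i + 1}: duplicated (chrom, pos)")
    return df


def read_counts(paths: Sequence, sample_to_group: dict,
                dialect: str = "coverage") -> MethylationTable:
    """Merge per-sample count files into a :class:`MethylationTable`.

    Parameters
    ----------
    paths : sequence of file paths, one per sample.
    sample_to_group : mapping ``path -> group label``; exactly two distinct
        labels are required.  Labels are assigned to group 0/1 in sorted
        order.
    dialect : ``"coverage"`` (bismark: chrom start end pct meth unmeth) or
        ``"generic"`` (chrom pos meth total).
    """
    if dialect not in ("coverage", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    paths = list(paths)
    labels = sorted({str(sample_to_group[p]) for p in paths})
    if paths and len(labels) != 2:
        raise ValidationError(
            f"exactly two group labels required, got {labels}"
        )
    frames = []
    for p in paths:
        df = _read_one(p, dialect)
        df = df.set_index(["chrom", "pos"])
        frames.append(df)
    if not frames:
        return MethylationTable(
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.empty((0, 0)), np.empty((0, 0)),
            np.array([], dtype=np.int64), [])
    index = frames[0].index
    for df in frames[1:]:
        index = index.union(df.index)
    index = index.sortlevel(["chrom", "pos"])[0]
    n = len(index)
    meth = np.full((n, len(paths)), np.nan)
    total = np.full((n, len(paths)), np.nan)
    for j, df in enumerate(frames):
        df = df.reindex(index)
        meth[:, j] = df["meth"].to_numpy()
        total[:, j] = df["total"].to_numpy()
    groups = np.array([labels.index(str(sample_to_group[p])) for p in paths])
    names = [str(p) for p in paths]
    chroms = index.get_level_values(0).to_numpy(dtype=object)
    pos = index.get_level_values(1).to_numpy(dtype=np.int64)
    return MethylationTable(chroms, pos, meth, total, groups, names)


def write_counts(table: MethylationTable, directory, prefix: str = "sample"):
    """Write one generic-dialect file per sample; returns (paths, mapping).

    Round-trips exactly through :func:`read_counts` with ``dialect="generic"``
    (missing sites are simply omitted from that sample's file).
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths, mapping = [], {}
    for j, name in enumerate(table.samples):
        path = os.path.join(directory, f"{prefix}_{name}.tsv")
        obs = np.isfinite(table.total[:, j])
        df = pd.DataFrame({
            "chrom": table.chrom[obs],
            "pos": table.pos[obs],
            "meth": table.meth[obs, j].astype(np.int64),
            "total": table.total[obs, j].astype(np.int64),
        })
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
        mapping[path] = f"g{table.groups[j] + 1}"
    return paths, mapping


# ---------------------------------------------------------------------------
# filtering and chunking
# ---------------------------------------------------------------------------

def filter_sites(table: MethylationTable,
                 min_fraction: float = 0.5) -> MethylationTable:
    """Drop CpGs covered in fewer than ``min_fraction`` of the samples.

    A sample covers a site when its total count is positive.  Sites at
    exactly the threshold are kept.  Idempotent; order preserving.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    if table.n_sites == 0:
        return table
    covered = np.isfinite(table.total) & (table.total > 0)
    frac = covered.sum(axis=1) / table.n_samples
    keep = frac >= min_fraction
    out = MethylationTable(table.chrom[keep], table.pos[keep],
                           table.meth[keep], table.total[keep],
                           table.groups, table.samples)
    for g in (0, 1):
        cols = out.group_columns(g)
        cov_g = np.isfinite(out.total[:, cols]) & (out.total[:, cols] > 0)
        n_empty = int(np.sum(cov_g.sum(axis=1) == 0))
        if n_empty:
            logger.warning(
                "%d retained sites have zero covered replicates in group %d; "
                "their profile will be interpolated", n_empty, g + 1)
    return out


def chunk_genome(table: MethylationTable,
                 gap_threshold: int = 3000) -> list:
    """Partition the table into chunks at chromosome changes and CpG gaps
    strictly greater than ``gap_threshold`` bp.

    Concatenating the chunks reproduces the table.
    """
    if table.n_sites == 0:
        return []
    new_chrom = np.empty(table.n_sites, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = table.chrom[1:] != table.chrom[:-1]
    gap = np.empty(table.n_sites, dtype=bool)
    gap[0] = False
    gap[1:] = np.diff(table.pos) > gap_threshold
    breaks = np.flatnonzero(new_chrom | gap)
    bounds = list(breaks) + [table.n_sites]
    chunks = []
    for k in range(len(breaks)):
        lo, hi = bounds[k], bounds[k + 1]
        chunks.append(Chunk(chrom=table.chrom[lo], index=k,
                            table=table.islice(lo, hi), start=lo, stop=hi))
    return chunks


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def write_site_table(profile: pd.DataFrame, path) -> None:
    """Write the per-CpG result TSV.

    Columns: chrom pos meanmeth_g1 meanmeth_g2 d p_neg p_null p_pos
    significant.
    """
    cols = ["chrom", "pos", "meanmeth_g1", "meanmeth_g2", "d",
            "p_neg", "p_null", "p_pos", "significant"]
    out = profile.loc[:, [c for c in cols if c in profile.columns]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED-like TSV: chrom start end name n_cpg mean_d.

    Internal coordinates are 1-based inclusive; BED is 0-based half-open,
    so start = first_pos - 1 and end = last_pos.
    """
    with open(path, "w") as fh:
        for k, row in enumerate(dmrs.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                     f"dmr_{k + 1}\t{row.n_cpg}\t{row.mean_d:.6g}\n")
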