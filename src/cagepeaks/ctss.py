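"""Single-nucleotide CAGE TSS (CTSS) tables: counting, normalization, I/O.

A CTSS record is one genomic position + strand carrying the number of CAGE
reads whose mapping *starts* there (the 5'-most aligned base of the read).
Coordinates are 0-based; a record occupies the half-open interval
``[pos, pos + 1)`` as in BED.

The on-disk format is BED6-like, tab separated::

    #chrom  start  end  name  count  strand

with ``end == start + 1`` always (CTSS are single-nucleotide) and the score
column holding the raw integer tag count.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]

_MILLION = 1_000_000.0


@dataclasses.dataclass
class CTSSTable:
    """Canonical container for CTSS records.

    ``df`` holds one row per (chrom, pos, strand) with a positive integer
    ``count`` and, after :func:`tpm_normalize`, a ``tpm`` column. Rows are
    kept sorted by (chrom, strand, pos); zero-count positions are never
    materialized.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CTSS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CTSS table missing columns: {missing}")
        if len(df):
            if (df["count"] < 1).any():
                raise ValueError("CTSS counts must be >= 1")
            if not df["strand"].isin(["+", "-"]).all():
                raise ValueError("strand must be '+' or '-'")
        df = df.sort_values(["chrom", "strand", "pos"], kind="mergesort")
        df = df.reset_index(drop=True)
        if len(df) and df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) in CTSS table")
        self.df = df

    @property
    def library_size(self) -> int:
        return int(self.df["count"].sum()) if len(self.df) else 0

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CTSSTable):
            return NotImplemented
        a = self.df[CTSS_COLUMNS].reset_index(drop=True)
        b = other.df[CTSS_COLUMNS].reset_index(drop=True)
        return a.equals(b)


def _iter_alignments(alignments):
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    elif isinstance(alignments, pysam.AlignmentFile):
        yield from alignments
    else:
        yield from alignments


def count_ctss(
    alignments,
    *,
    include_secondary: bool = False,
    include_supplementary: bool = False,
) -> CTSSTable:
    """Count CAGE read 5' ends at single-nucleotide resolution.

    Forward-strand reads contribute at their leftmost aligned base, reverse
    reads at their rightmost aligned base. Unmapped records are skipped;
    secondary and supplementary alignments are excluded by default so each
    tag is counted once, at its primary location.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file, an open :class:`pysam.AlignmentFile`, or an
        iterable of :class:`pysam.AlignedSegment`.
    """
    counts: dict[tuple[str, int, str], int] = {}
    for idx, aln in enumerate(_iter_alignments(alignments)):
        try:
            if aln.is_unmapped:
                continue
            if aln.is_secondary and not include_secondary:
                continue
            if aln.is_supplementary and not include_supplementary:
                continue
            chrom = aln.reference_name
            if aln.is_reverse:
                end = aln.reference_end
                if end is None:
                    raise ValueError("no aligned length")
                pos = end - 1
                strand = "-"
            else:
                pos = aln.reference_start
                strand = "+"
            if chrom is None or pos is None or pos < 0:
                raise ValueError("missing coordinates")
        except (ValueError, AttributeError, TypeError) as exc:
            raise ValueError(f"malformed alignment record at index {idx}: {exc}") from exc
        key = (chrom, pos, strand)
        counts[key] = counts.get(key, 0) + 1

    if not counts:
        return CTSSTable(pd.DataFrame(columns=CTSS_COLUMNS).astype(
            {"chrom": str, "pos": np.int64, "strand": str, "count": np.int64}
        ))
    rows = [(c, p, s, n) for (c, p, s), n in counts.items()]
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["count"] = df["count"].astype(np.int64)
    return CTSSTable(df)


def tpm_normalize(table: CTSSTable) -> CTSSTable:
    """Return a copy with tags-per-million: ``tpm = count * 1e6 / library_size``."""
    lib = table.library_size
    if lib == 0:
        raise ValueError("empty library")
    df = table.df.copy()
    df["tpm"] = df["count"].to_numpy(dtype=np.float64) * _MILLION / lib
    return CTSSTable(df)


def merge_tables(tables: Iterable[CTSSTable]) -> CTSSTable:
    """Sum counts of several CTSS tables position-wise (e.g. pooling replicates)."""
    frames = [t.df[CTSS_COLUMNS] for t in tables]
    if not frames:
        raise ValueError("no tables to merge")
    df = pd.concat(frames, ignore_index=True)
    df = df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
    return CTSSTable(df[CTSS_COLUMNS])


def read_ctss(path) -> CTSSTable:
    """Read a CTSS table from BED6-like text (see module docstring)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
            chrom, start_s, end_s, _name, count_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end != start + 1:
                raise ValueError(
                    f"{path}:{lineno}: CTSS records are single-nucleotide (end must be start+1)"
                )
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count {count_s!r}") from exc
            rows.append((chrom, start, strand, count))
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    if len(df) == 0:
        df = df.astype({"chrom": str, "pos": np.int64, "strand": str, "count": np.int64})
    return CTSSTable(df)


def write_ctss(table: CTSSTable, path) -> None:
    """Write a CTSS table as BED6 with a '#' header line.

    ``write_ctss`` then :func:`read_ctss` is the identity on canonical-sorted
    tables, and re-writing the read table reproduces the file byte for byte.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tcount\tstrand\n")
        for chrom, pos, strand, count in table.df[CTSS_COLUMNS].itertuples(index=False):
            name = f"{chrom}:{pos}:{strand}"
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\t{count}\t{strand}\n")
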