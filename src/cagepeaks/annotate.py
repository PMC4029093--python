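"""Assigning peaks to genes via promoter windows; known vs novel peaks.

A peak is assigned to every gene whose promoter window — the gene TSS plus
or minus ``window`` bp (inclusive on both ends) — it overlaps by at least
one base on the same strand. Peaks overlapping no window are *novel*.
Peak intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENE_TSS_COLUMNS = ["gene", "chrom", "tss", "strand"]


def read_gene_tss(path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene TSS positions from BED (6 or 12 columns) or refFlat text.

    TSS is ``txStart`` on '+' and ``txEnd - 1`` on '-'. Duplicate
    (gene, tss, strand) triples are collapsed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            use = fmt
            if use is None:  # refFlat carries strand in column 4, BED in column 6
                use = "refflat" if len(f) >= 6 and f[3] in "+-" else "bed"
            if use == "refflat":
                # geneName, name, chrom, strand, txStart, txEnd, ...
                gene, chrom, strand = f[0], f[2], f[3]
                start, end = int(f[4]), int(f[5])
            else:
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: BED gene model needs 6+ fields")
                chrom, gene, strand = f[0], f[3], f[5]
                start, end = int(f[1]), int(f[2])
            tss = start if strand == "+" else end - 1
            rows.append((gene, chrom, tss, strand))
    df = pd.DataFrame(rows, columns=GENE_TSS_COLUMNS)
    return df.drop_duplicates(["gene", "tss", "strand"]).reset_index(drop=True)


def assign_clusters(
    clusters: pd.DataFrame,
    gene_tss: pd.DataFrame,
    window: int = 500,
    *,
    stranded: bool = True,
) -> pd.DataFrame:
    """Assign each peak to overlapping gene promoter windows.

    Returns one row per (peak, gene) assignment with the distance from the
    peak to the TSS (0 when the TSS falls inside the peak), plus a
    ``known`` column on the peak grain: peaks without any assignment are
    novel. Peak ids are the row labels of ``clusters``.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    clusters = clusters.copy()
    rows = []
    keys = ["chrom", "strand"] if stranded else ["chrom"]
    tss_groups = {k: g for k, g in gene_tss.groupby(keys, sort=False)}
    for key, grp in clusters.groupby(keys, sort=False):
        g = tss_groups.get(key)
        if g is None:
            continue
        order = np.argsort(g["tss"].to_numpy(), kind="mergesort")
        tss_sorted = g["tss"].to_numpy()[order]
        genes_sorted = g["gene"].to_numpy()[order]
        for cid, s, e in zip(grp.index, grp["start"].to_numpy(), grp["end"].to_numpy()):
            # overlap with [tss - w, tss + w] iff tss in [s - w, e - 1 + w]
            lo = np.searchsorted(tss_sorted, s - window, side="left")
            hi = np.searchsorted(tss_sorted, e - 1 + window, side="right")
            for j in range(lo, hi):
                t = tss_sorted[j]
                dist = 0 if s <= t < e else int(min(abs(s - t), abs(e - 1 - t)))
                rows.append((cid, genes_sorted[j], dist))
    assignments = pd.DataFrame(rows, columns=["cluster", "gene", "distance"])
    return assignments


def known_novel(clusters: pd.DataFrame, assignments: pd.DataFrame) -> pd.Series:
    """Boolean per peak: True when assigned to at least one gene window."""
    known = pd.Series(False, index=clusters.index, name="known")
    if len(assignments):
        known.loc[assignments["cluster"].unique()] = True
    return known


def tpm_bin_summary(
    clusters: pd.DataFrame,
    bin_edges,
    *,
    reproducible: pd.Series | np.ndarray | None = None,
    known: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Count peaks per expression (TPM) bin, split by reproducibility and by
    known/novel status. Bins are right-closed; values at a bin edge fall in
    the bin that ends there. Counts partition the input."""
    df = pd.DataFrame({"tpm": clusters["tpm"].to_numpy()})
    edges = np.asarray(bin_edges, dtype=float)
    df["bin"] = pd.cut(df["tpm"], edges, right=True, include_lowest=True)
    df["reproducible"] = (
        np.asarray(reproducible, dtype=bool) if reproducible is not None else True
    )
    df["known"] = np.asarray(known, dtype=bool) if known is not None else True
    out = (
        df.groupby(["bin", "reproducible", "known"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return out
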