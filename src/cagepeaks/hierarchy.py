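"""Containment forests over reproducible peaks: bottom/top extraction.

Reproducible peaks at different density scales nest ("clusters within
clusters"). The containment forest links each peak to the smallest peak
strictly containing it. Two analysis classes are read off the forest:

* **bottom** peaks — roots, i.e. peaks not contained in any other peak
  (the broadest reproducible layer);
* **top** peaks — leaves, i.e. peaks containing no other peak (the
  narrowest layer, individual TSS positions in the extreme).

Intervals here are half-open ``[start, end)`` on one chromosome+strand.
Because merged intervals are intersections, partial overlaps are possible;
partially overlapping peaks share no edge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def build_forest(clusters: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``parent`` column: index of the smallest strictly containing
    peak on the same chromosome+strand, or -1.

    Input must be de-duplicated on (chrom, strand, start, end).
    """
    df = clusters.reset_index(drop=True).copy()
    if df.duplicated(["chrom", "strand", "start", "end"]).any():
        raise ValueError("duplicate intervals: de-duplicate before building the forest")
    parent = np.full(len(df), -1, dtype=np.int64)
    for _, grp in df.groupby(["chrom", "strand"], sort=False):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lengths = ends - starts
        for k in range(len(idx)):
            contains = (
                (starts <= starts[k]) & (ends >= ends[k]) & (lengths > lengths[k])
            )
            if contains.any():
                cand = np.flatnonzero(contains)
                best = cand[np.lexsort((starts[cand], lengths[cand]))[0]]
                parent[idx[k]] = idx[best]
    df["parent"] = parent
    return df


def extract_bottom(forest: pd.DataFrame) -> pd.DataFrame:
    """Root peaks: not contained in any other peak (broadest layer)."""
    return forest.loc[forest["parent"] == -1].reset_index(drop=True)


def extract_top(forest: pd.DataFrame) -> pd.DataFrame:
    """Leaf peaks: containing no other peak (narrowest layer)."""
    has_child = np.zeros(len(forest), dtype=bool)
    for p in forest["parent"].to_numpy():
        if p >= 0:
            has_child[p] = True
    return forest.loc[~has_child].reset_index(drop=True)


def descendant_counts(forest: pd.DataFrame) -> np.ndarray:
    """Number of peaks (transitively) contained in each peak."""
    n = len(forest)
    parent = forest["parent"].to_numpy()
    counts = np.zeros(n, dtype=np.int64)
    # children have larger lengths? No: process nodes in order of increasing
    # depth from leaves: accumulate along parent chains.
    order = np.argsort(forest["end"].to_numpy() - forest["start"].to_numpy())
    for i in order:  # shortest (deepest) first; child totals ready before parent
        p = parent[i]
        if p >= 0:
            counts[p] += counts[i] + 1
    return counts


def size_vs_content_histogram(
    forest: pd.DataFrame,
    bin_width: int = 10,
    content_bin_width: int = 40,
) -> pd.DataFrame:
    """Joint histogram of peak length vs number of contained peaks.

    Returns a table (length_bin, content_bin, count); bins are labelled by
    their lower edge, and the counts across all bins partition the peaks.
    Log-scaling of frequencies is left to the plotting layer.
    """
    if len(forest) == 0:
        return pd.DataFrame(columns=["length_bin", "content_bin", "count"])
    lengths = forest["end"].to_numpy() - forest["start"].to_numpy()
    contents = descendant_counts(forest)
    length_bin = (lengths // bin_width) * bin_width
    content_bin = np.where(
        contents == 0, -1, ((contents - 1) // content_bin_width) * content_bin_width + 1
    )
    df = pd.DataFrame({"length_bin": length_bin, "content_bin": content_bin})
    out = df.value_counts().rename("count").reset_index()
    return out.sort_values(["length_bin", "content_bin"]).reset_index(drop=True)


def write_forest(forest: pd.DataFrame, path) -> None:
    """Tab-separated edge list (child interval -> parent interval)."""
    cols = ["chrom", "strand", "start", "end", "parent"]
    with open(path, "w") as fh:
        fh.write("#node\t" + "\t".join(cols) + "\n")
        forest.to_csv(fh, sep="\t", header=False, index=True, columns=cols)
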