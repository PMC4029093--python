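"""Density clustering of CTSS sites into a laminar hierarchy of peaks.

For a density parameter ``d > 0`` a candidate peak spanning sites ``i..j``
scores ``S = T(i, j) - d * (pos_j - pos_i)`` where ``T`` is the tag sum. The
peak set at density ``d`` is the maximal-scoring-segment decomposition of the
site sequence (Ruzzo-Tompa on +count site elements and -d*gap inter-site
elements), trimmed to begin and end on sites. Varying ``d`` over (0, inf)
yields a laminar family: every segment is annotated with the infimum
(``min_d``) and supremum (``max_d``) of the density range over which it is
maximal scoring. Low ``d`` gives broad, sparse peaks; high ``d`` gives narrow
dense ones.

The implementation is the recursive split-at-weakest-break algorithm of the
Paraclu family: a segment's break density is the smallest density at which a
prefix or suffix detaches; the segment is reported for the density interval
(min_d, break_d) and the recursion descends into the two halves. Its output
is definitionally equal to the brute-force decomposition-over-all-densities
(the test suite enforces exact equality against an independent oracle).

Cluster coordinates are *inclusive* site positions (``start`` = first site,
``end`` = last site); extent in the score is ``end - start`` while length for
per-base filters is ``end - start + 1``. Exported BED uses ``[start, end+1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ctss import CTSSTable

CLUSTER_COLUMNS = [
    "chrom", "strand", "start", "end", "n_sites", "tag_sum",
    "min_d", "max_d", "parent",
]


def cluster_sites(
    positions,
    counts,
    *,
    chrom: str = "chr1",
    strand: str = "+",
) -> pd.DataFrame:
    """Cluster sorted CTSS sites of one chromosome+strand.

    Parameters
    ----------
    positions, counts
        Strictly increasing genomic positions and their positive tag counts.

    Returns
    -------
    DataFrame with one row per cluster: inclusive ``start``/``end``,
    ``n_sites``, ``tag_sum``, the density range ``[min_d, max_d)`` over which
    the segment is maximal scoring (root clusters have ``min_d = 0``,
    singletons ``max_d = inf``), and ``parent`` — the row index of the
    immediately containing cluster (-1 for roots). Parents always precede
    their children in the row order.
    """
    pos = np.asarray(positions, dtype=np.int64)
    cnt = np.asarray(counts, dtype=np.int64)
    if pos.ndim != 1 or cnt.shape != pos.shape:
        raise ValueError("positions and counts must be 1-D and equal length")
    n = len(pos)
    if n == 0:
        return _empty_clusters()
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing (sorted, unique)")
    if np.any(cnt <= 0):
        raise ValueError("all counts must be positive")

    # prefix sums: C[k] = sum(cnt[:k]); exact in float64 for realistic depths
    C = np.concatenate([[0.0], np.cumsum(cnt, dtype=np.float64)])

    rows: list[tuple] = []
    # stack of (site index range [i, j), min density, parent row)
    stack: list[tuple[int, int, float, int]] = [(0, n, 0.0, -1)]
    while stack:
        i, j, min_d, parent = stack.pop()
        total = C[j] - C[i]
        if j - i == 1:
            break_d, k = np.inf, -1
        else:
            # prefix break at k (i < k < j): sites i..k-1 detach at density
            # (tag sum of the prefix) / (pos_k - pos_i); suffix symmetric.
            pref = (C[i + 1:j] - C[i]) / (pos[i + 1:j] - pos[i])
            suf = (C[j] - C[i + 1:j]) / (pos[j - 1] - pos[i:j - 1])
            pi_ = int(np.argmin(pref))  # leftmost minimum
            si_ = int(np.argmin(suf))
            pd_, sd_ = pref[pi_], suf[si_]
            kp, ks = i + 1 + pi_, i + 1 + si_
            if pd_ < sd_:
                break_d, k = pd_, kp
            elif sd_ < pd_:
                break_d, k = sd_, ks
            else:  # tie: split at the leftmost minimizing break
                break_d, k = pd_, min(kp, ks)
        my_parent = parent
        if break_d > min_d:
            rows.append(
                (chrom, strand, pos[i], pos[j - 1], j - i, total, min_d, break_d, parent)
            )
            my_parent = len(rows) - 1
        if np.isfinite(break_d):
            new_min = max(min_d, break_d)
            # push right first so the left half is emitted before the right
            stack.append((k, j, new_min, my_parent))
            stack.append((i, k, new_min, my_parent))

    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return _cast_clusters(df)


def _empty_clusters() -> pd.DataFrame:
    return _cast_clusters(pd.DataFrame(columns=CLUSTER_COLUMNS))


def _cast_clusters(df: pd.DataFrame) -> pd.DataFrame:
    return df.astype(
        {
            "chrom": str, "strand": str,
            "start": np.int64, "end": np.int64,
            "n_sites": np.int64, "tag_sum": np.float64,
            "min_d": np.float64, "max_d": np.float64, "parent": np.int64,
        }
    )


def cluster_table(table: CTSSTable) -> pd.DataFrame:
    """Cluster every chromosome+strand of a CTSS table independently."""
    parts = []
    offset = 0
    for (chrom, strand), grp in table.df.groupby(["chrom", "strand"], sort=True):
        part = cluster_sites(
            grp["pos"].to_numpy(), grp["count"].to_numpy(), chrom=chrom, strand=strand
        )
        if len(part):
            parent = part["parent"].to_numpy()
            part["parent"] = np.where(parent >= 0, parent + offset, -1)
            parts.append(part)
            offset += len(part)
    if not parts:
        return _empty_clusters()
    return pd.concat(parts, ignore_index=True)


def add_stability(
    clusters: pd.DataFrame,
    *,
    ceiling: float = 1000.0,
    clip_finite: bool = False,
) -> pd.DataFrame:
    """Attach ``stability = max_d / min_d``.

    Root clusters (min_d = 0) and singletons (max_d = inf) have an infinite
    raw ratio; these are replaced by ``ceiling`` so that hierarchical sums
    stay finite and rank-usable downstream. Finite ratios are reported
    exactly unless ``clip_finite`` is set.
    """
    df = clusters.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["max_d"].to_numpy() / df["min_d"].to_numpy()
    stab = np.where(np.isfinite(ratio), ratio, ceiling)
    if clip_finite:
        stab = np.minimum(stab, ceiling)
    df["stability"] = stab
    return df


def density_filter(
    clusters: pd.DataFrame,
    library_size: float,
    min_tpm_per_base: float = 0.1,
) -> pd.DataFrame:
    """Discard clusters with normalized tag density below threshold.

    ``tpm_per_base = (tag_sum * 1e6 / library_size) / (end - start + 1)``;
    clusters strictly below ``min_tpm_per_base`` are removed (a cluster at
    exactly the threshold is kept). Surviving clusters have their ``parent``
    links re-wired to the nearest surviving ancestor.
    """
    if min_tpm_per_base < 0:
        raise ValueError("min_tpm_per_base must be non-negative")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    df = clusters.copy()
    length = df["end"].to_numpy() - df["start"].to_numpy() + 1
    df["tpm_per_base"] = df["tag_sum"].to_numpy() * 1e6 / library_size / length
    keep = df["tpm_per_base"].to_numpy() >= min_tpm_per_base
    return _subset_rewire(df, keep)


def _subset_rewire(df: pd.DataFrame, keep: np.ndarray) -> pd.DataFrame:
    """Keep rows where ``keep`` is True, re-wiring parents to the nearest
    surviving ancestor. Requires parents to precede children (as produced by
    :func:`cluster_sites`)."""
    n = len(df)
    parent = df["parent"].to_numpy()
    if n and np.any(parent >= np.arange(n)):
        raise ValueError("parent links must point to earlier rows")
    # nearest surviving ancestor-or-self, in old indices
    nearest = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        nearest[i] = i if keep[i] else (nearest[parent[i]] if parent[i] >= 0 else -1)
    new_index = np.cumsum(keep) - 1  # old surviving index -> new index
    out = df.loc[keep].reset_index(drop=True)
    new_parent = np.empty(int(keep.sum()), dtype=np.int64)
    for new_i, old_i in enumerate(np.flatnonzero(keep)):
        p = parent[old_i]
        anc = nearest[p] if p >= 0 else -1
        new_parent[new_i] = new_index[anc] if anc >= 0 else -1
    out["parent"] = new_parent
    return out


def compute_hierarchical_stability(clusters: pd.DataFrame) -> pd.DataFrame:
    """Sum each cluster's stability with the stabilities of all its ancestors.

    ``hier_stability(child) = hier_stability(parent) + stability(child)`` on
    every parent edge; orphans keep their own stability.
    """
    if "stability" not in clusters.columns:
        raise ValueError("run add_stability first")
    df = clusters.copy()
    n = len(df)
    parent = df["parent"].to_numpy()
    stab = df["stability"].to_numpy()
    hier = np.full(n, np.nan)
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in progress, 2 done
    for start in range(n):
        if state[start] == 2:
            continue
        chain = []
        i = start
        while i >= 0 and state[i] == 0:
            state[i] = 1
            chain.append(i)
            i = parent[i]
        if i >= 0 and state[i] == 1:
            raise ValueError("cycle in parent links")
        base = hier[i] if i >= 0 else 0.0
        for j in reversed(chain):
            base = base + stab[j]
            hier[j] = base
            state[j] = 2
    df["hier_stability"] = hier
    return df


def legacy_filter(
    clusters: pd.DataFrame,
    *,
    min_tags: float = 30,
    min_stability: float = 2.0,
    max_len: int = 200,
    collapse: bool = True,
) -> pd.DataFrame:
    """Original-Paraclu comparison filter.

    Keeps clusters with ``tag_sum >= min_tags``, ``stability >= min_stability``
    and length (``end - start + 1``) ``<= max_len``; with ``collapse`` the
    hierarchy is flattened by retaining only clusters not contained in any
    other surviving cluster (the single-scale consensus of the original tool).
    """
    if "stability" not in clusters.columns:
        raise ValueError("run add_stability first")
    df = clusters.copy()
    length = df["end"].to_numpy() - df["start"].to_numpy() + 1
    keep = (
        (df["tag_sum"].to_numpy() >= min_tags)
        & (df["stability"].to_numpy() >= min_stability)
        & (length <= max_len)
    )
    df = df.loc[keep].reset_index(drop=True)
    df["parent"] = -1  # hierarchy links are meaningless after this filter
    if not collapse or len(df) == 0:
        return df
    df = df.drop_duplicates(["chrom", "strand", "start", "end"]).reset_index(drop=True)
    outer = np.zeros(len(df), dtype=bool)
    for _, grp in df.groupby(["chrom", "strand"], sort=False):
        order = grp.sort_values(["start", "end"], ascending=[True, False])
        max_end = -1
        for idx, end in zip(order.index, order["end"].to_numpy()):
            if end > max_end:
                outer[idx] = True
                max_end = end
    return df.loc[outer].reset_index(drop=True)


def clusters_to_bed(clusters: pd.DataFrame, score: str = "hier_stability") -> pd.DataFrame:
    """Half-open BED6 view of a cluster table (end becomes ``end + 1``)."""
    bed = pd.DataFrame(
        {
            "chrom": clusters["chrom"],
            "start": clusters["start"],
            "end": clusters["end"] + 1,
            "name": [
                f"{c}:{s}-{e + 1},{st}"
                for c, s, e, st in zip(
                    clusters["chrom"], clusters["start"], clusters["end"], clusters["strand"]
                )
            ],
            "score": clusters[score] if score in clusters.columns else 0.0,
            "strand": clusters["strand"],
        }
    )
    return bed.reset_index(drop=True)


def write_clusters(clusters: pd.DataFrame, path) -> None:
    """Tab-separated cluster dump with a '#' header (Paraclu-style, extended)."""
    cols = [c for c in (
        "chrom", "strand", "start", "end", "n_sites", "tag_sum",
        "min_d", "max_d", "stability", "hier_stability", "tpm_per_base", "parent",
    ) if c in clusters.columns]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        clusters.to_csv(fh, sep="\t", header=False, index=False, columns=cols)
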