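"""Replicate agreement: reciprocal-overlap merging and the irreproducible
discovery rate (IDR).

Peaks are called independently in each replicate, matched across a replicate
pair by >= 90% reciprocal overlap (intersection coordinates are kept), and
the paired hierarchical-stability scores are fed to a two-component Gaussian
copula mixture: with probability ``pi1`` a peak pair is *reproducible* and
its latent scores are bivariate normal with mean ``(mu, mu)``, common
variance ``sigma^2`` and correlation ``rho``; otherwise the latents are
independent standard normal. Only the ranks of the observed scores enter the
fit (the observed scores are an arbitrary monotone transform of the
latents). The local IDR of a pair is the posterior probability of the
irreproducible component; the global IDR at rank ``r`` is the mean of the
``r`` smallest local IDRs — the expected irreproducibility rate of the set
selected down to that rank.

Merged intervals here use half-open BED coordinates ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

MERGED_COLUMNS = ["chrom", "strand", "start", "end", "score_a", "score_b", "a_idx", "b_idx"]


def clusters_half_open(clusters: pd.DataFrame, score: str = "hier_stability") -> pd.DataFrame:
    """Convert an inclusive-coordinate cluster table to half-open intervals."""
    return pd.DataFrame(
        {
            "chrom": clusters["chrom"].to_numpy(),
            "strand": clusters["strand"].to_numpy(),
            "start": clusters["start"].to_numpy(),
            "end": clusters["end"].to_numpy() + 1,
            "score": clusters[score].to_numpy(),
        }
    )


def reciprocal_overlap_merge(
    clusters_a: pd.DataFrame,
    clusters_b: pd.DataFrame,
    min_frac: float = 0.9,
) -> pd.DataFrame:
    """Match peaks across two replicates by reciprocal overlap.

    Inputs are half-open interval tables with columns
    ``chrom, strand, start, end, score``. A pair matches iff
    ``overlap/len_a >= min_frac`` and ``overlap/len_b >= min_frac`` on the
    same strand. Each input peak joins at most one output; conflicts are
    resolved greedily by best reciprocal fraction (ties: larger overlap,
    then leftmost). The output carries intersection coordinates and the two
    scores.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    candidates = []
    a = clusters_a.reset_index(drop=True)
    b = clusters_b.reset_index(drop=True)
    b_groups = {key: grp for key, grp in b.groupby(["chrom", "strand"], sort=False)}
    for key, ga in a.groupby(["chrom", "strand"], sort=False):
        gb = b_groups.get(key)
        if gb is None:
            continue
        a_start = ga["start"].to_numpy()
        a_end = ga["end"].to_numpy()
        b_start = gb["start"].to_numpy()
        b_end = gb["end"].to_numpy()
        # sort B by start for a windowed sweep
        order = np.argsort(b_start, kind="mergesort")
        bs, be = b_start[order], b_end[order]
        b_max_end = np.maximum.accumulate(be)
        for ia, (s, e) in zip(ga.index, zip(a_start, a_end)):
            hi = np.searchsorted(bs, e, side="left")
            for jj in range(hi - 1, -1, -1):
                if b_max_end[jj] <= s:
                    break
                ovl = min(e, be[jj]) - max(s, bs[jj])
                if ovl <= 0:
                    continue
                ib = gb.index[order[jj]]
                fa = ovl / (e - s)
                fb = ovl / (be[jj] - bs[jj])
                if fa >= min_frac and fb >= min_frac:
                    candidates.append(
                        (min(fa, fb), ovl, max(s, bs[jj]), min(e, be[jj]), ia, ib)
                    )
    # greedy best-pair-first, deterministic
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[4], c[5]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for frac, ovl, s, e, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append(
            (
                a.at[ia, "chrom"], a.at[ia, "strand"], s, e,
                a.at[ia, "score"], b.at[ib, "score"], ia, ib,
            )
        )
    df = pd.DataFrame(rows, columns=MERGED_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "strand", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df.astype(
        {"start": np.int64, "end": np.int64, "score_a": np.float64,
         "score_b": np.float64, "a_idx": np.int64, "b_idx": np.int64}
        if len(df) else {}
    )


@dataclasses.dataclass
class IDRFit:
    """Fitted copula mixture: reproducible-component proportion ``pi1``, its
    latent mean ``mu``, standard deviation ``sigma`` and correlation ``rho``,
    plus the per-iteration pseudo-log-likelihood trace of the final EM pass."""

    pi1: float
    mu: float
    sigma: float
    rho: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int


def _log_f1(z1, z2, mu, sigma, rho):
    d1 = (z1 - mu) / sigma
    d2 = (z2 - mu) / sigma
    q = (d1 * d1 - 2 * rho * d1 * d2 + d2 * d2) / (1 - rho * rho)
    return (
        -np.log(2 * np.pi) - 2 * np.log(sigma)
        - 0.5 * np.log(1 - rho * rho) - 0.5 * q
    )


def _log_f0(z1, z2):
    return -np.log(2 * np.pi) - 0.5 * (z1 * z1 + z2 * z2)


def _mixture_cdf(z, pi1, mu, sigma):
    return pi1 * norm.cdf((z - mu) / sigma) + (1 - pi1) * norm.cdf(z)


def _pseudo_scores(u, pi1, mu, sigma):
    """Invert the mixture marginal CDF at the rank quantiles (vectorized bisection)."""
    lo = np.full_like(u, min(-10.0, mu - 10 * sigma))
    hi = np.full_like(u, max(10.0, mu + 10 * sigma))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = _mixture_cdf(mid, pi1, mu, sigma) < u
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def _em_fixed_pseudo(z1, z2, params, tol, max_iter):
    """EM on (pi1, mu, sigma, rho) with the pseudo-scores held fixed.

    The pseudo-log-likelihood is non-decreasing across these iterations
    (standard EM monotonicity)."""
    pi1, mu, sigma, rho = params
    trace: list[float] = []
    gamma = None
    for _ in range(max_iter):
        lf1 = np.log(pi1) + _log_f1(z1, z2, mu, sigma, rho)
        lf0 = np.log1p(-pi1) + _log_f0(z1, z2)
        m = np.maximum(lf1, lf0)
        ll = float(np.sum(m + np.log(np.exp(lf1 - m) + np.exp(lf0 - m))))
        gamma = 1.0 / (1.0 + np.exp(lf0 - lf1))
        if trace and ll - trace[-1] < tol:
            trace.append(max(ll, trace[-1]))
            break
        trace.append(ll)
        w = gamma.sum()
        pi1 = float(np.clip(w / len(z1), 1e-4, 1 - 1e-4))
        mu = float(max((gamma * (z1 + z2)).sum() / (2 * w), 0.0))
        var = (gamma * ((z1 - mu) ** 2 + (z2 - mu) ** 2)).sum() / (2 * w)
        sigma = float(max(np.sqrt(var), 0.1))
        rho = float(np.clip(
            (gamma * (z1 - mu) * (z2 - mu)).sum() / (w * sigma * sigma),
            -0.999, 0.999,
        ))
    return (pi1, mu, sigma, rho), trace, gamma


def idr_fit(
    score_a,
    score_b,
    *,
    init: tuple[float, float, float, float] = (0.7, 2.6, 1.3, 0.8),
    tol: float = 1e-4,
    max_iter: int = 200,
    n_outer: int = 30,
    min_rho: float = 0.2,
) -> tuple[IDRFit, np.ndarray, np.ndarray]:
    """Fit the copula mixture to paired scores and compute local/global IDR.

    Scores only need to be rank-meaningful. Ranks (average ties) are scaled
    by ``1/(n+1)``, inverted through the mixture marginal CDF to pseudo
    normal scores, and the Gaussian-mixture EM is run; the rank inversion is
    refreshed between EM passes until the parameters settle.

    Identifiability guard: the reproducible component is *defined* by
    between-replicate concordance. When the two replicates carry no rank
    concordance the likelihood is maximized on a degenerate ridge (an
    uncorrelated "reproducible" component absorbing everything), so a fit
    whose correlation ends below ``min_rho`` is declared uninformative and
    every pair is reported irreproducible (local IDR 1).

    Returns ``(fit, local_idr, global_idr)`` aligned with the input order.
    """
    z_a = np.asarray(score_a, dtype=np.float64)
    z_b = np.asarray(score_b, dtype=np.float64)
    if z_a.shape != z_b.shape or z_a.ndim != 1:
        raise ValueError("score_a and score_b must be 1-D and equal length")
    n = len(z_a)
    if n < 20:
        raise ValueError("need at least 20 pairs to fit the IDR mixture")
    if len(np.unique(z_a)) < 2 or len(np.unique(z_b)) < 2:
        raise ValueError("degenerate ranks: constant scores in a replicate")

    u1 = rankdata(z_a, method="average") / (n + 1)
    u2 = rankdata(z_b, method="average") / (n + 1)

    params = tuple(float(p) for p in init)
    trace: list[float] = []
    gamma = None
    total_iter = 0
    converged = False
    last_ll = None
    # the refresh loop is capped: running the self-consistent rank transform
    # to a fixed point slowly shrinks the fitted scale along a likelihood
    # ridge, so a bounded number of refresh passes is the convention
    for _ in range(n_outer):
        z1 = _pseudo_scores(u1, params[0], params[1], params[2])
        z2 = _pseudo_scores(u2, params[0], params[1], params[2])
        params, trace, gamma = _em_fixed_pseudo(z1, z2, params, tol, max_iter)
        total_iter += len(trace)
        # relative change of the pseudo-log-likelihood across refresh passes
        if last_ll is not None and abs(trace[-1] - last_ll) < tol * abs(last_ll):
            converged = True
            break
        last_ll = trace[-1]
    if len(trace) >= max_iter:
        warnings.warn("IDR EM hit max_iter without meeting tol; best-so-far fit")

    if params[3] < min_rho:
        warnings.warn(
            "fitted reproducible-component correlation is near zero: replicates "
            "show no rank concordance; declaring all pairs irreproducible"
        )
        gamma = np.zeros(n)

    local_idr = 1.0 - gamma
    order = np.argsort(local_idr, kind="mergesort")
    cummean = np.cumsum(local_idr[order]) / np.arange(1, n + 1)
    global_idr = np.empty(n)
    global_idr[order] = cummean

    fit = IDRFit(
        pi1=params[0], mu=params[1], sigma=params[2], rho=params[3],
        loglik_trace=trace, converged=converged, n_iter=total_iter,
    )
    return fit, local_idr, global_idr


def idr_filter(
    merged: pd.DataFrame,
    threshold: float = 0.1,
    *,
    use_local: bool = False,
) -> pd.DataFrame:
    """Keep peaks with IDR strictly below ``threshold`` (IDR >= threshold is
    discarded as irreproducible). Uses the global IDR by default."""
    col = "local_idr" if use_local else "global_idr"
    if col not in merged.columns:
        raise ValueError(f"merged table lacks {col!r}; run idr_fit first")
    keep = merged[col].to_numpy() < threshold
    return merged.loc[keep].reset_index(drop=True)


def length_filter(merged: pd.DataFrame, max_len: int = 200) -> pd.DataFrame:
    """Drop peaks longer than ``max_len`` bp (length exactly ``max_len`` is kept)."""
    length = merged["end"].to_numpy() - merged["start"].to_numpy()
    return merged.loc[length <= max_len].reset_index(drop=True)
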