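"""Negative-binomial differential expression of peaks between two conditions.

CAGE tag counts across biological replicates are overdispersed relative to
Poisson, so counts are modelled as negative binomial with
``Var = mu + phi * mu^2`` and a single common dispersion ``phi`` shared by
all peaks. Two-group comparison uses the exact conditional test: after
equalizing counts to a common effective library size, the group sums
``(Y1, Y2)`` are compared conditionally on their total ``s = Y1 + Y2`` — the
p-value is the total conditional probability of outcomes at most as likely
as the observed split. At ``phi = 0`` this reduces to the conditional
binomial (Poisson limit).

Multiple testing uses Benjamini-Hochberg; a peak is called differentially
expressed when ``|log2 fold change| > 2`` (strict) and ``adjusted p < 0.05``
(strict) under the default thresholds. A gene is called when at least one
top or bottom peak assigned to its promoter window is significant — a "top"
call without a "bottom" call flags a sub-peak shift: fine-scale TSS usage
changing while the whole promoter's output does not.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

_PHI_LOWER = 1e-8
_PHI_UPPER = 20.0


@dataclasses.dataclass
class DispersionFit:
    """Common NB dispersion (``Var = mu + phi mu^2``); ``phi = 0`` is Poisson."""

    phi: float
    method: str = "conditional-likelihood"


def _equalize(counts: np.ndarray, lib_sizes: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale counts to the geometric-mean library size (continuous pseudo-counts)."""
    lib_sizes = np.asarray(lib_sizes, dtype=np.float64)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(lib_sizes))))
    return counts * (common / lib_sizes), common


def _group_cond_loglik(y: np.ndarray, phi: float) -> float:
    """Log conditional likelihood of within-group counts given the group sum,
    summed over rows, for one group (rows x samples), equal library sizes.

    For NB counts with size ``r = 1/phi`` the conditional law given the sum is
    Dirichlet-multinomial; terms constant in ``phi`` are dropped.
    """
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    return float(
        np.sum(gammaln(y + r)) - n * y.shape[0] * gammaln(r)
        + np.sum(gammaln(n * r) - gammaln(z + n * r))
    )


def estimate_common_dispersion(
    counts: np.ndarray | pd.DataFrame,
    groups,
    lib_sizes=None,
    *,
    default_phi: float = 0.1,
) -> DispersionFit:
    """Estimate one NB dispersion shared by all peaks.

    Maximizes the conditional likelihood of within-group counts given group
    sums, on counts equalized to a common effective library size. Requires at
    least two samples in some group; otherwise returns ``default_phi`` with a
    warning. An optimum at the lower search bound is reported as 0 (Poisson).
    """
    y = np.asarray(counts, dtype=np.float64)
    groups = np.asarray(groups)
    if lib_sizes is None:
        lib_sizes = y.sum(axis=0)
    pseudo, _ = _equalize(y, np.asarray(lib_sizes, dtype=np.float64))
    blocks = [pseudo[:, groups == g] for g in np.unique(groups)]
    blocks = [b for b in blocks if b.shape[1] >= 2]
    if not blocks:
        warnings.warn("one replicate per group: using default dispersion")
        return DispersionFit(phi=default_phi, method="default")

    def neg_ll(log_phi: float) -> float:
        return -sum(_group_cond_loglik(b, float(np.exp(log_phi))) for b in blocks)

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(_PHI_LOWER), np.log(_PHI_UPPER)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(np.exp(res.x))
    if phi < 1e-6:
        phi = 0.0
    return DispersionFit(phi=phi)


def exact_test_nb(
    y1,
    y2,
    lib1=None,
    lib2=None,
    phi: float = 0.0,
    *,
    prior_count: float = 0.5,
) -> tuple[float, float, float]:
    """Exact conditional NB test of group 2 vs group 1.

    Parameters
    ----------
    y1, y2
        Per-sample counts of the two groups (scalars or arrays).
    lib1, lib2
        Per-sample library sizes (defaults: all equal).
    phi
        Common NB dispersion; 0 gives the conditional-binomial Poisson limit.

    Returns
    -------
    (pvalue, logFC, logConc): two-sided exact p, log2 fold change of group 2
    over group 1 with ``prior_count`` added per group, and the log2 mean
    normalized abundance.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    y1 = np.atleast_1d(np.asarray(y1, dtype=np.float64))
    y2 = np.atleast_1d(np.asarray(y2, dtype=np.float64))
    n1, n2 = len(y1), len(y2)
    lib1 = np.full(n1, 1.0) if lib1 is None else np.atleast_1d(np.asarray(lib1, float))
    lib2 = np.full(n2, 1.0) if lib2 is None else np.atleast_1d(np.asarray(lib2, float))
    allc = np.concatenate([y1, y2])
    alll = np.concatenate([lib1, lib2])
    pseudo, common = _equalize(allc, alll)
    p1, p2 = pseudo[:n1], pseudo[n1:]
    Y1 = int(round(p1.sum()))
    Y2 = int(round(p2.sum()))
    s = Y1 + Y2

    c = prior_count
    logfc = float(np.log2((Y2 + c) / n2) - np.log2((Y1 + c) / n1))
    logconc = float(np.log2(np.mean((pseudo + c) / common)))

    if s == 0:
        return 1.0, 0.0, logconc

    ys = np.arange(s + 1)
    if phi == 0.0:
        logp = binom.logpmf(ys, s, n2 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        # shared success probability: group means proportional to group sizes
        p = 1.0 / (1.0 + phi * s / (n1 + n2))
        logp = nbinom.logpmf(ys, r2, p) + nbinom.logpmf(s - ys, r1, p)
        logp = logp - logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[Y2]
    pval = float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum()))
    return pval, logfc, logconc


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=np.float64)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test_matrix(
    counts: np.ndarray | pd.DataFrame,
    groups,
    lib_sizes=None,
    *,
    phi: float | None = None,
    min_abs_lfc: float = 2.0,
    alpha: float = 0.05,
    prior_count: float = 0.5,
    default_phi: float = 0.1,
) -> pd.DataFrame:
    """Run the exact test on every row of a peaks-by-samples count matrix.

    ``groups`` labels columns with exactly two condition names; the first
    label in sorted order is the reference (group 1). Returns a table with
    ``logFC, logConc, pvalue, padj, significant`` per row.
    """
    y = np.asarray(counts, dtype=np.float64)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two condition labels required")
    g1 = groups == labels[0]
    g2 = groups == labels[1]
    if lib_sizes is None:
        lib_sizes = y.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=np.float64)
    if phi is None:
        phi = estimate_common_dispersion(
            y, groups, lib_sizes, default_phi=default_phi
        ).phi
    out = np.empty((y.shape[0], 3))
    for i in range(y.shape[0]):
        out[i] = exact_test_nb(
            y[i, g1], y[i, g2], lib_sizes[g1], lib_sizes[g2], phi,
            prior_count=prior_count,
        )
    res = pd.DataFrame(out, columns=["pvalue", "logFC", "logConc"])
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    res["phi"] = phi
    if isinstance(counts, pd.DataFrame):
        res.index = counts.index
    return call_de_clusters(res, min_abs_lfc=min_abs_lfc, alpha=alpha)


def call_de_clusters(
    results: pd.DataFrame,
    *,
    min_abs_lfc: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag peaks with ``|logFC| > min_abs_lfc`` and ``padj < alpha`` (both strict)."""
    df = results.copy()
    df["significant"] = (np.abs(df["logFC"].to_numpy()) > min_abs_lfc) & (
        df["padj"].to_numpy() < alpha
    )
    return df


def call_de_genes(
    cluster_calls: pd.DataFrame,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-level calls from peak-level significance.

    ``cluster_calls`` needs ``significant`` and ``peak_class`` ('top' or
    'bottom') columns indexed by peak id; ``assignments`` maps ``cluster`` id
    to ``gene`` (a peak may be assigned to several genes). A gene is called
    when any assigned peak is significant; ``trigger`` records which classes
    fired, so a top-only trigger highlights sub-peak shifts under a stable
    promoter.
    """
    merged = assignments.merge(
        cluster_calls[["significant", "peak_class"]],
        left_on="cluster",
        right_index=True,
        how="left",
    )
    rows = []
    for gene, grp in merged.groupby("gene", sort=True):
        sig = grp.loc[grp["significant"] == True]  # noqa: E712 (NaN-safe)
        classes = sorted(set(sig["peak_class"]))
        rows.append((gene, len(sig) > 0, "+".join(classes)))
    return pd.DataFrame(rows, columns=["gene", "called", "trigger"])
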