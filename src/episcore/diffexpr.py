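"""SAM-style two-class permutation differential expression.

The per-probe statistic is a variance-stabilized t-like score

    d = (mean_1 − mean_2) / (pooled SE + s0),

computed on log2-transformed signals (microarray noise is multiplicative, so
the log scale makes the per-probe standard errors comparable and lets one
global fudge factor s0 — the median pooled SE across probes — do its job of
taming near-zero-variance probes).  The fold-change filter, by contrast, is
applied to the ratio of *linear-scale* group means, matching how MAS5-style
signals are reported.

Significance comes from permutation of the group labels.  For small designs
(total label arrangements ≤ 10,000 — e.g. 70 for the 4 vs 4 experiment) the
null is enumerated exactly.  By default the null d-values are pooled across
probes ("pooled" mode, the standard SAM procedure), giving p-value
resolution 1/(P·m) so Benjamini–Hochberg adjustment retains power at
genome scale; ``null_mode="probe"`` keeps each probe's own permutation null
(p-values then multiples of 1/P, e.g. 1/70 at 4 vs 4).
"""
from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["sam_d_statistic", "sam_test", "filter_de", "overlap_sets"]

logger = logging.getLogger(__name__)

EXACT_LIMIT = 10_000


def _group_arrays(matrix_values: np.ndarray, labels: np.ndarray, first=None):
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"sam requires exactly two groups, got {list(uniq)}")
    if first is not None:
        if first not in uniq:
            raise ValueError(f"group {first!r} not among labels {uniq}")
        uniq = [first] + [g for g in uniq if g != first]
    idx1 = np.flatnonzero(labels == uniq[0])
    idx2 = np.flatnonzero(labels == uniq[1])
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs at least 2 samples")
    return idx1, idx2, uniq


def _d_stats(values: np.ndarray, idx1, idx2, s0: float) -> np.ndarray:
    """Vectorized d statistic for all probes at one label assignment."""
    g1 = values[:, idx1]
    g2 = values[:, idx2]
    n1, n2 = g1.shape[1], g2.shape[1]
    diff = g1.mean(axis=1) - g2.mean(axis=1)
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)
    pooled_se = np.sqrt(ss / (n1 + n2 - 2) * (1 / n1 + 1 / n2))
    return diff / (pooled_se + s0)


def _pooled_se(values: np.ndarray, idx1, idx2) -> np.ndarray:
    g1 = values[:, idx1]
    g2 = values[:, idx2]
    n1, n2 = g1.shape[1], g2.shape[1]
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)
    return np.sqrt(ss / (n1 + n2 - 2) * (1 / n1 + 1 / n2))


def sam_d_statistic(expr_row, groups, s0: float) -> float:
    """d = (mean_1 − mean_2) / (pooled SE + s0) for a single probe.

    Group 1 is the lexicographically first label, so swapping the two
    labels negates d.  The row is used on the scale it is given
    (:func:`sam_test` handles the log transform).
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    x = np.asarray(expr_row, float)[None, :]
    labels = np.asarray(groups)
    idx1, idx2, _ = _group_arrays(x, labels)
    return float(_d_stats(x, idx1, idx2, s0)[0])


def _label_permutations(n1: int, n2: int, n_perm, rng):
    """Index sets for group 1 under label permutation.

    Returns (list of index arrays, exact_flag).  Exact enumeration is used
    when requested (or when n_perm == "exact") and C(n1+n2, n1) <= 10,000.
    """
    n = n1 + n2
    total = comb(n, n1)
    if n_perm == "exact":
        if total > EXACT_LIMIT:
            raise ValueError(
                f"exact enumeration infeasible: {total} arrangements > {EXACT_LIMIT}"
            )
        return [np.array(c) for c in itertools.combinations(range(n), n1)], True
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 or 'exact'")
    if total <= min(n_perm, EXACT_LIMIT):
        return [np.array(c) for c in itertools.combinations(range(n), n1)], True
    return [rng.permutation(n)[:n1] for _ in range(n_perm)], False


def sam_test(
    matrix: pd.DataFrame,
    groups,
    n_perm="exact",
    seed: int = 0,
    null_mode: str = "pooled",
    log_transform: bool = True,
    treated=None,
) -> pd.DataFrame:
    """Two-class SAM test for every probe of an expression matrix.

    Parameters
    ----------
    matrix : probes × samples linear-scale signals (positive).
    groups : per-sample labels (aligned to matrix columns).
    treated : which label is the ratio's numerator; default ``"treated"``
        when present, else the lexicographically first label.
    n_perm : number of label permutations, or ``"exact"`` to enumerate all
        arrangements (requires ≤ 10,000; automatic fallback to enumeration
        also happens whenever that is cheaper than sampling).
    null_mode : ``"pooled"`` (SAM standard; null d pooled across probes) or
        ``"probe"`` (each probe against its own permutation null).
    log_transform : compute d on log2 signals (default); the reported ratio
        is always linear-scale mean_treated / mean_vehicle.

    Returns a DataFrame indexed by probe with columns ``mean_treated``,
    ``mean_vehicle``, ``ratio``, ``d_stat``, ``p_raw``, ``p_adj``.
    """
    if isinstance(groups, (pd.Series, dict)):
        aligned = pd.Series(groups).reindex(matrix.columns)
        if aligned.isna().any():
            raise ValueError("group labels missing for some matrix samples")
        labels = aligned.to_numpy()
    else:
        labels = np.asarray(groups)
        if labels.size != matrix.shape[1]:
            raise ValueError("group labels length does not match sample count")
    values_lin = matrix.to_numpy(float)
    if (values_lin < 0).any():
        raise ValueError("expression signals must be non-negative")
    if treated is None and "treated" in labels:
        treated = "treated"
    idx1, idx2, uniq = _group_arrays(values_lin, labels, first=treated)
    if log_transform:
        # pure log2 keeps d exactly invariant to a global scale factor;
        # zeros (possible in MAS5-style data) are clipped, not shifted
        values = np.log2(np.maximum(values_lin, 1e-12))
    else:
        values = values_lin
    if np.allclose(values.var(axis=1), 0):
        raise ValueError("matrix is constant; no variation to test")

    se = _pooled_se(values, idx1, idx2)
    s0 = float(np.median(se))
    d_obs = _d_stats(values, idx1, idx2, s0)

    rng = np.random.default_rng(seed)
    n1 = len(idx1)
    perms, exact = _label_permutations(n1, len(idx2), n_perm, rng)
    logger.info(
        "sam_test: %d probes, %s null over %d label arrangements (%s)",
        matrix.shape[0], null_mode, len(perms), "exact" if exact else "sampled",
    )

    all_idx = np.arange(values.shape[1])
    abs_obs = np.abs(d_obs)
    if null_mode == "probe":
        counts = np.zeros(values.shape[0])
        for p1 in perms:
            p2 = np.setdiff1d(all_idx, p1, assume_unique=True)
            d_perm = _d_stats(values, p1, p2, s0)
            counts += np.abs(d_perm) >= abs_obs
        p_raw = counts / len(perms)
    elif null_mode == "pooled":
        null_pool = np.empty((len(perms), values.shape[0]))
        for i, p1 in enumerate(perms):
            p2 = np.setdiff1d(all_idx, p1, assume_unique=True)
            null_pool[i] = _d_stats(values, p1, p2, s0)
        flat = np.sort(np.abs(null_pool).ravel())
        # p = fraction of pooled null |d*| >= |d_obs|  (observed labeling is
        # among the enumerated arrangements, so p > 0 automatically)
        p_raw = 1.0 - np.searchsorted(flat, abs_obs, side="left") / flat.size
        p_raw = np.maximum(p_raw, 1.0 / flat.size)
    else:
        raise ValueError("null_mode must be 'pooled' or 'probe'")

    mean_t = values_lin[:, idx1].mean(axis=1)
    mean_v = values_lin[:, idx2].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_v > 0, mean_t / mean_v, np.inf)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_treated": mean_t,
            "mean_vehicle": mean_v,
            "ratio": ratio,
            "d_stat": d_obs,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=matrix.index.rename("probe_id"),
    )


def filter_de(
    results: pd.DataFrame, fdr_max: float = 0.05, ratio_min: float = 2.0
):
    """Split DE results into up/down probe sets by FDR and fold filters.

    up:   p_adj ≤ fdr_max and ratio ≥ ratio_min
    down: p_adj ≤ fdr_max and ratio ≤ 1/ratio_min

    Returns ``(up, down, annotated)`` where ``annotated`` adds a
    ``direction`` column (up/down/none) to the results.
    """
    sig = results["p_adj"] <= fdr_max
    up = set(results.index[sig & (results["ratio"] >= ratio_min)])
    down = set(results.index[sig & (results["ratio"] <= 1.0 / ratio_min)])
    annotated = results.copy()
    annotated["direction"] = "none"
    annotated.loc[sorted(up), "direction"] = "up"
    annotated.loc[sorted(down), "direction"] = "down"
    return up, down, annotated


def overlap_sets(set_a, set_b, probe_to_gene: dict):
    """Gene-level Venn partition of two probe sets.

    Probes collapse to genes by the "any probe passes" rule; a gene with
    probes in both input sets counts as shared.  Unmapped probes are logged
    and excluded, never silently dropped.

    Returns ``(a_only, shared, b_only)`` as sets of gene symbols.
    """
    def genes_of(probes, label):
        out = set()
        unmapped = []
        for p in probes:
            g = probe_to_gene.get(p)
            if g is None:
                unmapped.append(p)
            else:
                out.add(g)
        if unmapped:
            logger.warning(
                "overlap_sets: %d unmapped probes excluded from %s: %s",
                len(unmapped), label, unmapped,
            )
        return out

    genes_a = genes_of(set_a, "set A")
    genes_b = genes_of(set_b, "set B")
    shared = genes_a & genes_b
    return genes_a - shared, shared, genes_b - shared
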