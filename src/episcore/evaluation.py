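"""Downstream assessments of a fitted risk score.

* response prediction: 2×2 contingency of risk group × responder status,
  with sensitivity = P(high score | non-responder), specificity =
  P(low score | responder) and a two-sided Fisher exact test;
* correlation of the score with an ordinal patient grouping (e.g. the
  proliferation-index classes low/medium/high) via Spearman rank
  correlation;
* score comparisons of one focal molecular subgroup against every other
  subgroup via two-sided Mann–Whitney tests with Benjamini–Hochberg
  adjustment, reporting per-group medians and 10–90 percentiles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyResult",
    "GroupComparison",
    "response_contingency",
    "score_group_correlation",
    "compare_score_groups",
]

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    """2×2 risk-group × responder-status table with operating characteristics."""

    table: pd.DataFrame  # rows: non-responder/responder; cols: high/low
    sensitivity: float
    specificity: float
    fisher_p: float

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy()


def response_contingency(high_risk, non_responder) -> ContingencyResult:
    """Cross-tabulate risk group against response.

    ``high_risk`` and ``non_responder`` are aligned boolean vectors.
    Sensitivity is the fraction of non-responders flagged high-risk;
    specificity the fraction of responders flagged low-risk.  The p-value is
    the two-sided Fisher exact test on the 2×2 table.
    """
    high = np.asarray(high_risk, bool)
    nr = np.asarray(non_responder, bool)
    if high.size != nr.size:
        raise ValueError("risk and response vectors differ in length")
    if nr.all() or not nr.any():
        raise ValueError("response margin is empty (all one class)")
    if high.all() or not high.any():
        raise ValueError("risk margin is empty (all one class)")
    a = int((nr & high).sum())      # non-responder, high
    b = int((nr & ~high).sum())     # non-responder, low
    c = int((~nr & high).sum())     # responder, high
    d = int((~nr & ~high).sum())    # responder, low
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=pd.Index(["non-responder", "responder"], name="response"),
        columns=pd.Index(["high", "low"], name="risk"),
    )
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(
        table=table,
        sensitivity=a / (a + b),
        specificity=d / (c + d),
        fisher_p=float(p),
    )


def score_group_correlation(scores, ordinal_group) -> tuple[float, float]:
    """Spearman rank correlation between scores and an ordinal group index.

    Requires at least 3 distinct ordinal levels represented (a 2-level
    grouping is a comparison, not a trend).
    """
    s = np.asarray(scores, float)
    g = np.asarray(ordinal_group, float)
    if s.size != g.size:
        raise ValueError("scores and groups differ in length")
    if np.unique(g).size < 3:
        raise ValueError("need at least 3 distinct ordinal levels")
    if np.unique(s).size < 2:
        raise ValueError("scores are constant")
    r, p = stats.spearmanr(s, g)
    return float(r), float(p)


@dataclass
class GroupComparison:
    """Mann–Whitney comparison of the focal group against one other group."""

    focal: str
    other: str
    u_stat: float
    p_raw: float
    p_adj: float


def compare_score_groups(
    scores,
    labels,
    focal: str,
    min_group_size: int = 3,
    score_cutoff: float | None = None,
) -> dict:
    """Compare the focal subgroup's scores against every other subgroup.

    Two-sided Mann–Whitney tests (focal vs each other group), BH-adjusted
    across comparisons.  Groups smaller than ``min_group_size`` are excluded
    with a warning.  Returns a dict with ``comparisons`` (list of
    :class:`GroupComparison`), ``group_stats`` (per-group n, median, 10th and
    90th percentile of the score) and, when ``score_cutoff`` is given,
    ``focal_median_above_cutoff``.
    """
    s = pd.Series(np.asarray(scores, float))
    lab = pd.Series(np.asarray(labels, object))
    if len(s) != len(lab):
        raise ValueError("scores and labels differ in length")
    sizes = lab.value_counts()
    keep = sizes.index[sizes >= min_group_size]
    dropped = sorted(set(sizes.index) - set(keep))
    if dropped:
        logger.warning(
            "compare_score_groups: groups below n=%d excluded: %s",
            min_group_size, dropped,
        )
    if focal not in set(keep):
        raise ValueError(f"focal group {focal!r} absent or below minimum size")
    others = [g for g in keep if g != focal]
    if not others:
        raise ValueError("need at least one non-focal group")

    focal_scores = s[lab == focal].to_numpy()
    rows = []
    for g in others:
        other_scores = s[lab == g].to_numpy()
        u, p = stats.mannwhitneyu(focal_scores, other_scores, alternative="two-sided")
        rows.append((g, float(u), float(p)))
    p_adj = multipletests([r[2] for r in rows], method="fdr_bh")[1]
    comparisons = [
        GroupComparison(focal=focal, other=g, u_stat=u, p_raw=p, p_adj=float(pa))
        for (g, u, p), pa in zip(rows, p_adj)
    ]
    group_stats = {
        g: {
            "n": int((lab == g).sum()),
            "median": float(np.median(s[lab == g])),
            "p10": float(np.percentile(s[lab == g], 10)),
            "p90": float(np.percentile(s[lab == g], 90)),
        }
        for g in keep
    }
    out = {"comparisons": comparisons, "group_stats": group_stats}
    if score_cutoff is not None:
        out["focal_median_above_cutoff"] = bool(
            np.median(focal_scores) > score_cutoff
        )
        out["groups_with_median_above_cutoff"] = sorted(
            g for g, st in group_stats.items() if st["median"] > score_cutoff
        )
    return out
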