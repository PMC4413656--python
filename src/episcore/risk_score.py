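"""±β gene-expression risk scores and survival stratification.

A risk score model is a frozen list of prognostic probes — each with an
expression cutpoint (from the maxstat search on the training cohort) and a
Cox β coefficient (from the univariate fit on the training dichotomization)
— plus a score-level cutpoint θ.  A patient's score is

    score = Σ_g w_g · β_g,   w_g = +1 if signal_g > cutpoint_g else −1,

so it ranges over [−Σ|β|, +Σ|β|]; a probe with HR < 1 ("good prognostic")
contributes negatively when over-expressed.  Patients with score ≤ θ form
the low-risk group, score > θ the high-risk group.  Validation on an
independent cohort re-estimates nothing: per-probe cutpoints, βs and θ are
all carried over frozen from training.
"""
from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from . import maxstat as _maxstat
from .simulate import SurvivalCohort
from .survival import km_estimate, logrank_test, KMEstimate, NOT_REACHED

__all__ = [
    "PrognosticProbe",
    "RiskScoreModel",
    "RiskStratification",
    "compute_score",
    "compute_scores",
    "fit_score_cutpoint",
    "stratify",
    "validate",
    "load_published_model",
]

logger = logging.getLogger(__name__)

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PrognosticProbe:
    """One probe set of a risk score: training-frozen cutpoint and Cox β."""

    probe_id: str
    cutpoint: float | None
    beta: float
    p_adj: float | None = None
    gene: str | None = None

    @property
    def hr(self) -> float:
        return math.exp(self.beta)

    @property
    def prognosis(self) -> str:
        return "good" if self.hr < 1 else "bad"


@dataclass
class RiskScoreModel:
    """Frozen risk score: prognostic probes plus score-level cutpoint θ."""

    name: str
    probes: list[PrognosticProbe]
    theta: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.probes:
            raise ValueError("a risk score model needs at least one probe")
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe IDs in model")

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def score_bounds(self) -> tuple[float, float]:
        s = sum(abs(p.beta) for p in self.probes)
        return (-s, s)

    def with_cutpoints(self, cutpoints: dict) -> "RiskScoreModel":
        """Return a copy with user-supplied per-probe cutpoints (needed to
        score against published models whose cutpoints were not printed)."""
        missing = [p.probe_id for p in self.probes if p.probe_id not in cutpoints]
        if missing:
            raise ValueError(f"no cutpoint supplied for probes: {missing}")
        probes = [
            PrognosticProbe(
                probe_id=p.probe_id,
                cutpoint=float(cutpoints[p.probe_id]),
                beta=p.beta,
                p_adj=p.p_adj,
                gene=p.gene,
            )
            for p in self.probes
        ]
        return RiskScoreModel(
            name=self.name, probes=probes, theta=self.theta,
            provenance=dict(self.provenance),
        )

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "name": self.name,
            "theta": self.theta,
            "provenance": self.provenance,
            "probes": [asdict(p) for p in self.probes],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RiskScoreModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {payload.get('schema_version')!r}"
            )
        probes = [PrognosticProbe(**p) for p in payload["probes"]]
        return cls(
            name=payload["name"],
            probes=probes,
            theta=payload["theta"],
            provenance=payload.get("provenance", {}),
        )


def compute_score(model: RiskScoreModel, expr_vector: pd.Series) -> float:
    """Score one patient: Σ β_g weighted ±1 by signal above/below cutpoint.

    ``expr_vector`` must contain every model probe (missing probes raise,
    never silently imputed); values exactly at the cutpoint count as below.
    """
    missing = [p.probe_id for p in model.probes if p.probe_id not in expr_vector.index]
    if missing:
        raise ValueError(f"expression vector missing model probes: {missing}")
    no_cut = [p.probe_id for p in model.probes if p.cutpoint is None]
    if no_cut:
        raise ValueError(
            f"model probes without cutpoints (supply via with_cutpoints): {no_cut}"
        )
    score = 0.0
    for p in model.probes:
        w = 1.0 if float(expr_vector[p.probe_id]) > p.cutpoint else -1.0
        score += w * p.beta
    return score


def compute_scores(model: RiskScoreModel, matrix: pd.DataFrame) -> pd.Series:
    """Score every sample (column) of an expression matrix."""
    missing = [pid for pid in model.probe_ids if pid not in matrix.index]
    if missing:
        raise ValueError(f"expression matrix missing model probes: {missing}")
    no_cut = [p.probe_id for p in model.probes if p.cutpoint is None]
    if no_cut:
        raise ValueError(
            f"model probes without cutpoints (supply via with_cutpoints): {no_cut}"
        )
    sub = matrix.loc[model.probe_ids]
    cut = np.array([p.cutpoint for p in model.probes])
    beta = np.array([p.beta for p in model.probes])
    w = np.where(sub.to_numpy(float) > cut[:, None], 1.0, -1.0)
    return pd.Series(w.T @ beta, index=matrix.columns, name=f"{model.name}_score")


def fit_score_cutpoint(
    model: RiskScoreModel,
    matrix: pd.DataFrame,
    cohort: SurvivalCohort,
    q_lo: float = 0.10,
    q_hi: float = 0.90,
) -> float:
    """Select θ by running the maxstat engine on the score vector itself.

    Stores θ in the model and returns it.  A degenerate score distribution
    (all patients identical) is an error.
    """
    scores = compute_scores(model, matrix[cohort.sample_ids])
    if np.unique(scores.to_numpy()).size < 2:
        raise ValueError("degenerate score distribution: all patients score equal")
    res = _maxstat.maxstat_cutpoint(
        scores.to_numpy(float), cohort, q_lo=q_lo, q_hi=q_hi
    )
    model.theta = float(res.cutpoint)
    model.provenance.setdefault("theta_fit", {}).update(
        {"max_stat": res.max_stat, "q_range": [q_lo, q_hi],
         "n_training": len(cohort)}
    )
    return model.theta


@dataclass
class RiskStratification:
    """Low/high risk split of a cohort by a frozen score model."""

    model_name: str
    theta: float
    scores: pd.Series
    low_risk: pd.Index
    high_risk: pd.Index
    km_low: KMEstimate | None
    km_high: KMEstimate | None
    median_low: float | None  # inf = not reached
    median_high: float | None
    logrank_chi2: float | None
    logrank_p: float | None
    warnings: list = field(default_factory=list)

    @property
    def frac_low(self) -> float:
        return len(self.low_risk) / len(self.scores)

    @property
    def frac_high(self) -> float:
        return len(self.high_risk) / len(self.scores)

    def summary_dict(self) -> dict:
        def _med(m):
            if m is None:
                return None
            return "not reached" if not np.isfinite(m) else m

        return {
            "model": self.model_name,
            "theta": self.theta,
            "n": int(len(self.scores)),
            "n_low": int(len(self.low_risk)),
            "n_high": int(len(self.high_risk)),
            "frac_low": self.frac_low,
            "frac_high": self.frac_high,
            "median_os_low": _med(self.median_low),
            "median_os_high": _med(self.median_high),
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "warnings": list(self.warnings),
        }


def stratify(
    model: RiskScoreModel, matrix: pd.DataFrame, cohort: SurvivalCohort
) -> RiskStratification:
    """Split a cohort at θ (low: score ≤ θ; high: score > θ) and compare
    survival: per-group Kaplan–Meier curves, median OS and log-rank test.

    An empty risk group is reported with a warning and no test performed.
    """
    if model.theta is None:
        raise ValueError("model has no score cutpoint theta; fit or set it first")
    scores = compute_scores(model, matrix[cohort.sample_ids])
    low = scores.index[scores <= model.theta]
    high = scores.index[scores > model.theta]
    notes = []
    km_low = km_high = None
    med_low = med_high = None
    chi2 = p = None
    if len(low) == 0 or len(high) == 0:
        empty = "low" if len(low) == 0 else "high"
        notes.append(f"{empty}-risk group is empty; log-rank test not performed")
        warnings.warn(notes[-1], stacklevel=2)
    if len(low) > 0:
        sub = cohort.subset(low)
        km_low = km_estimate(sub.time, sub.event)
        med_low = km_low.median
    if len(high) > 0:
        sub = cohort.subset(high)
        km_high = km_estimate(sub.time, sub.event)
        med_high = km_high.median
    if len(low) > 0 and len(high) > 0:
        sub_lo, sub_hi = cohort.subset(low), cohort.subset(high)
        chi2, p = logrank_test(
            (sub_lo.time, sub_lo.event), (sub_hi.time, sub_hi.event)
        )
    return RiskStratification(
        model_name=model.name,
        theta=float(model.theta),
        scores=scores,
        low_risk=low,
        high_risk=high,
        km_low=km_low,
        km_high=km_high,
        median_low=med_low,
        median_high=med_high,
        logrank_chi2=chi2,
        logrank_p=p,
        warnings=notes,
    )


def validate(
    model: RiskScoreModel, matrix: pd.DataFrame, cohort: SurvivalCohort
) -> RiskStratification:
    """Apply a fully frozen model to an independent cohort.

    Identical computation to :func:`stratify`; nothing is re-estimated.
    Probes missing from the validation platform raise with the probe list.
    """
    if model.theta is None:
        raise ValueError("cannot validate an unfitted model (theta is None)")
    missing = [pid for pid in model.probe_ids if pid not in matrix.index]
    if missing:
        raise ValueError(f"validation matrix missing model probes: {missing}")
    return stratify(model, matrix, cohort)


def load_published_model(which: str) -> RiskScoreModel:
    """Load a published score model shipped with the package.

    ``which`` is ``"decitabine"`` (the 25-probe Mu-DM score) or
    ``"quisinostat"`` (the 61-probe Mu-HA score).  These carry the published
    probe sets, gene symbols, BH-adjusted p-values and hazard ratios
    (β = ln HR); the per-probe expression cutpoints and θ were not published,
    so scoring against them requires :meth:`RiskScoreModel.with_cutpoints`.
    """
    if which not in {"decitabine", "quisinostat"}:
        raise ValueError("which must be 'decitabine' or 'quisinostat'")
    name = f"published_{which}_model.json"
    text = resources.files("episcore.data").joinpath(name).read_text()
    return RiskScoreModel.from_json(text)
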