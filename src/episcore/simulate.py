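"""Synthetic microarray experiments and survival cohorts.

Every input the risk-score pipeline consumes can be generated here with the
statistical structure the downstream analysis assumes:

* a two-arm (treated vs vehicle) expression experiment with a planted
  fraction of up/down-regulated probe sets on a positive, right-skewed
  (lognormal) MAS5-like signal scale;
* a survival cohort in which selected probes carry a planted dichotomous
  proportional-hazards effect (good: HR < 1, bad: HR > 1) with right
  censoring;
* treatment-response labels with prescribed sensitivity/specificity against
  a high/low risk split, and categorical molecular-subgroup labels.

Truth tables are first-class outputs: recovery tests read the planted ground
truth directly instead of re-deriving it from the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TreatmentSimSpec",
    "CohortSimSpec",
    "SurvivalCohort",
    "gen_treatment_experiment",
    "gen_survival_cohort",
    "gen_response_labels",
    "gen_subgroup_labels",
]

# MAS5 "scale 100" style hyperparameters for probe baselines: median signal
# around 100 with roughly an order-of-magnitude spread either way.
_BASELINE_MEANLOG = np.log(100.0)
_BASELINE_SDLOG = 1.0
# Seed of the fixed "platform" profile shared by all survival cohorts over
# the same probe universe (see gen_survival_cohort).
_PLATFORM_SEED = 1907


def _validation_error(name: str, message: str) -> ValueError:
    return ValueError(f"invalid field '{name}': {message}")


@dataclass(frozen=True)
class TreatmentSimSpec:
    """Design of a two-group treated/vehicle expression experiment.

    Parameters
    ----------
    n_probes : total number of probe sets on the array.
    n_up, n_down : planted truly up-/down-regulated probe counts.
    fold_effect : multiplicative treated/vehicle effect (>1) on planted
        probes; down-regulated probes get ``1/fold_effect``.
    n_per_group : samples per arm (the emulated design is 4 vs 4).
    noise_cv : lognormal coefficient of variation of the signal noise.
    seed : RNG seed; identical seeds give bit-identical output.
    """

    n_probes: int
    n_up: int = 0
    n_down: int = 0
    fold_effect: float = 1.0
    n_per_group: int = 4
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 1:
            raise _validation_error("n_probes", "must be >= 1")
        if self.n_up < 0 or self.n_down < 0:
            raise _validation_error("n_up/n_down", "must be >= 0")
        if self.n_up + self.n_down > self.n_probes:
            raise _validation_error("n_up", "n_up + n_down must be <= n_probes")
        if not self.fold_effect >= 1.0:
            raise _validation_error("fold_effect", "must be >= 1 (1 = null)")
        if self.n_per_group < 2:
            raise _validation_error("n_per_group", "must be >= 2")
        if not self.noise_cv > 0:
            raise _validation_error("noise_cv", "must be > 0")


@dataclass(frozen=True)
class CohortSimSpec:
    """Design of a survival cohort with planted prognostic probes.

    ``planted_effects`` maps probe index (int, < n_probes) or probe ID to a
    ``(cutoff_quantile, beta)`` pair: patients whose signal for that probe
    exceeds the cutoff (the per-probe empirical quantile) have their hazard
    multiplied by ``exp(beta)``.
    """

    n_patients: int
    n_probes: int
    planted_effects: Mapping = field(default_factory=dict)
    baseline_hazard: float = 0.015  # events per month; median OS ~ 46 months
    censor_rate: float = 0.3
    followup_horizon: float = 120.0  # months
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise _validation_error("n_patients", "must be >= 2")
        if self.n_probes < 1:
            raise _validation_error("n_probes", "must be >= 1")
        if not 0 < self.censor_rate < 1:
            raise _validation_error("censor_rate", "must be in (0, 1)")
        if not self.baseline_hazard > 0:
            raise _validation_error("baseline_hazard", "must be > 0")
        if not self.followup_horizon > 0:
            raise _validation_error("followup_horizon", "must be > 0")
        for key, val in dict(self.planted_effects).items():
            q, beta = val
            if not 0 < q < 1:
                raise _validation_error(
                    "planted_effects", f"cutoff quantile for {key!r} not in (0,1)"
                )


class SurvivalCohort:
    """Per-sample survival endpoint with optional covariates and labels.

    Thin wrapper around a DataFrame indexed by sample ID with columns
    ``time_months`` (positive), ``event`` (1 = death, 0 = censored) and any
    number of covariate / ``response`` / ``subgroup`` columns.
    """

    def __init__(self, df: pd.DataFrame):
        if "time_months" not in df.columns or "event" not in df.columns:
            raise ValueError("cohort table needs 'time_months' and 'event' columns")
        if (df["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if df.index.duplicated().any():
            raise ValueError("duplicate sample IDs in cohort")
        self.df = df

    @property
    def sample_ids(self):
        return self.df.index

    @property
    def time(self) -> np.ndarray:
        return self.df["time_months"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(int)

    def covariate(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def __len__(self):
        return len(self.df)

    def subset(self, sample_ids) -> "SurvivalCohort":
        return SurvivalCohort(self.df.loc[sample_ids])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path, sep="\t")
        if "sample_id" not in df.columns:
            raise ValueError(f"cohort table {path!r} lacks a 'sample_id' column")
        return cls(df.set_index("sample_id"))


def _lognormal_signals(rng, means, cv):
    """Positive signals with E[X] = means and coefficient of variation cv."""
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(means.shape)
    return means * np.exp(sigma * z - sigma**2 / 2.0)


def gen_treatment_experiment(spec: TreatmentSimSpec):
    """Simulate a treated-vs-vehicle expression experiment.

    Returns ``(matrix, groups, truth)``: a probes × samples DataFrame of
    positive linear-scale signals, a Series of group labels
    (``treated``/``vehicle``) indexed by sample, and a per-probe truth table
    with columns ``planted``, ``direction`` and ``fold``.
    """
    rng = np.random.default_rng(spec.seed)
    probes = [f"probe_{i:05d}" for i in range(spec.n_probes)]
    samples = [f"T{i+1}" for i in range(spec.n_per_group)] + [
        f"V{i+1}" for i in range(spec.n_per_group)
    ]
    groups = pd.Series(
        ["treated"] * spec.n_per_group + ["vehicle"] * spec.n_per_group,
        index=samples,
        name="group",
    )

    baselines = np.exp(
        _BASELINE_MEANLOG + _BASELINE_SDLOG * rng.standard_normal(spec.n_probes)
    )
    direction = np.array(["none"] * spec.n_probes, dtype=object)
    planted_idx = rng.choice(
        spec.n_probes, size=spec.n_up + spec.n_down, replace=False
    )
    up_idx = planted_idx[: spec.n_up]
    down_idx = planted_idx[spec.n_up :]
    fold = np.ones(spec.n_probes)
    if spec.fold_effect > 1.0:
        fold[up_idx] = spec.fold_effect
        fold[down_idx] = 1.0 / spec.fold_effect
        direction[up_idx] = "up"
        direction[down_idx] = "down"

    mean_treated = baselines * fold
    means = np.column_stack(
        [np.tile(mean_treated[:, None], spec.n_per_group),
         np.tile(baselines[:, None], spec.n_per_group)]
    )
    matrix = pd.DataFrame(
        _lognormal_signals(rng, means, spec.noise_cv), index=probes, columns=samples
    )
    truth = pd.DataFrame(
        {
            "probe_id": probes,
            "planted": direction != "none",
            "direction": direction,
            "fold": fold,
        }
    ).set_index("probe_id")
    return matrix, groups, truth


def _solve_uniform_censor_bound(lam: np.ndarray, rate: float, horizon: float):
    """Upper bound b of U(0, b) censoring s.t. the expected censored fraction
    (including the administrative cap at `horizon`) matches `rate`."""

    def frac_censored(b):
        # P(T > C) for T ~ Exp(lam), C = min(U(0,b), horizon)
        c = np.minimum(b, horizon)
        with np.errstate(over="ignore"):
            p = (1.0 - np.exp(-lam * c)) / (lam * b)  # censored before c
        p = p + np.exp(-lam * np.minimum(b, horizon)) * np.clip(
            1 - horizon / b, 0, 1
        )  # administrative tail if b > horizon
        return float(np.mean(p))

    lo, hi = 1e-6, 1e7
    f_lo, f_hi = frac_censored(lo), frac_censored(hi)
    # frac_censored is decreasing in b: tiny b censors everyone immediately.
    if rate >= f_lo:
        return lo
    if rate <= f_hi:
        return hi
    return brentq(lambda b: frac_censored(b) - rate, lo, hi, xtol=1e-6, rtol=1e-8)


def gen_survival_cohort(spec: CohortSimSpec):
    """Simulate an expression matrix plus survival cohort with planted effects.

    Event times are exponential under proportional hazards: patient *i* has
    hazard ``baseline_hazard * exp(sum of beta_g * 1{x_ig > cutoff_g})`` over
    the planted probes *g*.  Censoring is uniform with an administrative cap
    at the follow-up horizon, calibrated so the expected censored fraction
    matches ``censor_rate``.

    Returns ``(matrix, cohort, truth)`` with the truth table listing every
    planted probe's cutoff value (on the signal scale) and true beta.
    """
    rng = np.random.default_rng(spec.seed)
    probes = [f"probe_{i:05d}" for i in range(spec.n_probes)]
    samples = [f"P{i+1:04d}" for i in range(spec.n_patients)]

    # Probe baselines are a property of the array platform, not of the
    # cohort draw: two cohorts over the same probe universe share them, so
    # training-frozen absolute expression cutpoints remain meaningful on an
    # independent validation cohort (as they are for MAS5-normalized arrays).
    platform_rng = np.random.default_rng(_PLATFORM_SEED)
    baselines = np.exp(
        _BASELINE_MEANLOG
        + _BASELINE_SDLOG * platform_rng.standard_normal(spec.n_probes)
    )
    means = np.tile(baselines[:, None], spec.n_patients)
    matrix = pd.DataFrame(
        _lognormal_signals(rng, means, 0.5), index=probes, columns=samples
    )

    probe_pos = {p: i for i, p in enumerate(probes)}
    log_mult = np.zeros(spec.n_patients)
    truth_rows = []
    for key, (q, beta) in dict(spec.planted_effects).items():
        if isinstance(key, (int, np.integer)):
            if not 0 <= key < spec.n_probes:
                raise ValueError(f"planted probe index {key} outside universe")
            pid = probes[key]
        else:
            if key not in probe_pos:
                raise ValueError(f"planted probe {key!r} not in probe universe")
            pid = key
        x = matrix.loc[pid].to_numpy()
        cutoff = float(np.quantile(x, q))
        above = x > cutoff
        log_mult += beta * above
        truth_rows.append(
            {"probe_id": pid, "cutoff_quantile": q, "cutoff_value": cutoff,
             "beta": beta, "n_above": int(above.sum())}
        )
    truth = pd.DataFrame(
        truth_rows, columns=["probe_id", "cutoff_quantile", "cutoff_value", "beta", "n_above"]
    )

    lam = spec.baseline_hazard * np.exp(log_mult)
    t_event = rng.exponential(1.0 / lam)
    b = _solve_uniform_censor_bound(lam, spec.censor_rate, spec.followup_horizon)
    c = np.minimum(rng.uniform(0.0, b, spec.n_patients), spec.followup_horizon)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-6)  # guard: all times strictly positive

    cohort = SurvivalCohort(
        pd.DataFrame({"time_months": time, "event": event}, index=pd.Index(samples, name="sample_id"))
    )
    return matrix, cohort, truth


def gen_response_labels(
    cohort: SurvivalCohort,
    high_risk: Sequence[bool],
    sensitivity: float,
    specificity: float,
    seed: int = 0,
) -> pd.Series:
    """Draw responder/non-responder labels against a given risk split.

    Labels are drawn so that, in expectation, the realized 2×2 table has
    ``P(high | non-responder) = sensitivity`` and
    ``P(low | responder) = specificity``.  Together with the fixed high-risk
    fraction *h* these targets pin down the non-response prevalence
    ``pi = (h - (1-specificity)) / (sensitivity - (1-specificity))``; *h*
    must lie strictly between ``1-specificity`` and ``sensitivity``.

    Returns a Series with values ``responder`` / ``non-responder``.
    """
    if not (0 < sensitivity < 1 or sensitivity == 1):
        raise ValueError("sensitivity must be in (0, 1]")
    if not (0 < specificity < 1 or specificity == 1):
        raise ValueError("specificity must be in (0, 1]")
    high = np.asarray(high_risk, bool)
    if len(high) != len(cohort):
        raise ValueError("risk split length does not match cohort size")
    n = len(high)
    h = high.mean()
    if high.sum() == 0 or high.sum() == n:
        raise ValueError("risk split has an empty group")
    fpr = 1.0 - specificity
    denom = sensitivity - fpr
    if denom <= 0:
        raise ValueError("sensitivity must exceed 1 - specificity")
    pi = (h - fpr) / denom
    if not 0 < pi < 1:
        raise ValueError(
            f"high-risk fraction {h:.3f} incompatible with targets: implied "
            f"non-response prevalence {pi:.3f} outside (0, 1)"
        )
    p_nr_high = np.clip(sensitivity * pi / h, 0, 1)
    p_nr_low = np.clip((1 - sensitivity) * pi / (1 - h), 0, 1)
    rng = np.random.default_rng(seed)
    p = np.where(high, p_nr_high, p_nr_low)
    labels = np.where(rng.random(n) < p, "non-responder", "responder")
    return pd.Series(labels, index=cohort.sample_ids, name="response")


def gen_subgroup_labels(
    n: int,
    groups: Sequence[str] = ("PR", "LB", "MS", "HY", "CD1", "CD2", "MF", "MY"),
    probs: Sequence[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Random categorical molecular-subgroup labels (plumbing for demos)."""
    rng = np.random.default_rng(seed)
    return rng.choice(list(groups), size=n, p=probs)
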