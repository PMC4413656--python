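"""Model/Results facade over the screen → score → stratify pipeline.

``PrognosticScoreModel`` holds the training data (an expression matrix and a
survival cohort) and the analysis settings; ``fit()`` runs the per-probe
maxstat screen, assembles the ±β risk score from the probes that survive the
FDR filter, selects the score cutpoint θ with the same maxstat engine, and
returns a ``PrognosticScoreResults`` carrying the frozen
:class:`~episcore.risk_score.RiskScoreModel`, the per-probe estimates with
their uncertainties, and stratification/validation/plotting methods.

Example
-------
>>> model = PrognosticScoreModel(matrix, cohort, name="Mu-DM")
>>> res = model.fit(seed=1)
>>> print(res.summary())
>>> strat = res.validate(val_matrix, val_cohort)
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxstat import screen_probes
from .risk_score import (
    RiskScoreModel,
    RiskStratification,
    compute_scores,
    fit_score_cutpoint,
    stratify,
    validate as _validate,
)
from .simulate import SurvivalCohort

__all__ = ["PrognosticScoreModel", "PrognosticScoreResults"]


class PrognosticScoreModel:
    """Prognostic ±β risk score model, built from training data.

    Parameters
    ----------
    matrix : probes × samples expression matrix (training cohort).
    cohort : :class:`~episcore.simulate.SurvivalCohort` aligned to the
        matrix columns.
    name : score name carried into outputs (e.g. ``"Mu-DM"``).
    candidate_probes : optional probe subset to screen (e.g. the human
        orthologs of treatment-deregulated murine genes); default all rows.
    fdr_max : BH-adjusted p threshold for keeping a probe.
    q_range : quantile window for the cutpoint searches.
    p_method : ``"permutation"`` (B permutations per probe) or
        ``"approximation"``.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        cohort: SurvivalCohort,
        name: str = "score",
        candidate_probes=None,
        fdr_max: float = 0.05,
        q_range: tuple[float, float] = (0.10, 0.90),
        p_method: str = "permutation",
        B: int = 999,
    ):
        if set(matrix.columns) != set(cohort.sample_ids):
            raise ValueError("matrix samples and cohort samples are misaligned")
        if candidate_probes is not None:
            missing = [p for p in candidate_probes if p not in matrix.index]
            if missing:
                raise ValueError(f"candidate probes absent from matrix: {missing}")
            matrix = matrix.loc[list(candidate_probes)]
        self.matrix = matrix[cohort.sample_ids]
        self.cohort = cohort
        self.name = name
        self.fdr_max = fdr_max
        self.q_range = q_range
        self.p_method = p_method
        self.B = B

    @classmethod
    def from_files(cls, matrix_path, cohort_path, **kwargs):
        from .io import read_expression

        return cls(
            read_expression(matrix_path),
            SurvivalCohort.from_tsv(cohort_path),
            **kwargs,
        )

    def fit(self, seed: int = 0) -> "PrognosticScoreResults":
        """Screen probes, build the score and select θ on the training data."""
        kept, table = screen_probes(
            self.matrix,
            self.cohort,
            fdr_max=self.fdr_max,
            q_lo=self.q_range[0],
            q_hi=self.q_range[1],
            p_method=self.p_method,
            B=self.B,
            seed=seed,
        )
        if not kept:
            raise ValueError(
                f"no probe passed the screen at FDR <= {self.fdr_max}; "
                "no score can be built"
            )
        score = RiskScoreModel(
            name=self.name,
            probes=kept,
            provenance={
                "n_training": len(self.cohort),
                "n_probes_screened": int(len(table)),
                "fdr_max": self.fdr_max,
                "q_range": list(self.q_range),
                "p_method": self.p_method,
                "B": self.B,
                "seed": seed,
            },
        )
        fit_score_cutpoint(
            score, self.matrix, self.cohort,
            q_lo=self.q_range[0], q_hi=self.q_range[1],
        )
        training_strat = stratify(score, self.matrix, self.cohort)
        return PrognosticScoreResults(
            model=self, score_model=score, screen_table=table,
            training_stratification=training_strat,
        )


@dataclass
class PrognosticScoreResults:
    """Fitted risk score: frozen parameters, diagnostics and downstream ops."""

    model: PrognosticScoreModel
    score_model: RiskScoreModel
    screen_table: pd.DataFrame
    training_stratification: RiskStratification
    extras: dict = field(default_factory=dict)

    @property
    def theta(self) -> float:
        return self.score_model.theta

    @property
    def probes(self) -> pd.DataFrame:
        """Per-probe estimates of the fitted score (cutpoint, β, HR, p_adj)."""
        rows = [
            {
                "probe_id": p.probe_id,
                "cutpoint": p.cutpoint,
                "beta": p.beta,
                "hr": p.hr,
                "p_adj": p.p_adj,
                "prognosis": p.prognosis,
            }
            for p in self.score_model.probes
        ]
        return pd.DataFrame(rows).set_index("probe_id")

    def scores(self, matrix: pd.DataFrame | None = None) -> pd.Series:
        return compute_scores(
            self.score_model, self.model.matrix if matrix is None else matrix
        )

    def stratify(self, matrix=None, cohort=None) -> RiskStratification:
        if matrix is None and cohort is None:
            return self.training_stratification
        return stratify(self.score_model, matrix, cohort)

    def validate(self, matrix: pd.DataFrame, cohort: SurvivalCohort) -> RiskStratification:
        """Frozen-parameter stratification of an independent cohort."""
        return _validate(self.score_model, matrix, cohort)

    def summary(self) -> str:
        """Human-readable fit summary (screen funnel, probes, θ, training split)."""
        sm = self.score_model
        st = self.training_stratification
        lo, hi = sm.score_bounds
        lines = [
            f"{sm.name} prognostic risk score",
            "=" * 46,
            f"probes screened      {len(self.screen_table):>8d}",
            f"probes kept (FDR<={self.model.fdr_max:g})"
            f"{len(sm.probes):>8d}"
            f"   good: {sum(p.prognosis == 'good' for p in sm.probes)}"
            f"   bad: {sum(p.prognosis == 'bad' for p in sm.probes)}",
            f"score range          [{lo:8.3f}, {hi:8.3f}]",
            f"theta (score cutoff) {sm.theta:>12.3f}",
            f"training split       low {len(st.low_risk)} ({st.frac_low:.1%})"
            f" / high {len(st.high_risk)} ({st.frac_high:.1%})",
        ]

        def _med(m):
            return "not reached" if m is None or not np.isfinite(m) else f"{m:.1f} mo"

        lines.append(
            f"median OS            low {_med(st.median_low)} / high {_med(st.median_high)}"
        )
        if st.logrank_p is not None:
            lines.append(
                f"log-rank             chi2 = {st.logrank_chi2:.2f}, p = {st.logrank_p:.3g}"
            )
        lines.append("")
        lines.append(self.probes.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot_km(self, stratification: RiskStratification | None = None, ax=None):
        """Kaplan–Meier curves of the low/high risk groups."""
        import matplotlib.pyplot as plt

        st = stratification or self.training_stratification
        if ax is None:
            _, ax = plt.subplots()
        for km, label, color in (
            (st.km_low, f"low risk (n={len(st.low_risk)})", "tab:blue"),
            (st.km_high, f"high risk (n={len(st.high_risk)})", "tab:red"),
        ):
            if km is None:
                continue
            t = np.concatenate([[0.0], km.table["time"].to_numpy()])
            s = np.concatenate([[1.0], km.table["survival"].to_numpy()])
            ax.step(t, s, where="post", label=label, color=color)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.05)
        title = f"{st.model_name}: θ = {st.theta:.2f}"
        if st.logrank_p is not None:
            title += f", log-rank p = {st.logrank_p:.2g}"
        ax.set_title(title)
        ax.legend()
        return ax
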