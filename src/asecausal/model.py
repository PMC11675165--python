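"""Model/results interface over the ASE causal pipeline.

``AseStudy`` wraps a cohort table (real or synthetic) together with a
working causal graph; ``fit`` runs the pre-registered analysis — the five
conditional-independence tests, the two effect targets under their three
estimators, and the single-edge graph revision — and returns an
``AseStudyResults`` carrying every estimate, its uncertainty, the test
decisions, and a printable summary.

    >>> from asecausal import AseStudy, default_pbihb_like_config, generate_cohort
    >>> study = AseStudy(generate_cohort(default_pbihb_like_config()))
    >>> res = study.fit(seed=1)
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cohort import validate_cohort
from .graph import Dag, J0
from .pipeline import full_report, report_to_json

__all__ = ["AseStudy", "AseStudyResults"]


class AseStudy:
    """The ASE causal analysis as a fittable model over a cohort table.

    Parameters
    ----------
    data
        Cohort table with columns A, G, M, F, S, D (see
        :mod:`asecausal.cohort`).
    dag
        Working causal graph; defaults to the original ASE graph J0.
    """

    def __init__(self, data: pd.DataFrame, dag: Dag = J0):
        self.data = validate_cohort(data)
        self.dag = dag

    @classmethod
    def from_csv(cls, path, column_map=None, dag: Dag = J0) -> "AseStudy":
        from .cohort import load_cohort_csv

        return cls(load_cohort_csv(path, column_map), dag=dag)

    def fit(
        self,
        seed: int = 0,
        methods: Sequence[str] = ("MIcg", "GCM", "KCI"),
        folds: int = 5,
        dml_learner: str = "boosted",
        decision_rule: str = "majority",
    ) -> "AseStudyResults":
        """Run Hypotheses 1-3 and the reconciliation step."""
        bundle = full_report(
            self.data, seed=seed, methods=methods, folds=folds,
            dml_learner=dml_learner, dag=self.dag,
            decision_rule=decision_rule,
        )
        return AseStudyResults(
            model=self,
            bundle=bundle,
            seed=seed,
        )


@dataclass(frozen=True)
class AseStudyResults:
    """Fitted results of an :class:`AseStudy`."""

    model: AseStudy
    bundle: Mapping[str, object]
    seed: int
    _frames: dict = field(default_factory=dict, repr=False)

    def _frame(self, key: str) -> pd.DataFrame:
        if key not in self._frames:
            self._frames[key] = pd.DataFrame(self.bundle[key]["items"])
        return self._frames[key]

    @property
    def h1(self) -> pd.DataFrame:
        """Conditional-independence test table (statement x method)."""
        return self._frame("H1")

    @property
    def h2(self) -> pd.DataFrame:
        """Metacognition -> fatigue effect estimates."""
        return self._frame("H2")

    @property
    def h3(self) -> pd.DataFrame:
        """Fatigue x self-efficacy interaction effect estimates."""
        return self._frame("H3")

    @property
    def reconciliation(self) -> Mapping[str, object]:
        return self.bundle["reconciliation"]

    @property
    def top_revision(self) -> tuple[str, str] | None:
        """Best single-edge addition (None = keep the graph unchanged)."""
        edge = self.reconciliation["top_revision"]
        return tuple(edge) if edge is not None else None

    def to_json(self, path=None) -> str:
        return report_to_json(dict(self.bundle), path)

    def summary(self) -> str:
        """Human-readable account of all three hypotheses and the revision."""
        lines: list[str] = []
        n = len(self.model.data)
        lines.append("ASE causal analysis")
        lines.append(f"  cohort: N = {n}; seed = {self.seed}")
        lines.append("")
        lines.append("Hypothesis 1: conditional independencies implied by the graph")
        h1 = self.h1
        for (x, y, z), grp in h1.groupby(["x", "y", "z"], sort=False):
            verdicts = ", ".join(
                f"{r.method} p={r.p_value:.4g}{'*' if r.rejected else ''}"
                for r in grp.itertuples()
            )
            lines.append(f"  {x} _||_ {y} | {z}:  {verdicts}")
        lines.append("  (* rejected at the Bonferroni-corrected level 0.01)")
        lines.append("")
        for key, label in (
            ("H2", "Hypothesis 2: metacognition -> fatigue effect (theta3)"),
            ("H3", "Hypothesis 3: fatigue x self-efficacy interaction (theta10)"),
        ):
            lines.append(label)
            for r in self._frame(key).itertuples():
                star = "*" if r.rejected else ""
                lines.append(
                    f"  {r.method:>10} | Z={{{r.adjustment_set}}}: "
                    f"{r.theta_hat:+.4f}{star} "
                    f"[{r.ci_low:+.4f}, {r.ci_high:+.4f}] "
                    f"t={r.t_value:+.3f} p1={r.p_one_sided:.4g}"
                )
            lines.append("  (* one-sided p < 0.017, negative direction)")
            lines.append("")
        top = self.top_revision
        if top is None:
            lines.append("Graph revision: no single-edge addition improves on "
                         "the working graph.")
        else:
            lines.append(f"Graph revision: best single-edge addition is "
                         f"{top[0]} -> {top[1]}.")
        return "\n".join(lines)
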