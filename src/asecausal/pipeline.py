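"""End-to-end hypothesis pipeline: the three pre-registered hypotheses of
the ASE causal analysis, plus the single-edge graph revision step.

Hypothesis 1 — the observational distribution satisfies the five
conditional-independence statements implied by the ASE graph J0:
M _||_ S | A,G;  M _||_ D | F,A,G;  M _||_ D | F,A,G,S;
F _||_ S | A,G;  F _||_ S | A,G,M (Bonferroni family of five at family
level 0.05, so each test runs at 0.01).

Hypothesis 2 — a negative average causal effect of metacognition of
allostatic control on fatigue (th3), estimated by covariate-adjustment
regression, generalized propensity score and DML, for the primary
adjustment set {A, G} and the sensitivity set {A, G, S}, one-sided at
alpha = 0.017.

Hypothesis 3 — a negative average causal effect of the fatigue x
self-efficacy interaction on depression (th10), same three estimators,
adjustment sets {A, G} and {A, G, M}, one-sided at alpha = 0.017.

The reconciliation step scores every single-edge addition to J0 against the
Hypothesis-1 decisions; on data shaped like the empirical study the
top-ranked revision is the edge M -> S (graph J1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ci import (
    CiTestResult,
    bonferroni_decide,
    gcm_test,
    kci_test,
    micg_test,
    results_to_frame,
)
from .cohort import validate_cohort
from .estimate import (
    EffectEstimate,
    ace_dml,
    ace_propensity,
    ace_regression,
    estimates_to_frame,
    interaction_ace,
)
from .graph import CiStatement, Dag, J0, reconcile_single_edge

__all__ = [
    "H1_STATEMENTS",
    "HypothesisReport",
    "run_hypothesis_1",
    "run_hypothesis_2",
    "run_hypothesis_3",
    "full_report",
    "majority_decisions",
]

# The five statements of Hypothesis 1, in report order.
H1_STATEMENTS: tuple[CiStatement, ...] = (
    CiStatement("M", "S", {"A", "G"}),
    CiStatement("M", "D", {"F", "A", "G"}),
    CiStatement("M", "D", {"F", "A", "G", "S"}),
    CiStatement("F", "S", {"A", "G"}),
    CiStatement("F", "S", {"A", "G", "M"}),
)

H1_FAMILY_ALPHA = 0.05
H1_FAMILY_SIZE = 5
EFFECT_ALPHA = 0.017  # Bonferroni across the three estimators

H2_ADJUSTMENT_SETS = (frozenset({"A", "G"}), frozenset({"A", "G", "S"}))
H3_ADJUSTMENT_SETS = (frozenset({"A", "G"}), frozenset({"A", "G", "M"}))


@dataclass(frozen=True)
class HypothesisReport:
    """Results of one pre-registered hypothesis, with provenance."""

    hypothesis: str  # "H1" | "H2" | "H3"
    items: tuple  # CiTestResult or EffectEstimate entries
    family_alpha: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if self.hypothesis == "H1":
            return results_to_frame(self.items)
        return estimates_to_frame(self.items)

    @property
    def decisions(self) -> dict[str, bool]:
        """Map from item label to its rejection decision."""
        out: dict[str, bool] = {}
        for item in self.items:
            if isinstance(item, CiTestResult):
                key = f"{item.method}: {item.statement}"
            else:
                zs = ",".join(sorted(item.adjustment_set))
                key = f"{item.method}: {item.target} | {zs}"
            out[key] = bool(item.rejected)
        return out

    def to_dict(self) -> dict:
        records = self.to_frame().to_dict(orient="records")
        for rec in records:  # absent df entries become NaN in the frame
            for k, v in rec.items():
                if isinstance(v, float) and not np.isfinite(v):
                    rec[k] = None
        return {
            "hypothesis": self.hypothesis,
            "family_alpha": self.family_alpha,
            "items": records,
            "provenance": dict(self.provenance),
        }


def _provenance(table: pd.DataFrame, **extra: object) -> dict[str, object]:
    import hashlib

    digest = hashlib.sha256(
        table.to_csv(index=False).encode()).hexdigest()[:16]
    return {
        "n": int(len(table)),
        "columns": list(table.columns),
        "input_sha256": digest,
        "version": __version__,
        **extra,
    }


def run_hypothesis_1(
    table: pd.DataFrame,
    methods: Sequence[str] = ("MIcg", "GCM", "KCI"),
    seed: int = 0,
    gcm_regressor: str = "boosted",
) -> HypothesisReport:
    """Test the five J0-implied conditional independencies.

    Each requested method tests every statement; decisions use the
    Bonferroni family of five at family level 0.05 (per-test 0.01).
    """
    validate_cohort(table)
    results: list[CiTestResult] = []
    for stmt in H1_STATEMENTS:
        for method in methods:
            if method == "MIcg":
                results.append(micg_test(table, stmt))
            elif method == "GCM":
                results.append(
                    gcm_test(table, stmt, regressor=gcm_regressor, seed=seed))
            elif method == "KCI":
                results.append(kci_test(table, stmt, seed=seed))
            else:
                raise ValueError(f"unknown CI test method {method!r}")
    results = bonferroni_decide(results, H1_FAMILY_SIZE, H1_FAMILY_ALPHA)
    return HypothesisReport(
        "H1", tuple(results), H1_FAMILY_ALPHA / H1_FAMILY_SIZE,
        _provenance(table, methods=list(methods), seed=seed),
    )


def run_hypothesis_2(
    table: pd.DataFrame,
    seed: int = 0,
    folds: int = 5,
    dml_learner: str = "boosted",
    dag: Dag = J0,
) -> HypothesisReport:
    """Estimate the metacognition -> fatigue effect three ways.

    Primary adjustment set {A, G}; sensitivity set {A, G, S}.  One-sided
    tests (negative direction) at alpha = 0.017.
    """
    validate_cohort(table)
    items: list[EffectEstimate] = []
    for z in H2_ADJUSTMENT_SETS:
        items.append(ace_regression(
            table, "M", "F", z, dag=dag, target="theta3", alpha=EFFECT_ALPHA))
        items.append(ace_propensity(
            table, "M", "F", z, dag=dag, target="theta3", alpha=EFFECT_ALPHA))
        items.append(ace_dml(
            table, "M", "F", z, folds=folds, seed=seed, learner=dml_learner,
            dag=dag, target="theta3", alpha=EFFECT_ALPHA))
    return HypothesisReport(
        "H2", tuple(items), EFFECT_ALPHA,
        _provenance(table, seed=seed, folds=folds, learner=dml_learner),
    )


def run_hypothesis_3(
    table: pd.DataFrame,
    seed: int = 0,
    folds: int = 5,
    dml_learner: str = "boosted",
) -> HypothesisReport:
    """Estimate the fatigue x self-efficacy interaction effect three ways."""
    validate_cohort(table)
    items: list[EffectEstimate] = []
    for z in H3_ADJUSTMENT_SETS:
        for method in ("regression", "propensity", "dml"):
            items.append(interaction_ace(
                table, "D", z, method=method, folds=folds, seed=seed,
                learner=dml_learner, alpha=EFFECT_ALPHA))
    return HypothesisReport(
        "H3", tuple(items), EFFECT_ALPHA,
        _provenance(table, seed=seed, folds=folds, learner=dml_learner),
    )


def majority_decisions(
    h1: HypothesisReport,
) -> list[tuple[CiStatement, bool]]:
    """Per-statement rejection decisions by majority vote across methods.

    Ties (possible only with an even method count) resolve to "not
    rejected" — the conservative reading that keeps the graph unrevised
    absent a majority against it.
    """
    votes: dict[CiStatement, list[bool]] = {}
    for item in h1.items:
        votes.setdefault(item.statement, []).append(bool(item.rejected))
    out = []
    for stmt in H1_STATEMENTS:
        if stmt in votes:
            v = votes[stmt]
            out.append((stmt, sum(v) * 2 > len(v)))
    return out


def full_report(
    table: pd.DataFrame,
    seed: int = 0,
    methods: Sequence[str] = ("MIcg", "GCM", "KCI"),
    folds: int = 5,
    dml_learner: str = "boosted",
    dag: Dag = J0,
    decision_rule: str = "majority",
) -> dict:
    """Run Hypotheses 1-3 and the single-edge reconciliation; bundle all.

    ``decision_rule`` picks how Hypothesis-1 method votes collapse to one
    decision per statement before reconciliation: "majority" (default)
    or the name of a single method ("MIcg", "GCM", "KCI").

    Returns a JSON-serializable dict with the three reports, the ranked
    revision candidates, and the named top revision.
    """
    h1 = run_hypothesis_1(table, methods=methods, seed=seed)
    h2 = run_hypothesis_2(table, seed=seed, folds=folds,
                          dml_learner=dml_learner, dag=dag)
    h3 = run_hypothesis_3(table, seed=seed, folds=folds,
                          dml_learner=dml_learner)

    if decision_rule == "majority":
        decisions = majority_decisions(h1)
    elif decision_rule in methods:
        decisions = [
            (item.statement, bool(item.rejected))
            for item in h1.items
            if item.method == decision_rule
        ]
    else:
        raise ValueError(f"unknown decision rule {decision_rule!r}")

    ranked = reconcile_single_edge(dag, decisions)
    candidates = [
        {
            "edge": list(edge) if edge is not None else None,
            "mismatches": int(miss),
        }
        for _, edge, miss in ranked
    ]
    top_edge = ranked[0][1]
    return {
        "H1": h1.to_dict(),
        "H2": h2.to_dict(),
        "H3": h3.to_dict(),
        "reconciliation": {
            "decision_rule": decision_rule,
            "decisions": [
                {"statement": str(s), "x": s.x, "y": s.y,
                 "z": sorted(s.z), "rejected": bool(r)}
                for s, r in decisions
            ],
            "candidates": candidates,
            "top_revision": list(top_edge) if top_edge is not None else None,
        },
    }


def report_to_json(report: dict, path=None) -> str:
    """Serialize a full-report bundle; round-trips via ``json.loads``."""
    text = json.dumps(report, indent=2, sort_keys=True, allow_nan=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
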