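"""Linear-Gaussian structural causal model of the allostatic self-efficacy
(ASE) account of fatigue and depression.

The model is a set of structural equations over age (A), gender (G),
metacognition of allostatic control (M), fatigue (F), general self-efficacy
(S) and depression (D)::

    A = N_a                                (Gaussian)
    G = N_g                                (Bernoulli)
    M = th1*A + th2*G + N_m
    F = th3*M + th4*A + th5*G + N_f
    S = th6*A + th7*G + N_s
    D = th8*F + th9*S + th10*F*S + th11*A + th12*G + N_d

with jointly independent noise.  The interaction term ``th10*F*S`` is an
extra term in D's equation, not a graph edge: the DAG keeps only F -> D and
S -> D, so d-separation semantics stay standard.

The model induces both the observational distribution and, by replacing the
equation of any intervened node with a constant, every do-distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .graph import Dag, GraphError, J0

__all__ = [
    "GaussianNoise",
    "BernoulliNoise",
    "LinearGaussianScm",
    "Intervention",
    "ase_scm",
    "sample_observational",
    "sample_interventional",
    "analytic_ace",
    "analytic_interaction_ace",
]

# Noise is drawn once per call in this fixed node order so that seeds are
# portable across graphs that share the ASE variable set.
NOISE_ORDER = ("A", "G", "M", "S", "F", "D")


class ScmError(ValueError):
    """Invalid SCM specification or unsupported structure."""


@dataclass(frozen=True)
class GaussianNoise:
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if not self.sd > 0:
            raise ScmError("Gaussian sd must be strictly positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)

    @property
    def expectation(self) -> float:
        return self.mean


@dataclass(frozen=True)
class BernoulliNoise:
    p: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ScmError("Bernoulli p must lie in the open interval (0, 1)")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)

    @property
    def expectation(self) -> float:
        return self.p


@dataclass(frozen=True)
class Intervention:
    """An atomic intervention do(node := value) on one or more nodes."""

    assignments: Mapping[str, float] = field(default_factory=dict)

    def __init__(self, assignments: Mapping[str, float] | None = None, **kw: float):
        merged = dict(assignments or {})
        for k, v in kw.items():
            if k in merged:
                raise ScmError(f"node {k!r} assigned twice")
            merged[k] = v
        object.__setattr__(self, "assignments", dict(merged))


@dataclass(frozen=True)
class LinearGaussianScm:
    """A DAG with linear edge coefficients and per-node noise laws.

    Parameters
    ----------
    dag
        Causal skeleton.  Every coefficient key must be one of its edges.
    coefficients
        Map ``(parent, child) -> float``.  Edges without a coefficient get 0.
    noise
        Map ``node -> GaussianNoise | BernoulliNoise`` covering every node.
    intercepts
        Map ``node -> float``; missing nodes default to 0.
    interaction
        Optional coefficient of the F*S product term in D's equation
        (``th10``).  Allowed only when both F -> D and S -> D are edges.
    """

    dag: Dag
    coefficients: Mapping[tuple[str, str], float]
    noise: Mapping[str, GaussianNoise | BernoulliNoise]
    intercepts: Mapping[str, float] = field(default_factory=dict)
    interaction: float | None = None
    interaction_parents: tuple[str, str] = ("F", "S")
    interaction_child: str = "D"

    def __post_init__(self):
        for edge in self.coefficients:
            if tuple(edge) not in self.dag.edges:
                raise ScmError(f"coefficient on non-edge {edge}")
        missing = set(self.dag.nodes) - set(self.noise)
        if missing:
            raise ScmError(f"missing noise law for node(s) {sorted(missing)}")
        for node in self.intercepts:
            self.dag._check_nodes([node])
        if self.interaction is not None:
            a, b = self.interaction_parents
            c = self.interaction_child
            if (a, c) not in self.dag.edges or (b, c) not in self.dag.edges:
                raise ScmError(
                    "interaction term requires both factor->outcome edges "
                    f"({a}->{c} and {b}->{c})"
                )

    def coefficient(self, parent: str, child: str) -> float:
        return float(self.coefficients.get((parent, child), 0.0))

    def intercept(self, node: str) -> float:
        return float(self.intercepts.get(node, 0.0))

    # -- simulation ------------------------------------------------------

    def _draw_noise(self, n: int, seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        draws: dict[str, np.ndarray] = {}
        for node in NOISE_ORDER:
            if node in self.noise:
                draws[node] = self.noise[node].draw(rng, n)
        for node in self.dag.nodes:  # nodes outside the canonical order
            if node not in draws:
                draws[node] = self.noise[node].draw(rng, n)
        return draws

    def sample(
        self,
        n: int,
        seed: int,
        intervention: Intervention | None = None,
    ) -> pd.DataFrame:
        """Draw ``n`` i.i.d. rows, optionally under an intervention.

        Intervened nodes have their structural equation replaced by the
        assigned constant; all other equations are untouched (autonomy).
        """
        if n <= 0:
            raise ScmError("n must be a positive integer")
        assigned = dict(intervention.assignments) if intervention else {}
        self.dag._check_nodes(assigned)
        noise = self._draw_noise(n, seed)
        values: dict[str, np.ndarray] = {}
        for node in self.dag.topological_order():
            if node in assigned:
                values[node] = np.full(n, float(assigned[node]))
                continue
            v = self.intercept(node) + noise[node]
            for p in self.dag.parents(node):
                v = v + self.coefficient(p, node) * values[p]
            if self.interaction is not None and node == self.interaction_child:
                a, b = self.interaction_parents
                v = v + self.interaction * values[a] * values[b]
            values[node] = v
        return pd.DataFrame({v: values[v] for v in self.dag.nodes})


def sample_observational(scm: LinearGaussianScm, n: int, seed: int) -> pd.DataFrame:
    """Sample the observational distribution induced by ``scm``."""
    return scm.sample(n, seed)


def sample_interventional(
    scm: LinearGaussianScm, intervention: Intervention, n: int, seed: int
) -> pd.DataFrame:
    """Sample the do-distribution induced by ``scm`` under ``intervention``."""
    return scm.sample(n, seed, intervention=intervention)


def analytic_ace(scm: LinearGaussianScm, treatment: str, outcome: str) -> float:
    """Average causal effect d/dt E[outcome | do(treatment := t)].

    In a linear SCM this is the sum over directed paths of the product of
    edge coefficients; for the ASE model's (M, F) pair it is exactly th3.
    Raises when the interaction term sits on a treatment->outcome path —
    the ACE is then not a single derivative; use
    :func:`analytic_interaction_ace` for the mixed derivative th10.
    """
    scm.dag._check_nodes([treatment, outcome])
    if treatment == outcome:
        raise ScmError("treatment and outcome must differ")
    if scm.interaction is not None and scm.interaction != 0.0:
        c = scm.interaction_child
        child_feeds_outcome = outcome == c or c in scm.dag.ancestors([outcome])
        treatment_feeds_child = c in scm.dag.descendants(treatment)
        if child_feeds_outcome and treatment_feeds_child:
            raise ScmError(
                "interaction term lies on a treatment->outcome path; "
                "the effect is not a single path-coefficient sum"
            )
    total = 0.0
    for path in _directed_paths(scm.dag, treatment, outcome):
        prod = 1.0
        for p, c in zip(path, path[1:]):
            prod *= scm.coefficient(p, c)
        total += prod
    return total


def _directed_paths(dag: Dag, src: str, dst: str):
    stack = [(src, [src])]
    while stack:
        v, path = stack.pop()
        if v == dst:
            yield path
            continue
        for c in sorted(dag.children(v)):
            if c not in path:
                stack.append((c, path + [c]))


def analytic_interaction_ace(scm: LinearGaussianScm) -> float:
    """Mixed derivative d^2/(df ds) E[D | do(F:=f, S:=s)] — equals th10."""
    if scm.interaction is None:
        raise ScmError("SCM has no interaction term")
    return float(scm.interaction)


def ase_scm(
    theta: Mapping[str, float] | None = None,
    noise_sd: Mapping[str, float] | None = None,
    intercepts: Mapping[str, float] | None = None,
    age_mean: float = 30.0,
    age_sd: float = 8.0,
    gender_p: float = 0.5,
    dag: Dag = J0,
    extra_edges: Iterable[tuple[str, str]] = (),
) -> LinearGaussianScm:
    """Build the ASE SCM with named coefficients ``th1`` .. ``th12``.

    ``theta`` overrides individual coefficients by name; ``th13`` is the
    M -> S coefficient of the revised graph J1 (requires that edge).
    Age defaults to Normal(30, 8) — a young-adult cohort — and gender to
    Bernoulli(0.5); all other noise means are 0.
    """
    edge_names = {
        "th1": ("A", "M"), "th2": ("G", "M"),
        "th3": ("M", "F"), "th4": ("A", "F"), "th5": ("G", "F"),
        "th6": ("A", "S"), "th7": ("G", "S"),
        "th8": ("F", "D"), "th9": ("S", "D"),
        "th11": ("A", "D"), "th12": ("G", "D"),
        "th13": ("M", "S"),
    }
    theta = dict(theta or {})
    for p, c in extra_edges:
        dag = dag.add_edge(p, c)
    coeffs: dict[tuple[str, str], float] = {}
    for name, edge in edge_names.items():
        if name in theta:
            val = float(theta.pop(name))
            if edge not in dag.edges:
                if val == 0.0:
                    continue
                raise ScmError(f"{name} set but edge {edge} absent from dag")
            coeffs[edge] = val
    th10 = float(theta.pop("th10", 0.0))
    if theta:
        raise ScmError(f"unknown coefficient name(s): {sorted(theta)}")
    sds = dict(noise_sd or {})
    noise: dict[str, GaussianNoise | BernoulliNoise] = {
        "A": GaussianNoise(age_mean, age_sd),
        "G": BernoulliNoise(gender_p),
    }
    for node in ("M", "F", "S", "D"):
        noise[node] = GaussianNoise(0.0, float(sds.get(node, 1.0)))
    return LinearGaussianScm(
        dag=dag,
        coefficients=coeffs,
        noise=noise,
        intercepts=dict(intercepts or {}),
        interaction=th10 if th10 != 0.0 else None,
    )
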