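"""Discrete Bayesian-network data model.

A Bayesian network here is a directed acyclic graph (DAG) over categorical
variables together with one conditional probability table (CPT) per node, so
that the joint distribution factorizes as

    P(X1, ..., Xn) = prod_i P(Xi | Pa(Xi)),

where ``Pa(Xi)`` is the parent set of node ``Xi`` in the DAG.  The module
provides the containers (:class:`VariableSpec`, :class:`DiscreteDataset`,
:class:`DagStructure`, :class:`Cpt`, :class:`BayesianNetwork`) and the four
core operations: exact joint evaluation, Bayesian (Dirichlet-smoothed)
parameter estimation from possibly-incomplete data, ancestral sampling, and
the closed-form posterior of a star-shaped (naive-Bayes) network.

Missing cells are first-class: parameter estimation uses available-case
counting per CPT family, and missing evidence is marginalized by omission in
the star posterior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariableSpec",
    "DiscreteDataset",
    "DagStructure",
    "Cpt",
    "BayesianNetwork",
    "joint_probability",
    "fit_parameters",
    "sample",
    "naive_posterior",
    "enumerate_posterior",
]

#: Sentinel for a missing cell. ``None`` and NaN in input frames normalize to it.
MISSING = None

# Products over more than this many factors are accumulated in log space.
_LOG_SPACE_THRESHOLD = 20


class IncompleteAssignmentError(KeyError):
    """An assignment does not cover every network node."""


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: a name, its ordered grade labels, and a role.

    ``role`` is one of ``"indicator"``, ``"outcome"``, ``"covariate"``.
    """

    name: str
    states: tuple[str, ...]
    role: str = "indicator"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be nonempty")
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 2:
            raise ValueError(f"{self.name}: at least 2 states required")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate states")
        if self.role not in ("indicator", "outcome", "covariate"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")

    def index_of(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"state {state!r} not in domain of {self.name}: {self.states}"
            ) from None


class DiscreteDataset:
    """Rectangular records of categorical grades, with missing cells allowed.

    Wraps a pandas DataFrame of object dtype (missing encoded as ``None``)
    plus the governing :class:`VariableSpec` list.  Every non-missing cell is
    validated against its variable's grade set.
    """

    def __init__(self, variables: Sequence[VariableSpec], frame: pd.DataFrame):
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        if len(self.variables) == 0:
            raise ValueError("at least one variable required")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        missing_cols = set(names) - set(frame.columns)
        if missing_cols:
            raise ValueError(f"frame lacks columns: {sorted(missing_cols)}")
        frame = frame.loc[:, names].astype(object)
        frame = frame.where(pd.notna(frame), other=None)
        for v in self.variables:
            col = frame[v.name]
            bad = col[~col.isin(list(v.states)) & col.notna()]
            if len(bad):
                i = bad.index[0]
                raise ValueError(
                    f"row {i}, column {v.name!r}: grade {bad.iloc[0]!r} "
                    f"not in {v.states}"
                )
        self.frame: pd.DataFrame = frame.reset_index(drop=True)
        self._codes: np.ndarray | None = None

    # -- basic accessors ----------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def var(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def column(self, name: str) -> list:
        return list(self.frame[name])

    def codes(self) -> np.ndarray:
        """Integer-coded data matrix (n_records, n_vars); missing = -1."""
        if self._codes is None:
            cols = []
            for v in self.variables:
                lut = {s: i for i, s in enumerate(v.states)}
                cols.append(
                    self.frame[v.name].map(lambda x: lut.get(x, -1)).to_numpy(np.int32)
                )
            self._codes = (
                np.stack(cols, axis=1) if cols else np.empty((0, 0), np.int32)
            )
        return self._codes

    def subset_records(self, index: Sequence[int]) -> "DiscreteDataset":
        return DiscreteDataset(self.variables, self.frame.iloc[list(index)])

    def select_variables(self, names: Sequence[str]) -> "DiscreteDataset":
        specs = [self.var(n) for n in names]
        return DiscreteDataset(specs, self.frame[list(names)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DiscreteDataset)
            and self.variables == other.variables
            and self.frame.equals(other.frame)
        )

    def __repr__(self) -> str:
        return f"DiscreteDataset({self.n_records} records, {len(self.variables)} variables)"


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph ``G = <V, E>`` with a fixed node order."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge endpoint outside node set: {u}->{v}")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> tuple[str, ...]:
        # parents in declared node order, for deterministic CPT layout
        return tuple(u for u in self.nodes if (u, node) in self.edges)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for v in self.nodes if (node, v) in self.edges)

    def topological_order(self) -> tuple[str, ...]:
        """Kahn's algorithm with the declared node order as tie-break."""
        indeg = {n: 0 for n in self.nodes}
        for _, v in self.edges:
            indeg[v] += 1
        order: list[str] = []
        ready = [n for n in self.nodes if indeg[n] == 0]
        while ready:
            n = ready.pop(0)
            order.append(n)
            for m in self.children(n):
                indeg[m] -= 1
                if indeg[m] == 0:
                    ready.append(m)
            ready.sort(key=self.nodes.index)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return tuple(order)

    def with_edge(self, u: str, v: str) -> "DagStructure":
        return DagStructure(self.nodes, self.edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "DagStructure":
        return DagStructure(self.nodes, self.edges - {(u, v)})


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table ``P(child | parents)``.

    ``table`` maps each parent configuration (one state per parent, in the
    declared parent order) to a probability vector over the child's states;
    rows cover the full Cartesian product of the parent state sets.
    """

    child: str
    child_states: tuple[str, ...]
    parents: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    table: Mapping[tuple[str, ...], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        expected = set(itertools.product(*self.parent_states)) if self.parents else {()}
        got = set(self.table.keys())
        if got != expected:
            raise ValueError(
                f"CPT of {self.child}: rows do not cover the parent-configuration "
                f"Cartesian product ({len(got)} rows, expected {len(expected)})"
            )
        for cfg, vec in self.table.items():
            vec = np.asarray(vec, float)
            if vec.shape != (len(self.child_states),):
                raise ValueError(f"CPT of {self.child}: bad row length at {cfg}")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"CPT of {self.child}: row {cfg} not a probability vector"
                )

    def row(self, parent_assignment: Mapping[str, str]) -> np.ndarray:
        cfg = tuple(parent_assignment[p] for p in self.parents)
        return np.asarray(self.table[cfg], float)

    def prob(self, state: str, parent_assignment: Mapping[str, str]) -> float:
        i = self.child_states.index(state)
        return float(self.row(parent_assignment)[i])


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG plus one CPT per node; the joint is the product of the CPTs."""

    dag: DagStructure
    cpts: Mapping[str, Cpt]

    def __post_init__(self) -> None:
        if set(self.cpts.keys()) != set(self.dag.nodes):
            raise ValueError("CPT map must cover exactly the DAG nodes")
        for n in self.dag.nodes:
            if self.cpts[n].parents != self.dag.parents(n):
                raise ValueError(
                    f"CPT parents of {n} ({self.cpts[n].parents}) disagree with "
                    f"DAG parents ({self.dag.parents(n)})"
                )

    def states(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].child_states

    def variable_specs(self) -> list[VariableSpec]:
        return [VariableSpec(n, self.states(n)) for n in self.dag.nodes]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def joint_probability(bn: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """Evaluate ``P(X1=x1, ..., Xn=xn)`` for a full assignment.

    The product is accumulated in log space when the network has more than
    20 nodes, to avoid underflow on long factorizations.
    """
    missing = [n for n in bn.dag.nodes if n not in assignment]
    if missing:
        raise IncompleteAssignmentError(f"assignment lacks nodes: {missing}")
    factors = []
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        state = assignment[node]
        if state not in cpt.child_states:
            raise ValueError(f"unknown state {state!r} for node {node}")
        factors.append(cpt.prob(state, assignment))
    if len(factors) > _LOG_SPACE_THRESHOLD:
        if any(f == 0.0 for f in factors):
            return 0.0
        return math.exp(sum(math.log(f) for f in factors))
    p = 1.0
    for f in factors:
        p *= f
    return p


def fit_parameters(
    structure: DagStructure,
    data: DiscreteDataset,
    equivalent_sample_size: float = 1.0,
) -> BayesianNetwork:
    """Bayesian parameter estimation with a BDeu-style Dirichlet prior.

    Each CPT entry is the posterior mean

        (N_{config,state} + a) / (N_config + a * r),    a = ess / (q * r),

    with ``q`` the number of parent configurations and ``r`` the child's state
    count.  Counts are available-case: a record contributes to a family's
    counts only when the child and all its parents are observed, so missing
    values never need imputation.
    """
    if equivalent_sample_size <= 0:
        raise ValueError("equivalent_sample_size must be > 0")
    name_to_idx = {n: i for i, n in enumerate(data.names)}
    unknown = [n for n in structure.nodes if n not in name_to_idx]
    if unknown:
        raise ValueError(f"structure nodes not in data: {unknown}")
    codes = data.codes()
    cpts: dict[str, Cpt] = {}
    for node in structure.nodes:
        spec = data.var(node)
        parents = structure.parents(node)
        pspecs = [data.var(p) for p in parents]
        r = len(spec.states)
        cards = [len(p.states) for p in pspecs]
        q = int(np.prod(cards)) if parents else 1
        alpha = equivalent_sample_size / (q * r)
        cidx = name_to_idx[node]
        pidx = [name_to_idx[p] for p in parents]
        child_col = codes[:, cidx]
        ok = child_col >= 0
        for j in pidx:
            ok &= codes[:, j] >= 0
        counts = np.zeros((q, r), float)
        if ok.any():
            if parents:
                cfg = np.zeros(int(ok.sum()), np.int64)
                for j, card in zip(pidx, cards):
                    cfg = cfg * card + codes[ok, j]
            else:
                cfg = np.zeros(int(ok.sum()), np.int64)
            flat = cfg * r + child_col[ok]
            counts += np.bincount(flat, minlength=q * r).reshape(q, r)
        probs = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * r)
        table = {}
        for row_i, cfg_states in enumerate(
            itertools.product(*[p.states for p in pspecs]) if parents else [()]
        ):
            table[tuple(cfg_states)] = probs[row_i]
        cpts[node] = Cpt(
            child=node,
            child_states=spec.states,
            parents=parents,
            parent_states=tuple(p.states for p in pspecs),
            table=table,
        )
    return BayesianNetwork(dag=structure, cpts=cpts)


def sample(bn: BayesianNetwork, n: int, seed: int) -> DiscreteDataset:
    """Draw ``n`` complete records by ancestral sampling in topological order."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    cols: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        r = len(cpt.child_states)
        if not cpt.parents:
            p = np.asarray(cpt.table[()], float)
            cols[node] = rng.choice(r, size=n, p=p)
        else:
            out = np.zeros(n, np.int64)
            cards = [len(s) for s in cpt.parent_states]
            cfg = np.zeros(n, np.int64)
            for p_name, card in zip(cpt.parents, cards):
                cfg = cfg * card + cols[p_name]
            # group records by parent configuration and draw per group
            rows = np.array(
                [
                    cpt.table[c]
                    for c in itertools.product(*cpt.parent_states)
                ],
                float,
            )
            u = rng.random(n)
            cum = rows.cumsum(axis=1)
            out = (u[:, None] > cum[cfg]).sum(axis=1)
            cols[node] = out
    frame = pd.DataFrame(
        {
            node: pd.Series(cols[node]).map(
                dict(enumerate(bn.states(node)))
            )
            for node in bn.dag.nodes
        }
    )
    if n == 0:
        frame = pd.DataFrame({node: pd.Series(dtype=object) for node in bn.dag.nodes})
    return DiscreteDataset(bn.variable_specs(), frame)


def _check_star(bn: BayesianNetwork, outcome: str) -> None:
    if outcome not in bn.dag.nodes:
        raise ValueError(f"outcome {outcome!r} not in network")
    if bn.dag.parents(outcome):
        raise ValueError("star model: the outcome must be the (parentless) root")
    for node in bn.dag.nodes:
        if node == outcome:
            continue
        if bn.dag.parents(node) != (outcome,):
            raise ValueError(
                f"star model: node {node} must have exactly the outcome as parent"
            )


def naive_posterior(
    bn_star: BayesianNetwork,
    evidence: Mapping[str, str | None],
    outcome: str,
) -> np.ndarray:
    """Posterior over outcome states in a star (naive-Bayes) network.

    The network has the outcome as root and every indicator as a child, i.e.
    the indicators are conditionally independent given the outcome.  By Bayes'
    rule the posterior is the normalized product

        P(s | e) prop. P(s) * prod_{x in evidence} P(x = e_x | s).

    Indicators absent from ``evidence`` (or with a missing value) are
    marginalized simply by omission from the likelihood product.
    """
    _check_star(bn_star, outcome)
    if outcome in evidence:
        raise ValueError("evidence must not include the outcome itself")
    states = bn_star.states(outcome)
    log_post = np.log(np.asarray(bn_star.cpts[outcome].table[()], float))
    for ind, val in evidence.items():
        if val is MISSING:
            continue
        if ind not in bn_star.dag.nodes:
            raise ValueError(f"unknown indicator {ind!r}")
        cpt = bn_star.cpts[ind]
        if val not in cpt.child_states:
            raise ValueError(f"unknown state {val!r} for indicator {ind}")
        k = cpt.child_states.index(val)
        lik = np.array([cpt.table[(s,)][k] for s in states], float)
        with np.errstate(divide="ignore"):
            log_post += np.log(lik)
    log_post -= log_post.max()
    post = np.exp(log_post)
    return post / post.sum()


def enumerate_posterior(
    bn: BayesianNetwork, evidence: Mapping[str, str], query: str
) -> np.ndarray:
    """Posterior by brute-force enumeration of the full joint (small nets)."""
    states = bn.states(query)
    other = [n for n in bn.dag.nodes if n != query and n not in evidence]
    weights = np.zeros(len(states))
    for qi, qs in enumerate(states):
        base = dict(evidence, **{query: qs})
        for combo in itertools.product(*[bn.states(n) for n in other]):
            full = dict(base)
            full.update(zip(other, combo))
            weights[qi] += joint_probability(bn, full)
    return weights / weights.sum()
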