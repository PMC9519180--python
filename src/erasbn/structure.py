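"""Score-based Bayesian-network structure learning, including LSHCT.

LSHCT ("SCC Local structure determination by Hill Climbing Twice") is a
divide-and-conquer score-search method.  Instead of hill climbing over the
full structure space at once it

1. computes the mutual-information (MI) matrix between all variable pairs;
2. for every node, learns a small sub-network over the node and its four
   highest-MI neighbors by plain hill climbing;
3. merges all sub-networks into one directed graph, resolving conflicting
   edge directions by majority vote (an exact tie keeps both directions, so
   the conflict survives into a strongly connected component and is settled
   by the score);
4. finds the strongly connected components (SCCs) of the merged graph —
   an SCC marks a region where the voted directions are cyclic;
5. re-orients each SCC locally: its undirected skeleton, doubled into both
   directions, is used as a whitelist for hill climbing run twice (first
   pass add/delete from the empty graph, second pass add/delete/reverse
   starting from the first pass's result);
6. assembles the oriented components with the voted between-component edges
   (acyclic by construction of the condensation) and finishes with one
   unrestricted hill-climbing local search from that graph.

Scores are decomposable (BIC by default, BDeu optional), computed with
available-case counts per family so missing cells are tolerated, and cached
by (child, parent set).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import DagStructure, DiscreteDataset

__all__ = [
    "LshctConfig",
    "MiMatrix",
    "DirectedGraphDraft",
    "EdgeVoteTally",
    "ScoreCache",
    "mutual_information",
    "mi_matrix",
    "top_k_neighbors",
    "local_score",
    "network_score",
    "hill_climb",
    "learn_sub_bn",
    "merge_sub_bns",
    "strongly_connected_components",
    "orient_component",
    "lshct",
]

# Minimum score gain for a hill-climbing move to count as an improvement.
_SCORE_TOL = 1e-9


@dataclass(frozen=True)
class LshctConfig:
    """Tunable knobs of the structure search.

    ``neighbor_count`` is the MI-screening width: each node's sub-network is
    built over the node plus its ``neighbor_count`` strongest-MI neighbors
    (default 4, i.e. five-node sub-networks).  ``score`` selects BIC
    (penalized log-likelihood, natural log) or BDeu with the given equivalent
    sample size.  ``expert_whitelist`` edges are forced into the final
    structure; ``expert_blacklist`` edges are never allowed.
    """

    neighbor_count: int = 4
    score: str = "bic"
    equivalent_sample_size: float = 1.0
    max_parents: int | None = None
    seed: int = 0
    expert_whitelist: frozenset[tuple[str, str]] = frozenset()
    expert_blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.neighbor_count < 1:
            raise ValueError("neighbor_count must be >= 1")
        if self.max_parents is not None and self.max_parents < 1:
            raise ValueError("max_parents must be >= 1 when set")
        if self.score not in ("bic", "bdeu"):
            raise ValueError(f"unknown score {self.score!r}")


@dataclass(frozen=True)
class MiMatrix:
    """Pairwise mutual information (nats); the diagonal holds entropies."""

    order: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.order), len(self.order)):
            raise ValueError("values must be square over `order`")
        if not np.allclose(v, v.T):
            raise ValueError("MI matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.order.index(a), self.order.index(b)])


@dataclass(frozen=True)
class DirectedGraphDraft:
    """A directed graph that may contain cycles (including 2-cycles)."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        nodeset = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge endpoint outside node set: {u}->{v}")


@dataclass
class EdgeVoteTally:
    """Per unordered pair, how many sub-networks voted each direction."""

    votes: dict[frozenset, dict[tuple[str, str], int]] = field(default_factory=dict)

    def add(self, u: str, v: str) -> None:
        pair = frozenset((u, v))
        d = self.votes.setdefault(pair, {})
        d[(u, v)] = d.get((u, v), 0) + 1


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

class UndefinedMiError(ValueError):
    """No pairwise-complete records: MI is undefined."""


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        raise UndefinedMiError("no pairwise-complete records")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in empirical MI (nats) over pairwise-complete records."""
    if len(x) != len(y):
        raise ValueError("columns must have equal length")
    pairs = [(a, b) for a, b in zip(x, y) if a is not None and b is not None]
    if not pairs:
        raise UndefinedMiError("no pairwise-complete records")
    xs = sorted({a for a, _ in pairs}, key=str)
    ys = sorted({b for _, b in pairs}, key=str)
    counts = np.zeros((len(xs), len(ys)))
    xi = {s: i for i, s in enumerate(xs)}
    yi = {s: i for i, s in enumerate(ys)}
    for a, b in pairs:
        counts[xi[a], yi[b]] += 1
    return _mi_from_counts(counts)


def mi_matrix(data: DiscreteDataset) -> MiMatrix:
    """All pairwise MI values; diagonal entries are the empirical entropies."""
    if len(data.variables) < 2:
        raise ValueError("at least 2 variables required")
    codes = data.codes()
    p = len(data.variables)
    cards = [len(v.states) for v in data.variables]
    m = np.zeros((p, p))
    for i in range(p):
        xi = codes[:, i]
        ok_i = xi >= 0
        if not ok_i.any():
            raise UndefinedMiError(f"variable {data.names[i]} entirely missing")
        cnt = np.bincount(xi[ok_i], minlength=cards[i]).astype(float)
        q = cnt / cnt.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            m[i, i] = float(-np.nansum(q * np.log(q)))
        for j in range(i + 1, p):
            ok = ok_i & (codes[:, j] >= 0)
            if not ok.any():
                raise UndefinedMiError(
                    f"no pairwise-complete records for ({data.names[i]}, {data.names[j]})"
                )
            flat = xi[ok] * cards[j] + codes[ok, j]
            counts = np.bincount(flat, minlength=cards[i] * cards[j]).reshape(
                cards[i], cards[j]
            )
            m[i, j] = m[j, i] = _mi_from_counts(counts.astype(float))
    return MiMatrix(order=data.names, values=m)


def top_k_neighbors(m: MiMatrix, node: str, k: int) -> list[str]:
    """The ``k`` other nodes with largest MI to ``node``.

    Ties are broken by position in ``m.order`` (deterministic).
    """
    if node not in m.order:
        raise KeyError(node)
    if k < 0:
        raise ValueError("k must be >= 0")
    i = m.order.index(node)
    others = [(j, m.order[j]) for j in range(len(m.order)) if j != i]
    others.sort(key=lambda t: (-m.values[i, t[0]], t[0]))
    return [name for _, name in others[:k]]


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

class ScoreCache:
    """Decomposable local scores over one dataset, cached by family.

    Counts are available-case: each family ``(child, parents)`` uses only the
    records in which the child and every parent are observed.
    """

    def __init__(self, data: DiscreteDataset, config: LshctConfig):
        self.data = data
        self.config = config
        self.names = data.names
        self._idx = {n: i for i, n in enumerate(self.names)}
        self._codes = data.codes()
        self._cards = [len(v.states) for v in data.variables]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, child: str, parents: Sequence[str]) -> float:
        if child in parents:
            raise ValueError(f"{child} listed among its own parents")
        ci = self._idx[child]
        pis = tuple(sorted(self._idx[p] for p in parents))
        key = (ci, pis)
        if key not in self._cache:
            self._cache[key] = self._compute(ci, pis)
        return self._cache[key]

    def _family_counts(self, ci: int, pis: tuple[int, ...]) -> np.ndarray:
        codes = self._codes
        r = self._cards[ci]
        cards = [self._cards[j] for j in pis]
        q = int(np.prod(cards)) if pis else 1
        ok = codes[:, ci] >= 0
        for j in pis:
            ok &= codes[:, j] >= 0
        if not ok.any():
            return np.zeros((q, r))
        cfg = np.zeros(int(ok.sum()), np.int64)
        for j, card in zip(pis, cards):
            cfg = cfg * card + codes[ok, j]
        flat = cfg * r + codes[ok, ci]
        return np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)

    def _compute(self, ci: int, pis: tuple[int, ...]) -> float:
        counts = self._family_counts(ci, pis)
        q, r = counts.shape
        n = counts.sum()
        if n == 0:
            return 0.0
        if self.config.score == "bic":
            nc = counts.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.nansum(counts * np.log(counts / nc))
            return float(ll - math.log(n) / 2.0 * q * (r - 1))
        # BDeu marginal likelihood
        ess = self.config.equivalent_sample_size
        a_j = ess / q
        a_jk = ess / (q * r)
        from scipy.special import gammaln

        nj = counts.sum(axis=1)
        term = gammaln(a_j) - gammaln(a_j + nj)
        term = term.sum()
        term += (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
        return float(term)


def local_score(
    child: str,
    parents: Sequence[str],
    data: DiscreteDataset,
    config: LshctConfig | None = None,
) -> float:
    config = config or LshctConfig()
    return ScoreCache(data, config).local(child, parents)


def network_score(
    dag: DagStructure,
    data: DiscreteDataset,
    config: LshctConfig | None = None,
    cache: ScoreCache | None = None,
) -> float:
    """Sum of local scores over all families of the DAG."""
    config = config or LshctConfig()
    cache = cache or ScoreCache(data, config)
    return sum(cache.local(n, dag.parents(n)) for n in dag.nodes)


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------

def _creates_cycle(edges: set[tuple[str, str]], u: str, v: str) -> bool:
    """Would adding u->v create a cycle? True iff u is reachable from v."""
    stack = [v]
    seen = {v}
    adj: dict[str, list[str]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    while stack:
        x = stack.pop()
        if x == u:
            return True
        for y in adj.get(x, ()):
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return False


def hill_climb(
    data: DiscreteDataset,
    initial: DagStructure,
    whitelist: frozenset[tuple[str, str]] | None = None,
    blacklist: frozenset[tuple[str, str]] = frozenset(),
    config: LshctConfig | None = None,
    max_iter: int | None = None,
    operators: tuple[str, ...] = ("add", "delete", "reverse"),
    protected: frozenset[tuple[str, str]] = frozenset(),
    cache: ScoreCache | None = None,
) -> DagStructure:
    """Greedy best-move local search over add/delete/reverse edge operations.

    ``whitelist`` (when given) is the set of *allowed* directed edges — every
    edge of the result is a member.  ``blacklist`` edges are forbidden.
    ``protected`` edges may not be deleted or reversed (used for expert-forced
    edges).  Moves must keep the graph acyclic; search stops when no move
    improves the score by more than 1e-9 or after ``max_iter`` moves
    (default ``10 * |V|**2``).  Ties between equal-gain moves are broken by
    the deterministic enumeration order: operator class (add, delete,
    reverse), then edge lexicographic order in the node declaration order.
    """
    config = config or LshctConfig()
    cache = cache or ScoreCache(data, config)
    nodes = initial.nodes
    if max_iter is None:
        max_iter = 10 * len(nodes) ** 2

    def allowed(e: tuple[str, str]) -> bool:
        if e in blacklist:
            return False
        return whitelist is None or e in whitelist

    for e in initial.edges:
        if not allowed(e):
            raise ValueError(f"initial edge {e} violates whitelist/blacklist")

    edges = set(initial.edges)
    parents: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in edges:
        parents[v].append(u)

    def pscore(node: str, ps: Iterable[str]) -> float:
        return cache.local(node, tuple(ps))

    node_order = {n: i for i, n in enumerate(nodes)}
    pairs = [
        (u, v)
        for u in sorted(nodes, key=node_order.get)
        for v in sorted(nodes, key=node_order.get)
        if u != v
    ]

    for _ in range(max_iter):
        best_gain = _SCORE_TOL
        best_move = None
        for op in operators:
            for u, v in pairs:
                e = (u, v)
                if op == "add":
                    if e in edges or not allowed(e) or (v, u) in edges:
                        continue
                    if (
                        config.max_parents is not None
                        and len(parents[v]) >= config.max_parents
                    ):
                        continue
                    if _creates_cycle(edges, u, v):
                        continue
                    gain = pscore(v, parents[v] + [u]) - pscore(v, parents[v])
                elif op == "delete":
                    if e not in edges or e in protected:
                        continue
                    new_p = [p for p in parents[v] if p != u]
                    gain = pscore(v, new_p) - pscore(v, parents[v])
                else:  # reverse
                    if e not in edges or e in protected or not allowed((v, u)):
                        continue
                    if (
                        config.max_parents is not None
                        and len(parents[u]) >= config.max_parents
                    ):
                        continue
                    if _creates_cycle(edges - {e}, v, u):
                        continue
                    gain = (
                        pscore(v, [p for p in parents[v] if p != u])
                        - pscore(v, parents[v])
                        + pscore(u, parents[u] + [v])
                        - pscore(u, parents[u])
                    )
                if gain > best_gain:
                    best_gain = gain
                    best_move = (op, u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            edges.add((u, v))
            parents[v].append(u)
        elif op == "delete":
            edges.discard((u, v))
            parents[v].remove(u)
        else:
            edges.discard((u, v))
            edges.add((v, u))
            parents[v].remove(u)
            parents[u].append(v)
    return DagStructure(nodes, edges)


def learn_sub_bn(
    data: DiscreteDataset,
    node_subset: Sequence[str],
    config: LshctConfig | None = None,
    cache: ScoreCache | None = None,
) -> DagStructure:
    """Hill-climb a sub-network restricted to ``node_subset`` from empty."""
    if len(node_subset) < 2:
        raise ValueError("node subset must contain at least 2 nodes")
    config = config or LshctConfig()
    # keep data order for determinism
    order = [n for n in data.names if n in set(node_subset)]
    empty = DagStructure(order, ())
    wl = frozenset(
        (u, v) for u in order for v in order if u != v
    ) - config.expert_blacklist
    return hill_climb(
        data,
        empty,
        whitelist=wl,
        config=config,
        cache=cache,
    )


def merge_sub_bns(sub_dags: Sequence[DagStructure]) -> DirectedGraphDraft:
    """Union of sub-networks with direction conflicts resolved by vote.

    If only one direction of a pair ever appears it is kept; with both
    directions the majority wins; an exact tie keeps both directions so the
    conflict lands in an SCC and the score settles it later.
    """
    if not sub_dags:
        raise ValueError("need at least one sub-network")
    nodes: list[str] = []
    for d in sub_dags:
        for n in d.nodes:
            if n not in nodes:
                nodes.append(n)
    tally = EdgeVoteTally()
    for d in sub_dags:
        for u, v in d.edges:
            tally.add(u, v)
    edges: set[tuple[str, str]] = set()
    for pair, dirs in tally.votes.items():
        if len(dirs) == 1:
            edges.add(next(iter(dirs)))
        else:
            (e1, c1), (e2, c2) = dirs.items()
            if c1 > c2:
                edges.add(e1)
            elif c2 > c1:
                edges.add(e2)
            else:
                edges.add(e1)
                edges.add(e2)
    return DirectedGraphDraft(nodes, edges)


def strongly_connected_components(g: DirectedGraphDraft) -> list[frozenset[str]]:
    """Maximal mutually-reachable node sets, via iterative Tarjan.

    Components are returned in a deterministic order (sorted by the position
    of their smallest member in ``g.nodes``).  The condensation of the graph
    by this partition is acyclic.
    """
    index_of: dict[str, int] = {}
    low: dict[str, int] = {}
    on_stack: set[str] = set()
    stack: list[str] = []
    comps: list[frozenset[str]] = []
    adj: dict[str, list[str]] = {n: [] for n in g.nodes}
    order = {n: i for i, n in enumerate(g.nodes)}
    for u, v in sorted(g.edges, key=lambda e: (order[e[0]], order[e[1]])):
        adj[u].append(v)
    counter = itertools.count()
    for root in g.nodes:
        if root in index_of:
            continue
        work: list[tuple[str, int]] = [(root, 0)]
        while work:
            node, pi = work[-1]
            if pi == 0:
                index_of[node] = low[node] = next(counter)
                stack.append(node)
                on_stack.add(node)
            recurse = False
            for i in range(pi, len(adj[node])):
                w = adj[node][i]
                if w not in index_of:
                    work[-1] = (node, i + 1)
                    work.append((w, 0))
                    recurse = True
                    break
                if w in on_stack:
                    low[node] = min(low[node], index_of[w])
            if recurse:
                continue
            work.pop()
            if low[node] == index_of[node]:
                comp = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.add(w)
                    if w == node:
                        break
                comps.append(frozenset(comp))
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[node])
    comps.sort(key=lambda c: min(order[n] for n in c))
    return comps


def orient_component(
    component: frozenset[str] | set[str],
    internal_edges: Iterable[frozenset[str]],
    data: DiscreteDataset,
    config: LshctConfig | None = None,
    cache: ScoreCache | None = None,
) -> DagStructure:
    """Re-orient one SCC's skeleton by hill climbing twice.

    The undirected skeleton, doubled into both directions, is the whitelist.
    Pass 1 climbs from the empty graph with add/delete moves only; pass 2
    resumes from pass 1's result with the reversal operator enabled.  The
    result is acyclic and uses only skeleton edges.
    """
    config = config or LshctConfig()
    comp = set(component)
    pairs = [frozenset(p) for p in internal_edges]
    for p in pairs:
        if not p <= comp:
            raise ValueError(f"skeleton edge {set(p)} outside the component")
    order = [n for n in data.names if n in comp]
    wl = set()
    for p in pairs:
        a, b = sorted(p, key=order.index)
        wl.add((a, b))
        wl.add((b, a))
    wl -= set(config.expert_blacklist)
    whitelist = frozenset(wl)
    cache = cache or ScoreCache(data, config)
    empty = DagStructure(order, ())
    pass1 = hill_climb(
        data, empty, whitelist=whitelist, config=config,
        operators=("add", "delete"), cache=cache,
    )
    pass2 = hill_climb(
        data, pass1, whitelist=whitelist, config=config,
        operators=("add", "delete", "reverse"), cache=cache,
    )
    return pass2


def lshct(data: DiscreteDataset, config: LshctConfig | None = None,
          trace: dict | None = None) -> DagStructure:
    """Full divide-and-conquer structure search (see module docstring).

    ``trace``, when a dict is supplied, is filled with the per-stage
    artifacts (MI matrix, sub-networks, merged draft, SCCs, assembled DAG
    and scores) for logging/inspection.
    """
    config = config or LshctConfig()
    if len(data.variables) < 2:
        raise ValueError("at least 2 variables required")
    if data.n_records < 1:
        raise ValueError("at least 1 record required")
    cache = ScoreCache(data, config)
    m = mi_matrix(data)
    subs = []
    for node in data.names:
        neigh = top_k_neighbors(m, node, config.neighbor_count)
        subs.append(learn_sub_bn(data, [node] + neigh, config, cache=cache))
    draft = merge_sub_bns(subs)
    comps = strongly_connected_components(draft)
    comp_of = {n: i for i, c in enumerate(comps) for n in c}
    between = {
        (u, v) for u, v in draft.edges if comp_of[u] != comp_of[v]
    }
    oriented: set[tuple[str, str]] = set()
    for comp in comps:
        if len(comp) == 1:
            continue
        internal = {
            frozenset((u, v))
            for u, v in draft.edges
            if comp_of[u] == comp_of[v] and u in comp
        }
        local = orient_component(comp, internal, data, config, cache=cache)
        oriented |= set(local.edges)
    assembled = DagStructure(data.names, between | oriented)  # acyclic or raises
    # Expert-forced edges take precedence: they seed the initial structure and
    # may never be deleted or reversed; assembled edges that would conflict
    # (cycle or reverse of a forced edge) are dropped from the start point.
    forced = frozenset(config.expert_whitelist)
    order = {n: i for i, n in enumerate(data.names)}
    init_edges: set[tuple[str, str]] = set()
    for e in sorted(forced, key=lambda e: (order[e[0]], order[e[1]])):
        if _creates_cycle(init_edges, *e):
            raise ValueError(f"expert whitelist is cyclic at edge {e}")
        init_edges.add(e)
    anti_forced = {(v, u) for u, v in forced}
    for e in sorted(assembled.edges, key=lambda e: (order[e[0]], order[e[1]])):
        if e not in anti_forced and not _creates_cycle(init_edges, *e):
            init_edges.add(e)
    initial = DagStructure(data.names, init_edges)
    final = hill_climb(
        data,
        initial,
        whitelist=None,
        blacklist=frozenset(config.expert_blacklist) | frozenset(anti_forced),
        config=config,
        protected=forced,
        cache=cache,
    )
    s_assembled = network_score(assembled, data, config, cache=cache)
    s_initial = network_score(initial, data, config, cache=cache)
    s_final = network_score(final, data, config, cache=cache)
    assert s_final >= s_initial - _SCORE_TOL, "local search must not lose score"
    if not forced and not config.expert_blacklist:
        # without expert constraints the start point is the assembled DAG
        assert s_final >= s_assembled - _SCORE_TOL
    if trace is not None:
        trace.update(
            mi=m,
            sub_bns=subs,
            merged=draft,
            sccs=comps,
            assembled=assembled,
            score_assembled=s_assembled,
            score_final=s_final,
        )
    return final
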