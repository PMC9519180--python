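"""Key-indicator extraction for anesthetic decision optimization.

The protocol ranks observed indicator-grade combinations by the modeled
probability of the *optimal* outcome state under a star-shaped (naive-Bayes)
Bayesian network, retains combinations whose posterior exceeds a threshold
(default 0.9), and then works on the two resulting case pools:

1. the numeric outcome (length of stay in days, or total cost) is split at
   its arithmetic mean into state-0 (below the mean, optimal) and state-1;
2. a star network with the outcome state as root is fitted and every
   observed combination's posterior is computed; combinations with posterior
   strictly above the threshold for a state form that state's case pool;
3. each indicator's grade distribution across the two pools is tabulated and
   tested (Pearson chi-square), and indicators are ordered by ascending p;
4. for each indicator the grade most frequent in the state-0 pool is chosen;
5. the chosen (indicator, grade) pairs are accumulated in the p-value order,
   and at each step the pools are tested for how many cases still match the
   growing combination (2x2 Pearson chi-square);
6. indicators whose cumulative-step p is below alpha (strict) are selected.

Because the two states' posteriors sum to one and the threshold exceeds 0.5,
a record can enter at most one pool; records whose combination clears the
threshold for neither state belong to no pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BayesianNetwork,
    DagStructure,
    DiscreteDataset,
    VariableSpec,
    fit_parameters,
    naive_posterior,
)
from .stats import ContingencyTable, DegenerateTableError, pearson_chi2

__all__ = [
    "OutcomeBinarization",
    "CombinationRecord",
    "BreakdownRow",
    "CumulativeRow",
    "SelectionReport",
    "discretize_by_mean",
    "build_star_model",
    "retain_combinations",
    "build_pools",
    "breakdown_tables",
    "choose_grades",
    "cumulative_combination",
    "select_final_indicators",
    "run_selection",
]


@dataclass(frozen=True)
class OutcomeBinarization:
    """Mean split of a numeric outcome: state 0 below the mean, state 1 at/above."""

    outcome: str
    threshold: float
    state0_label: str = "0"
    state1_label: str = "1"


@dataclass(frozen=True)
class CombinationRecord:
    """One observed indicator-grade combination with its posterior and support."""

    assignment: tuple[tuple[str, str | None], ...]
    posterior: float
    case_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must lie in [0, 1]")
        if self.case_count < 0:
            raise ValueError("case_count must be >= 0")

    def as_dict(self) -> dict[str, str | None]:
        return dict(self.assignment)


@dataclass(frozen=True)
class BreakdownRow:
    """One (indicator, grade) line of the single-indicator pool comparison."""

    indicator: str
    grade: str
    count0: int
    percent0: float
    count1: int
    percent1: float
    p: float


@dataclass(frozen=True)
class CumulativeRow:
    """One step of the cumulative multi-indicator combination analysis."""

    step: int
    indicator: str
    grade: str
    count0: int
    proportion0: float
    count1: int
    proportion1: float
    p: float | None


@dataclass(frozen=True)
class SelectionReport:
    """Full output of the selection protocol for one outcome."""

    outcome: str
    binarization: OutcomeBinarization
    alpha: float
    retention_threshold: float
    pool_sizes: tuple[int, int]
    n_combinations: tuple[int, int]
    breakdown: tuple[BreakdownRow, ...]
    indicator_order: tuple[tuple[str, float], ...]  # ascending p
    chosen_grades: tuple[tuple[str, str], ...]
    cumulative: tuple[CumulativeRow, ...]
    selected: frozenset[str]
    log: tuple[str, ...] = ()


def discretize_by_mean(
    values: Sequence[float | None], outcome: str = "outcome"
) -> tuple[OutcomeBinarization, list[str | None]]:
    """Split a numeric outcome at its mean: ``"0"`` if below, ``"1"`` if at/above.

    Missing values get a missing state label (``None``) and are excluded from
    the mean.
    """
    arr = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not arr:
        raise ValueError("all outcome values missing")
    threshold = float(np.mean(arr))
    if not math.isfinite(threshold):
        raise ValueError("outcome mean is not finite")
    bz = OutcomeBinarization(outcome=outcome, threshold=threshold)
    labels: list[str | None] = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            labels.append(None)
        else:
            labels.append(bz.state0_label if v < threshold else bz.state1_label)
    return bz, labels


def build_star_model(
    indicators: DiscreteDataset,
    outcome_labels: Sequence[str | None],
    outcome: str,
    equivalent_sample_size: float = 1.0,
) -> tuple[BayesianNetwork, DiscreteDataset]:
    """Fit the independence (star) network: outcome root, indicators as leaves.

    Returns the fitted network and the dataset augmented with the binarized
    outcome column.
    """
    if len(outcome_labels) != indicators.n_records:
        raise ValueError("outcome labels must align with the records")
    specs = [VariableSpec(outcome, ("0", "1"), role="outcome")] + list(
        indicators.variables
    )
    frame = indicators.frame.copy()
    frame.insert(0, outcome, list(outcome_labels))
    data = DiscreteDataset(specs, frame)
    dag = DagStructure(
        [outcome] + list(indicators.names),
        [(outcome, ind) for ind in indicators.names],
    )
    return fit_parameters(dag, data, equivalent_sample_size), data


def _observed_combinations(
    data: DiscreteDataset, indicator_names: Sequence[str]
) -> dict[tuple, list[int]]:
    combos: dict[tuple, list[int]] = {}
    frame = data.frame[list(indicator_names)]
    for i, row in enumerate(frame.itertuples(index=False, name=None)):
        combos.setdefault(row, []).append(i)
    return combos


def retain_combinations(
    star_model: BayesianNetwork,
    data: DiscreteDataset,
    outcome: str,
    target_state: str,
    threshold: float = 0.9,
) -> list[CombinationRecord]:
    """Observed combinations whose posterior for ``target_state`` exceeds threshold.

    Only combinations actually present in the data are enumerated (the full
    Cartesian product over 18 indicators is astronomically larger than any
    realistic dataset).  The inequality is strict: a posterior exactly equal
    to the threshold is not retained.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    states = star_model.states(outcome)
    if len(states) != 2:
        raise ValueError("the outcome must be binary")
    si = states.index(target_state)
    indicator_names = [n for n in star_model.dag.nodes if n != outcome]
    present = [n for n in indicator_names if n in data.names]
    retained: list[CombinationRecord] = []
    for combo, rows in _observed_combinations(data, present).items():
        evidence = {k: v for k, v in zip(present, combo)}
        post = naive_posterior(star_model, evidence, outcome)[si]
        if post > threshold:
            retained.append(
                CombinationRecord(
                    assignment=tuple(zip(present, combo)),
                    posterior=float(post),
                    case_count=len(rows),
                )
            )
    retained.sort(key=lambda r: (-r.posterior, r.assignment))
    return retained


def build_pools(
    star_model: BayesianNetwork,
    data: DiscreteDataset,
    outcome: str,
    threshold: float = 0.9,
) -> dict[str, list[int]]:
    """Record indices per outcome state whose combination was retained for it."""
    states = star_model.states(outcome)
    indicator_names = [n for n in star_model.dag.nodes if n != outcome]
    present = [n for n in indicator_names if n in data.names]
    pools: dict[str, list[int]] = {s: [] for s in states}
    for combo, rows in _observed_combinations(data, present).items():
        evidence = dict(zip(present, combo))
        post = naive_posterior(star_model, evidence, outcome)
        for si, s in enumerate(states):
            if post[si] > threshold:
                pools[s].extend(rows)
    for s in pools:
        pools[s].sort()
    return pools


def breakdown_tables(
    pool0: DiscreteDataset,
    pool1: DiscreteDataset,
    indicators: Sequence[VariableSpec],
) -> list[BreakdownRow]:
    """Single-indicator grade distributions across the two pools, with p-values.

    Percentages are relative to the pool size; the p-value is a two-sided
    Pearson chi-square over the indicator's grade-by-pool table (all-zero
    grades dropped first).  Rows are emitted in declared grade order.
    """
    if pool0.n_records == 0 or pool1.n_records == 0:
        raise ValueError("both pools must be nonempty")
    n0, n1 = pool0.n_records, pool1.n_records
    rows: list[BreakdownRow] = []
    for spec in indicators:
        c0 = pool0.frame[spec.name].value_counts()
        c1 = pool1.frame[spec.name].value_counts()
        counts = [(int(c0.get(g, 0)), int(c1.get(g, 0))) for g in spec.states]
        table = ContingencyTable(
            counts, row_labels=spec.states, col_labels=("state0", "state1")
        )
        try:
            p = pearson_chi2(table).p
        except DegenerateTableError:
            p = float("nan")
        for g, (k0, k1) in zip(spec.states, counts):
            rows.append(
                BreakdownRow(
                    indicator=spec.name,
                    grade=g,
                    count0=k0,
                    percent0=100.0 * k0 / n0,
                    count1=k1,
                    percent1=100.0 * k1 / n1,
                    p=p,
                )
            )
    return rows


def choose_grades(rows: Sequence[BreakdownRow]) -> dict[str, str]:
    """Per indicator, the grade with the largest state-0-pool share.

    Ties resolve to the grade declared first.
    """
    best: dict[str, tuple[float, int, str]] = {}
    position: dict[str, int] = {}
    for row in rows:
        pos = position.setdefault(row.indicator, 0)
        cur = best.get(row.indicator)
        if cur is None or row.percent0 > cur[0]:
            best[row.indicator] = (row.percent0, pos, row.grade)
        position[row.indicator] = pos + 1
    return {ind: v[2] for ind, v in best.items()}


def cumulative_combination(
    order: Sequence[str],
    grades: Mapping[str, str],
    pool0: DiscreteDataset,
    pool1: DiscreteDataset,
) -> list[CumulativeRow]:
    """Accumulate the chosen (indicator, grade) pairs in the given order.

    Step k counts, in each pool, the records matching all of the first k
    pairs (a missing cell never matches); the p-value is the two-sided
    Pearson chi-square of the match/no-match by pool 2x2.  When a margin of
    that table is empty (for example no matching case remains in either
    pool) the p-value is undefined and reported as ``None``.
    """
    n0, n1 = pool0.n_records, pool1.n_records
    mask0 = np.ones(n0, bool)
    mask1 = np.ones(n1, bool)
    rows: list[CumulativeRow] = []
    for k, ind in enumerate(order, start=1):
        g = grades[ind]
        mask0 &= (pool0.frame[ind] == g).to_numpy()
        mask1 &= (pool1.frame[ind] == g).to_numpy()
        m0, m1 = int(mask0.sum()), int(mask1.sum())
        try:
            p = pearson_chi2(
                ContingencyTable([[m0, m1], [n0 - m0, n1 - m1]])
            ).p
        except DegenerateTableError:
            p = None
        rows.append(
            CumulativeRow(
                step=k,
                indicator=ind,
                grade=g,
                count0=m0,
                proportion0=m0 / n0,
                count1=m1,
                proportion1=m1 / n1,
                p=p,
            )
        )
    return rows


def select_final_indicators(
    rows: Sequence[CumulativeRow],
    alpha: float = 0.05,
    expert_add: Sequence[str] = (),
    expert_remove: Sequence[str] = (),
) -> tuple[frozenset[str], list[str]]:
    """Indicators whose cumulative-step p is strictly below alpha.

    Explicit expert overrides may add or remove indicators; every override is
    logged.  Returns the final set and the log lines.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    selected = {r.indicator for r in rows if r.p is not None and r.p < alpha}
    log: list[str] = []
    for ind in expert_add:
        if ind not in selected:
            selected.add(ind)
            log.append(f"expert override: added {ind}")
    for ind in expert_remove:
        if ind in selected:
            selected.discard(ind)
            log.append(f"expert override: removed {ind}")
    return frozenset(selected), log


def run_selection(
    indicators: DiscreteDataset,
    outcome_values: Sequence[float | None],
    outcome: str,
    retention_threshold: float = 0.9,
    alpha: float = 0.05,
    equivalent_sample_size: float = 1.0,
    expert_add: Sequence[str] = (),
    expert_remove: Sequence[str] = (),
) -> SelectionReport:
    """The full selection protocol for one numeric outcome (see module docs)."""
    bz, labels = discretize_by_mean(outcome_values, outcome)
    star, data = build_star_model(indicators, labels, outcome,
                                  equivalent_sample_size)
    retained0 = retain_combinations(star, data, outcome, "0", retention_threshold)
    retained1 = retain_combinations(star, data, outcome, "1", retention_threshold)
    pools = build_pools(star, data, outcome, retention_threshold)
    pool0 = indicators.subset_records(pools["0"])
    pool1 = indicators.subset_records(pools["1"])
    if pool0.n_records == 0 or pool1.n_records == 0:
        raise ValueError(
            "a pool is empty: no combination clears the retention threshold "
            f"for one outcome state (threshold={retention_threshold})"
        )
    rows = breakdown_tables(pool0, pool1, indicators.variables)
    p_by_ind: dict[str, float] = {}
    for r in rows:
        p_by_ind.setdefault(r.indicator, r.p)
    ind_pos = {v.name: i for i, v in enumerate(indicators.variables)}
    order = sorted(
        p_by_ind,
        key=lambda ind: (
            p_by_ind[ind] if math.isfinite(p_by_ind[ind]) else float("inf"),
            ind_pos[ind],
        ),
    )
    grades = choose_grades(rows)
    cum = cumulative_combination(order, grades, pool0, pool1)
    selected, log = select_final_indicators(cum, alpha, expert_add, expert_remove)
    borderline = [
        f"note: {r.indicator} listed at step {r.step} has p={r.p} >= alpha"
        for r in cum
        if r.p is not None and alpha <= r.p < 0.1
    ]
    return SelectionReport(
        outcome=outcome,
        binarization=bz,
        alpha=alpha,
        retention_threshold=retention_threshold,
        pool_sizes=(pool0.n_records, pool1.n_records),
        n_combinations=(len(retained0), len(retained1)),
        breakdown=tuple(rows),
        indicator_order=tuple((ind, p_by_ind[ind]) for ind in order),
        chosen_grades=tuple((ind, grades[ind]) for ind in order),
        cumulative=tuple(cum),
        selected=selected,
        log=tuple(log) + tuple(borderline),
    )
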