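"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from erasbn.core import (
    BayesianNetwork,
    Cpt,
    DagStructure,
    DiscreteDataset,
    VariableSpec,
)


def dataset(columns: dict[str, list], states: dict[str, tuple[str, ...]] | None = None
            ) -> DiscreteDataset:
    """Build a DiscreteDataset from literal columns (None = missing cell)."""
    states = states or {}
    specs = []
    for name, col in columns.items():
        if name in states:
            st = states[name]
        else:
            st = tuple(sorted({c for c in col if c is not None}, key=str))
            if len(st) < 2:
                st = st + ("_pad",)
        specs.append(VariableSpec(name, st))
    return DiscreteDataset(specs, pd.DataFrame(columns, dtype=object))


def binary_root(name: str, p1: float) -> Cpt:
    return Cpt(name, ("0", "1"), (), (), {(): np.array([1 - p1, p1])})


def binary_child(name: str, parent: str, p1_given: dict[str, float]) -> Cpt:
    """Binary node with one binary parent; p1_given maps parent state -> P(1)."""
    return Cpt(
        name, ("0", "1"), (parent,), (("0", "1"),),
        {(s,): np.array([1 - p, p]) for s, p in p1_given.items()},
    )


def random_star_model(rng: np.random.Generator, n_indicators: int,
                      max_states: int = 3) -> BayesianNetwork:
    """A random naive-Bayes network: binary outcome root, indicator leaves."""
    outcome = "out"
    names = [outcome] + [f"i{k}" for k in range(n_indicators)]
    dag = DagStructure(names, [(outcome, n) for n in names[1:]])
    prior = rng.dirichlet([1.0, 1.0])
    cpts = {outcome: Cpt(outcome, ("0", "1"), (), (), {(): prior})}
    for n in names[1:]:
        r = int(rng.integers(2, max_states + 1))
        states = tuple(f"s{j}" for j in range(r))
        table = {(s,): rng.dirichlet([1.0] * r) for s in ("0", "1")}
        cpts[n] = Cpt(n, states, (outcome,), (("0", "1"),), table)
    return BayesianNetwork(dag, cpts)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
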