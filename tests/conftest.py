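"""Shared fixtures: hand-built toy graphs and random graph factories."""

from __future__ import annotations

import numpy as np
import pytest

from lbdkit.graph import TemporalGraph, load_graph


def make_graph(edge_rows, extra_nodes=(), node_rows=None, totals_rows=None) -> TemporalGraph:
    """Build a consistent TemporalGraph from (u, v, year, sent, doc) rows.

    Node occurrence counts default to the sum of incident edge counts plus a
    small margin, and corpus totals to the per-year sums, so all contingency
    invariants hold by construction.
    """
    if node_rows is None:
        node_sent: dict[tuple[str, int], int] = {}
        for u, v, year, sent, _doc in edge_rows:
            for e in (u, v):
                node_sent[(e, year)] = node_sent.get((e, year), 0) + sent
        years = sorted({y for (_, y) in node_sent}) or [2000]
        entities = sorted({e for (e, _) in node_sent} | set(extra_nodes))
        node_rows = [
            (e, "other", y, node_sent.get((e, y), 0) + 1)
            for e in entities
            for y in years
        ]
    if totals_rows is None:
        year_tot: dict[int, int] = {}
        for e, _t, y, n in node_rows:
            year_tot[y] = year_tot.get(y, 0) + n
        totals_rows = [(y, t + 10, t + 10) for y, t in sorted(year_tot.items())]
    return load_graph(edge_rows, node_rows, totals_rows)


def random_graph(rng: np.random.Generator, n_nodes: int, p_edge: float, year: int = 2000):
    """Random single-year graph with random counts; returns (graph, slice)."""
    names = [f"N{i:02d}" for i in range(n_nodes)]
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                sent = int(rng.integers(1, 20))
                doc = int(rng.integers(1, sent + 1))
                rows.append((names[i], names[j], year, sent, doc))
    graph = make_graph(rows, extra_nodes=names)
    return graph, graph.slice(year)


@pytest.fixture
def toy_graph() -> TemporalGraph:
    """Small fixed graph used across modules.

    A-B1-C and A-B2-C wedges plus a B1-D spur; no direct A-C edge.
    """
    rows = [
        ("A", "B1", 2000, 4, 2),
        ("B1", "C", 2000, 6, 3),
        ("A", "B2", 2000, 2, 1),
        ("B2", "C", 2001, 3, 2),
        ("B1", "D", 2001, 5, 4),
    ]
    return make_graph(rows)


@pytest.fixture
def toy_slice(toy_graph):
    return toy_graph.slice(2001)
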