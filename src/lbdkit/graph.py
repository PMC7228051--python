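"""Temporal co-occurrence graph: loading, validation, slicing, candidates.

Edges are undirected and stored canonically with ``u < v``.  Each edge
carries per-year sentence and document co-occurrence counts; nodes carry
per-year sentence occurrence counts and every year has corpus totals.
Slicing at a cutoff year aggregates counts additively over all retained
years, with no decay weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from lbdkit.metrics import ContingencyCounts

__all__ = [
    "Entity",
    "EdgeObservation",
    "TemporalGraph",
    "GraphSlice",
    "DiscoveryCase",
    "GraphDataError",
    "load_graph",
    "read_graph_tsv",
    "write_graph_tsv",
    "b_candidates",
    "c_candidates",
    "timeslice_split",
    "read_cases",
    "write_cases",
]

ENTITY_TYPES = frozenset(
    {"chemical", "gene", "disease", "mutation", "species", "cancer-hallmark", "other"}
)


class GraphDataError(ValueError):
    """Malformed or referentially inconsistent graph input."""


@dataclass(frozen=True)
class Entity:
    id: str
    entity_type: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphDataError("entity id must be non-empty")


@dataclass(frozen=True)
class EdgeObservation:
    """One year's co-occurrence counts for an undirected entity pair."""

    u: str
    v: str
    year: int
    sent_count: int
    doc_count: int

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise GraphDataError(f"self-loop on {self.u!r}")
        if self.u > self.v:
            raise GraphDataError("observation endpoints must be canonical (u < v)")
        if self.sent_count < 1:
            raise GraphDataError(
                f"{self.u}-{self.v} ({self.year}): sent_count must be >= 1"
            )
        if not (0 <= self.doc_count <= self.sent_count):
            raise GraphDataError(
                f"{self.u}-{self.v} ({self.year}): doc_count {self.doc_count} "
                f"exceeds sent_count {self.sent_count}"
            )


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class TemporalGraph:
    """Entities plus year-stamped co-occurrence observations and totals."""

    entities: dict[str, Entity] = field(default_factory=dict)
    # (u, v) canonical -> {year -> [sent_count, doc_count]}
    edge_years: dict[tuple[str, str], dict[int, list[int]]] = field(default_factory=dict)
    # (entity, year) -> sentence occurrence count
    node_year_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    # year -> (total sentences, total documents)
    corpus_totals: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        ys = {y for yc in self.edge_years.values() for y in yc}
        ys.update(y for (_, y) in self.node_year_counts)
        ys.update(self.corpus_totals)
        return sorted(ys)

    def add_observation(self, obs: EdgeObservation) -> None:
        for e in (obs.u, obs.v):
            if e not in self.entities:
                raise GraphDataError(f"observation references unknown entity {e!r}")
        counts = self.edge_years.setdefault((obs.u, obs.v), {})
        cur = counts.setdefault(obs.year, [0, 0])
        cur[0] += obs.sent_count
        cur[1] += obs.doc_count

    def observations(self):
        for (u, v), yc in sorted(self.edge_years.items()):
            for year in sorted(yc):
                s, d = yc[year]
                yield EdgeObservation(u, v, year, s, d)

    def validate(self) -> None:
        """Check referential integrity and count consistency for every year."""
        for (u, v), yc in self.edge_years.items():
            for e in (u, v):
                if e not in self.entities:
                    raise GraphDataError(f"edge endpoint {e!r} not in entities")
            for year, (s, d) in yc.items():
                if d > s or s < 1:
                    raise GraphDataError(f"bad counts on {u}-{v} ({year})")
        for (e, year), n in self.node_year_counts.items():
            if e not in self.entities:
                raise GraphDataError(f"node count for unknown entity {e!r}")
            if year in self.corpus_totals and n > self.corpus_totals[year][0]:
                raise GraphDataError(
                    f"node count for {e!r} in {year} exceeds corpus total"
                )

    def slice(self, cutoff_year: int) -> GraphSlice:
        return GraphSlice.build(self, cutoff_year)


@dataclass
class GraphSlice:
    """Counts aggregated over all observation years <= ``cutoff_year``."""

    parent: TemporalGraph
    cutoff_year: int
    edge_counts: dict[tuple[str, str], tuple[int, int]]
    node_counts: dict[str, int]
    total_sentences: int
    total_documents: int
    adjacency: dict[str, set[str]]

    @classmethod
    def build(cls, graph: TemporalGraph, cutoff_year: int) -> GraphSlice:
        edge_counts: dict[tuple[str, str], tuple[int, int]] = {}
        adjacency: dict[str, set[str]] = {e: set() for e in graph.entities}
        for (u, v), yc in graph.edge_years.items():
            s = sum(c[0] for y, c in yc.items() if y <= cutoff_year)
            d = sum(c[1] for y, c in yc.items() if y <= cutoff_year)
            if s > 0:
                edge_counts[(u, v)] = (s, d)
                adjacency[u].add(v)
                adjacency[v].add(u)
        node_counts = {e: 0 for e in graph.entities}
        for (e, year), n in graph.node_year_counts.items():
            if year <= cutoff_year:
                node_counts[e] = node_counts.get(e, 0) + n
        total_s = sum(
            t[0] for y, t in graph.corpus_totals.items() if y <= cutoff_year
        )
        total_d = sum(
            t[1] for y, t in graph.corpus_totals.items() if y <= cutoff_year
        )
        return cls(
            parent=graph,
            cutoff_year=cutoff_year,
            edge_counts=edge_counts,
            node_counts=node_counts,
            total_sentences=total_s,
            total_documents=total_d,
            adjacency=adjacency,
        )

    @property
    def nodes(self) -> list[str]:
        return sorted(self.adjacency)

    def has_edge(self, a: str, b: str) -> bool:
        return _canon(a, b) in self.edge_counts

    def neighbors(self, a: str) -> set[str]:
        try:
            return self.adjacency[a]
        except KeyError:
            raise KeyError(f"unknown entity {a!r}") from None

    def degree(self, a: str) -> int:
        return len(self.neighbors(a))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.edge_counts)

    def contingency(self, a: str, b: str) -> ContingencyCounts:
        """Sentence/document contingency counts for the pair within the slice."""
        u, v = _canon(a, b)
        s, d = self.edge_counts.get((u, v), (0, 0))
        n_a = self.node_counts.get(a)
        n_b = self.node_counts.get(b)
        if n_a is None or n_b is None:
            raise KeyError(f"unknown entity in pair ({a!r}, {b!r})")
        # Node occurrence files may undercount relative to edge files; clamp
        # so the contingency invariant n_xy <= min(n_x, n_y) always holds.
        n_a = max(n_a, s)
        n_b = max(n_b, s)
        big_n = max(self.total_sentences, n_a, n_b, 1)
        big_d = max(self.total_documents, d, 1)
        return ContingencyCounts(
            n_xy=s, n_x=n_a, n_y=n_b, N=big_n, d_xy=d, d_x=d, d_y=d, D=big_d
        )


@dataclass(frozen=True)
class DiscoveryCase:
    """One evaluation unit: (a, c, gold B) for closed or (a, gold C) for open."""

    a: str
    gold: str
    cutoff_year: int
    c: str | None = None

    def __post_init__(self) -> None:
        if self.c is not None:
            if self.a == self.c:
                raise GraphDataError("closed case requires a != c")
            if self.gold in (self.a, self.c):
                raise GraphDataError("gold B must differ from a and c")
        elif self.gold == self.a:
            raise GraphDataError("gold C must differ from a")

    @property
    def is_closed(self) -> bool:
        return self.c is not None


# ---------------------------------------------------------------------------
# Loading and saving
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["entity1", "entity2", "year", "sent_count", "doc_count"]
NODE_COLUMNS = ["entity", "entity_type", "year", "sent_occurrence_count"]
TOTALS_COLUMNS = ["year", "total_sentences", "total_documents"]


def load_graph(edge_rows, node_rows, totals_rows) -> TemporalGraph:
    """Assemble and validate a :class:`TemporalGraph` from tabular records.

    Each argument is an iterable of tuples/lists matching the corresponding
    TSV schema (without header).  Duplicate ``(u, v, year)`` edge rows are
    summed after canonicalisation.
    """
    graph = TemporalGraph()
    for i, row in enumerate(node_rows, start=1):
        try:
            ent, etype, year, n = row
            year, n = int(year), int(n)
        except (ValueError, TypeError) as exc:
            raise GraphDataError(f"node row {i}: malformed ({exc})") from None
        if etype not in ENTITY_TYPES:
            etype = "other"
        if ent in graph.entities and graph.entities[ent].entity_type != etype:
            raise GraphDataError(f"node row {i}: conflicting type for {ent!r}")
        graph.entities.setdefault(ent, Entity(ent, etype))
        key = (ent, year)
        graph.node_year_counts[key] = graph.node_year_counts.get(key, 0) + n

    for i, row in enumerate(totals_rows, start=1):
        try:
            year, ns, nd = (int(x) for x in row)
        except (ValueError, TypeError) as exc:
            raise GraphDataError(f"totals row {i}: malformed ({exc})") from None
        prev = graph.corpus_totals.get(year, (0, 0))
        graph.corpus_totals[year] = (prev[0] + ns, prev[1] + nd)

    for i, row in enumerate(edge_rows, start=1):
        try:
            e1, e2, year, s, d = row
            year, s, d = int(year), int(s), int(d)
        except (ValueError, TypeError) as exc:
            raise GraphDataError(f"edge row {i}: malformed ({exc})") from None
        u, v = _canon(str(e1), str(e2))
        try:
            obs = EdgeObservation(u, v, year, s, d)
        except GraphDataError as exc:
            raise GraphDataError(f"edge row {i}: {exc}") from None
        try:
            graph.add_observation(obs)
        except GraphDataError as exc:
            raise GraphDataError(f"edge row {i}: {exc}") from None

    graph.validate()
    return graph


def read_graph_tsv(edge_path, node_path, totals_path) -> TemporalGraph:
    """Read the three-file TSV representation (header rows required)."""
    edges = pd.read_csv(edge_path, sep="\t", dtype=str)
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    totals = pd.read_csv(totals_path, sep="\t", dtype=str)
    for df, cols, path in (
        (edges, EDGE_COLUMNS, edge_path),
        (nodes, NODE_COLUMNS, node_path),
        (totals, TOTALS_COLUMNS, totals_path),
    ):
        if list(df.columns) != cols:
            raise GraphDataError(
                f"{path}: expected header {cols}, found {list(df.columns)}"
            )
    return load_graph(
        edges.itertuples(index=False, name=None),
        nodes.itertuples(index=False, name=None),
        totals.itertuples(index=False, name=None),
    )


def write_graph_tsv(graph: TemporalGraph, edge_path, node_path, totals_path) -> None:
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for obs in graph.observations():
            fh.write(f"{obs.u}\t{obs.v}\t{obs.year}\t{obs.sent_count}\t{obs.doc_count}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for (ent, year), n in sorted(graph.node_year_counts.items()):
            etype = graph.entities[ent].entity_type
            fh.write(f"{ent}\t{etype}\t{year}\t{n}\n")
    with open(totals_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TOTALS_COLUMNS) + "\n")
        for year in sorted(graph.corpus_totals):
            s, d = graph.corpus_totals[year]
            fh.write(f"{year}\t{s}\t{d}\n")


def read_cases(path) -> list[DiscoveryCase]:
    """Read discovery cases from a flat key-value text file.

    Records are blank-line separated blocks of ``key: value`` lines with keys
    ``a``, ``c`` (empty or omitted for open discovery), ``gold``,
    ``cutoff_year``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    cases = []
    for block in text.split("\n\n"):
        block = block.strip()
        if not block:
            continue
        fields: dict[str, str] = {}
        for line in block.splitlines():
            if ":" not in line:
                raise GraphDataError(f"malformed case line: {line!r}")
            key, _, value = line.partition(":")
            fields[key.strip()] = value.strip()
        c = fields.get("c") or None
        try:
            cases.append(
                DiscoveryCase(
                    a=fields["a"],
                    c=c,
                    gold=fields["gold"],
                    cutoff_year=int(fields["cutoff_year"]),
                )
            )
        except KeyError as exc:
            raise GraphDataError(f"case missing field {exc}") from None
    return cases


def write_cases(cases, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        blocks = []
        for case in cases:
            lines = [f"a: {case.a}"]
            if case.c is not None:
                lines.append(f"c: {case.c}")
            lines.append(f"gold: {case.gold}")
            lines.append(f"cutoff_year: {case.cutoff_year}")
            blocks.append("\n".join(lines))
        fh.write("\n\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# Candidate generation and time slicing
# ---------------------------------------------------------------------------


def b_candidates(slice_: GraphSlice, a: str, c: str) -> set[str]:
    """Linking-term candidates: common neighbours of ``a`` and ``c``.

    A direct a-c edge does not disqualify a common neighbour.
    """
    return (slice_.neighbors(a) & slice_.neighbors(c)) - {a, c}


def c_candidates(slice_: GraphSlice, a: str) -> set[str]:
    """Target candidates: nodes at shortest-path distance exactly 2 from ``a``.

    Direct neighbours of ``a`` are excluded — an existing a-c edge is not a
    discovery — as is ``a`` itself.
    """
    direct = slice_.neighbors(a)
    two_hop: set[str] = set()
    for b in direct:
        two_hop |= slice_.adjacency[b]
    return two_hop - direct - {a}


def timeslice_split(
    graph: TemporalGraph,
    cutoff_year: int,
    dev_fraction: float,
    seed: int,
) -> tuple[GraphSlice, set[tuple[str, str]], set[tuple[str, str]]]:
    """Split post-cutoff *new* links into development and test pair sets.

    A link counts as new knowledge only if it has no observation at or before
    the cutoff.  The returned training slice contains the pre-cutoff graph.
    """
    import numpy as np

    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must lie in (0, 1)")
    train = graph.slice(cutoff_year)
    new_links = sorted(
        (u, v)
        for (u, v), yc in graph.edge_years.items()
        if (u, v) not in train.edge_counts and any(y > cutoff_year for y in yc)
    )
    if not new_links:
        raise GraphDataError(f"no new links after cutoff {cutoff_year}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(new_links))
    n_dev = int(round(dev_fraction * len(new_links)))
    dev = {new_links[i] for i in order[:n_dev]}
    test = {new_links[i] for i in order[n_dev:]}
    return train, dev, test
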