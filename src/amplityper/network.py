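"""Type-to-type distances and minimum spanning haplotype networks.

Provesti's distance between two haploid character vectors is the proportion
of compared columns at which they differ; a gap is a state, ambiguity codes
compare literally (an optional overlap mode treats R vs A as a match), and
columns with a missing-data symbol in either vector are dropped from the
denominator.

The minimum spanning network is a Kruskal-grown spanning forest in which
edges whose weight ties the merge threshold of their endpoints' components
are retained as *alternative* connections (epsilon = 0: only exact ties).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import TypeCatalog, state_set
from .variants import CondensedMatrix

MISSING_STATES = frozenset({"N", "?"})


@dataclass(frozen=True)
class EventDistance:
    substitutions: int
    indel_events: int
    homopolymer_attached: int = 0

    def __post_init__(self) -> None:
        if min(self.substitutions, self.indel_events, self.homopolymer_attached) < 0:
            raise ValueError("negative counts")
        if self.homopolymer_attached > self.indel_events:
            raise ValueError("homopolymer count exceeds indel events")

    @property
    def total(self) -> int:
        return self.substitutions + self.indel_events

    def __str__(self) -> str:
        s = f"{self.substitutions} subs"
        plain = self.indel_events - self.homopolymer_attached
        if plain:
            s += f" + {plain} indel"
        if self.homopolymer_attached:
            s += f" (+{self.homopolymer_attached} homopolymer indel)"
        return s


def provesti_distance(
    a: Sequence[str], b: Sequence[str], mode: str = "literal"
) -> float:
    """Proportion of compared columns at which two state vectors differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    compared = mismatch = 0
    for x, y in zip(a, b):
        if x in MISSING_STATES or y in MISSING_STATES:
            continue
        compared += 1
        if mode == "overlap":
            if not (state_set(x) & state_set(y)):
                mismatch += 1
        elif x != y:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return mismatch / compared


def event_distance(
    a: Sequence[str], b: Sequence[str], condensed: CondensedMatrix
) -> EventDistance:
    """Differing characters between two rows of a condensed matrix, split into
    substitutions and indel events (homopolymer-attached ones counted apart).

    Pass rows from a matrix condensed with ``exclude_homopolymer=False`` so
    the homopolymer-attached events are present to be counted.
    """
    a, b = tuple(a), tuple(b)
    if not len(a) == len(b) == len(condensed.columns):
        raise ValueError("vectors must match the condensed matrix columns")
    subs = indels = homo = 0
    for col, x, y in zip(condensed.columns, a, b):
        if x == y:
            continue
        if col.kind == "substitution":
            subs += 1
        else:
            indels += 1
            if col.event is not None and col.event.homopolymer_attached:
                homo += 1
    return EventDistance(substitutions=subs, indel_events=indels,
                         homopolymer_attached=homo)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.nanmax(np.abs(np.diag(v))) > 0:
            raise ValueError("diagonal must be zero")
        finite = v[np.isfinite(v)]
        if finite.size and finite.min() < 0:
            raise ValueError("distances must be nonnegative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="type")
        return path


def pairwise_matrix(cat: TypeCatalog, metric: str = "provesti") -> DistanceMatrix:
    """Symmetric distance matrix over all catalog types."""
    names = list(cat.types)
    if len(names) < 2:
        raise ValueError("need at least two types")
    n = len(names)
    values = np.zeros((n, n))
    cols = None
    if metric == "events_total":
        cols = CondensedMatrix(columns=cat.columns,
                               rows={nm: cat.types[nm].states for nm in names},
                               excluded_columns=frozenset())
    for i, j in itertools.combinations(range(n), 2):
        a, b = cat.types[names[i]].states, cat.types[names[j]].states
        if metric == "provesti":
            d = provesti_distance(a, b)
        elif metric == "events_total":
            d = event_distance(a, b, cols).total
        else:
            raise ValueError(f"unknown metric {metric!r}")
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=names, values=values)


def build_msn(
    d: DistanceMatrix,
    sizes: Mapping[str, int] | None = None,
    species: Mapping[str, Mapping[str, int]] | None = None,
    edge_labels: Mapping[tuple[str, str], EventDistance] | None = None,
) -> nx.Graph:
    """Minimum spanning network with tied alternative edges.

    Edges are scanned in ascending weight.  Within one weight class, an edge
    joining two components that were separate *before the class started* is
    kept: the ones that still merge components are primary (they form a
    spanning tree per connected component), the rest are alternatives — they
    tie the threshold at which their endpoints' components merged.  Infinite
    distances disconnect the graph; a warning is issued and per-component
    networks are returned in one graph.
    """
    labels = d.labels
    g = nx.Graph()
    for name in labels:
        g.add_node(name, size=int(sizes.get(name, 1)) if sizes else 1)
        if species and name in species:
            g.nodes[name]["species"] = ",".join(
                f"{sp}:{n}" for sp, n in sorted(species[name].items())
            )
    edges = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        w = d.values[i, j]
        if np.isfinite(w):
            edges.append((w, labels[i], labels[j]))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    parent = {name: name for name in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for w, batch in itertools.groupby(edges, key=lambda e: e[0]):
        batch = list(batch)
        before = {name: find(name) for name in labels}
        for _, a, b in batch:
            if before[a] == before[b]:
                continue  # connected at a strictly smaller weight: no edge
            ra, rb = find(a), find(b)
            alternative = ra == rb  # merged within this same weight class
            if not alternative:
                parent[ra] = rb
            attrs = {"weight": float(w), "alternative": alternative}
            if edge_labels is not None:
                lab = edge_labels.get((a, b)) or edge_labels.get((b, a))
                if lab is not None:
                    attrs["label"] = str(lab)
                    attrs["substitutions"] = lab.substitutions
                    attrs["indel_events"] = lab.indel_events
                    attrs["homopolymer_indels"] = lab.homopolymer_attached
            g.add_edge(a, b, **attrs)

    n_comp = nx.number_connected_components(g) if len(g) else 0
    if n_comp > 1:
        warnings.warn(
            f"distance graph is disconnected: {n_comp} component-wise networks",
            stacklevel=2,
        )
    return g


def primary_tree(net: nx.Graph) -> nx.Graph:
    """Subgraph of primary (non-alternative) edges."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes(data=True))
    g.add_edges_from(
        (a, b, attrs) for a, b, attrs in net.edges(data=True)
        if not attrs.get("alternative", False)
    )
    return g


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Lossless attribute export to GraphML or DOT."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("graph haplonet {\n")
            for node, attrs in net.nodes(data=True):
                opts = [f'size="{attrs.get("size", 1)}"']
                if "species" in attrs:
                    opts.append(f'species="{attrs["species"]}"')
                fh.write(f'  "{node}" [{", ".join(opts)}];\n')
            for a, b, attrs in net.edges(data=True):
                opts = [f'weight="{attrs["weight"]}"',
                        f'alternative="{str(attrs.get("alternative", False)).lower()}"']
                if "label" in attrs:
                    opts.append(f'label="{attrs["label"]}"')
                if attrs.get("alternative"):
                    opts.append('style="dashed"')
                fh.write(f'  "{a}" -- "{b}" [{", ".join(opts)}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
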