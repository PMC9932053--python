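"""Directed body-part coupling graphs from delay-aligned partial correlations.

Edges carry the shift-maximized partial correlation (strength) and the
maximizing shift (delay).  Direction is a pure function of the delay
sign — the leading series is the source ("the cause precedes the
response"); zero-delay pairs are kept as undirected edges.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .errors import IncompleteGraphError, ParameterError

__all__ = ["build_graph", "compare_graphs", "export_graph", "read_graph"]

DEFAULT_MIDPOINT = "midpoint"


def build_graph(
    labels: list[str],
    strengths: np.ndarray,
    delays: np.ndarray,
    scale_frames: int,
    fps: float = 30.0,
    midpoint: str = DEFAULT_MIDPOINT,
) -> nx.DiGraph:
    """Assemble the interaction graph at one scale.

    Parameters
    ----------
    labels : node labels (body parts or part:axis series).
    strengths : symmetric (m, m) matrix of shift-maximized couplings.
    delays : antisymmetric (m, m) matrix of delays in frames;
        ``delays[i, j] > 0`` means node i leads node j.
    scale_frames : the analysis scale s in frames.
    midpoint : label whose edges are flagged as the network backbone.

    Edge attributes: ``strength``, ``delay_s`` (>= 0, seconds between
    source and target), ``scale_s``, ``directed`` (False for zero-delay
    pairs, which are emitted source = lower label index), ``backbone``.
    """
    strengths = np.asarray(strengths, dtype=float)
    delays = np.asarray(delays)
    m = len(labels)
    if strengths.shape != (m, m) or delays.shape != (m, m):
        raise ParameterError("strength/delay matrices must be (m, m)")
    missing = [
        (labels[i], labels[j])
        for i in range(m)
        for j in range(i + 1, m)
        if not np.isfinite(strengths[i, j])
    ]
    if missing:
        raise IncompleteGraphError(
            f"couplings missing for pairs: {missing}"
        )
    g = nx.DiGraph(scale_frames=int(scale_frames), scale_s=scale_frames / fps, fps=fps)
    g.add_nodes_from(labels)
    for i in range(m):
        for j in range(i + 1, m):
            t = int(delays[i, j])
            if t >= 0:
                src, dst = i, j
            else:
                src, dst = j, i
            base = {labels[i].split(":")[0], labels[j].split(":")[0]}
            g.add_edge(
                labels[src],
                labels[dst],
                strength=float(strengths[i, j]),
                delay_s=abs(t) / fps,
                scale_s=scale_frames / fps,
                directed=t != 0,
                backbone=midpoint in base and len(base) == 2,
            )
    return g


def _edge_table(graphs) -> pd.DataFrame:
    """Canonical per-pair (unordered) edge records of one or more graphs."""
    if isinstance(graphs, nx.DiGraph):
        graphs = [graphs]
    rows = []
    for gi, g in enumerate(graphs):
        for u, v, attrs in g.edges(data=True):
            a, b = sorted((u, v))
            # signed delay in the canonical (a, b) orientation
            t = attrs["delay_s"] if u == a else -attrs["delay_s"]
            rows.append(
                dict(graph=gi, node_a=a, node_b=b, delay_s=t, strength=attrs["strength"])
            )
    return pd.DataFrame(rows)


def compare_graphs(graphs_a, graphs_b) -> pd.DataFrame:
    """Per-edge delay and strength differences between two groups.

    Each argument is a graph or a list of graphs over the same node set
    and scale.  Delays are compared in the canonical orientation of each
    unordered pair; differences are group-a median minus group-b median.
    No significance is attached.
    """
    ta, tb = _edge_table(graphs_a), _edge_table(graphs_b)
    if ta.empty or tb.empty:
        raise ParameterError("both groups need at least one graph with edges")
    nodes_a = set(ta["node_a"]) | set(ta["node_b"])
    nodes_b = set(tb["node_a"]) | set(tb["node_b"])
    if nodes_a != nodes_b:
        raise ParameterError(
            f"graphs cover different node sets: {sorted(nodes_a ^ nodes_b)}"
        )
    ma = ta.groupby(["node_a", "node_b"])[["delay_s", "strength"]].median()
    mb = tb.groupby(["node_a", "node_b"])[["delay_s", "strength"]].median()
    joined = ma.join(mb, lsuffix="_a", rsuffix="_b", how="outer")
    joined["delta_delay_s"] = joined["delay_s_a"] - joined["delay_s_b"]
    joined["delta_strength"] = joined["strength_a"] - joined["strength_b"]
    return joined.reset_index()


def export_graph(g: nx.DiGraph, path, fmt: str = "graphml") -> None:
    """Write a coupling graph as GraphML or flat edge-list CSV."""
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "csv":
        rows = [
            dict(
                src=u,
                dst=v,
                directed=attrs["directed"],
                strength=attrs["strength"],
                delay_s=attrs["delay_s"],
                scale_s=attrs["scale_s"],
                backbone=attrs.get("backbone", False),
            )
            for u, v, attrs in g.edges(data=True)
        ]
        pd.DataFrame(
            rows,
            columns=["src", "dst", "directed", "strength", "delay_s", "scale_s", "backbone"],
        ).to_csv(path, index=False)
    else:
        raise ParameterError(f"unknown graph format {fmt!r}")


def read_graph(path, fmt: str = "graphml") -> nx.DiGraph:
    """Read a graph written by :func:`export_graph`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        g = nx.DiGraph()
        for _, row in df.iterrows():
            g.add_edge(
                row["src"],
                row["dst"],
                directed=bool(row["directed"]),
                strength=float(row["strength"]),
                delay_s=float(row["delay_s"]),
                scale_s=float(row["scale_s"]),
                backbone=bool(row.get("backbone", False)),
            )
        return g
    raise ParameterError(f"unknown graph format {fmt!r}")
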