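"""PPI graph parsing, degree topology and degree-weighted network effects.

A protein's degree in a high-confidence PPI network is used as a crude but
effective proxy for its leverage over the cellular machinery: binding a hub
perturbs more of the interactome than binding a peripheral node.  The
*network-effect* score of a (compound, protein) pair is therefore the
compound's rank-normalised docking score at that protein multiplied by the
protein's node degree — hub bindings are amplified, isolated proteins
contribute nothing.

Supported edge-list formats:

* ``string_tsv`` — STRING database export with columns
  ``protein1 protein2 combined_score`` (whitespace- or tab-separated).
  STRING stores combined scores x1000 (0-1000); they are divided by 1000 on
  read so ``min_confidence=0.7`` matches STRING's "high confidence" 700.
* ``sif`` — Cytoscape SIF, ``A <interaction> B [C ...]`` (no confidence).
* ``tsv2col`` — plain two-column pairs, optional third column = confidence
  already on the 0-1 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .docking import RankMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkEffectMatrix",
    "read_ppi",
    "node_degrees",
    "betweenness",
    "network_effect",
    "write_sif",
    "read_degree_table",
    "write_degree_table",
]


def _iter_edges_string_tsv(lines, path):
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        if not header_seen and parts[:2] == ["protein1", "protein2"]:
            header_seen = True
            continue
        if len(parts) < 3:
            yield lineno, None
            continue
        a, b, raw_score = parts[0], parts[1], parts[2]
        try:
            score = float(raw_score)
        except ValueError:
            yield lineno, None
            continue
        conf = score / 1000.0 if score > 1.0 else score
        if not 0.0 <= conf <= 1.0:
            yield lineno, None
            continue
        yield lineno, (a, b, conf)


def _iter_edges_sif(lines, path):
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 1:
            # lone node line: SIF allows isolated nodes
            yield lineno, (parts[0], None, None)
            continue
        if len(parts) < 3:
            yield lineno, None
            continue
        src, targets = parts[0], parts[2:]
        for t in targets:
            yield lineno, (src, t, None)


def _iter_edges_tsv2col(lines, path):
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        if len(parts) < 2:
            yield lineno, None
            continue
        conf = None
        if len(parts) >= 3:
            try:
                conf = float(parts[2])
            except ValueError:
                yield lineno, None
                continue
            if not 0.0 <= conf <= 1.0:
                yield lineno, None
                continue
        yield lineno, (parts[0], parts[1], conf)


_FORMAT_PARSERS = {
    "string_tsv": _iter_edges_string_tsv,
    "sif": _iter_edges_sif,
    "tsv2col": _iter_edges_tsv2col,
}


def read_ppi(
    path: str | Path,
    format: str = "string_tsv",
    min_confidence: float = 0.7,
    nodes_path: str | Path | None = None,
    strict: bool = False,
) -> nx.Graph:
    """Parse a PPI edge list into an undirected simple graph.

    Edges with confidence below ``min_confidence`` are dropped (formats
    without confidence keep all edges); duplicates and self-loops are removed
    with a logged count.  The node set is the endpoints of surviving edges,
    plus self-loop endpoints, plus any symbols in the optional node-list file.
    Edge attribute ``confidence`` holds the 0-1 score where available.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such PPI file: {path}")
    if format not in _FORMAT_PARSERS:
        raise ValueError(f"unknown PPI format {format!r}")

    g = nx.Graph()
    n_dupes = n_selfloops = n_filtered = n_malformed = 0
    for lineno, edge in _FORMAT_PARSERS[format](path.read_text().splitlines(), path):
        if edge is None:
            msg = f"{path}:{lineno}: malformed line"
            if strict:
                raise ValueError(msg)
            logger.warning("skipping %s", msg)
            n_malformed += 1
            continue
        a, b, conf = edge
        if b is None:  # lone node
            g.add_node(a)
            continue
        if a == b:
            n_selfloops += 1
            g.add_node(a)  # node retained, loop dropped
            continue
        if conf is not None and conf < min_confidence:
            n_filtered += 1
            continue
        if g.has_edge(a, b):
            n_dupes += 1
            continue
        if conf is None:
            g.add_edge(a, b)
        else:
            g.add_edge(a, b, confidence=conf)

    if nodes_path is not None:
        for raw in Path(nodes_path).read_text().splitlines():
            sym = raw.strip()
            if sym and not sym.startswith("#"):
                g.add_node(sym)

    logger.info(
        "read PPI %s: %d nodes, %d edges (dropped %d below confidence %.2f, "
        "%d duplicates, %d self-loops, %d malformed lines)",
        path, g.number_of_nodes(), g.number_of_edges(),
        n_filtered, min_confidence, n_dupes, n_selfloops, n_malformed,
    )
    return g


def node_degrees(g: nx.Graph) -> pd.Series:
    """Degree of every node (0 for isolated nodes), as an int Series."""
    deg = pd.Series(dict(g.degree()), dtype="int64", name="degree")
    deg.index.name = "protein_id"
    return deg.sort_index()


def betweenness(g: nx.Graph) -> pd.Series:
    """Betweenness centrality per node. Report-only: never enters the
    network-effect score."""
    bc = pd.Series(nx.betweenness_centrality(g), dtype=float, name="betweenness")
    bc.index.name = "protein_id"
    return bc.sort_index()


@dataclass
class NetworkEffectMatrix:
    """Compound x protein matrix of rank x degree network-effect scores."""

    effects: pd.DataFrame
    degrees: pd.Series  # degree actually applied per retained protein column

    @property
    def compound_ids(self) -> list[str]:
        return list(self.effects.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.effects.columns)

    def to_csv(self, path: str | Path) -> None:
        self.effects.to_csv(path, index_label="compound_id", na_rep="NA")


def network_effect(
    ranks: RankMatrix,
    degrees: pd.Series | dict,
    missing_protein_policy: str = "zero",
) -> NetworkEffectMatrix:
    """Multiply each protein's rank column by that protein's PPI degree.

    Proteins absent from the degree table are handled per
    ``missing_protein_policy``: ``zero`` assigns degree 0 (no PPI evidence =
    no network leverage, the default), ``drop`` removes the column, ``error``
    fails naming the proteins.  Either way the absentees are logged.
    """
    if missing_protein_policy not in {"zero", "drop", "error"}:
        raise ValueError(f"unknown missing_protein_policy {missing_protein_policy!r}")
    deg = pd.Series(degrees, dtype=float)
    df = ranks.ranks
    present = [p for p in df.columns if p in deg.index]
    absent = [p for p in df.columns if p not in deg.index]
    if not present:
        raise ValueError("no protein id of the rank matrix appears in the degree table")
    if absent:
        logger.warning(
            "%d protein(s) missing from degree table (policy=%s): %s",
            len(absent), missing_protein_policy, absent,
        )
        if missing_protein_policy == "error":
            raise ValueError(f"proteins missing from degree table: {absent}")
    if missing_protein_policy == "drop":
        df = df[present]
    applied = deg.reindex(df.columns).fillna(0.0)
    effects = df.mul(applied, axis=1)
    return NetworkEffectMatrix(effects=effects, degrees=applied)


def write_sif(g: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    """Echo a graph as SIF (isolated nodes as lone-node lines)."""
    with open(path, "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for n in sorted(g.nodes()):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")


def write_degree_table(deg: pd.Series, path: str | Path) -> None:
    deg.to_csv(path, header=True)


def read_degree_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    s.name = "degree"
    s.index.name = "protein_id"
    return s
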