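"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the MCS oracle
exhaustively enumerates connected common edge-subgraphs via networkx
monomorphism tests (no RDKit MCS machinery), and the network-effect oracle
is an explicit double loop.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism
from rdkit import Chem


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), element=a.GetAtomicNum())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                   order=b.GetBondTypeAsDouble())
    return g


def brute_force_mcs_atoms(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Heavy-atom count of the maximum common connected subgraph.

    Enumerates every connected edge-subgraph of the molecule with fewer
    bonds (largest atom count first) and returns the first that maps
    injectively into the other molecule with matching elements and exact
    bond orders.  A shared element with no shared bond counts as a 1-atom
    common subgraph.  Exponential in bond count: fixture molecules must stay
    small (<= 8 heavy atoms).
    """
    ga, gb = mol_graph(mol_a), mol_graph(mol_b)
    if ga.number_of_edges() > gb.number_of_edges():
        ga, gb = gb, ga
    ea = {d["element"] for _, d in ga.nodes(data=True)}
    eb = {d["element"] for _, d in gb.nodes(data=True)}
    best = 1 if ea & eb else 0
    bonds = list(ga.edges())
    candidates = []
    for r in range(1, len(bonds) + 1):
        for sub in itertools.combinations(bonds, r):
            h = ga.edge_subgraph(sub)
            if nx.is_connected(h):
                candidates.append((h.number_of_nodes(), sub))
    candidates.sort(key=lambda t: -t[0])
    node_match = isomorphism.categorical_node_match("element", None)
    edge_match = isomorphism.categorical_edge_match("order", None)
    for n_atoms, sub in candidates:
        if n_atoms <= best:
            break
        h = ga.edge_subgraph(sub)
        gm = isomorphism.GraphMatcher(gb, h, node_match=node_match,
                                      edge_match=edge_match)
        if gm.subgraph_is_monomorphic():
            best = n_atoms
    return best


def double_loop_network_effect(ranks: np.ndarray, degrees: np.ndarray) -> np.ndarray:
    """Cell-by-cell rank x degree product, the slow obvious way."""
    n, p = ranks.shape
    out = np.empty((n, p))
    for i in range(n):
        for j in range(p):
            out[i, j] = ranks[i, j] * degrees[j]
    return out
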