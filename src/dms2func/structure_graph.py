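"""Residue contact graphs and the four baseline control graphs.

A structure graph has one node per residue and an edge between residues whose
beta carbons (alpha carbon for glycine) are within a distance threshold.
Baseline graphs (shuffled, disconnected, sequential, complete) deliberately
discard structural information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from dms2func.sequence_data import WildType

GRAPH_KINDS = ("contact", "shuffled", "disconnected", "sequential", "complete")


@dataclass
class StructureGraph:
    """Undirected residue graph with L nodes labelled 0..L-1."""

    graph: nx.Graph
    kind: str = "contact"

    def __post_init__(self) -> None:
        if self.kind not in GRAPH_KINDS:
            raise ValueError(f"unknown graph kind {self.kind!r}")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("structure graph must not contain self-loops")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        return nx.to_numpy_array(self.graph, nodelist=range(self.n_nodes))

    def norm_adjacency(self) -> np.ndarray:
        """Row-normalized adjacency used for neighbor averaging.

        Rows of degree-0 nodes are all zero, so isolated nodes receive no
        neighbor signal.
        """
        A = self.adjacency()
        deg = A.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            N = np.where(deg > 0, A / deg, 0.0)
        return N

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree)


def residue_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (angstroms) between residue coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must be an (L, 3) array")
    if not np.isfinite(coords).all():
        bad = sorted(set(np.argwhere(~np.isfinite(coords))[:, 0].tolist()))
        raise ValueError(f"missing/non-finite coordinates for residues {bad}")
    return squareform(pdist(coords))


def build_contact_graph(coords: np.ndarray, threshold_angstrom: float) -> StructureGraph:
    """Edges between residues within ``threshold_angstrom`` (closed threshold)."""
    if threshold_angstrom <= 0:
        raise ValueError("threshold must be positive")
    D = residue_distance_matrix(coords)
    L = D.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(L))
    ii, jj = np.nonzero(np.triu(D <= threshold_angstrom, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return StructureGraph(g, kind="contact")


def baseline_graph(
    kind: str,
    L: int,
    seed: int | None = None,
    reference: StructureGraph | None = None,
) -> StructureGraph:
    """One of the four control graphs: shuffled, disconnected, sequential, complete."""
    if kind == "disconnected":
        g = nx.empty_graph(L)
    elif kind == "sequential":
        g = nx.path_graph(L)
    elif kind == "complete":
        g = nx.complete_graph(L)
    elif kind == "shuffled":
        if reference is None:
            raise ValueError("shuffled baseline requires a reference graph")
        if reference.n_nodes != L:
            raise ValueError("reference graph node count differs from L")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(L)
        g = nx.relabel_nodes(
            reference.graph, {i: int(perm[i]) for i in range(L)}, copy=True
        )
        g.add_nodes_from(range(L))
    else:
        raise ValueError(f"unknown baseline graph kind {kind!r}")
    return StructureGraph(g, kind=kind)


def coords_from_pdb(
    path: str | Path, chain: str = "A", wt: WildType | None = None
) -> np.ndarray:
    """Extract per-residue Cb coordinates (Ca for glycine) from a PDB chain.

    Residues are taken in chain order after filtering heteroatoms / waters.
    With a wild type given, the extracted residue letters must match its
    sequence exactly; mismatches raise rather than silently renumbering.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa
    from Bio.SeqUtils import seq1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(iter(structure))
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not found in {path}")
    coords, letters = [], []
    for res in model[chain]:
        if not is_aa(res, standard=True):
            continue
        atom = res["CB"] if "CB" in res else res["CA"]
        coords.append(atom.coord)
        letters.append(seq1(res.get_resname()))
    coords_arr = np.asarray(coords, dtype=float)
    if wt is not None:
        got = "".join(letters)
        if got != wt.sequence:
            raise ValueError(
                f"PDB chain sequence does not match wild type:\n  pdb: {got}\n  wt:  {wt.sequence}"
            )
    return coords_arr


def write_edge_list(g: StructureGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={g.kind} nodes={g.n_nodes}\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> StructureGraph:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(item.split("=") for item in header.lstrip("# ").split())
        L = int(meta["nodes"])
        kind = meta.get("kind", "contact")
        g = nx.Graph()
        g.add_nodes_from(range(L))
        for line in fh:
            if line.strip():
                u, v = map(int, line.split())
                g.add_edge(u, v)
    return StructureGraph(g, kind=kind)
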