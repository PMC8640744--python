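"""Independent oracle implementations shared by test modules."""

import networkx as nx
import numpy as np

from dms2func import structure_graph as sg


def random_graph(L, p, rng):
    g = nx.gnp_random_graph(L, p, seed=int(rng.integers(2**31)))
    g.add_nodes_from(range(L))
    return sg.StructureGraph(g, kind="contact")


def naive_graph_conv(X, graph, W_C, W_N, b):
    """Per-node loop oracle for the graph convolution operator."""
    L = X.shape[0]
    out = np.zeros((L, W_C.shape[1]))
    adj = graph.adjacency()
    for i in range(L):
        z = W_C.T @ X[i] + b
        nbrs = np.nonzero(adj[i])[0]
        if len(nbrs):
            z = z + np.mean([W_N.T @ X[j] for j in nbrs], axis=0)
        out[i] = z
    return out
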