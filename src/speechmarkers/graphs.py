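"""Word-trajectory speech graphs and connectivity measures.

Each unique word of a response is a node; a directed edge links every pair
of consecutively spoken words (the sequence runs across sentence
boundaries; stopwords are retained by default). Connectivity is summarised
by the node count of the largest weakly connected component (LCC) and the
largest strongly connected component (LSC). Because both scale with how
often words recur, they are also reported normalised against graphs built
from uniformly shuffled word sequences: LCCr = LCC / mean(shuffled LCC),
and analogously LSCr (ratios near 1 mean connectivity is what word
repetition alone would produce).

Component sizes are computed with scipy's compiled connected-components
(weak and strong), which keeps the default 1000-shuffle normalisation fast;
:func:`to_networkx` exports the graph object for inspection or GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_N_SHUFFLES = 1000


@dataclass(frozen=True)
class SpeechGraph:
    """Directed word-adjacency graph of one response."""

    words: tuple[str, ...]  # node labels, index = node id
    edges: tuple[tuple[int, int], ...]  # distinct directed pairs
    sequence_length: int

    @property
    def n_nodes(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class SpeechGraphMetrics:
    lcc: int
    lsc: int
    lccr: float
    lscr: float
    n_shuffles: int
    seed: Optional[int]


def _encode(word_sequence: Sequence[str]) -> np.ndarray:
    if len(word_sequence) == 0:
        raise ValueError("empty word sequence")
    _, codes = np.unique(np.asarray(word_sequence, dtype=object), return_inverse=True)
    return codes


def build_speech_graph(word_sequence: Sequence[str]) -> SpeechGraph:
    """Build the directed graph of consecutive-word transitions."""
    seq = list(word_sequence)
    if not seq:
        raise ValueError("empty word sequence")
    uniq = list(dict.fromkeys(seq))  # first-occurrence order
    index = {w: i for i, w in enumerate(uniq)}
    edges = {(index[a], index[b]) for a, b in zip(seq, seq[1:])}
    return SpeechGraph(
        words=tuple(uniq),
        edges=tuple(sorted(edges)),
        sequence_length=len(seq),
    )


def _component_sizes(codes: np.ndarray) -> tuple[int, int]:
    """(LCC, LSC) for the transition graph of an integer-coded sequence."""
    n = int(codes.max()) + 1
    if len(codes) == 1:
        return 1, 1
    src, dst = codes[:-1], codes[1:]
    data = np.ones(len(src), dtype=np.int8)
    adj = coo_matrix((data, (src, dst)), shape=(n, n))
    _, weak = connected_components(adj, directed=True, connection="weak")
    _, strong = connected_components(adj, directed=True, connection="strong")
    lcc = int(np.bincount(weak).max())
    lsc = int(np.bincount(strong).max())
    return lcc, lsc


def connectivity(graph: SpeechGraph | Sequence[str]) -> tuple[int, int]:
    """(LCC, LSC): node counts of the largest weak / strong components."""
    if isinstance(graph, SpeechGraph):
        n = graph.n_nodes
        if not graph.edges:
            return 1, 1
        src, dst = zip(*graph.edges)
        adj = coo_matrix(
            (np.ones(len(src), dtype=np.int8), (src, dst)), shape=(n, n)
        )
        _, weak = connected_components(adj, directed=True, connection="weak")
        _, strong = connected_components(adj, directed=True, connection="strong")
        return int(np.bincount(weak).max()), int(np.bincount(strong).max())
    return _component_sizes(_encode(graph))


def normalized_connectivity(
    word_sequence: Sequence[str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: Optional[int | np.random.Generator] = None,
) -> SpeechGraphMetrics:
    """LCC/LSC plus their ratios to the mean over shuffled sequences.

    Shuffles are uniform permutations of the word multiset, graphed with the
    same construction rule. ``seed`` (an int or a Generator) fixes the
    permutation stream for reproducibility.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    codes = _encode(word_sequence)
    lcc, lsc = _component_sizes(codes)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lccs = np.empty(n_shuffles)
    lscs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(codes)
        lccs[k], lscs[k] = _component_sizes(shuffled)
    seed_out = seed if isinstance(seed, int) else None
    return SpeechGraphMetrics(
        lcc=lcc,
        lsc=lsc,
        lccr=lcc / float(lccs.mean()),
        lscr=lsc / float(lscs.mean()),
        n_shuffles=n_shuffles,
        seed=seed_out,
    )


def to_networkx(graph: SpeechGraph):
    """Export as a networkx DiGraph (node labels = words)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(graph.words)
    g.add_edges_from(
        (graph.words[a], graph.words[b]) for a, b in graph.edges
    )
    return g
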