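"""Speech-graph connectivity of a word sequence.

Builds the directed word-trajectory graph of a short response and prints
LCC/LSC with their shuffle-normalised ratios.
"""

from speechmarkers import build_speech_graph, connectivity, normalized_connectivity

words = "the cat sat on the mat then the cat ran to the mat again".split()
graph = build_speech_graph(words)
lcc, lsc = connectivity(graph)
metrics = normalized_connectivity(words, n_shuffles=1000, seed=0)

print(f"sequence length: {len(words)} tokens, {graph.n_nodes} unique words")
print(f"LCC  = {lcc}  (largest weakly connected component, nodes)")
print(f"LSC  = {lsc}  (largest strongly connected component, nodes)")
print(f"LCCr = {metrics.lccr:.3f}  (ratio to mean over 1000 shuffled sequences)")
print(f"LSCr = {metrics.lscr:.3f}")
print()
print("Recurring words ('the', 'cat', 'mat') create directed cycles, so most")
print("words sit in one strongly connected component; ratios near 1 mean the")
print("observed connectivity is what this word multiset produces in any order.")
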