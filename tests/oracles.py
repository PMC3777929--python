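"""Independent reference implementations used as oracles by the tests.

These deliberately avoid the package's vectorized code paths: subgraph
enumeration via itertools + networkx, probabilities via Counter
arithmetic.
"""

import itertools
from collections import Counter

import networkx as nx

import cranesig as cs


def oracle_best_mi(graph, binarized, labels, d_max):
    """Maximum plug-in I(C;F) over every connected subset of <= d_max nodes."""
    samples = labels.samples
    y = [labels.labels[s] for s in samples]
    n = len(samples)
    p_c = Counter(y)
    h_c = cs.entropy([p_c["STS"] / n, p_c["LTS"] / n])
    # gene -> sample -> H/L char, read once
    chars = {
        g: {s: binarized.state_char(g, s) for s in samples}
        for g in binarized.gene_ids
    }
    best = 0.0
    nodes = sorted(graph.nodes)
    for size in range(1, d_max + 1):
        for combo in itertools.combinations(nodes, size):
            if size > 1 and not nx.is_connected(graph.subgraph(combo)):
                continue
            strings = ["".join(chars[g][s] for g in combo) for s in samples]
            h_cond = 0.0
            for state, cnt in Counter(strings).items():
                joint = Counter(c for st, c in zip(strings, y) if st == state)
                h_cond += (cnt / n) * cs.entropy(
                    [joint["STS"] / cnt, joint["LTS"] / cnt]
                )
            best = max(best, h_c - h_cond)
    return best
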