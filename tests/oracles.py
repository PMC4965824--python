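"""Independent brute-force oracles shared across test modules.

Deliberately naive (explicit loops, dict-of-dict distances) so they stay
independent of the vectorized implementation paths they check.
"""

import numpy as np
import pandas as pd


def path_distance(tree, a, b):
    """Tip-to-tip distance via the lowest common ancestor."""
    ta = tree.find(a)
    tb = tree.find(b)
    lca = tree.lowest_common_ancestor([ta, tb])
    return ta.accumulate_to_ancestor(lca) + tb.accumulate_to_ancestor(lca)


def beta_mntd_loops(f1, f2, taxa, dist):
    """Naive double-loop abundance-weighted betaMNTD."""
    present1 = [i for i, v in enumerate(f1) if v > 0]
    present2 = [i for i, v in enumerate(f2) if v > 0]
    w1 = np.asarray(f1, float) / np.sum(f1)
    w2 = np.asarray(f2, float) / np.sum(f2)
    term1 = sum(
        w1[i] * min(dist[taxa[i]][taxa[j]] for j in present2) for i in present1
    )
    term2 = sum(
        w2[i] * min(dist[taxa[i]][taxa[j]] for j in present1) for i in present2
    )
    return 0.5 * (term1 + term2)


def rel_abund_two_cherries(tree):
    """Three communities on a 4-tip tree: the two cherries and a mix."""
    from biofacies.turnover import cophenetic

    order = list(cophenetic(tree).ids)
    return pd.DataFrame(
        {
            "s1": [0.5 if t in ("A", "B") else 0.0 for t in order],
            "s2": [0.5 if t in ("C", "D") else 0.0 for t in order],
            "s3": [0.25, 0.25, 0.25, 0.25],
        },
        index=order,
    )
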