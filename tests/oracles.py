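"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, closures, per-gene
counting in plain Python) and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools


def efd_bruteforce(values, k=4):
    """Optimal monotone tie-respecting EFD by enumerating all cut points.

    Returns {value: bin}. Minimizes sum over bins of |count - n/k| (in
    k-scaled integer arithmetic); ties broken by the lexicographically
    smallest assignment in sorted-value order.
    """
    vals = sorted(values)
    n = len(vals)
    blocks = []
    for v in vals:
        if blocks and blocks[-1][0] == v:
            blocks[-1][1] += 1
        else:
            blocks.append([v, 1])
    m = len(blocks)
    best = None
    for cuts in itertools.combinations_with_replacement(range(m + 1), k - 1):
        bounds = (0,) + cuts + (m,)
        if any(b < a for a, b in zip(bounds, bounds[1:])):
            continue
        sizes = [sum(c for _, c in blocks[bounds[j]: bounds[j + 1]])
                 for j in range(k)]
        dev = sum(abs(k * s - n) for s in sizes)
        assign = []
        for j in range(k):
            assign += [j + 1] * sum(c for _, c in blocks[bounds[j]: bounds[j + 1]])
        key = (dev, tuple(assign))
        if best is None or key < best[0]:
            block_bins = {}
            for j in range(k):
                for b in range(bounds[j], bounds[j + 1]):
                    block_bins[blocks[b][0]] = j + 1
            best = (key, block_bins)
    return best[1]


def majority_oracle(state, edges, no_input="hold"):
    """One synchronous majority-rule step, counted gene by gene.

    ``edges``: iterable of (source, target, sign) with sign in
    {"activation", "inhibition"}.
    """
    nxt = {}
    for gene in state:
        a = sum(1 for s, t, sg in edges
                if t == gene and sg == "activation" and state[s] == 1)
        i = sum(1 for s, t, sg in edges
                if t == gene and sg == "inhibition" and state[s] == 1)
        if a > i:
            nxt[gene] = 1
        elif i > a or (a == i and a + i > 0):
            nxt[gene] = 0
        else:
            nxt[gene] = state[gene] if no_input == "hold" else 0
    return nxt


def consistency_oracle(states, edges):
    """Mean over states of the per-gene fraction reproduced by one update."""
    total = 0.0
    for state in states:
        nxt = majority_oracle(state, edges)
        total += sum(1 for g in state if nxt[g] == state[g]) / len(state)
    return total / len(states)


def exhaustive_contextualize(edges, states, removal_penalty=0.1):
    """Best fitness over all keep/remove x sign assignments.

    ``edges``: list of (source, target, sign) where sign may be
    "unassigned". Returns the maximal fitness (mean consistency minus
    removal_penalty * removed fraction).
    """
    n_edges = len(edges)
    unassigned = [i for i, (_, _, sg) in enumerate(edges) if sg == "unassigned"]
    best = None
    for keep_bits in itertools.product((0, 1), repeat=n_edges):
        for sign_bits in itertools.product((0, 1), repeat=len(unassigned)):
            signs = [sg for _, _, sg in edges]
            for j, i in enumerate(unassigned):
                signs[i] = "activation" if sign_bits[j] else "inhibition"
            kept = [(s, t, signs[i]) for i, (s, t, _) in enumerate(edges)
                    if keep_bits[i]]
            fit = consistency_oracle(states, kept) \
                - removal_penalty * (n_edges - sum(keep_bits)) / n_edges
            if best is None or fit > best:
                best = fit
    return best


def reachability_sccs(nodes, arcs):
    """SCCs via transitive closure: u ~ v iff u reaches v and v reaches u."""
    reach = {u: {u} for u in nodes}
    changed = True
    while changed:
        changed = False
        for s, t in arcs:
            new = reach[t] - reach[s]
            if new:
                reach[s] |= new
                changed = True
    comps = []
    seen = set()
    for u in nodes:
        if u in seen:
            continue
        comp = frozenset(v for v in nodes if v in reach[u] and u in reach[v])
        comps.append(comp)
        seen |= comp
    return set(comps)


def bh_oracle(pvalues):
    """Step-up BH by the textbook rule."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj


def filter_oracle(results, qe_stem, qe_diff, baseline_q, scc, prior_pairs,
                  alpha=0.05, threshold=2):
    """Re-check every pair against the four candidate criteria.

    ``prior_pairs``: set of frozensets {g1, g2} with a direct edge.
    Returns the set of frozenset pairs that pass.
    """
    kept = set()
    for row in results.itertuples(index=False):
        if row.p_adj >= alpha:
            continue
        g1, g2 = row.gene1, row.gene2

        def up(g):
            return qe_diff[g] - baseline_q[g] >= threshold

        def down(g):
            return qe_stem[g] - baseline_q[g] <= -threshold

        c1 = up(g1) or up(g2)
        c2 = not (down(g1) or down(g2))
        linked = frozenset((g1, g2)) in prior_pairs
        c3 = g1 in scc and g2 in scc and linked
        c4 = ((g1 in scc) != (g2 in scc)) and linked
        if c1 and c2 and (c3 or c4):
            kept.add(frozenset((g1, g2)))
    return kept
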