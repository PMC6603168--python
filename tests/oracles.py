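"""Independent brute-force oracles used by the test suite.

These re-derive expected values by the most direct method available —
exhaustive dynamic programming, per-position tallies, transitive closure —
and never share code with the implementation paths they check.
"""

import itertools

import numpy as np


def semiglobal_score(ref: str, query: str, match=1, mismatch=-1, gap=-4) -> int:
    """Exhaustive semi-global alignment score (terminal gaps free)."""
    n, m = len(ref), len(query)
    neg = -10**9
    # dp[i][j]: best score of alignment consuming ref[:i], query[:j],
    # where terminal gaps cost nothing (handled by init and final max)
    dp = np.full((n + 1, m + 1), neg, dtype=np.int64)
    dp[0, :] = 0
    dp[:, 0] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == query[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + s,
                           dp[i - 1, j] + gap,
                           dp[i, j - 1] + gap)
    return int(max(dp[n, :].max(), dp[:, m].max()))


def consensus_tally(reads) -> str:
    """Quality-weighted per-position majority with N on ties (brute force)."""
    max_len = max(len(r.bases) for r in reads)
    out = []
    for pos in range(max_len):
        covered = [(r.bases[pos], float(r.qualities[pos]))
                   for r in reads if pos < len(r.bases)]
        if len(covered) < len(reads) / 2:
            break
        weights = {}
        for base, q in covered:
            weights[base] = weights.get(base, 0.0) + q
        best = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(best) > 1 and best[0][1] == best[1][1]:
            out.append("N")
        else:
            out.append(best[0][0])
    return "".join(out)


def transitive_clusters(seqs: list[str], threshold: float) -> list[frozenset]:
    """Single-linkage components by repeated merging (brute force)."""
    clusters = [{i} for i in range(len(seqs))]

    def linked(a, b):
        return any(
            sum(x != y for x, y in zip(seqs[i], seqs[j])) / len(seqs[i]) <= threshold
            for i in a for j in b
        )

    changed = True
    while changed:
        changed = False
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                if linked(clusters[x], clusters[y]):
                    clusters[x] |= clusters.pop(y)
                    changed = True
                    break
            if changed:
                break
    return [frozenset(c) for c in clusters]


def mst_total_length(seqs: list[str]) -> int:
    """Minimum spanning tree total weight under Hamming distance.

    Exhaustive over all spanning trees for ≤6 nodes, Prim's algorithm
    (written here, independent of the implementation) otherwise.
    """
    n = len(seqs)
    dist = [[sum(x != y for x, y in zip(seqs[i], seqs[j])) for j in range(n)]
            for i in range(n)]
    if n <= 1:
        return 0
    if n <= 6:
        best = None
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for combo in itertools.combinations(edges, n - 1):
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            ok = True
            for i, j in combo:
                ri, rj = find(i), find(j)
                if ri == rj:
                    ok = False
                    break
                parent[ri] = rj
            if ok:
                total = sum(dist[i][j] for i, j in combo)
                best = total if best is None else min(best, total)
        return best
    # Prim
    in_tree = {0}
    total = 0
    while len(in_tree) < n:
        best = min(
            (dist[i][j], j)
            for i in in_tree for j in range(n) if j not in in_tree
        )
        total += best[0]
        in_tree.add(best[1])
    return total
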