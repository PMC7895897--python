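"""Independent naive Markov Clustering used as a test oracle.

Written directly from the algorithm's published description with plain
column-by-column Python loops, no pruning and no shared code with the
package implementation, so the two can disagree where either is wrong.
"""

from typing import Dict, FrozenSet, List, Sequence


def naive_mcl(nodes: Sequence, edges: Sequence, inflation: float = 6.0,
              tol: float = 1e-8, max_iters: int = 200) -> List[FrozenSet]:
    nodes = list(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = [[0.0] * n for _ in range(n)]
    for a, b in edges:
        i, j = index[a], index[b]
        M[i][j] = M[j][i] = 1.0
    for i in range(n):
        M[i][i] = 1.0  # self-loop

    def col_normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s:
                for i in range(n):
                    mat[i][j] /= s

    col_normalize(M)
    for _ in range(max_iters):
        # expansion: matrix squaring
        E = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
             for i in range(n)]
        # inflation: entrywise power + column renormalization
        for i in range(n):
            for j in range(n):
                E[i][j] = E[i][j] ** inflation
        col_normalize(E)
        delta = max(abs(E[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = E
        if delta < tol:
            break

    # clusters: attractor rows and their supports; overlapping systems merged
    thresh = 1e-7
    member_sets = []
    for i in range(n):
        if M[i][i] > thresh:
            member_sets.append({j for j in range(n) if M[i][j] > thresh} | {i})
    parent: Dict[int, int] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in member_sets:
        first = min(s)
        for other in s:
            parent[find(other)] = find(first)
    groups: Dict[int, set] = {}
    for s in member_sets:
        for node in s:
            groups.setdefault(find(node), set()).add(node)
    clusters = [frozenset(nodes[i] for i in g) for g in groups.values()]
    claimed = set().union(*groups.values()) if groups else set()
    clusters += [frozenset({nodes[i]}) for i in range(n) if i not in claimed]
    return sorted(clusters, key=lambda c: (-len(c), sorted(map(str, c))))
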