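"""Independent oracles used to check the implementation from the outside.

Both oracles are deliberately written against different data structures
than the library (dict-of-dict sparse columns instead of dense numpy;
hand-rolled BFS path enumeration instead of Brandes accumulation), so an
agreement between the two routes is evidence, not tautology.
"""

from __future__ import annotations

from collections import deque


def oracle_mcl(
    edges: list[tuple[str, str, float]],
    nodes: list[str],
    inflation: float = 2.6,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[list[str]]:
    """Reference Markov clustering on sparse dict columns.

    Same mathematical recipe as the library (self-loops = max column
    weight, expansion power 2, absolute pruning that spares each column's
    maximum), but the clusters are read off as connected components of the
    converged matrix's nonzero structure.
    """
    nodes = sorted(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    cols: list[dict[int, float]] = [dict() for _ in range(n)]
    for a, b, w in edges:
        if a == b:
            continue
        i, j = idx[a], idx[b]
        cols[j][i] = max(cols[j].get(i, 0.0), w)
        cols[i][j] = max(cols[i].get(j, 0.0), w)
    for j in range(n):
        cols[j][j] = max(cols[j].values()) if cols[j] else 1.0

    def normalize(columns):
        out = []
        for c in columns:
            s = sum(c.values())
            out.append({i: v / s for i, v in c.items()})
        return out

    cols = normalize(cols)
    for _ in range(max_iter):
        expanded: list[dict[int, float]] = []
        for j in range(n):
            acc: dict[int, float] = {}
            for k, vkj in cols[j].items():
                for i, vik in cols[k].items():
                    acc[i] = acc.get(i, 0.0) + vik * vkj
            expanded.append(acc)
        for j in range(n):
            infl = {i: v**inflation for i, v in expanded[j].items()}
            mx = max(infl, key=infl.get)
            expanded[j] = {i: v for i, v in infl.items() if v >= prune or i == mx}
        expanded = normalize(expanded)
        diff = 0.0
        for j in range(n):
            for i in set(expanded[j]) | set(cols[j]):
                diff = max(diff, abs(expanded[j].get(i, 0.0) - cols[j].get(i, 0.0)))
        cols = expanded
        if diff < tol:
            break

    # clusters = connected components of the nonzero structure
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for j in range(n):
        for i, v in cols[j].items():
            if v > 1e-12 and i != j:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    clusters = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u] - comp:
                comp.add(v)
                queue.append(v)
        seen |= comp
        clusters.append(sorted(nodes[i] for i in comp))
    return sorted(clusters)


def brute_force_betweenness(edges: list[tuple[str, str]], nodes: list[str]) -> dict[str, float]:
    """All-pairs shortest-path enumeration, normalized per component.

    For every ordered pair (s, t) all shortest paths are enumerated by
    BFS + recursive backtracking; each interior node collects its share.
    Feasible for graphs up to ~12 nodes.
    """
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def component(start: str) -> set[str]:
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u] - comp:
                comp.add(v)
                queue.append(v)
        return comp

    def all_shortest_paths(s: str, t: str) -> list[list[str]]:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        if t not in dist:
            return []
        paths: list[list[str]] = []

        def back(path: list[str]) -> None:
            head = path[-1]
            if head == s:
                paths.append(path[::-1])
                return
            for v in adj[head]:
                if dist.get(v, -1) == dist[head] - 1:
                    back(path + [v])

        back([t])
        return paths

    score = dict.fromkeys(nodes, 0.0)
    seen: set[str] = set()
    for start in nodes:
        if start in seen:
            continue
        comp = sorted(component(start))
        seen |= set(comp)
        n = len(comp)
        if n < 3:
            continue
        for i, s in enumerate(comp):
            for t in comp[i + 1 :]:
                paths = all_shortest_paths(s, t)
                for path in paths:
                    for v in path[1:-1]:
                        score[v] += 1.0 / len(paths)
        norm = (n - 1) * (n - 2) / 2.0
        for v in comp:
            score[v] /= norm
    return score
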