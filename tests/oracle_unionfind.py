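"""Independent grouping oracles for component tests.

Deliberately naive: a hand-rolled disjoint-set union over symmetrized edges,
and a brute-force reachability closure. Neither touches the graph library
used by the implementation.
"""


def union_find_partition(nodes, edges):
    """Partition nodes by connectivity under the symmetrized edge relation."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda g: min(str(m) for m in g))


def reachability_partition(nodes, edges):
    """Transitive closure of the symmetrized relation, by repeated sweeps."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    unseen = set(nodes)
    groups = []
    while unseen:
        start = unseen.pop()
        frontier, group = {start}, {start}
        while frontier:
            nxt = set()
            for node in frontier:
                nxt |= adj[node] - group
            group |= nxt
            frontier = nxt
        unseen -= group
        groups.append(group)
    return sorted(groups, key=lambda g: min(str(m) for m in g))
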