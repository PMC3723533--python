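"""Independent brute-force oracles for the parsimony reconstructions.

These enumerate every legal state assignment explicitly and never share code
with the dynamic-programming implementations they check.
"""

from itertools import product

from palinconv.model import PseudoGenotype

HOM_ANC = PseudoGenotype.HOM_ANC
HET = PseudoGenotype.HET
HOM_DER = PseudoGenotype.HOM_DER
INF = float("inf")

_COST = {
    (HOM_ANC, HOM_ANC): 0, (HET, HET): 0, (HOM_DER, HOM_DER): 0,
    (HET, HOM_ANC): 1, (HET, HOM_DER): 1,
}


def _edge_cost(a, b):
    return _COST.get((a, b), INF)


def _paths_to_root(tree, name):
    node = tree.nodes[tree.sample_map.get(name, name)] if name in tree.sample_map else tree.nodes[name]
    path = []
    while node is not None:
        path.append(node.name)
        node = node.parent
    if name in tree.sample_map:
        path.insert(0, name)  # sample pseudo-leaf below its haplogroup
    return path


def mrca_name(tree, names):
    """MRCA over samples/haplogroups by path intersection (independent)."""
    paths = [list(reversed(_paths_to_root(tree, n))) for n in names]
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        level = {p[depth] for p in paths}
        if len(level) == 1:
            mrca = level.pop()
        else:
            break
    return mrca


def _expanded_edges(tree):
    """(parent, child) name pairs of the haplogroup tree + sample leaves."""
    edges = []
    for node in tree.root.preorder():
        for child in node.children:
            edges.append((node.name, child.name))
    for sample, hg in tree.sample_map.items():
        edges.append((hg, sample))
    return edges


def min_events_bruteforce(tree, column):
    """Minimum conversion events by exhaustive enumeration.

    Places the mutation at the independent MRCA of derived carriers, then
    tries every assignment of {HOM_ANC, HET, HOM_DER} to all free nodes in
    the mutation clade (observed samples fixed), scoring with the directed
    transition costs.  Returns 0 when no chromosome carries a derived allele.
    """
    carriers = [s for s, g in column.items() if g.carries_derived]
    if not carriers:
        return 0
    mut = mrca_name(tree, carriers)

    edges = _expanded_edges(tree)
    # restrict to the clade below (and including) mut
    below = {mut}
    changed = True
    while changed:
        changed = False
        for p, c in edges:
            if p in below and c not in below:
                below.add(c)
                changed = True
    clade_edges = [(p, c) for p, c in edges if p in below]

    fixed = {
        s: g for s, g in column.items()
        if s in below and g.is_observed
    }
    free = sorted(below - set(fixed))
    states = (HOM_ANC, HET, HOM_DER)
    best = INF
    for combo in product(states, repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        total = _edge_cost(HET, assign[mut])
        if total is INF:
            continue
        for p, c in clade_edges:
            total += _edge_cost(assign[p], assign[c])
            if total == INF:
                break
        best = min(best, total)
    return int(best)


def min_flips_bruteforce(tree, orientations):
    """Minimum orientation flips by exhaustive binary enumeration."""
    from palinconv.phase import Orientation

    edges = _expanded_edges(tree)
    nodes = {n for e in edges for n in e} | {tree.root.name}
    fixed = {
        s: o for s, o in orientations.items()
        if o in (Orientation.SAME, Orientation.INVERTED)
    }
    free = sorted(nodes - set(fixed))
    best = INF
    for combo in product((Orientation.SAME, Orientation.INVERTED), repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        total = sum(assign[p] != assign[c] for p, c in edges)
        best = min(best, total)
    return int(best)
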