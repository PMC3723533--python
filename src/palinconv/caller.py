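"""Phylogeny-constrained minimum-event calling of gene conversions.

Each PSV is treated as a single-origin character on the haplogroup tree: the
0/0 -> 0/1 mutation is placed by maximum parsimony at the most recent common
ancestor of all chromosomes carrying the derived allele, and the minimum set
of conversion events (0/1 -> 0/0 or 0/1 -> 1/1) explaining the observed
pseudo-genotypes is found by dynamic programming over the tree with a
directed transition system:

* HET -> HET costs 0; HET -> HOM_ANC and HET -> HOM_DER cost 1 (a conversion);
* HOM states are absorbing (a pseudohomozygous lineage cannot regain the lost
  allele without recurrent mutation, which is neglected);
* HOM_ANC <-> HOM_DER is forbidden.

Samples mapping to the same leaf haplogroup hang off that leaf as a star
polytomy, which gives the same per-haplogroup minimum as any true (unknown)
substructure.  The minimum event count is invariant across equally
parsimonious reconstructions; event *placement* is tie-broken towards the
tips and flagged when ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .model import (
    GcClass,
    GenotypeMatrix,
    HaplogroupTree,
    Psv,
    PseudoGenotype,
    TreeNode,
    gc_class,
)

INF = math.inf

HOM_ANC = PseudoGenotype.HOM_ANC
HET = PseudoGenotype.HET
HOM_DER = PseudoGenotype.HOM_DER
DP_STATES = (HOM_ANC, HET, HOM_DER)


class NoDataError(ValueError):
    """Raised when a PSV column has no observed genotype at all."""


def transition_cost(parent: PseudoGenotype, child: PseudoGenotype) -> float:
    """Branch cost of the directed transition system (conversions cost 1)."""
    if parent == child:
        return 0.0
    if parent == HET and child in (HOM_ANC, HOM_DER):
        return 1.0
    return INF


@dataclass(frozen=True)
class ConversionEvent:
    psv_id: str
    parent: str
    child: str
    direction: str  # "to_ancestral" | "to_derived"
    gc: GcClass

    TO_ANCESTRAL = "to_ancestral"
    TO_DERIVED = "to_derived"


@dataclass
class PsvHistory:
    """Minimum-event reconstruction for one PSV.

    ``mutation_node`` is None for a PSV with no derived-allele carrier;
    ``node_states`` maps every haplogroup and sample to its reconstructed
    state (UNKNOWN only where nothing constrains an unsampled side clade is
    never needed here because nodes outside the mutation clade are HOM_ANC).
    ``ambiguous_placement`` is True when more than one equally parsimonious
    event placement exists; the event *count* is invariant regardless.
    """

    psv: Psv
    mutation_node: str | None
    node_states: dict[str, PseudoGenotype] = field(default_factory=dict)
    events: list[ConversionEvent] = field(default_factory=list)
    ambiguous_placement: bool = False
    clade_members: frozenset = frozenset()  # nodes at/below the mutation

    def lineage_converted(self, name: str, state: PseudoGenotype) -> bool:
        """True when a HOM state at *name* implies a conversion in its past.

        A pseudohomozygous chromosome inside the mutation clade must have
        lost an allele by conversion somewhere between the mutation and
        itself; outside the clade HOM_ANC is simply the pre-mutation state.
        """
        return (
            state in (HOM_ANC, HOM_DER)
            and self.mutation_node is not None
            and name in self.clade_members
        )

    @property
    def n_events(self) -> int:
        return len(self.events)

    def founder_state(self, haplogroup: str) -> PseudoGenotype:
        return self.node_states.get(haplogroup, HOM_ANC)


def _expanded_tree(tree: HaplogroupTree) -> TreeNode:
    """Copy of the haplogroup tree with sample pseudo-leaves attached.

    Each sample becomes a child of its leaf haplogroup (star polytomy).
    Sample node names are the sample ids; haplogroup node names are kept.
    """
    mapping: dict[str, TreeNode] = {}

    def copy(node: TreeNode) -> TreeNode:
        new = TreeNode(node.name, node.generations)
        mapping[node.name] = new
        for child in node.children:
            new.add_child(copy(child))
        return new

    root = copy(tree.root)
    for sample, hg in tree.sample_map.items():
        mapping[hg].add_child(TreeNode(sample))
    return root


def place_mutation(
    tree: HaplogroupTree, column: Mapping[str, PseudoGenotype]
) -> str | None:
    """Parsimony placement of a PSV's single-origin mutation.

    Returns the name of the most recent common ancestor (haplogroup or
    single sample) of all chromosomes carrying at least one derived allele,
    or None when no chromosome does.  Raises :class:`NoDataError` when the
    column is entirely MISSING/EXCLUDED.
    """
    observed = [s for s, g in column.items() if g.is_observed]
    if not observed:
        raise NoDataError("column has no observed genotypes")
    carriers = [s for s, g in column.items() if g.carries_derived]
    if not carriers:
        return None
    if len(carriers) == 1:
        return carriers[0]
    hgs = {tree.sample_map[s] for s in carriers}
    if len(hgs) == 1:
        hg = next(iter(hgs))
        # all carriers inside one leaf haplogroup: the star MRCA is the leaf
        return hg
    return tree.mrca(sorted(hgs)).name


def reconstruct_history(
    tree: HaplogroupTree, column: Mapping[str, PseudoGenotype], psv: Psv
) -> PsvHistory:
    """Minimum-event reconstruction of one PSV's conversion history."""
    mutation = place_mutation(tree, column)
    if mutation is None:
        return PsvHistory(psv=psv, mutation_node=None)

    root = _expanded_tree(tree)
    nodes = {n.name: n for n in root.preorder()}
    mut_node = nodes[mutation]

    # Bottom-up Sankoff pass below the mutation node.  Sample leaves with an
    # observed state are fixed; MISSING/EXCLUDED samples (and unsampled leaf
    # haplogroups) impose no constraint.
    cost: dict[str, dict[PseudoGenotype, float]] = {}
    for node in mut_node.postorder():
        if node.is_leaf:
            if node.name in column and column[node.name].is_observed:
                obs = column[node.name]
                cost[node.name] = {s: (0.0 if s == obs else INF) for s in DP_STATES}
            else:
                cost[node.name] = {s: 0.0 for s in DP_STATES}
        else:
            here = {}
            for s in DP_STATES:
                total = 0.0
                for child in node.children:
                    total += min(
                        transition_cost(s, t) + cost[child.name][t] for t in DP_STATES
                    )
                here[s] = total
            cost[node.name] = here

    # The branch into the mutation node carries the 0/0 -> 0/1 mutation, so
    # the state entering the clade is HET; a conversion may act immediately.
    best = min(transition_cost(HET, s) + cost[mutation][s] for s in DP_STATES)
    assert best < INF, "column inconsistent with single-origin transition rules"

    # Top-down traceback.  Among equally parsimonious child states prefer the
    # parent's state (identity first), which pushes events towards the tips.
    states: dict[str, PseudoGenotype] = {}
    events: list[ConversionEvent] = []
    ambiguous = False
    preference = {HET: (HET, HOM_ANC, HOM_DER),
                  HOM_ANC: (HOM_ANC,),
                  HOM_DER: (HOM_DER,)}

    def choose(entering: PseudoGenotype, node: TreeNode) -> PseudoGenotype:
        options = {
            s: transition_cost(entering, s) + cost[node.name][s] for s in DP_STATES
        }
        target = min(options.values())
        argmins = [s for s in preference[entering] if options[s] == target]
        return argmins[0], len([v for v in options.values() if v == target]) > 1

    def descend(node: TreeNode, entering: PseudoGenotype, parent_name: str) -> None:
        nonlocal ambiguous
        state, tie = choose(entering, node)
        if tie:
            ambiguous = True
        states[node.name] = state
        if entering == HET and state in (HOM_ANC, HOM_DER):
            direction = (
                ConversionEvent.TO_ANCESTRAL if state == HOM_ANC
                else ConversionEvent.TO_DERIVED
            )
            fixed = (
                psv.allele_ancestral if state == HOM_ANC else psv.allele_derived
            )
            events.append(
                ConversionEvent(psv.id, parent_name, node.name, direction,
                                gc_class(psv, fixed))
            )
        for child in node.children:
            descend(child, state, node.name)

    parent_name = mut_node.parent.name if mut_node.parent is not None else "ROOT"
    descend(mut_node, HET, parent_name)

    # Everything outside the mutation clade is ancestral by construction.
    in_clade = set(states)
    for name in nodes:
        if name not in in_clade:
            states[name] = HOM_ANC

    history = PsvHistory(
        psv=psv,
        mutation_node=mutation,
        node_states=states,
        events=events,
        ambiguous_placement=ambiguous,
        clade_members=frozenset(in_clade),
    )
    assert history.n_events == int(best)
    return history


@dataclass
class ConversionEventTable:
    """All called events across PSVs, with per-PSV histories and summaries."""

    events: pd.DataFrame
    histories: dict[str, PsvHistory]

    def summary(self) -> dict:
        df = self.events
        n_total = len(df)
        to_anc = int((df["direction"] == ConversionEvent.TO_ANCESTRAL).sum()) if n_total else 0
        to_der = n_total - to_anc
        fixes_s = int((df["gc_class"] == GcClass.FIXES_S.value).sum()) if n_total else 0
        fixes_w = int((df["gc_class"] == GcClass.FIXES_W.value).sum()) if n_total else 0
        return {
            "total_events": n_total,
            "to_ancestral": to_anc,
            "to_derived": to_der,
            "gc_informative": fixes_s + fixes_w,
            "fixes_S": fixes_s,
            "fixes_W": fixes_w,
        }


def enumerate_events(
    tree: HaplogroupTree, matrix: GenotypeMatrix, psvs: Sequence[Psv]
) -> ConversionEventTable:
    """Run the minimum-event reconstruction for every PSV and collect events."""
    histories: dict[str, PsvHistory] = {}
    rows = []
    for psv in psvs:
        column = matrix.column(psv.id)
        observed = any(g.is_observed for g in column.values())
        if not observed:
            histories[psv.id] = PsvHistory(psv=psv, mutation_node=None)
            continue
        history = reconstruct_history(tree, column, psv)
        histories[psv.id] = history
        for ev in history.events:
            rows.append(
                {
                    "psv_id": ev.psv_id,
                    "parent": ev.parent,
                    "child": ev.child,
                    "direction": ev.direction,
                    "gc_class": ev.gc.value,
                }
            )
    events = pd.DataFrame(rows, columns=["psv_id", "parent", "child", "direction", "gc_class"])
    return ConversionEventTable(events=events, histories=histories)
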