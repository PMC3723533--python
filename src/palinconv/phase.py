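"""Phase-aware analyses: inversion detection and co-conversion tracts.

Arm-specific typing of PSVs ("phasing") tells us which allele sits on the
proximal and which on the distal arm.  Comparing a chromosome's phase with a
reference phase at pseudoheterozygous (informative) PSVs detects arm
inversions; mapping the resulting SAME/INVERTED labels onto the haplogroup
tree and minimising state flips (binary-character parsimony) yields the
minimum number of independent inversion events.

Phase also resolves co-conversion: a run of adjacent converted PSVs whose
fixed alleles all match a single arm-specific reference haplotype is most
parsimoniously explained by one conversion tract; runs matching neither arm
must be independent opposite conversions and are split.  Tract lengths are
minimum estimates - the bp span between the outermost converted members.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .caller import ConversionEventTable
from .model import HaplogroupTree, Psv, PseudoGenotype, TreeNode


class Orientation(enum.Enum):
    SAME = "same"
    INVERTED = "inverted"
    UNINFORMATIVE = "uninformative"
    MOSAIC = "mosaic"  # mixed pattern; reported for manual review, never resolved


#: reference phase: psv_id -> (proximal_allele, distal_allele)
ReferencePhase = Mapping[str, tuple[str, str]]


class ConfigurationError(ValueError):
    pass


def phase_orientation(
    sample_phase: Mapping[str, tuple[str, str]], reference_phase: ReferencePhase
) -> Orientation:
    """Orientation of one chromosome's arms relative to the reference phase.

    Only pseudoheterozygous PSVs (two distinct arm alleles, in both sample
    and reference) are informative.  SAME when every informative PSV matches
    the reference arm assignment, INVERTED when every one is swapped,
    UNINFORMATIVE with no informative PSV, MOSAIC otherwise.
    """
    if not reference_phase:
        raise ConfigurationError("reference phase is not defined")
    n_same = n_swapped = 0
    for psv_id, (prox, dist) in sample_phase.items():
        if prox == dist or psv_id not in reference_phase:
            continue
        ref_prox, ref_dist = reference_phase[psv_id]
        if ref_prox == ref_dist:
            continue
        if (prox, dist) == (ref_prox, ref_dist):
            n_same += 1
        elif (prox, dist) == (ref_dist, ref_prox):
            n_swapped += 1
        # alleles not matching the reference pair at all: arm-uninformative
    if n_same and n_swapped:
        return Orientation.MOSAIC
    if n_same:
        return Orientation.SAME
    if n_swapped:
        return Orientation.INVERTED
    return Orientation.UNINFORMATIVE


@dataclass(frozen=True)
class InversionCall:
    """A minimum inversion event on the stem branch of a clade."""

    parent: str
    child: str
    interval_bp: tuple[int, int] | None  # outermost informative PSV coords


def min_inversions(
    tree: HaplogroupTree,
    orientations: Mapping[str, Orientation],
    psvs: Sequence[Psv] | None = None,
    informative_psvs: Mapping[str, Sequence[str]] | None = None,
) -> list[InversionCall]:
    """Minimum set of orientation flips on the tree explaining the labels.

    Two-state minimum-flip parsimony (Sankoff with unit flip cost, exact on
    polytomies) over the haplogroup tree with samples attached as
    pseudo-leaves; UNINFORMATIVE/unlabelled samples are unconstrained.  The
    root is anchored at SAME orientation when tied (the reference chromosome
    is part of the sample).  Each call reports the ascertainment interval
    spanned by the informative PSVs of the supporting samples when
    ``informative_psvs`` (sample -> HET psv ids) and ``psvs`` are given.
    """
    from .caller import _expanded_tree  # shared star-polytomy expansion

    root = _expanded_tree(tree)
    STATES = (Orientation.SAME, Orientation.INVERTED)
    INF = float("inf")

    cost: dict[str, dict[Orientation, float]] = {}
    for node in root.postorder():
        if node.is_leaf:
            label = orientations.get(node.name)
            if label in STATES:
                cost[node.name] = {s: (0.0 if s == label else INF) for s in STATES}
            else:
                cost[node.name] = {s: 0.0 for s in STATES}
        else:
            cost[node.name] = {
                s: sum(
                    min(cost[c.name][t] + (s != t) for t in STATES)
                    for c in node.children
                )
                for s in STATES
            }

    # top-down assignment: prefer the parent's state; root prefers SAME
    calls: list[InversionCall] = []

    def assign(node: TreeNode, parent_state: Orientation | None) -> None:
        options = {
            s: cost[node.name][s]
            + (0 if parent_state is None else (s != parent_state))
            for s in STATES
        }
        best = min(options.values())
        preferred = [parent_state or Orientation.SAME,
                     Orientation.SAME, Orientation.INVERTED]
        state = next(s for s in preferred if options.get(s) == best)
        if parent_state is not None and state != parent_state:
            calls.append(
                InversionCall(node.parent.name, node.name,
                              _interval(node, informative_psvs, psvs))
            )
        for child in node.children:
            assign(child, state)

    assign(root, None)
    return calls


def _interval(node: TreeNode, informative_psvs, psvs) -> tuple[int, int] | None:
    if informative_psvs is None or psvs is None:
        return None
    coords = {p.id: p.proximal_coord for p in psvs}
    spans = [
        coords[pid]
        for leaf in node.preorder()
        if leaf.is_leaf
        for pid in informative_psvs.get(leaf.name, ())
        if pid in coords
    ]
    if not spans:
        return None
    return (min(spans), max(spans))


PROXIMAL = "proximal"
DISTAL = "distal"


@dataclass(frozen=True)
class CoConversionTract:
    """A maximal run of co-converted PSVs compatible with one donor arm."""

    haplogroup: str
    psv_ids: tuple[str, ...]
    fixed_alleles: tuple[str, ...]
    donor_arm: str | None  # None when arm-ambiguous (reference HOM throughout)
    min_length_bp: int

    @property
    def size(self) -> int:
        return len(self.psv_ids)


@dataclass
class TractSet:
    tracts: list[CoConversionTract]
    total_conversions: int  # individual converted-PSV calls in the window
    skipped_samples: list[str] = field(default_factory=list)

    @property
    def explained_conversions(self) -> int:
        return sum(t.size for t in self.tracts if t.size >= 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "haplogroup": t.haplogroup,
                    "psv_ids": ",".join(t.psv_ids),
                    "fixed_alleles": ",".join(t.fixed_alleles),
                    "donor_arm": t.donor_arm or "ambiguous",
                    "size": t.size,
                    "min_length_bp": t.min_length_bp,
                }
                for t in self.tracts
            ],
            columns=["haplogroup", "psv_ids", "fixed_alleles", "donor_arm",
                     "size", "min_length_bp"],
        )


def min_coconversion_tracts(
    tree: HaplogroupTree,
    matrix,
    calls: ConversionEventTable,
    psvs: Sequence[Psv],
    reference_phase: ReferencePhase,
    window: Sequence[str] | None = None,
) -> TractSet:
    """Minimum co-conversion tracts among phased-window PSVs.

    For each sample, the converted PSVs are those where the haplogroup
    founder is reconstructed pseudoheterozygous but the sample is
    pseudohomozygous.  Maximal runs of adjacent converted PSVs are split
    wherever the fixed alleles stop matching a single arm-specific reference
    haplotype; a pseudoheterozygous PSV breaks a run, while PSVs that are
    missing, excluded or not founder-HET are passed over without breaking it.
    Identical tracts seen in several samples of one haplogroup are counted
    once (they descend from one historical event).
    """
    ordered = sorted(psvs, key=lambda p: p.proximal_coord)
    if window is not None:
        ordered = [p for p in ordered if p.id in set(window)]
    else:
        ordered = [p for p in ordered if p.id in reference_phase]
    coords = {p.id: p.proximal_coord for p in ordered}

    seen: set[tuple] = set()
    tracts: list[CoConversionTract] = []
    conversions: set[tuple[str, str, str]] = set()  # (hg, psv, fixed allele)

    for sample in matrix.sample_ids:
        hg = tree.sample_map[sample]
        runs = _sample_runs(sample, hg, matrix, calls, ordered)
        for run in runs:
            for psv_id, allele in run:
                conversions.add((hg, psv_id, allele))
            for segment, donor in _split_by_arm(run, reference_phase):
                key = (hg, tuple(p for p, _ in segment), tuple(a for _, a in segment))
                if key in seen:
                    continue
                seen.add(key)
                psv_ids = tuple(p for p, _ in segment)
                tracts.append(
                    CoConversionTract(
                        haplogroup=hg,
                        psv_ids=psv_ids,
                        fixed_alleles=tuple(a for _, a in segment),
                        donor_arm=donor,
                        min_length_bp=coords[psv_ids[-1]] - coords[psv_ids[0]],
                    )
                )
    return TractSet(tracts=tracts, total_conversions=len(conversions))


def _sample_runs(sample, hg, matrix, calls, ordered_psvs):
    """Maximal runs of converted PSVs for one sample, HET breaks a run."""
    runs: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for psv in ordered_psvs:
        history = calls.histories.get(psv.id)
        state = matrix.df.at[sample, psv.id]
        converted = history is not None and history.lineage_converted(sample, state)
        if state == PseudoGenotype.HET:
            if current:
                runs.append(current)
                current = []
        elif converted:
            fixed = (
                psv.allele_ancestral
                if state == PseudoGenotype.HOM_ANC
                else psv.allele_derived
            )
            current.append((psv.id, fixed))
        # MISSING/EXCLUDED or not founder-HET: pass over without breaking
    if current:
        runs.append(current)
    return runs


def _split_by_arm(run, reference_phase: ReferencePhase):
    """Split a run of (psv_id, fixed_allele) into arm-consistent segments.

    A member constrains the donor arm to those reference arms carrying its
    fixed allele; where the reference is pseudohomozygous the member is
    arm-uninformative.  When the running intersection of compatible arms
    empties, the segment closes (independent opposite conversions).
    """
    segments = []
    current: list[tuple[str, str]] = []
    compatible: set[str] = {PROXIMAL, DISTAL}
    for psv_id, allele in run:
        member_arms = _compatible_arms(psv_id, allele, reference_phase)
        if current and not (compatible & member_arms):
            segments.append((current, _donor(compatible)))
            current = []
            compatible = {PROXIMAL, DISTAL}
        current.append((psv_id, allele))
        compatible &= member_arms
    if current:
        segments.append((current, _donor(compatible)))
    return segments


def _compatible_arms(psv_id, allele, reference_phase) -> set[str]:
    if psv_id not in reference_phase:
        return {PROXIMAL, DISTAL}
    prox, dist = reference_phase[psv_id]
    if prox == dist:
        return {PROXIMAL, DISTAL}
    arms = set()
    if allele == prox:
        arms.add(PROXIMAL)
    if allele == dist:
        arms.add(DISTAL)
    return arms or {PROXIMAL, DISTAL}  # allele absent from reference: uninformative


def _donor(compatible: set[str]) -> str | None:
    return next(iter(compatible)) if len(compatible) == 1 else None


def tract_stats(tract_set: TractSet) -> dict:
    """Summary of minimum tract lengths and the fraction of events explained.

    Mean/max are over multi-PSV tracts (singletons have trivial length 0 and
    carry no length information).
    """
    multi = [t for t in tract_set.tracts if t.size >= 2]
    total = tract_set.total_conversions
    explained = tract_set.explained_conversions
    out = {
        "n_tracts_multi": len(multi),
        "n_tracts_total": len(tract_set.tracts),
        "total_conversions": total,
        "explained_conversions": explained,
        "fraction_explained": (explained / total) if total else None,
        "mean_min_length_bp": None,
        "max_min_length_bp": None,
    }
    if multi:
        lengths = [t.min_length_bp for t in multi]
        out["mean_min_length_bp"] = sum(lengths) / len(lengths)
        out["max_min_length_bp"] = max(lengths)
    return out


def borrow_phase(
    tree: HaplogroupTree, orientations: Mapping[str, Orientation]
) -> dict[str, Orientation]:
    """Extend orientations to unphased samples within concordant haplogroups.

    Inversions are rare and phased chromosomes within a haplogroup are always
    concordant in practice, so an unphased chromosome inherits its
    haplogroup's orientation - but only when every phased member agrees.
    """
    extended = dict(orientations)
    by_hg: dict[str, set[Orientation]] = {}
    for sample, label in orientations.items():
        if label in (Orientation.SAME, Orientation.INVERTED):
            by_hg.setdefault(tree.sample_map[sample], set()).add(label)
    for sample, hg in tree.sample_map.items():
        if sample in extended:
            continue
        labels = by_hg.get(hg)
        if labels and len(labels) == 1:
            extended[sample] = next(iter(labels))
    return extended
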