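"""Forward simulator of palindrome-arm evolution with full ground truth.

Two generators cover the two observation layers of the analysis:

* :func:`simulate_phylogeny` + :func:`simulate_conversion_history` evolve the
  two arm copies of each PSV down a random haplogroup tree.  Each PSV's
  0/0 -> 0/1 mutation is planted once (single origin, no recurrence);
  conversion events arrive per branch as a Poisson process, extend a
  geometric-length tract symmetrically around a focal PSV, and copy the donor
  arm's alleles onto the other arm; the donor arm is chosen with a tunable
  bias towards fixing the strong (G/C) allele at GC-informative PSVs and the
  ancestral allele otherwise.  Rare intra-chromatid inversions swap the arm
  assignment of PSVs in the phased window.  Every planted event is logged.

* :func:`simulate_triad` evolves human/chimp/gorilla sequences down the fixed
  species tree with region-specific substitution rates and an arm-restricted
  bias of substitution targets towards strong bases, logging every
  replacement with its lineage.

Defaults mirror the surveyed study conditions: 63 haplogroups x 6 samples
(~378 chromosomes), a 340,000-generation tree, per-PSV conversion rate
5e-5/generation, ancestral-fixation probability 86/146, S-fixation
probability 59/79, mean tract 2068 bp, inversion rate 1e-5/generation, and
the ten bundled PSVs.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets
from .evo import ARM, SPACER, RegionMask, TriadAlignment
from .model import (
    GenotypeMatrix,
    HaplogroupTree,
    Psv,
    PseudoGenotype,
    TreeNode,
    write_genotypes,
    write_psvs,
    write_samples,
    write_tree,
)
from .phase import DISTAL, PROXIMAL

BASES = np.array([b"A", b"C", b"G", b"T"])
S_IDX = (1, 2)  # C, G
W_IDX = (0, 3)  # A, T


@dataclass
class SimParams:
    """Tunable study conditions for the forward simulator (seed mandatory)."""

    seed: int
    n_haplogroups: int = 63
    samples_per_haplogroup: int = 6
    total_generations: float = 340_000.0
    psvs: list[Psv] = field(default_factory=datasets.synthetic_psv_set)
    psv_origin: str = "mixed"  # "root" | "branch" | "mixed"
    root_origin_fraction: float = 0.3  # used by "mixed"
    conversion_rate: float = 5e-5  # events per PSV per generation
    p_ancestral: float = 86 / 146
    p_gc: float = 59 / 79
    tract_mean_bp: float = 2068.0
    inversion_rate: float = 1e-5  # events per generation
    phased_window: tuple = datasets.PHASED_WINDOW
    # triad sequence evolution (region lengths scaled down from ~104/46 kb)
    arm_length: int = 30_000
    spacer_length: int = 15_000
    arm_divergence_hc: float = 0.0144
    spacer_divergence_hc: float = 0.0200
    arm_divergence_hg: float = 0.0196
    spacer_divergence_hg: float = 0.0248
    gc_content: float = 0.38
    arm_s_target_bias: float = 0.60
    spacer_s_target_bias: float = 0.45

    def __post_init__(self) -> None:
        for name in ("root_origin_fraction", "p_ancestral", "p_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("conversion_rate", "inversion_rate", "tract_mean_bp",
                     "total_generations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_haplogroups < 2:
            raise ValueError("need at least 2 haplogroups")
        if self.psv_origin not in ("root", "branch", "mixed"):
            raise ValueError("psv_origin must be root, branch or mixed")


@dataclass
class GroundTruth:
    """Complete planted-event log for one simulated history."""

    mutations: dict[str, str] = field(default_factory=dict)  # psv -> node/"ROOT"
    derived_arm: dict[str, str] = field(default_factory=dict)
    conversion_events: list[dict] = field(default_factory=list)
    inversion_events: list[dict] = field(default_factory=list)
    reference_phase: dict[str, tuple[str, str]] = field(default_factory=dict)
    total_generations: float = 0.0
    triad_replacements: list[dict] = field(default_factory=list)

    @property
    def observable_fixations(self) -> list[dict]:
        """Per-PSV fixations that changed a pseudoheterozygous state."""
        out = []
        for ev in self.conversion_events:
            out.extend(ev["fixations"])
        return out

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["reference_phase"] = {k: list(v) for k, v in self.reference_phase.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def draw_direction(p_ancestral: float, rng: np.random.Generator) -> str:
    """One conversion direction: 'to_ancestral' with probability p_ancestral."""
    return "to_ancestral" if rng.random() < p_ancestral else "to_derived"


def draw_direction_counts(
    n_events: int, p_ancestral: float, rng: np.random.Generator
) -> tuple[int, int]:
    """(to_ancestral, to_derived) counts for n_events independent conversions."""
    a = int(rng.binomial(n_events, p_ancestral))
    return a, n_events - a


def simulate_phylogeny(params: SimParams, rng: np.random.Generator | None = None):
    """Random rooted haplogroup tree plus per-sample private branch lengths.

    Topology grows by random sequential joins; branch generations (including
    each sample's private branch below its leaf haplogroup) are exponential
    weights rescaled so the whole tree sums to ``params.total_generations``.

    Returns ``(tree, sample_generations)``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    subtrees = [TreeNode(f"HG{i + 1:03d}") for i in range(params.n_haplogroups)]
    counter = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        counter += 1
        parent = TreeNode(f"N{counter:03d}")
        parent.add_child(subtrees[i])
        parent.add_child(subtrees[j])
        subtrees = [t for k, t in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(parent)
    root = subtrees[0]
    root.name = "ROOT"

    sample_map = {}
    for leaf in [n for n in root.preorder() if n.is_leaf]:
        for k in range(params.samples_per_haplogroup):
            sample_map[f"{leaf.name}_S{k + 1}"] = leaf.name

    tree = HaplogroupTree(root, sample_map)
    branch_nodes = [n for n in root.preorder() if n.parent is not None]
    weights = rng.exponential(1.0, size=len(branch_nodes) + len(sample_map))
    weights *= params.total_generations / weights.sum()
    for node, w in zip(branch_nodes, weights):
        node.generations = float(w)
    sample_generations = {
        s: float(w) for s, w in zip(sample_map, weights[len(branch_nodes):])
    }
    return tree, sample_generations


def _plant_mutations(tree, sample_generations, params, rng, truth: GroundTruth):
    branch_nodes = [n for n in tree.root.preorder() if n.parent is not None]
    names = [n.name for n in branch_nodes] + list(sample_generations)
    gens = np.array([n.generations for n in branch_nodes]
                    + list(sample_generations.values()))
    probs = gens / gens.sum()
    for psv in params.psvs:
        if params.psv_origin == "root":
            at_root = True
        elif params.psv_origin == "branch":
            at_root = False
        else:
            at_root = rng.random() < params.root_origin_fraction
        node = "ROOT" if at_root else names[int(rng.choice(len(names), p=probs))]
        truth.mutations[psv.id] = node
        truth.derived_arm[psv.id] = PROXIMAL if rng.random() < 0.5 else DISTAL


def _apply_conversions(state, node_name, parent_name, generations, params, rng,
                       truth: GroundTruth, coords, psv_by_id):
    n = rng.poisson(params.conversion_rate * generations * len(params.psvs))
    psv_ids = [p.id for p in params.psvs]
    for _ in range(n):
        focal = psv_ids[int(rng.integers(len(psv_ids)))]
        length = int(rng.geometric(1.0 / max(params.tract_mean_bp, 1.0)))
        left = coords[focal] - length // 2
        right = coords[focal] + (length - length // 2)
        covered = [p for p in psv_ids if left <= coords[p] <= right]
        if focal not in covered:
            covered = [focal]
        prox, dist = state[focal]
        psv = psv_by_id[focal]
        if prox != dist:
            if psv.gc_informative:
                strong = prox if prox in "GC" else dist
                weak = dist if strong == prox else prox
                preferred = strong if rng.random() < params.p_gc else weak
            else:
                preferred = (
                    psv.allele_ancestral
                    if rng.random() < params.p_ancestral
                    else psv.allele_derived
                )
            donor = PROXIMAL if state[focal][0] == preferred else DISTAL
        else:
            donor = PROXIMAL if rng.random() < 0.5 else DISTAL
        fixations = []
        for pid in covered:
            p, d = state[pid]
            src = p if donor == PROXIMAL else d
            if p != d:
                member = psv_by_id[pid]
                fixations.append(
                    {
                        "psv_id": pid,
                        "fixed_allele": src,
                        "direction": (
                            "to_ancestral" if src == member.allele_ancestral
                            else "to_derived"
                        ),
                    }
                )
            state[pid] = (src, src)
        truth.conversion_events.append(
            {
                "parent": parent_name,
                "child": node_name,
                "focal_psv": focal,
                "covered_psvs": covered,
                "donor_arm": donor,
                "tract_length_bp": length,
                "fixations": fixations,
            }
        )


def _apply_inversions(state, node_name, parent_name, generations, params, rng,
                      truth: GroundTruth):
    n = rng.poisson(params.inversion_rate * generations)
    for _ in range(n):
        for pid in params.phased_window:
            if pid in state:
                p, d = state[pid]
                state[pid] = (d, p)
        truth.inversion_events.append({"parent": parent_name, "child": node_name})


def simulate_conversion_history(
    tree: HaplogroupTree,
    sample_generations: dict[str, float],
    params: SimParams,
    rng: np.random.Generator | None = None,
):
    """Evolve arm states down the tree; emit genotypes, phases and truth.

    Returns ``(GenotypeMatrix, phase_table, reference_phase, GroundTruth)``
    where ``phase_table`` is a DataFrame (sample_id, psv_id, proximal_allele,
    distal_allele) restricted to the phased window and ``reference_phase``
    maps window PSVs to the arm assignment at their mutation (the orientation
    the labels SAME/INVERTED are relative to).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    truth = GroundTruth(
        total_generations=sum(
            n.generations for n in tree.root.preorder() if n.parent is not None
        )
        + sum(sample_generations.values())
    )
    _plant_mutations(tree, sample_generations, params, rng, truth)
    coords = {p.id: p.proximal_coord for p in params.psvs}
    psv_by_id = {p.id: p for p in params.psvs}

    def mutated_state(psv: Psv) -> tuple[str, str]:
        anc, der = psv.allele_ancestral, psv.allele_derived
        return (der, anc) if truth.derived_arm[psv.id] == PROXIMAL else (anc, der)

    for psv in params.psvs:
        truth.reference_phase[psv.id] = mutated_state(psv)

    root_state = {}
    for psv in params.psvs:
        root_state[psv.id] = (
            mutated_state(psv)
            if truth.mutations[psv.id] == "ROOT"
            else (psv.allele_ancestral, psv.allele_ancestral)
        )

    sample_states: dict[str, dict] = {}

    def descend(node: TreeNode, state: dict) -> None:
        state = dict(state)
        if node.parent is not None:
            parent_name = node.parent.name
            for psv in params.psvs:
                if truth.mutations[psv.id] == node.name:
                    state[psv.id] = mutated_state(psv)
            _apply_conversions(state, node.name, parent_name, node.generations,
                               params, rng, truth, coords, psv_by_id)
            _apply_inversions(state, node.name, parent_name, node.generations,
                              params, rng, truth)
        if node.is_leaf:
            for sample in tree.samples_of(node.name):
                sstate = dict(state)
                for psv in params.psvs:
                    if truth.mutations[psv.id] == sample:
                        sstate[psv.id] = mutated_state(psv)
                gens = sample_generations[sample]
                _apply_conversions(sstate, sample, node.name, gens, params, rng,
                                   truth, coords, psv_by_id)
                _apply_inversions(sstate, sample, node.name, gens, params, rng, truth)
                sample_states[sample] = sstate
        for child in node.children:
            descend(child, state)

    descend(tree.root, root_state)

    psv_ids = [p.id for p in params.psvs]
    matrix = pd.DataFrame(index=list(tree.sample_map), columns=psv_ids, dtype=object)
    phase_rows = []
    for sample, state in sample_states.items():
        for psv in params.psvs:
            prox, dist = state[psv.id]
            if prox == dist:
                geno = (
                    PseudoGenotype.HOM_ANC
                    if prox == psv.allele_ancestral
                    else PseudoGenotype.HOM_DER
                )
            else:
                geno = PseudoGenotype.HET
            matrix.at[sample, psv.id] = geno
            if psv.id in params.phased_window:
                phase_rows.append(
                    {"sample_id": sample, "psv_id": psv.id,
                     "proximal_allele": prox, "distal_allele": dist}
                )
    phase_table = pd.DataFrame(
        phase_rows, columns=["sample_id", "psv_id", "proximal_allele", "distal_allele"]
    )
    reference_phase = {
        pid: truth.reference_phase[pid]
        for pid in params.phased_window
        if pid in truth.reference_phase
    }
    return GenotypeMatrix(matrix), phase_table, reference_phase, truth


# ---------------------------------------------------------------------------
# triad sequence evolution


def _random_sequence(length: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _mutate(seq: np.ndarray, p_sub: np.ndarray, s_bias: np.ndarray, rng,
            log: list[dict] | None, lineage: str, region_of) -> np.ndarray:
    """One branch of substitution: per-site Bernoulli, biased target class."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < p_sub)
    for col in hits:
        cur = out[col]
        to_strong = rng.random() < s_bias[col]
        pool = [i for i in (S_IDX if to_strong else W_IDX) if i != cur]
        if not pool:  # current base is the only member of the target class
            pool = [i for i in range(4) if i != cur]
        new = int(pool[int(rng.integers(len(pool)))])
        if log is not None:
            log.append(
                {
                    "column": int(col),
                    "region": region_of(col),
                    "lineage": lineage,
                    "from": BASES[cur].decode(),
                    "to": BASES[new].decode(),
                }
            )
        out[col] = new
    return out


def simulate_triad(params: SimParams, rng: np.random.Generator | None = None):
    """Human/chimp/gorilla sequences with region-specific divergence.

    Branch substitution probabilities are set so expected pairwise divergence
    matches the configured human-chimp and human-gorilla values per region
    (multiple hits are rare at these rates and ignored).  Substitution
    targets are drawn strong (G/C) with the region's S-target bias.

    Returns ``(TriadAlignment, RegionMask, GroundTruth)`` with a full
    per-replacement log (column, lineage, from, to).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    n_arm, n_spc = params.arm_length, params.spacer_length
    length = n_arm + n_spc
    is_arm = np.arange(length) < n_arm

    def per_region(arm_value, spc_value):
        return np.where(is_arm, arm_value, spc_value)

    p_hc = per_region(params.arm_divergence_hc / 2, params.spacer_divergence_hc / 2)
    p_outgroup = (
        per_region(params.arm_divergence_hg, params.spacer_divergence_hg) - p_hc
    ) / 2
    p_outgroup = np.clip(p_outgroup, 0.0, None)
    s_bias = per_region(params.arm_s_target_bias, params.spacer_s_target_bias)

    def region_of(col: int) -> str:
        return ARM if col < n_arm else SPACER

    truth = GroundTruth()
    root = _random_sequence(length, params.gc_content, rng)
    log = truth.triad_replacements
    gorilla = _mutate(root, p_outgroup, s_bias, rng, log, "gorilla", region_of)
    hc_anc = _mutate(root, p_outgroup, s_bias, rng, log, "hc_ancestor", region_of)
    human = _mutate(hc_anc, p_hc, s_bias, rng, log, "human", region_of)
    chimp = _mutate(hc_anc, p_hc, s_bias, rng, log, "chimp", region_of)

    def decode(arr: np.ndarray) -> str:
        return BASES[arr].tobytes().decode()

    triad = TriadAlignment(decode(human), decode(chimp), decode(gorilla))
    mask = RegionMask([(0, n_arm, ARM), (n_arm, length, SPACER)])
    return triad, mask, truth


# ---------------------------------------------------------------------------
# bundle emission


def write_bundle(outdir, params: SimParams) -> Path:
    """Run the full simulator and write a loadable input bundle.

    Emits tree.nwk, samples.tsv, psvs.tsv, genotypes.tsv, phases.tsv,
    reference_phase.tsv, triad.fasta, regions.tsv and truth.json into
    ``outdir``; returns the directory path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    tree, sample_generations = simulate_phylogeny(params, rng)
    matrix, phase_table, reference_phase, truth = simulate_conversion_history(
        tree, sample_generations, params, rng
    )
    triad, mask, triad_truth = simulate_triad(params, rng)
    truth.triad_replacements = triad_truth.triad_replacements

    write_tree(tree, outdir / "tree.nwk")
    write_samples(tree.sample_map, outdir / "samples.tsv")
    write_psvs(params.psvs, outdir / "psvs.tsv")
    write_genotypes(matrix, outdir / "genotypes.tsv")
    phase_table.to_csv(outdir / "phases.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"psv_id": pid, "proximal_allele": p, "distal_allele": d}
            for pid, (p, d) in reference_phase.items()
        ]
    ).to_csv(outdir / "reference_phase.tsv", sep="\t", index=False)
    triad.to_fasta(outdir / "triad.fasta")
    mask.to_tsv(outdir / "regions.tsv")
    truth.to_json(outdir / "truth.json")
    return outdir


def load_reference_phase(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return {
        r.psv_id: (r.proximal_allele, r.distal_allele) for r in df.itertuples()
    }


def load_phase_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")
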