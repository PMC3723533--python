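"""Data model for palindrome-arm PSV analysis on a haplogroup phylogeny.

A palindrome arm pair in a haploid chromosome behaves like a pseudo-diploid
locus: a paralogous sequence variant (PSV) whose two arm copies differ is
"pseudoheterozygous", and gene conversion between arms can drive it to either
"pseudohomozygous" state.  This module holds the observables: the PSV
metadata, the three-valued pseudo-genotype matrix, and the rooted haplogroup
tree that samples attach to, together with TSV/newick loaders and writers.

Coordinates are 1-based on input and output (matching published GRCh37
conventions); interval arithmetic elsewhere in the package is 0-based
half-open.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

S_NUCLEOTIDES = frozenset("GC")
W_NUCLEOTIDES = frozenset("AT")
VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed inputs violate a cross-reference or invariant."""


class PseudoGenotype(enum.Enum):
    """Arm-pair state of a PSV in one chromosome.

    ``HOM_ANC`` (0/0): both arms carry the ancestral allele.
    ``HET`` (0/1): arms differ (the pseudoheterozygous state).
    ``HOM_DER`` (1/1): both arms carry the derived allele.
    ``MISSING``: assay failed or not attempted.
    ``EXCLUDED``: sample failed arm-presence checks (e.g. abnormal
    karyotype); reported separately from MISSING downstream.
    """

    HOM_ANC = "00"
    HET = "01"
    HOM_DER = "11"
    MISSING = "NA"
    EXCLUDED = "EX"

    @property
    def is_observed(self) -> bool:
        return self in (PseudoGenotype.HOM_ANC, PseudoGenotype.HET, PseudoGenotype.HOM_DER)

    @property
    def carries_derived(self) -> bool:
        return self in (PseudoGenotype.HET, PseudoGenotype.HOM_DER)


class GcClass(enum.Enum):
    """GC classification of a conversion: which base class it fixes."""

    FIXES_S = "fixes_S"
    FIXES_W = "fixes_W"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class Psv:
    """A single-nucleotide paralogous sequence variant between palindrome arms.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"PSV1"``.
    proximal_coord : int
        1-based bp position of the variant on the proximal arm.
    allele_ancestral, allele_derived : str
        The two arm alleles, polarised by outgroup comparison; the derived
        allele is the one created by the original mutation.
    """

    id: str
    proximal_coord: int
    allele_ancestral: str
    allele_derived: str

    def __post_init__(self) -> None:
        for allele in (self.allele_ancestral, self.allele_derived):
            if allele not in VALID_BASES:
                raise ValidationError(f"PSV {self.id}: invalid allele {allele!r}")
        if self.allele_ancestral == self.allele_derived:
            raise ValidationError(f"PSV {self.id}: alleles must differ")
        if self.proximal_coord < 1:
            raise ValidationError(f"PSV {self.id}: coordinate must be >= 1")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_ancestral, self.allele_derived))

    @property
    def gc_informative(self) -> bool:
        """True iff the two alleles differ in strong/weak (S/W) class.

        A G<->C or A<->T transversion is uninformative about GC bias because
        both alleles belong to the same class.
        """
        return not (self.alleles <= S_NUCLEOTIDES or self.alleles <= W_NUCLEOTIDES)


def gc_class(psv: Psv, fixed_allele: str) -> GcClass:
    """Classify a conversion at *psv* that fixes *fixed_allele*.

    Returns UNINFORMATIVE when the PSV's alleles share an S/W class;
    otherwise FIXES_S iff the fixed allele is G or C.
    """
    if fixed_allele not in psv.alleles:
        raise ValidationError(
            f"allele {fixed_allele!r} is not one of PSV {psv.id}'s alleles "
            f"{sorted(psv.alleles)}"
        )
    if not psv.gc_informative:
        return GcClass.UNINFORMATIVE
    return GcClass.FIXES_S if fixed_allele in S_NUCLEOTIDES else GcClass.FIXES_W


class TreeNode:
    """Node of a rooted haplogroup tree (lightweight, mutable)."""

    __slots__ = ("name", "parent", "children", "generations", "markers")

    def __init__(self, name: str, generations: float = 0.0):
        self.name = name
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.generations = generations  # branch length above this node
        self.markers: tuple[str, ...] = ()

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r})"


class HaplogroupTree:
    """Rooted haplogroup tree with a sample -> leaf-haplogroup map.

    Internal nodes are named haplogroups; samples attach to leaf haplogroups.
    All parsimony reconstructions in the package run on this structure.
    """

    def __init__(self, root: TreeNode, sample_map: Mapping[str, str]):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        for node in root.preorder():
            if not node.name:
                raise ValidationError("every tree node must be labelled")
            if node.name in self.nodes:
                raise ValidationError(f"duplicate haplogroup name {node.name!r}")
            self.nodes[node.name] = node
        leaf_names = {n.name for n in self.leaves()}
        self.sample_map: dict[str, str] = {}
        for sample, hg in sample_map.items():
            if sample in self.sample_map:
                raise ValidationError(f"duplicate sample id {sample!r}")
            if hg not in leaf_names:
                raise ValidationError(
                    f"sample {sample!r} maps to {hg!r}, which is not a leaf haplogroup"
                )
            self.sample_map[sample] = hg

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if n.is_leaf]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_map)

    def samples_of(self, haplogroup: str) -> list[str]:
        return [s for s, hg in self.sample_map.items() if hg == haplogroup]

    def mrca(self, names: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named nodes."""
        if not names:
            raise ValueError("mrca of empty set")
        paths = []
        for name in names:
            node = self.nodes[name]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            candidate = paths[0][depth]
            if all(p[depth] is candidate for p in paths):
                mrca = candidate
            else:
                break
        return mrca

    # -- newick round-trip (dendropy does the parsing/serialising) --------

    @classmethod
    def from_newick(cls, newick: str, sample_map: Mapping[str, str]) -> "HaplogroupTree":
        try:
            # labels as plain node labels: duplicate checking is ours
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      suppress_internal_node_taxa=True,
                                      suppress_leaf_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"could not parse newick tree: {exc}") from exc

        def convert(dnode) -> TreeNode:
            label = dnode.label if dnode.label else (
                dnode.taxon.label if dnode.taxon is not None else None
            )
            node = TreeNode(label or "", generations=float(dnode.edge.length or 0.0))
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node), sample_map)

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            length = f":{node.generations:g}" if node.generations else ""
            if node.is_leaf:
                return f"{node.name}{length}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.name}{length}"

        return fmt(self.root) + ";"


@dataclass
class GenotypeMatrix:
    """Samples x PSVs matrix of :class:`PseudoGenotype` states.

    Backed by a pandas DataFrame (rows = sample ids, columns = PSV ids,
    cells = PseudoGenotype).  Cells absent from the long-format input file
    default to MISSING.
    """

    df: pd.DataFrame

    def column(self, psv_id: str) -> dict[str, PseudoGenotype]:
        return self.df[psv_id].to_dict()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def psv_ids(self) -> list[str]:
        return list(self.df.columns)

    def validate(self, tree: HaplogroupTree, psvs: Sequence[Psv]) -> None:
        unknown_samples = [s for s in self.df.index if s not in tree.sample_map]
        if unknown_samples:
            raise ValidationError(f"genotypes for unknown samples: {unknown_samples}")
        known_psvs = {p.id for p in psvs}
        unknown_psvs = [p for p in self.df.columns if p not in known_psvs]
        if unknown_psvs:
            raise ValidationError(f"genotypes for unknown PSVs: {unknown_psvs}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeMatrix) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# TSV / newick plumbing


def _read_tsv(path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def load_psvs(path) -> list[Psv]:
    df = _read_tsv(path, ["psv_id", "proximal_coord", "allele_ancestral", "allele_derived"])
    if df["psv_id"].duplicated().any():
        dupes = sorted(df.loc[df["psv_id"].duplicated(), "psv_id"])
        raise ValidationError(f"duplicate PSV ids: {dupes}")
    psvs = [
        Psv(row.psv_id, int(row.proximal_coord), row.allele_ancestral, row.allele_derived)
        for row in df.itertuples()
    ]
    psvs.sort(key=lambda p: p.proximal_coord)
    coords = [p.proximal_coord for p in psvs]
    if len(set(coords)) != len(coords):
        raise ValidationError("PSV proximal coordinates must be distinct")
    return psvs


def load_samples(path) -> dict[str, str]:
    df = _read_tsv(path, ["sample_id", "haplogroup"])
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample ids: {dupes}")
    return dict(zip(df["sample_id"], df["haplogroup"]))


def load_genotypes(path, samples: Iterable[str], psvs: Sequence[Psv]) -> GenotypeMatrix:
    df = _read_tsv(path, ["sample_id", "psv_id", "state"])
    valid_states = {g.value for g in PseudoGenotype}
    bad = sorted(set(df["state"]) - valid_states)
    if bad:
        raise FormatError(f"{path}: invalid genotype states {bad}")
    psv_ids = [p.id for p in psvs]
    matrix = pd.DataFrame(PseudoGenotype.MISSING, index=list(samples), columns=psv_ids,
                          dtype=object)
    unknown_samples = sorted(set(df["sample_id"]) - set(matrix.index))
    if unknown_samples:
        raise ValidationError(f"genotypes for unknown samples: {unknown_samples}")
    unknown_psvs = sorted(set(df["psv_id"]) - set(psv_ids))
    if unknown_psvs:
        raise ValidationError(f"genotypes for unknown PSVs: {unknown_psvs}")
    for row in df.itertuples():
        matrix.at[row.sample_id, row.psv_id] = PseudoGenotype(row.state)
    return GenotypeMatrix(matrix)


def load_inputs(tree_file, samples_file, psv_file, genotypes_file):
    """Load and cross-validate the full input bundle.

    Returns ``(HaplogroupTree, [Psv], GenotypeMatrix)`` with all references
    resolved; any dangling sample/PSV reference or duplicate id raises
    :class:`ValidationError`, malformed files raise :class:`FormatError`.
    """
    sample_map = load_samples(samples_file)
    with open(tree_file) as fh:
        tree = HaplogroupTree.from_newick(fh.read(), sample_map)
    psvs = load_psvs(psv_file)
    matrix = load_genotypes(genotypes_file, sample_map, psvs)
    matrix.validate(tree, psvs)
    return tree, psvs, matrix


def write_psvs(psvs: Sequence[Psv], path) -> None:
    pd.DataFrame(
        {
            "psv_id": [p.id for p in psvs],
            "proximal_coord": [p.proximal_coord for p in psvs],
            "allele_ancestral": [p.allele_ancestral for p in psvs],
            "allele_derived": [p.allele_derived for p in psvs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_samples(sample_map: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(sample_map), "haplogroup": list(sample_map.values())}
    ).to_csv(path, sep="\t", index=False)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    long = matrix.df.stack().map(lambda g: g.value).rename("state").reset_index()
    long.columns = ["sample_id", "psv_id", "state"]
    long.to_csv(path, sep="\t", index=False)


def write_tree(tree: HaplogroupTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
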