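"""Interspecific arm/spacer divergence and W<->S replacement analysis.

Palindrome arms diverge more slowly between species than their spacers,
because gene conversion keeps returning new arm mutations to the ancestral
state.  This module measures pairwise divergence per region, polarises fixed
human/chimp differences with the gorilla outgroup, tabulates weak-to-strong
(W->S: A/T -> G/C) and strong-to-weak replacements with optional masking of
hypermutable CpG/TpG/CpA dinucleotide contexts, compares GC content between
regions, and calls a consensus base from pileup-like read evidence.

Alignment coordinates: region masks are 1-based inclusive on input (BED-like
TSV) and converted to 0-based half-open internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import S_NUCLEOTIDES, VALID_BASES, W_NUCLEOTIDES, FormatError
from .stats import yates_chisq_2x2

ARM = "arm"
SPACER = "spacer"

GAP_CHARS = frozenset("-.")

#: hypermutable dinucleotide contexts (5'->3') removed before replacement counts
HYPERMUTABLE_DINUCLEOTIDES = ("CG", "TG", "CA")


class WsClass(enum.Enum):
    W_TO_S = "W_to_S"
    S_TO_W = "S_to_W"
    W_TO_W = "W_to_W"
    S_TO_S = "S_to_S"


def ws_class(from_base: str, to_base: str) -> WsClass:
    f = "S" if from_base in S_NUCLEOTIDES else "W"
    t = "S" if to_base in S_NUCLEOTIDES else "W"
    return WsClass(f"{f}_to_{t}")


class Lineage(enum.Enum):
    HUMAN = "human"
    CHIMP = "chimp"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReplacementRecord:
    column: int  # 0-based alignment column
    region: str
    lineage: Lineage
    from_base: str
    to_base: str
    ws: WsClass
    cpg_masked: bool = False


@dataclass
class RegionMask:
    """Labelled, non-overlapping intervals over alignment columns.

    Stored 0-based half-open; :meth:`from_tsv` reads 1-based inclusive rows
    (start, end, label).
    """

    intervals: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals)
        for (s1, e1, _), (s2, _, _) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError("mask intervals overlap")
        self.intervals = ordered

    def label_array(self, length: int) -> np.ndarray:
        labels = np.full(length, "", dtype=object)
        for start, end, label in self.intervals:
            labels[start:min(end, length)] = label
        return labels

    @classmethod
    def from_tsv(cls, path) -> "RegionMask":
        df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int, "label": str},
                         comment="#")
        for col in ("start", "end", "label"):
            if col not in df.columns:
                raise FormatError(f"{path}: mask needs columns start, end, label")
        return cls([(int(r.start) - 1, int(r.end), r.label) for r in df.itertuples()])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(s + 1, e, lab) for s, e, lab in self.intervals],
            columns=["start", "end", "label"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class TriadAlignment:
    """Aligned human/chimpanzee/gorilla sequences (equal lengths, gaps allowed)."""

    human: str
    chimp: str
    gorilla: str

    def __post_init__(self) -> None:
        lengths = {len(self.human), len(self.chimp), len(self.gorilla)}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        self.human = self.human.upper()
        self.chimp = self.chimp.upper()
        self.gorilla = self.gorilla.upper()

    def __len__(self) -> int:
        return len(self.human)

    @classmethod
    def from_fasta(cls, path) -> "TriadAlignment":
        records = {r.id.lower(): str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        try:
            return cls(records["human"], records["chimp"], records["gorilla"])
        except KeyError as exc:
            raise FormatError(
                f"{path}: triad FASTA needs records named human, chimp, gorilla"
            ) from exc

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in (("human", self.human), ("chimp", self.chimp),
                              ("gorilla", self.gorilla)):
                fh.write(f">{name}\n{seq}\n")


def region_divergence(seq_a: str, seq_b: str, mask: RegionMask) -> pd.DataFrame:
    """Pairwise divergence per region plus the arm-vs-spacer Yates contrast.

    Only columns ungapped in both sequences count; divergence is
    100 * substitutions / ungapped length.  The returned frame has one row
    per region (ungapped_length, n_substitutions, divergence_pct) and, when
    both an arm and a spacer region are present, attrs["arm_vs_spacer_p"]
    from a 2x2 Yates chi-square on (substituted, unsubstituted) x region.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    labels = mask.label_array(len(seq_a))
    a_arr = np.frombuffer(seq_a.encode(), dtype="S1")
    b_arr = np.frombuffer(seq_b.encode(), dtype="S1")
    gaps = [g.encode() for g in GAP_CHARS]
    ungapped_mask = ~(np.isin(a_arr, gaps) | np.isin(b_arr, gaps))
    rows = []
    counts = {}
    for region in sorted({lab for _, _, lab in mask.intervals}):
        idx = (labels == region) & ungapped_mask
        ungapped = int(idx.sum())
        subs = int((a_arr[idx] != b_arr[idx]).sum())
        if ungapped == 0:
            continue  # empty region skipped
        counts[region] = (subs, ungapped)
        rows.append(
            {
                "region": region,
                "ungapped_length": ungapped,
                "n_substitutions": subs,
                "divergence_pct": 100.0 * subs / ungapped,
            }
        )
    out = pd.DataFrame(rows)
    if ARM in counts and SPACER in counts:
        (sa, na), (ss, ns) = counts[ARM], counts[SPACER]
        try:
            chi2_stat, p = yates_chisq_2x2([[sa, na - sa], [ss, ns - ss]])
        except ValueError:  # e.g. identical sequences: no substituted margin
            chi2_stat, p = None, None
        out.attrs["arm_vs_spacer_chi2"] = chi2_stat
        out.attrs["arm_vs_spacer_p"] = p
    return out


def assign_lineage(
    human: str, chimp: str, gorilla: str, column: int = 0, region: str = ""
) -> ReplacementRecord | None:
    """Polarise one ungapped triad column with the gorilla outgroup.

    A replacement is assigned to the human lineage when chimp and gorilla
    agree but human differs, and to the chimpanzee lineage when human and
    gorilla agree but chimp differs.  Identical columns return None;
    three-way differences and gorilla-only differences are UNASSIGNED.
    Non-ACGT symbols raise ValueError (callers skip and tally them).
    """
    bases = (human, chimp, gorilla)
    if any(b in GAP_CHARS for b in bases):
        raise ValueError("gapped column passed to assign_lineage")
    if any(b not in VALID_BASES for b in bases):
        raise ValueError(f"non-ACGT symbol in column: {bases}")
    if human == chimp == gorilla:
        return None
    if chimp == gorilla and human != chimp:
        return ReplacementRecord(column, region, Lineage.HUMAN, chimp, human,
                                 ws_class(chimp, human))
    if human == gorilla and chimp != human:
        return ReplacementRecord(column, region, Lineage.CHIMP, human, chimp,
                                 ws_class(human, chimp))
    # human == chimp != gorilla (gorilla-lineage or stem change), or 3 states
    return ReplacementRecord(column, region, Lineage.UNASSIGNED, gorilla,
                             human if human != gorilla else chimp,
                             ws_class(gorilla, human if human != gorilla else chimp))


def mask_dinucleotide_contexts(triad: TriadAlignment) -> np.ndarray:
    """Columns participating in a CpG, TpG or CpA dinucleotide in any species.

    Dinucleotides are read 5'->3' along each sequence, skipping alignment
    gaps; both members of a triggering dinucleotide are masked, in all
    species.  Returns a boolean array (True = masked) over columns.
    """
    masked = np.zeros(len(triad), dtype=bool)
    for seq in (triad.human, triad.chimp, triad.gorilla):
        prev_col = None
        for col, base in enumerate(seq):
            if base in GAP_CHARS:
                continue
            if prev_col is not None:
                if seq[prev_col] + base in HYPERMUTABLE_DINUCLEOTIDES:
                    masked[prev_col] = True
                    masked[col] = True
            prev_col = col
    return masked


def collect_replacements(
    triad: TriadAlignment,
    mask: RegionMask,
    dinucleotide_mask: np.ndarray | None = None,
) -> tuple[list[ReplacementRecord], pd.DataFrame, int]:
    """Scan the triad alignment for lineage-polarised replacements.

    Returns (records, denominators, n_skipped) where ``denominators`` counts
    the ancestral-base W and S nucleotides per region over analyzable columns
    (ungapped in all three species, inside a labelled region, not
    dinucleotide-masked).  The ancestral base of a column is the base shared
    by at least two species; columns with three distinct bases are excluded
    from denominators.  ``n_skipped`` tallies columns with non-ACGT symbols.
    """
    labels = mask.label_array(len(triad))
    records: list[ReplacementRecord] = []
    denom: dict[tuple[str, str], int] = {}
    skipped = 0
    for col in range(len(triad)):
        region = labels[col]
        if not region:
            continue
        if dinucleotide_mask is not None and dinucleotide_mask[col]:
            continue
        h, c, g = triad.human[col], triad.chimp[col], triad.gorilla[col]
        if any(b in GAP_CHARS for b in (h, c, g)):
            continue
        try:
            record = assign_lineage(h, c, g, column=col, region=region)
        except ValueError:
            skipped += 1
            continue
        ancestral = _ancestral_base(h, c, g)
        if ancestral is not None:
            cls = "S" if ancestral in S_NUCLEOTIDES else "W"
            denom[(region, cls)] = denom.get((region, cls), 0) + 1
        if record is not None:
            records.append(record)
    denominators = pd.DataFrame(
        [
            {"region": region, "ws": cls, "n": n}
            for (region, cls), n in sorted(denom.items())
        ],
        columns=["region", "ws", "n"],
    )
    return records, denominators, skipped


def _ancestral_base(h: str, c: str, g: str) -> str | None:
    """Base shared by at least two species; None for three-way differences."""
    if h == c or h == g:
        return h
    if c == g:
        return c
    return None


def summarize_replacements(n_ws: int, w_nt: int, n_sw: int, s_nt: int) -> dict:
    """Rates and the to-W/to-S ratio from replacement counts and denominators.

    ``pct_ws`` = 100 * W->S replacements / total W nucleotides; ``ratio``
    normalises the to-W rate by the to-S rate:
    (S->W / S nt) / (W->S / W nt).  Zero denominators yield None.
    """
    pct_ws = 100.0 * n_ws / w_nt if w_nt else None
    pct_sw = 100.0 * n_sw / s_nt if s_nt else None
    ratio = (pct_sw / pct_ws) if (pct_ws and pct_sw is not None) else None
    return {"n_ws": n_ws, "w_nt": w_nt, "pct_ws": pct_ws,
            "n_sw": n_sw, "s_nt": s_nt, "pct_sw": pct_sw,
            "ratio_to_w_over_to_s": ratio}


def replacement_table(
    triad: TriadAlignment, mask: RegionMask, apply_dinucleotide_mask: bool = False
) -> pd.DataFrame:
    """Per lineage x region replacement summary (optionally dinucleotide-masked).

    One row per (lineage, region): total replacements, W->S and S->W counts,
    W/S denominators, percentages, the normalised to-W/to-S ratio, and the
    Yates p-value contrasting this region's W->S vs S->W rates.  The frame's
    attrs carry arm:spacer rate ratios and arm-vs-spacer Yates p-values per
    lineage and replacement class.
    """
    dmask = mask_dinucleotide_contexts(triad) if apply_dinucleotide_mask else None
    records, denominators, _ = collect_replacements(triad, mask, dmask)
    denom = {(r.region, r.ws): r.n for r in denominators.itertuples()}
    regions = sorted({lab for _, _, lab in mask.intervals})
    rows = []
    attrs: dict[str, float] = {}
    for lineage in (Lineage.HUMAN, Lineage.CHIMP):
        per_region: dict[str, dict] = {}
        for region in regions:
            recs = [r for r in records if r.lineage is lineage and r.region == region]
            n_ws = sum(r.ws is WsClass.W_TO_S for r in recs)
            n_sw = sum(r.ws is WsClass.S_TO_W for r in recs)
            w_nt = denom.get((region, "W"), 0)
            s_nt = denom.get((region, "S"), 0)
            summary = summarize_replacements(n_ws, w_nt, n_sw, s_nt)
            summary.update({"lineage": lineage.value, "region": region,
                            "total_replacements": len(recs)})
            if w_nt and s_nt:
                _, summary["p_to_w_vs_to_s"] = yates_chisq_2x2(
                    [[n_ws, w_nt - n_ws], [n_sw, s_nt - n_sw]]
                )
            else:
                summary["p_to_w_vs_to_s"] = None
            per_region[region] = summary
            rows.append(summary)
        if ARM in per_region and SPACER in per_region:
            arm, spc = per_region[ARM], per_region[SPACER]
            for key, label in (("pct_ws", "ws"), ("pct_sw", "sw")):
                if arm[key] and spc[key]:
                    attrs[f"{lineage.value}_arm_spacer_ratio_{label}"] = arm[key] / spc[key]
            for nkey, dkey, label in (("n_ws", "w_nt", "ws"), ("n_sw", "s_nt", "sw")):
                if arm[dkey] and spc[dkey]:
                    _, p = yates_chisq_2x2(
                        [[arm[nkey], arm[dkey] - arm[nkey]],
                         [spc[nkey], spc[dkey] - spc[nkey]]]
                    )
                    attrs[f"{lineage.value}_arm_vs_spacer_p_{label}"] = p
    out = pd.DataFrame(rows)
    out.attrs.update(attrs)
    return out


def gc_content_test(seq_a: str, seq_b: str, yates: bool = False) -> dict:
    """GC percentage of two sequences and a 2x2 chi-square on S/W counts."""
    from scipy.stats import chi2_contingency

    def counts(seq: str) -> tuple[int, int]:
        seq = seq.upper()
        s = sum(b in S_NUCLEOTIDES for b in seq)
        w = sum(b in W_NUCLEOTIDES for b in seq)
        if s + w == 0:
            raise ValueError("sequence has no ACGT bases")
        return s, w

    sa, wa = counts(seq_a)
    sb, wb = counts(seq_b)
    table = np.array([[sa, wa], [sb, wb]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        p = 1.0
    else:
        p = float(chi2_contingency(table, correction=yates).pvalue)
    return {
        "gc_a_pct": 100.0 * sa / (sa + wa),
        "gc_b_pct": 100.0 * sb / (sb + wb),
        "p": p,
    }


NO_CALL = "N"


def consensus_from_pileup(
    reads: Iterable[tuple[str, float]], min_reads: int = 5, min_qual: float = 20.0,
    max_discordant_fraction: float = 0.0,
) -> str:
    """Consensus base from (base, quality) read evidence, or ``"N"``.

    A base is called iff at least ``min_reads`` quality-passing reads support
    it and the fraction of quality-passing reads supporting any other base is
    at most ``max_discordant_fraction`` (0 = strict unanimity).
    """
    passing = [(b.upper(), q) for b, q in reads if q >= min_qual]
    if not passing:
        return NO_CALL
    tally: dict[str, int] = {}
    for base, _ in passing:
        tally[base] = tally.get(base, 0) + 1
    best = max(tally, key=tally.get)
    discordant = sum(n for b, n in tally.items() if b != best)
    if tally[best] >= min_reads and discordant <= max_discordant_fraction * len(passing):
        return best
    return NO_CALL
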