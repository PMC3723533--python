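"""End-to-end orchestration: load -> call -> test -> rate -> phase -> triad.

`run_pipeline` ties the stages together the way the full analysis is run:
conversion calling on the haplogroup tree, directional and GC bias tests
(raw, and deduplicated after collapsing co-conversion tracts), rate
estimation against a generation budget, inversion and tract inference from
phase data, and optionally the interspecific arm/spacer comparisons.  Every
output table carries a provenance header (tool version, config hash, seed)
and the whole run is deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, datasets
from .caller import ConversionEventTable, enumerate_events
from .evo import RegionMask, TriadAlignment, region_divergence, replacement_table
from .model import load_inputs
from .phase import (
    Orientation,
    borrow_phase,
    min_coconversion_tracts,
    min_inversions,
    phase_orientation,
    tract_stats,
)
from .simulate import load_phase_table, load_reference_phase
from .stats import GenerationBudget, gof_chisq, rate_range

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Inputs, options and output location for one pipeline run.

    Defaults reproduce the published analysis settings: no continuity
    correction on the 1:1 bias tests, Yates on 2x2 region contrasts, the
    printed 175,000-505,500 generation budget, and the PSV1-7 phased window.
    """

    tree: str
    samples: str
    psvs: str
    genotypes: str
    outdir: str
    phases: str | None = None
    reference_phase: str | None = None
    alignment: str | None = None
    regions: str | None = None
    gen_lower: float = 175_000.0
    gen_upper: float = 505_500.0
    phased_window: list[str] = field(default_factory=lambda: list(datasets.PHASED_WINDOW))
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        # analysis-relevant fields only: where the output lands (and how
        # chatty the run is) must not change the provenance stamp
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("outdir", "verbosity")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (
        f"# palinconv {__version__} config={config.config_hash()} seed={config.seed}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the summary bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # ---- stage: call-conversions
    try:
        tree, psvs, matrix = load_inputs(
            config.tree, config.samples, config.psvs, config.genotypes
        )
    except FileNotFoundError as exc:
        raise PipelineError(f"load-inputs: missing input file: {exc.filename}") from exc
    except Exception as exc:
        raise PipelineError(f"load-inputs: {exc}") from exc
    try:
        calls = enumerate_events(tree, matrix, psvs)
    except Exception as exc:
        raise PipelineError(f"call-conversions: {exc}") from exc
    _write_table(calls.events, outdir / "events.tsv", config)
    summary["conversion_calls"] = calls.summary()

    # ---- stage: test-bias (raw)
    summary["bias_tests"] = {"raw": _bias_tests(calls.summary())}

    # ---- stage: estimate-rate
    budget = GenerationBudget.from_generations(config.gen_lower, config.gen_upper)
    rates = rate_range(calls.summary()["total_events"], budget)
    summary["rates"] = {
        "n_events": rates.n_events,
        "generations": [budget.gen_lower, budget.gen_upper],
        "conversion_rate_per_generation": [rates.rate_lower, rates.rate_upper],
    }

    # ---- stage: phase (optional)
    if config.phases and config.reference_phase:
        try:
            summary["phase"] = _phase_stage(
                config, outdir, tree, matrix, calls, psvs
            )
        except Exception as exc:
            raise PipelineError(f"phase: {exc}") from exc
        dedup = summary["phase"].get("deduplicated_bias")
        if dedup is not None:
            summary["bias_tests"]["deduplicated"] = dedup

    # ---- stage: interspecific (optional)
    if config.alignment and config.regions:
        try:
            summary["interspecific"] = _interspecific_stage(config, outdir)
        except Exception as exc:
            raise PipelineError(f"interspecific: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _bias_tests(counts: dict) -> dict:
    out = {}
    if counts["total_events"]:
        r = gof_chisq(counts["to_ancestral"], counts["to_derived"])
        out["direction"] = {"to_ancestral": r.count_a, "to_derived": r.count_b,
                            "chi2": r.chi2, "p": r.p}
    if counts["gc_informative"]:
        r = gof_chisq(counts["fixes_S"], counts["fixes_W"])
        out["gc"] = {"fixes_S": r.count_a, "fixes_W": r.count_b,
                     "chi2": r.chi2, "p": r.p}
    return out


def _phase_stage(config, outdir, tree, matrix, calls: ConversionEventTable, psvs):
    phase_df = load_phase_table(config.phases)
    reference = load_reference_phase(config.reference_phase)
    window = [p for p in config.phased_window if p in {x.id for x in psvs}]

    by_sample: dict[str, dict] = {}
    for row in phase_df.itertuples():
        by_sample.setdefault(row.sample_id, {})[row.psv_id] = (
            row.proximal_allele, row.distal_allele
        )
    orientations = {
        s: phase_orientation(rows, reference) for s, rows in by_sample.items()
    }
    orientations = borrow_phase(tree, orientations)
    informative = {
        s: [p for p, (a, b) in rows.items() if a != b]
        for s, rows in by_sample.items()
    }
    inversions = min_inversions(tree, orientations, psvs, informative)
    inv_df = pd.DataFrame(
        [
            {
                "parent": c.parent,
                "child": c.child,
                "interval_start": c.interval_bp[0] if c.interval_bp else "",
                "interval_end": c.interval_bp[1] if c.interval_bp else "",
            }
            for c in inversions
        ],
        columns=["parent", "child", "interval_start", "interval_end"],
    )
    _write_table(inv_df, outdir / "inversions.tsv", config)

    tracts = min_coconversion_tracts(tree, matrix, calls, psvs, reference, window)
    _write_table(tracts.to_frame(), outdir / "tracts.tsv", config)
    stats = tract_stats(tracts)

    dedup = _deduplicated_bias(calls, tracts, psvs)
    return {
        "n_phased_samples": len(by_sample),
        "orientation_counts": {
            o.value: sum(1 for v in orientations.values() if v is o)
            for o in Orientation
        },
        "n_inversions": len(inversions),
        "tracts": stats,
        "deduplicated_bias": dedup,
    }


def _deduplicated_bias(calls: ConversionEventTable, tracts, psvs) -> dict:
    """Re-run both bias tests counting each co-conversion tract once.

    Multi-PSV tracts collapse to a single event whose direction/GC class is
    taken from the tract's first member; events at PSVs outside any tract
    keep their individual counts.
    """
    from .model import GcClass, gc_class

    psv_by_id = {p.id: p for p in psvs}
    in_tract: dict[tuple[str, str], tuple] = {}
    for t in tracts.tracts:
        if t.size >= 2:
            for pid in t.psv_ids:
                in_tract[(t.haplogroup, pid)] = (t.haplogroup, t.psv_ids, t.fixed_alleles)

    to_anc = to_der = fixes_s = fixes_w = 0
    seen_tracts = set()
    for ev in calls.events.itertuples():
        # a tract lives at a haplogroup; the event branch touches it as
        # either endpoint (stem event: child, within-star event: parent)
        tract = in_tract.get((ev.child, ev.psv_id)) or in_tract.get(
            (ev.parent, ev.psv_id)
        )
        if tract is not None:
            if tract in seen_tracts:
                continue
            seen_tracts.add(tract)
            pid, allele = tract[1][0], tract[2][0]
        else:
            pid = ev.psv_id
            allele = (
                psv_by_id[pid].allele_ancestral
                if ev.direction == "to_ancestral"
                else psv_by_id[pid].allele_derived
            )
        psv = psv_by_id[pid]
        direction_anc = allele == psv.allele_ancestral
        to_anc += direction_anc
        to_der += not direction_anc
        g = gc_class(psv, allele)
        fixes_s += g is GcClass.FIXES_S
        fixes_w += g is GcClass.FIXES_W

    out = {}
    if to_anc + to_der:
        r = gof_chisq(to_anc, to_der)
        out["direction"] = {"to_ancestral": to_anc, "to_derived": to_der,
                            "chi2": r.chi2, "p": r.p}
    if fixes_s + fixes_w:
        r = gof_chisq(fixes_s, fixes_w)
        out["gc"] = {"fixes_S": fixes_s, "fixes_W": fixes_w,
                     "chi2": r.chi2, "p": r.p}
    return out


def _interspecific_stage(config, outdir) -> dict:
    triad = TriadAlignment.from_fasta(config.alignment)
    mask = RegionMask.from_tsv(config.regions)
    out = {}
    pair_rows = []
    for name_a, name_b, seq_a, seq_b in (
        ("human", "chimp", triad.human, triad.chimp),
        ("human", "gorilla", triad.human, triad.gorilla),
        ("chimp", "gorilla", triad.chimp, triad.gorilla),
    ):
        div = region_divergence(seq_a, seq_b, mask)
        for row in div.itertuples():
            pair_rows.append(
                {"pair": f"{name_a}_vs_{name_b}", "region": row.region,
                 "ungapped_length": row.ungapped_length,
                 "n_substitutions": row.n_substitutions,
                 "divergence_pct": row.divergence_pct}
            )
        out[f"{name_a}_vs_{name_b}"] = {
            "arm_vs_spacer_p": div.attrs.get("arm_vs_spacer_p"),
        }
    _write_table(pd.DataFrame(pair_rows), outdir / "divergence.tsv", config)

    repl = {}
    for masked in (False, True):
        table = replacement_table(triad, mask, apply_dinucleotide_mask=masked)
        label = "after_dinucleotide_removal" if masked else "before_dinucleotide_removal"
        _write_table(table, outdir / f"replacements_{label}.tsv", config)
        repl[label] = {
            f"{r.lineage}_{r.region}_ratio": r.ratio_to_w_over_to_s
            for r in table.itertuples()
        }
    out["replacement_ratios"] = repl
    return out
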