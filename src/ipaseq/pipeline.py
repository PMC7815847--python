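"""End-to-end orchestration of the synthetic-world analysis plus bookkeeping.

The stage order mirrors the analysis narrative: PASS-read extraction per
library -> clustering -> exclusion intervals -> gene assignment ->
expression/robustness filters -> category annotation -> single-site
re-annotation -> ambiguous-overlap removal -> FPU -> differential IpA calls
with RNA-seq validation -> optional knockdown intersection -> distal 3'UTR
usage. Every stage logs input / per-reason removals / retained so that
conservation (input = retained + removed) can be asserted at each step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fpu_stats, read_processing, rnaseq_windows, site_calling, synthetic_data
from .genome import Genome
from .site_calling import GeneModel, IntervalSet, ParamSet, PolyASite
from .synthetic_data import SimConfig, TruthSet


@dataclass
class StageLedger:
    """Per-stage bookkeeping: input = retained + sum of per-reason removals."""

    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, n_input: int, removals: dict[str, int], n_retained: int) -> None:
        self.stages.append(
            {"stage": name, "input": n_input, "removals": dict(removals), "retained": n_retained}
        )

    def conserved(self) -> bool:
        return all(
            s["input"] == s["retained"] + sum(s["removals"].values()) for s in self.stages
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s["stage"],
                    "input": s["input"],
                    "removed": sum(s["removals"].values()),
                    "retained": s["retained"],
                }
                for s in self.stages
            ]
        )


@dataclass
class PipelineResult:
    config: SimConfig
    params: ParamSet
    genome: Genome
    models: list[GeneModel]
    truth: TruthSet
    library_stats: dict[str, dict[str, int]]
    pass_reads: dict[str, list]
    sites: list[PolyASite]
    site_table: pd.DataFrame
    counts: pd.DataFrame
    genes: pd.Series
    fpu: pd.DataFrame
    diff: pd.DataFrame
    window_counts: dict[str, pd.DataFrame]
    ipa_result: fpu_stats.DifferentialIpAResult
    distal: pd.DataFrame
    ledger: StageLedger
    rnaseq_reads: dict[str, pd.DataFrame]
    knockdown_diff: pd.DataFrame | None = None
    cpsf_calls: pd.DataFrame | None = None

    @property
    def calls(self) -> pd.DataFrame:
        c = self.ipa_result.calls
        return c[c["passed"]] if len(c) else c


def run_synthetic_pipeline(
    config: SimConfig,
    params: ParamSet | None = None,
    interval_sets: list[IntervalSet] | None = None,
    rnaseq_depth: int = 100_000,
) -> PipelineResult:
    """Simulate a world from ``config`` and run the full analysis on it."""
    params = params or ParamSet()
    interval_sets = interval_sets or []
    genome, models, truth = synthetic_data.build_toy_world(config)
    conditions = config.all_conditions()
    cond_A, cond_B = config.conditions

    # --- per-library PASS-read extraction ---------------------------------
    library_stats: dict[str, dict[str, int]] = {}
    pass_reads: dict[str, list] = {}
    rows = []
    for cond in conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            label = site_calling.library_label(cond, rep)
            records = synthetic_data.simulate_threads_library(genome, truth, cond, config, rep)
            raw = [
                read_processing.RawRead(r.read_id, r.sequence, r.quality) for r in records
            ]
            passed, stats = read_processing.process_reads(
                raw,
                genome,
                umi_length=config.umi_length,
                min_insert=params.min_insert,
                min_mapq=params.min_mapq,
                rescue_window=params.rescue_window,
            )
            library_stats[label] = stats
            pass_reads[label] = passed
            rows += [
                (p.chrom, p.transcript_strand, p.cleavage_pos, cond, rep) for p in passed
            ]
    pass_df = pd.DataFrame(
        rows, columns=["chrom", "strand", "position", "condition", "replicate"]
    )

    # --- RNA-seq simulation ------------------------------------------------
    rnaseq_reads = {
        cond: synthetic_data.simulate_rnaseq_library(
            genome, models, truth, cond, rnaseq_depth, seed=config.seed + 101 + i
        )
        for i, cond in enumerate(conditions)
    }
    gene_tbl = pd.DataFrame(
        {cond: rnaseq_windows.gene_counts(reads, models) for cond, reads in rnaseq_reads.items()}
    )

    # --- site calling ------------------------------------------------------
    ledger = StageLedger()
    sites = site_calling.cluster_ends(pass_df, params.merge_window)
    ledger.record("cluster", len(sites), {}, len(sites))  # aggregation, no removals

    retained, removed = site_calling.apply_exclusion_filters(sites, interval_sets)
    ledger.record(
        "exclusion_intervals",
        len(sites),
        {label: sum(1 for s in removed if label in s.filter_flags)
         for label in {f for s in removed for f in s.filter_flags}},
        len(retained),
    )

    n_in = len(retained)
    retained, removed = site_calling.assign_genes(retained, models)
    ledger.record(
        "gene_assignment",
        n_in,
        {
            "intergenic": sum(1 for s in removed if "intergenic" in s.filter_flags),
            "multiple_genes": sum(1 for s in removed if "multiple_genes" in s.filter_flags),
        },
        len(retained),
    )

    n_in = len(retained)
    gene_tbl_ab = gene_tbl[[cond_A, cond_B]]
    retained, removed, robust_stats = site_calling.apply_robustness_filters(
        retained, gene_tbl_ab, params
    )
    ledger.record("robustness", n_in, {"failed_any_criterion": len(removed)}, len(retained))

    site_calling.annotate_all(retained, models)
    retained, adjustments = site_calling.reannotate_single_site_genes(retained)

    n_in = len(retained)
    retained, removed = site_calling.flag_ambiguous_overlaps(retained, models)
    ledger.record("ambiguous_overlap", n_in, {"ambiguous_overlap": len(removed)}, len(retained))

    sites = retained
    site_table = site_calling.sites_to_frame(sites)
    counts, genes = site_calling.sites_count_frame(sites)

    # --- statistics --------------------------------------------------------
    fpu = fpu_stats.compute_fpu(counts, genes) if len(sites) else counts
    if len(sites):
        diff = fpu_stats.differential_site_usage(counts, genes, cond_A, cond_B)
    else:
        diff = pd.DataFrame()
    window_counts = {
        cond: rnaseq_windows.count_site_windows(rnaseq_reads[cond], sites, params)
        for cond in (cond_A, cond_B)
    }
    libsizes = {cond: len(rnaseq_reads[cond]) for cond in (cond_A, cond_B)}
    ipa_result = fpu_stats.call_differential_ipa(
        diff, site_table, window_counts, cond_A, cond_B, params, libsizes
    ) if len(sites) else fpu_stats.DifferentialIpAResult(pd.DataFrame(), 0)
    distal = fpu_stats.distal_usage_index(counts, site_table, cond_A, cond_B, params) \
        if len(sites) else pd.DataFrame()

    knockdown_diff = None
    cpsf_calls = None
    if config.include_knockdown and len(sites):
        knockdown_diff = fpu_stats.differential_site_usage(counts, genes, "CTRL", "KD")
        cpsf_calls = fpu_stats.cpsf_dependence(
            ipa_result.calls if len(ipa_result.calls) else pd.DataFrame(columns=["passed"]),
            knockdown_diff,
            params,
        )

    result = PipelineResult(
        config=config,
        params=params,
        genome=genome,
        models=models,
        truth=truth,
        library_stats=library_stats,
        pass_reads=pass_reads,
        sites=sites,
        site_table=site_table,
        counts=counts,
        genes=genes,
        fpu=fpu,
        diff=diff,
        window_counts=window_counts,
        ipa_result=ipa_result,
        distal=distal,
        ledger=ledger,
        rnaseq_reads=rnaseq_reads,
        knockdown_diff=knockdown_diff,
        cpsf_calls=cpsf_calls,
    )
    result._robust_stats = robust_stats            # per-criterion removal counts
    result._reannotation = adjustments             # prior-category adjustment counts
    return result


# ---------------------------------------------------------------------------
# evaluation against planted truth


def truth_support_counts(result: PipelineResult) -> pd.Series:
    """Pooled PASS-read support per truth site, keyed by (chrom, position)."""
    from .synthetic_data import read_origin

    counts: dict[tuple[str, int], int] = {}
    for reads in result.pass_reads.values():
        for r in reads:
            kind, _gene, chrom, pos = read_origin(r.read_id)
            if kind == "site":
                counts[(chrom, pos)] = counts.get((chrom, pos), 0) + 1
    return pd.Series(counts, dtype=int)


def match_sites_to_truth(result: PipelineResult, tolerance: int | None = None) -> dict:
    """Site-level recovery and precision against planted truth.

    A truth site with at least 10 pooled supporting PASS reads counts as
    recovered when a final site of matching strand lies within ``tolerance``
    (default: the merge window) of its planted position. Precision is the
    fraction of final sites within tolerance of any truth site.
    """
    tol = result.params.merge_window if tolerance is None else tolerance
    support = truth_support_counts(result)
    eligible = [
        s for s in result.truth.sites
        if support.get((s.chrom, s.cleavage_pos), 0) >= 10
    ]
    final = [(s.chrom, s.strand, s.position) for s in result.sites]
    recovered = 0
    for t in eligible:
        if any(
            c == t.chrom and st == t.strand and abs(p - t.cleavage_pos) <= tol
            for c, st, p in final
        ):
            recovered += 1
    truth_pos = [(t.chrom, t.strand, t.cleavage_pos) for t in result.truth.sites]
    matched_calls = sum(
        1
        for c, st, p in final
        if any(tc == c and ts == st and abs(tp - p) <= tol for tc, ts, tp in truth_pos)
    )
    return {
        "n_truth_eligible": len(eligible),
        "n_recovered": recovered,
        "recovery": recovered / len(eligible) if eligible else float("nan"),
        "n_called": len(final),
        "n_called_matching_truth": matched_calls,
        "precision": matched_calls / len(final) if final else float("nan"),
    }


def planted_differential_sites(result: PipelineResult) -> list:
    """Truth intronic sites whose usage shifts between the two conditions."""
    a, b = result.config.conditions
    return [
        s for s in result.truth.sites
        if s.category == "intron"
        and abs(s.usage_fraction_by_condition[a] - s.usage_fraction_by_condition[b]) > 1e-9
    ]


def _truth_to_called_site(result: PipelineResult, truth_site) -> str | None:
    tol = result.params.merge_window
    best = None
    for s in result.sites:
        if (
            s.chrom == truth_site.chrom
            and s.strand == truth_site.strand
            and abs(s.position - truth_site.cleavage_pos) <= tol
        ):
            if best is None or abs(s.position - truth_site.cleavage_pos) < abs(
                best.position - truth_site.cleavage_pos
            ):
                best = s
    return best.site_id if best else None


def differential_call_evaluation(result: PipelineResult) -> dict:
    """Recall of planted differential intronic sites (support >= 10 reads) and
    the false-call rate among eligible non-differential intronic sites."""
    support = truth_support_counts(result)
    called_ids = set(result.calls.index) if len(result.calls) else set()
    planted = [
        s for s in planted_differential_sites(result)
        if support.get((s.chrom, s.cleavage_pos), 0) >= 10
    ]
    n_detected = sum(
        1 for s in planted if (_truth_to_called_site(result, s) in called_ids)
    )
    evaluated = set(result.ipa_result.calls.index) if len(result.ipa_result.calls) else set()
    planted_mapped = {_truth_to_called_site(result, s) for s in planted}
    null_eligible = evaluated - planted_mapped
    false_calls = len(called_ids & null_eligible)
    return {
        "n_planted": len(planted),
        "n_detected": n_detected,
        "recall": n_detected / len(planted) if planted else float("nan"),
        "n_null_eligible": len(null_eligible),
        "n_false_calls": false_calls,
        "false_call_rate": false_calls / len(null_eligible) if null_eligible else 0.0,
    }


# ---------------------------------------------------------------------------
# report


def direction_split(calls: pd.DataFrame) -> dict:
    """Up/down counts and percentages of passed differential calls."""
    if len(calls) == 0:
        return {"total": 0, "up": 0, "down": 0, "pct_up": float("nan"), "pct_down": float("nan")}
    up = int((calls["direction"] == "up").sum())
    down = int((calls["direction"] == "down").sum())
    total = len(calls)
    return {
        "total": total,
        "up": up,
        "down": down,
        "pct_up": 100.0 * up / total,
        "pct_down": 100.0 * down / total,
    }


def build_report(result: PipelineResult) -> dict:
    """Machine-readable run summary mirroring the genome-scale bookkeeping."""
    categories = result.site_table["category"].value_counts().to_dict() if len(
        result.site_table
    ) else {}
    split = direction_split(result.calls)
    distal_classes = (
        result.distal["classification"].value_counts().to_dict() if len(result.distal) else {}
    )
    complete = len(result.sites) > 0
    report = {
        "total_sites": len(result.sites),
        "sites_by_category": categories,
        "library_partitions": result.library_stats,
        "stage_ledger": result.ledger.stages,
        "conservation_ok": result.ledger.conserved(),
        "differential_ipa": split,
        "n_unevaluable_ipa": result.ipa_result.n_unevaluable,
        "distal_usage_classes": distal_classes,
        "reannotation_adjustments": getattr(result, "_reannotation", {}),
        "robustness_removals": getattr(result, "_robust_stats", {}),
        "thresholds": {k: getattr(result.params, k) for k in vars(result.params)},
        "incomplete": not complete,
    }
    if result.cpsf_calls is not None:
        report["cpsf_dependent_calls"] = int(len(result.cpsf_calls))
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
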