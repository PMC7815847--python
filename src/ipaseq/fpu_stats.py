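"""Fraction-of-polyA-site-usage (FPU) statistics and differential calling.

FPU is a site's PASS-read count divided by the summed counts over all sites
of the same gene, per library. Because it is a within-gene fraction it is
internally normalized inside each library and comparable across libraries
without depth scaling.

Differential usage between two conditions is threshold-driven: the operative
filter is the fold change of mean FPU (epsilon-floored); the accompanying
p-value comes from a two-sided Fisher exact test on the pooled
site-versus-rest-of-gene count table. Intronic calls additionally require an
RNA-seq window fold change of at least ``fc_rnaseq`` in the same direction
and more RNA-seq counts upstream than downstream of the site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .site_calling import LIBRARY_SEP, ParamSet


def _condition_of(library: str) -> str:
    return library.split(LIBRARY_SEP)[0]


def compute_fpu(counts: pd.DataFrame, genes: pd.Series) -> pd.DataFrame:
    """Per-library FPU for a site x library count matrix.

    ``genes`` maps each site (index of ``counts``) to its gene. Libraries in
    which a gene has zero total counts yield NaN for all its sites in that
    library only.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    gene_totals = counts.groupby(genes).transform("sum")
    fpu = counts / gene_totals.where(gene_totals > 0)
    return fpu


def fpu_records(counts: pd.DataFrame, genes: pd.Series) -> pd.DataFrame:
    """Long-format FPU table: site_id, gene_id, library, count, gene_total, fpu."""
    fpu = compute_fpu(counts, genes)
    gene_totals = counts.groupby(genes).transform("sum")
    long = pd.concat(
        {
            "count": counts.stack(),
            "gene_total": gene_totals.stack(),
            "fpu": fpu.stack(),
        },
        axis=1,
    ).reset_index(names=["site_id", "library"])
    long.insert(1, "gene_id", long["site_id"].map(genes))
    return long


def differential_site_usage(
    counts: pd.DataFrame,
    genes: pd.Series,
    cond_A: str,
    cond_B: str,
    epsilon: float = 1e-4,
) -> pd.DataFrame:
    """Per-site FPU fold change B over A plus a Fisher exact p-value.

    fc = (mean FPU in B + eps) / (mean FPU in A + eps); the mean is over
    replicate libraries where FPU is defined, flooring to 0 when the gene is
    silent in a whole condition (flag ``one_condition``). The p-value tests
    the pooled 2x2 table [site count, rest of gene] x [A, B].
    """
    fpu = compute_fpu(counts, genes)
    libs_A = [c for c in counts.columns if _condition_of(c) == cond_A]
    libs_B = [c for c in counts.columns if _condition_of(c) == cond_B]
    if not libs_A or not libs_B:
        missing = cond_A if not libs_A else cond_B
        raise ValueError(f"no libraries for condition {missing!r}")
    gene_totals = counts.groupby(genes).transform("sum")

    mean_A = fpu[libs_A].mean(axis=1)
    mean_B = fpu[libs_B].mean(axis=1)
    one_condition = mean_A.isna() | mean_B.isna()
    mean_A, mean_B = mean_A.fillna(0.0), mean_B.fillna(0.0)
    fc = (mean_B + epsilon) / (mean_A + epsilon)

    site_A = counts[libs_A].sum(axis=1)
    site_B = counts[libs_B].sum(axis=1)
    rest_A = gene_totals[libs_A].sum(axis=1) - site_A
    rest_B = gene_totals[libs_B].sum(axis=1) - site_B
    pvals = np.ones(len(counts))
    for i, (a, ra, b, rb) in enumerate(zip(site_A, rest_A, site_B, rest_B)):
        if (a or b) and (ra or rb):
            pvals[i] = fisher_exact([[a, ra], [b, rb]], alternative="two-sided")[1]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "mean_fpu_A": mean_A,
            "mean_fpu_B": mean_B,
            "fc_threads": fc,
            "p_value": pvals,
            "direction": np.where(fc >= 1.0, "up", "down"),
            "one_condition": one_condition,
        },
        index=counts.index,
    )


@dataclass(frozen=True)
class DifferentialIpAResult:
    calls: pd.DataFrame           # all evaluated intronic sites, criterion flags
    n_unevaluable: int            # intronic sites lacking RNA-seq window counts


def call_differential_ipa(
    diff: pd.DataFrame,
    site_table: pd.DataFrame,
    window_counts: dict[str, pd.DataFrame],
    cond_A: str,
    cond_B: str,
    params: ParamSet,
    libsizes: dict[str, int] | None = None,
) -> DifferentialIpAResult:
    """Differentially used intronic polyA sites with RNA-seq validation.

    A site is called when all of: category intron; |FPU fold change| beyond
    ``fc_ipa_threads``; RNA-seq +/-100 bp window fold change beyond
    ``fc_rnaseq`` in the same direction; and more RNA-seq counts upstream than
    downstream of the site, evaluated in the condition with higher FPU.
    Per-criterion booleans are retained for reporting.
    """
    intronic = site_table[site_table["category"] == "intron"]
    wc_A, wc_B = window_counts[cond_A], window_counts[cond_B]
    scale = 1.0
    if libsizes and libsizes.get(cond_A) and libsizes.get(cond_B):
        scale = libsizes[cond_A] / libsizes[cond_B]

    rows = []
    n_unevaluable = 0
    for site_id in intronic.index:
        if site_id not in diff.index:
            n_unevaluable += 1
            continue
        if site_id not in wc_A.index or site_id not in wc_B.index:
            n_unevaluable += 1
            continue
        d = diff.loc[site_id]
        down = d["fc_threads"] < 1.0
        fc_threads_pass = (
            d["fc_threads"] >= params.fc_ipa_threads
            or d["fc_threads"] <= 1.0 / params.fc_ipa_threads
        )
        wA = wc_A.loc[site_id, "window_count"]
        wB = wc_B.loc[site_id, "window_count"] * scale
        fc_rna = (wB + 1.0) / (wA + 1.0)
        rna_pass = (fc_rna <= 1.0 / params.fc_rnaseq) if down else (fc_rna >= params.fc_rnaseq)
        high = wc_A if d["mean_fpu_A"] >= d["mean_fpu_B"] else wc_B
        upstream = int(high.loc[site_id, "upstream_count"])
        downstream = int(high.loc[site_id, "downstream_count"])
        rows.append(
            {
                "site_id": site_id,
                "gene_id": d["gene_id"],
                "mean_fpu_A": d["mean_fpu_A"],
                "mean_fpu_B": d["mean_fpu_B"],
                "fc_threads": d["fc_threads"],
                "p_value": d["p_value"],
                "fc_rnaseq": fc_rna,
                "direction": "down" if down else "up",
                "upstream_count": upstream,
                "downstream_count": downstream,
                "fc_threads_pass": bool(fc_threads_pass),
                "fc_rnaseq_pass": bool(rna_pass),
                "upstream_gt_downstream": upstream > downstream,
                "passed": bool(fc_threads_pass and rna_pass and upstream > downstream),
            }
        )
    calls = pd.DataFrame(rows)
    if len(calls):
        calls = calls.set_index("site_id")
    return DifferentialIpAResult(calls=calls, n_unevaluable=n_unevaluable)


def cpsf_dependence(
    calls: pd.DataFrame,
    knockdown_diff: pd.DataFrame,
    params: ParamSet,
) -> pd.DataFrame:
    """Subset of differential IpA calls whose knockdown fold change passes
    ``fc_cpsf`` in the same direction as the differentiation call. Sites
    missing from the knockdown libraries are excluded (column
    ``in_knockdown`` False)."""
    passed = calls[calls["passed"]] if "passed" in calls else calls
    rows = []
    for site_id, call in passed.iterrows():
        if site_id not in knockdown_diff.index:
            continue
        kd_fc = knockdown_diff.loc[site_id, "fc_threads"]
        if call["direction"] == "down":
            dependent = kd_fc <= 1.0 / params.fc_cpsf
        else:
            dependent = kd_fc >= params.fc_cpsf
        if dependent:
            row = call.to_dict()
            row["site_id"] = site_id
            row["fc_knockdown"] = kd_fc
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.set_index("site_id") if len(out) else out


def distal_usage_index(
    counts: pd.DataFrame,
    site_table: pd.DataFrame,
    cond_A: str,
    cond_B: str,
    params: ParamSet,
    epsilon: float = 1e-4,
) -> pd.DataFrame:
    """Per-gene distal 3'UTR usage fraction and its shift between conditions.

    Only genes with >=2 3'UTR sites are eligible; the distal site is the
    3'-most in transcript orientation. distal fraction = distal counts /
    summed 3'UTR counts (replicates pooled per condition); fc = B over A,
    epsilon-floored; classification: lengthened (fc > fc_distal), shortened
    (fc < 1/fc_distal), else unchanged.
    """
    utr = site_table[site_table["category"] == "utr3"]
    libs_A = [c for c in counts.columns if _condition_of(c) == cond_A]
    libs_B = [c for c in counts.columns if _condition_of(c) == cond_B]
    rows = []
    for gene_id, grp in utr.groupby("gene_id"):
        if len(grp) < 2:
            continue
        strand = grp["strand"].iloc[0]
        distal_id = grp["position"].idxmax() if strand == "+" else grp["position"].idxmin()
        fracs = {}
        for cond, libs in ((cond_A, libs_A), (cond_B, libs_B)):
            total = counts.loc[grp.index, libs].to_numpy().sum()
            distal = counts.loc[distal_id, libs].sum()
            fracs[cond] = distal / total if total > 0 else np.nan
        fa, fb = fracs[cond_A], fracs[cond_B]
        fc = (np.nan_to_num(fb) + epsilon) / (np.nan_to_num(fa) + epsilon)
        if fc > params.fc_distal:
            cls = "lengthened"
        elif fc < 1.0 / params.fc_distal:
            cls = "shortened"
        else:
            cls = "unchanged"
        rows.append(
            {
                "gene_id": gene_id,
                "distal_site": distal_id,
                f"distal_fraction_{cond_A}": fa,
                f"distal_fraction_{cond_B}": fb,
                "fc": fc,
                "classification": cls,
            }
        )
    out = pd.DataFrame(rows)
    return out.set_index("gene_id") if len(out) else out


def intersect_de_lists(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> tuple[list[str], dict[str, int]]:
    """Genes differentially expressed in both external DE tables.

    Tables need columns gene, log2fc, pvalue. A gene is shared when it passes
    |fold change| >= fc_min and p < p_max in both tables with the same sign of
    change. Returns (sorted shared genes, Venn counts).
    """
    required = {"gene", "log2fc", "pvalue"}
    for name, tbl in (("table_a", table_a), ("table_b", table_b)):
        missing = required - set(tbl.columns)
        if missing:
            raise ValueError(f"{name} lacks columns: {sorted(missing)}")
    thr = np.log2(fc_min)

    def passing(tbl: pd.DataFrame) -> pd.Series:
        ok = (tbl["log2fc"].abs() >= thr) & (tbl["pvalue"] < p_max)
        return tbl.loc[ok].set_index("gene")["log2fc"]

    a, b = passing(table_a), passing(table_b)
    shared = sorted(
        g for g in set(a.index) & set(b.index) if np.sign(a[g]) == np.sign(b[g])
    )
    venn = {
        "a_only": len(set(a.index) - set(shared)),
        "b_only": len(set(b.index) - set(shared)),
        "shared": len(shared),
    }
    return shared, venn
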