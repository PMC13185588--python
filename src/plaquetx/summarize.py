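"""Taxonomic and cohort summaries, and the final run report.

Covers per-species paired caries/non-caries fold changes, species
accumulation curves over random sample orderings, descriptive cohort
statistics (two-sample t-tests on caries indices, Fisher exact tests on
binary diet variables), and assembly of the machine-readable run report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dge import estimate_size_factors


def species_fold_change(counts: pd.DataFrame, sheet: pd.DataFrame,
                        size_factors: pd.Series | None = None,
                        pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-species paired caries vs non-caries fold changes.

    Species totals (sum of that species' gene counts per sample) are
    size-factor normalized; each subject contributes the ratio
    (caries + pc) / (non_caries + pc). Returns one row per species with the
    median ratio across subjects and the number of subjects with ratio > 1.
    Species with zero counts everywhere are omitted.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    totals = counts.groupby(level="species_id").sum()
    totals = totals.loc[totals.sum(axis=1) > 0]
    norm = totals / size_factors

    pairs = []
    for subj, sub in sheet.groupby("subject_id"):
        car = sub.loc[sub["condition"] == "caries", "sample_id"]
        non = sub.loc[sub["condition"] == "non_caries", "sample_id"]
        if len(car) == 1 and len(non) == 1:
            pairs.append((subj, car.iloc[0], non.iloc[0]))
    rows = []
    for sp in norm.index:
        ratios = [(norm.loc[sp, c] + pseudocount) / (norm.loc[sp, n] + pseudocount)
                  for _, c, n in pairs]
        ratios = np.asarray(ratios)
        rows.append({"species_id": sp, "median_fold_change": float(np.median(ratios)),
                     "n_subjects": len(ratios),
                     "n_subjects_enriched": int((ratios > 1).sum())})
    return pd.DataFrame(rows).set_index("species_id")


def accumulation_curve(per_sample_species_counts: pd.DataFrame,
                       threshold: int = 1000, n_orderings: int = 200,
                       seed: int = 0) -> pd.DataFrame:
    """Species accumulation curve by Monte-Carlo permutation of sample order.

    ``per_sample_species_counts``: species x samples read counts. A species is
    detected in a sample when its count is >= threshold. For m = 1..M the mean
    and standard deviation over random orderings of the number of distinct
    species detected within the first m samples are reported. The mean curve
    is monotone non-decreasing and ends at the total richness.
    """
    if per_sample_species_counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    present = (per_sample_species_counts.to_numpy() >= threshold)
    n_species, n_samples = present.shape
    curves = np.zeros((n_orderings, n_samples))
    for t in range(n_orderings):
        order = rng.permutation(n_samples)
        seen = np.zeros(n_species, dtype=bool)
        for m, j in enumerate(order):
            seen |= present[:, j]
            curves[t, m] = seen.sum()
    return pd.DataFrame({
        "m": np.arange(1, n_samples + 1),
        "mean_species": curves.mean(axis=0),
        "sd_species": curves.std(axis=0, ddof=0),
    })


def expected_accumulation(per_sample_species_counts: pd.DataFrame,
                          threshold: int = 1000) -> np.ndarray:
    """Exact expectation of the accumulation curve under random orderings.

    E[distinct at m] = sum over species of 1 - C(M - d_s, m) / C(M, m), where
    d_s is the number of samples detecting species s. Used as the analytic
    cross-check for the Monte-Carlo curve.
    """
    from math import comb
    present = (per_sample_species_counts.to_numpy() >= threshold)
    M = present.shape[1]
    d = present.sum(axis=1)
    out = np.zeros(M)
    for m in range(1, M + 1):
        out[m - 1] = sum(1.0 - (comb(M - int(ds), m) / comb(M, m) if M - ds >= m else 0.0)
                         for ds in d)
    return out


def cohort_summary(subject_table: pd.DataFrame,
                   numeric_vars: tuple = ("age", "dmft", "dmfs"),
                   binary_vars: tuple = (),
                   welch: bool = False) -> dict:
    """Descriptive cohort statistics and between-group tests.

    ``subject_table`` has one row per subject with a ``group`` column,
    numeric caries-burden indices, and optional binary (0/1) diet variables.
    Numeric variables get two-sample unpaired t-tests (pooled variance by
    default, Welch by flag); binary variables get two-sided Fisher exact
    tests on the 2x2 group x value table. Groups with fewer than two
    subjects skip the tests with a notice.
    """
    groups = list(dict.fromkeys(subject_table["group"]))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = groups
    a = subject_table[subject_table["group"] == ga]
    b = subject_table[subject_table["group"] == gb]
    out: dict = {"groups": {ga: {"n": len(a)}, gb: {"n": len(b)}},
                 "tests": {}, "notices": []}
    for v in numeric_vars:
        if v not in subject_table.columns:
            continue
        out["groups"][ga][f"mean_{v}"] = float(a[v].mean())
        out["groups"][gb][f"mean_{v}"] = float(b[v].mean())
        if len(a) < 2 or len(b) < 2:
            out["notices"].append(f"t-test for {v} skipped: a group has n < 2")
            continue
        t, p = stats.ttest_ind(a[v], b[v], equal_var=not welch)
        out["tests"][v] = {"kind": "t", "statistic": float(t), "p": float(p)}
    for v in binary_vars:
        if v not in subject_table.columns:
            continue
        if len(a) < 2 or len(b) < 2:
            out["notices"].append(f"Fisher test for {v} skipped: a group has n < 2")
            continue
        tab = [[int((a[v] == 1).sum()), int((a[v] == 0).sum())],
               [int((b[v] == 1).sum()), int((b[v] == 0).sum())]]
        _, p = stats.fisher_exact(tab, alternative="two-sided")
        out["tests"][v] = {"kind": "fisher", "table": tab, "p": float(p)}
    return out


# ------------------------------------------------------------------ the report

REPORT_SCHEMA = {
    "sde_counts": dict,        # label -> {direction -> count}
    "top_species_shares": list,
    "convergence": dict,
    "consistency_averages": dict,
    "top_fold_change_species": list,
    "accumulation_curve": list,
    "gaps": list,
}


def validate_report(report: dict) -> list[str]:
    """Return a list of schema violations (empty means valid)."""
    problems = []
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            problems.append(f"missing key: {key}")
        elif not isinstance(report[key], typ):
            problems.append(f"key {key}: expected {typ.__name__}, got {type(report[key]).__name__}")
    if "sde_counts" in report and isinstance(report["sde_counts"], dict):
        for label, dirs in report["sde_counts"].items():
            if not isinstance(dirs, dict) or not all(
                    isinstance(v, int) and v >= 0 for v in dirs.values()):
                problems.append(f"sde_counts[{label}] must map direction -> nonnegative int")
    return problems


def build_report(labels: pd.DataFrame | None = None,
                 shares: pd.DataFrame | None = None,
                 convergence_summary: dict | None = None,
                 consistency_averages: dict | None = None,
                 fold_changes: pd.DataFrame | None = None,
                 curve: pd.DataFrame | None = None,
                 top_n: int = 10) -> dict:
    """Assemble the final machine-readable report.

    Any missing stage produces an entry in ``gaps`` and zeroed/empty fields;
    the document always validates against :data:`REPORT_SCHEMA`.
    """
    gaps = []
    sde_counts: dict = {}
    if labels is not None:
        for (label, direction), cell in labels[labels["label"] != "none"] \
                .groupby(["label", "direction"]):
            sde_counts.setdefault(label, {})[direction] = int(len(cell))
    else:
        gaps.append("labels")

    top_shares = []
    if shares is not None and len(shares):
        top = shares.sort_values("pct", ascending=False).head(top_n)
        top_shares = top.to_dict("records")
    elif shares is None:
        gaps.append("species_shares")

    conv = convergence_summary if convergence_summary is not None else {}
    if convergence_summary is None:
        gaps.append("convergence")

    cons = consistency_averages if consistency_averages is not None else {}
    if consistency_averages is None:
        gaps.append("consistency")

    top_fc = []
    if fold_changes is not None and len(fold_changes):
        top = fold_changes.sort_values("median_fold_change", ascending=False).head(top_n)
        top_fc = top.reset_index().to_dict("records")
    elif fold_changes is None:
        gaps.append("fold_changes")

    curve_data = curve.to_dict("records") if curve is not None else []
    if curve is None:
        gaps.append("accumulation_curve")

    report = {
        "sde_counts": sde_counts,
        "top_species_shares": top_shares,
        "convergence": conv,
        "consistency_averages": cons,
        "top_fold_change_species": top_fc,
        "accumulation_curve": curve_data,
        "gaps": gaps,
    }
    problems = validate_report(report)
    if problems:
        raise AssertionError(f"report failed schema validation: {problems}")
    return report


def render_report_markdown(report: dict) -> str:
    """Short human-readable rendering of the run report."""
    lines = ["# Run report", "", "## SDE gene counts by label and direction"]
    for label, dirs in sorted(report["sde_counts"].items()):
        for d, n in sorted(dirs.items()):
            lines.append(f"- {label} / {d}: {n}")
    lines += ["", "## Top species contributions"]
    for r in report["top_species_shares"]:
        lines.append(f"- {r['species_id']}: {r['pct']:.1f}% of {r['label']} {r['direction']} genes")
    lines += ["", "## Convergence summary"]
    for dclass, s in report["convergence"].items():
        if isinstance(s, dict) and "differed_pct" in s:
            lines.append(f"- {dclass}: {s['n_kos']} KOs, "
                         f"{s['differed_in_attribution']} ({s['differed_pct']:.1f}%) differed in "
                         f"species attribution, {s['no_overlap']} ({s['no_overlap_pct']:.1f}%) with no overlap")
    lines += ["", "## Consistency averages (fraction of subjects with >= 2-fold concordant change)"]
    for g, v in report["consistency_averages"].items():
        lines.append(f"- {g}: {v:.2f}" if isinstance(v, float) and np.isfinite(v) else f"- {g}: NA")
    lines += ["", "## Top median paired fold-change species"]
    for r in report["top_fold_change_species"]:
        lines.append(f"- {r['species_id']}: median {r['median_fold_change']:.1f}x "
                     f"({r['n_subjects_enriched']}/{r['n_subjects']} subjects enriched)")
    if report["gaps"]:
        lines += ["", f"Missing stages: {', '.join(report['gaps'])}"]
    return "\n".join(lines) + "\n"
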