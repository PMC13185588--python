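"""SDE calling, Shared / group-specific labeling, and functional convergence.

A feature is significantly differentially expressed (SDE) in a group when its
BH-adjusted p-value is <= alpha and its shrunken |log2 fold change| is
strictly greater than the cutoff (default 0.58 = log2 1.5). Features SDE in
both groups are labeled "shared"; a feature SDE in exactly one group is
rescued into "shared" when the other group's shrunken fold change is within
the rescue window (default 0.5 log2 units) of the significant one — so that
near-threshold effects are not split by cutoff placement — and otherwise
labeled "<group>_only". Shared features whose two effects disagree in sign
are direction "opposite".

The convergence analysis asks, per KEGG ortholog (KO) differentially
expressed in both groups and in the same direction, whether the species
contributing its SDE genes coincide between groups: identical attribution,
overlapping but different, or no overlap at all (distinct taxa filling the
same functional niche). KOs SDE in only one group are group-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import estimate_size_factors

CONVERGENCE_CATEGORIES = ("identical_attribution", "overlapping_but_different",
                          "no_overlap", "group_specific_AA", "group_specific_LAH")


@dataclass(frozen=True)
class Thresholds:
    alpha: float = 0.05
    lfc_cut: float = 0.58        # log2(1.5)
    rescue_window: float = 0.5   # log2 units
    fold_consistency: float = 2.0
    rescue_sign_guard: bool = True

    def __post_init__(self):
        if min(self.alpha, self.lfc_cut, self.rescue_window, self.fold_consistency) <= 0:
            raise ValueError("thresholds must be positive")


def call_sde(padj: float, shrunken_lfc: float, thresholds: Thresholds = Thresholds()):
    """SDE iff padj <= alpha AND |shrunken lfc| > lfc_cut (strict).

    Returns (is_sde, direction) with direction in {"up", "down", None}.
    Missing padj (NaN) is never SDE.
    """
    if padj is None or not np.isfinite(padj) or not np.isfinite(shrunken_lfc):
        return False, None
    sde = (padj <= thresholds.alpha) and (abs(shrunken_lfc) > thresholds.lfc_cut)
    if not sde:
        return False, None
    return True, ("up" if shrunken_lfc > 0 else "down")


def _pivot_dge(dge: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = dge[dge["contrast"] == group].set_index(["species_id", "gene_id", "ko_id"])
    return sub[["lfc_shrunk", "padj"]]


def label_genes(dge: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Label every feature shared / <groupA>_only / <groupB>_only / none.

    ``dge`` is the long table from :func:`plaquetx.dge.run_contrasts` with
    both contrasts per feature. Returns a frame indexed by feature with
    columns sde_A, sde_B, slfc_A, slfc_B, label, direction; label values use
    the actual group names (e.g. "AA_only"). Direction is "up"/"down" when
    the effective signs agree, "opposite" for shared features with opposing
    signs, NaN for label "none".
    """
    groups = list(dict.fromkeys(dge["contrast"]))
    if len(groups) != 2:
        raise ValueError("need exactly two contrasts")
    ga, gb = groups
    a = _pivot_dge(dge, ga)
    b = _pivot_dge(dge, gb)
    joined = a.join(b, how="inner", lsuffix="_A", rsuffix="_B")

    out = []
    for idx, r in joined.iterrows():
        sde_a, dir_a = call_sde(r["padj_A"], r["lfc_shrunk_A"], thresholds)
        sde_b, dir_b = call_sde(r["padj_B"], r["lfc_shrunk_B"], thresholds)
        la, lb = r["lfc_shrunk_A"], r["lfc_shrunk_B"]
        label, direction = _label_one(sde_a, sde_b, la, lb, ga, gb, thresholds)
        out.append({"sde_A": sde_a, "sde_B": sde_b, "slfc_A": la, "slfc_B": lb,
                    "label": label, "direction": direction})
    res = pd.DataFrame(out, index=joined.index)
    res.attrs["groups"] = (ga, gb)
    return res


def _label_one(sde_a: bool, sde_b: bool, la: float, lb: float,
               ga: str, gb: str, th: Thresholds):
    """The labeling rule for a single feature."""
    if sde_a and sde_b:
        if la * lb < 0:
            return "shared", "opposite"
        return "shared", ("up" if la > 0 else "down")
    if sde_a or sde_b:
        sig, other = (la, lb) if sde_a else (lb, la)
        rescued = (np.isfinite(other)
                   and abs(la - lb) <= th.rescue_window
                   and (other * sig > 0 or not th.rescue_sign_guard))
        if rescued:
            if la * lb < 0:
                return "shared", "opposite"
            return "shared", ("up" if sig > 0 else "down")
        return (f"{ga}_only", "up" if la > 0 else "down") if sde_a \
            else (f"{gb}_only", "up" if lb > 0 else "down")
    return "none", None


def consistency_fraction(counts: pd.DataFrame, sheet: pd.DataFrame,
                         feature, direction: str,
                         size_factors: pd.Series | None = None,
                         thresholds: Thresholds = Thresholds(),
                         pseudocount: float = 0.5) -> dict[str, float]:
    """Fraction of each group's subjects whose paired normalized counts change
    at least ``fold_consistency``-fold in the SDE gene's direction.

    Per subject the ratio (caries + pc) / (non_caries + pc) of size-factor
    normalized counts is computed; a subject is consistent when the ratio is
    >= fold_consistency for an "up" gene or <= 1/fold_consistency for "down".
    Subjects missing either condition are excluded from the denominator.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    y = counts.loc[feature]
    if isinstance(y, pd.DataFrame):
        y = y.iloc[0]
    norm = y / size_factors
    out = {}
    for g, sub in sheet.groupby("group"):
        consistent = total = 0
        for _, pair in sub.groupby("subject_id"):
            car = pair.loc[pair["condition"] == "caries", "sample_id"]
            non = pair.loc[pair["condition"] == "non_caries", "sample_id"]
            if len(car) != 1 or len(non) != 1:
                continue
            total += 1
            ratio = (norm[car.iloc[0]] + pseudocount) / (norm[non.iloc[0]] + pseudocount)
            if direction == "up" and ratio >= thresholds.fold_consistency:
                consistent += 1
            if direction == "down" and ratio <= 1.0 / thresholds.fold_consistency:
                consistent += 1
        out[g] = consistent / total if total else np.nan
    return out


def group_consistency_averages(counts: pd.DataFrame, sheet: pd.DataFrame,
                               labels: pd.DataFrame,
                               size_factors: pd.Series | None = None,
                               thresholds: Thresholds = Thresholds()) -> dict[str, float]:
    """Average, over SDE genes, of each group's consistency fraction.

    A gene enters a group's average when it is SDE in that group; its
    direction is the sign of that group's shrunken fold change.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    ga, gb = labels.attrs.get("groups", ("A", "B"))
    acc = {ga: [], gb: []}
    for idx, r in labels.iterrows():
        for g, sde, slfc in ((ga, r["sde_A"], r["slfc_A"]), (gb, r["sde_B"], r["slfc_B"])):
            if not sde:
                continue
            direction = "up" if slfc > 0 else "down"
            frac = consistency_fraction(counts, sheet, idx, direction,
                                        size_factors, thresholds)[g]
            if np.isfinite(frac):
                acc[g].append(frac)
    return {g: float(np.mean(v)) if v else np.nan for g, v in acc.items()}


# --------------------------------------------------------------- KO hierarchy

def assign_ko_category(ko: str, hierarchy: pd.DataFrame,
                       dataset_ko_counts: dict[tuple, int]) -> tuple:
    """Pick one functional category path for a KO with several.

    ``hierarchy`` has columns ko, levelA, levelB, levelC (levelB/levelC may be
    empty for shallower paths); ``dataset_ko_counts`` maps a path tuple to its
    occurrence count over the SDE genes of the data set. The most common path
    wins; ties go to the deeper (more specific) path, then lexicographic.
    KOs absent from the hierarchy return ("uncategorized",).
    """
    cand = hierarchy[hierarchy["ko"] == ko]
    if cand.empty:
        return ("uncategorized",)
    paths = []
    for r in cand.itertuples():
        path = tuple(x for x in (r.levelA, getattr(r, "levelB", ""), getattr(r, "levelC", ""))
                     if isinstance(x, str) and x)
        paths.append(path)
    return max(paths, key=lambda p: (dataset_ko_counts.get(p, 0), len(p),
                                     tuple(-ord(c) for c in "\x00".join(p))))


def ko_path_counts(labels: pd.DataFrame, hierarchy: pd.DataFrame) -> dict[tuple, int]:
    """Occurrence count of every candidate category path over SDE genes' KOs."""
    counts: dict[tuple, int] = {}
    sde = labels[(labels["sde_A"]) | (labels["sde_B"])]
    for (_, _, ko) in sde.index:
        for r in hierarchy[hierarchy["ko"] == ko].itertuples():
            path = tuple(x for x in (r.levelA, getattr(r, "levelB", ""), getattr(r, "levelC", ""))
                         if isinstance(x, str) and x)
            counts[path] = counts.get(path, 0) + 1
    return counts


# ----------------------------------------------------------------- convergence

def _ko_group_state(labels: pd.DataFrame, which: str):
    """Per KO: (species set of SDE genes, majority direction) for one group.

    ``which`` is "A" or "B". The KO-level direction is the majority sign of
    its SDE genes' shrunken fold changes in that group.
    """
    sde = labels[labels[f"sde_{which}"]]
    state: dict[str, tuple[set, str]] = {}
    for ko, sub in sde.groupby(level="ko_id"):
        species = set(sub.index.get_level_values("species_id"))
        ups = int((sub[f"slfc_{which}"] > 0).sum())
        downs = len(sub) - ups
        direction = "up" if ups >= downs else "down"
        state[ko] = (species, direction)
    return state


def convergence_analysis(labels: pd.DataFrame, catalog_kos: set[str] | None = None):
    """Classify each KO's species attribution across the two groups.

    For KOs SDE in both groups with the same aggregate direction, compare the
    species sets contributing SDE genes: identical_attribution, overlapping_
    but_different, or no_overlap. KOs SDE in exactly one group are
    group_specific. Returns (table, summary) where the table has one row per
    KO and the summary carries counts and percentages per direction class.
    """
    ga, gb = labels.attrs.get("groups", ("A", "B"))
    sa = _ko_group_state(labels, "A")
    sb = _ko_group_state(labels, "B")
    rows = []
    for ko in sorted(set(sa) | set(sb)):
        if catalog_kos is not None and ko not in catalog_kos:
            continue
        in_a, in_b = ko in sa, ko in sb
        if in_a and in_b:
            spa, da = sa[ko]
            spb, db = sb[ko]
            if da != db:
                dir_class = "discordant"
                cat = "overlapping_but_different" if (spa & spb) else "no_overlap"
                if spa == spb:
                    cat = "identical_attribution"
            else:
                dir_class = f"{da}_in_both"
                if spa == spb:
                    cat = "identical_attribution"
                elif spa & spb:
                    cat = "overlapping_but_different"
                else:
                    cat = "no_overlap"
            rows.append({"ko": ko, "direction_class": dir_class, "category": cat,
                         f"species_{ga}": ",".join(sorted(spa)),
                         f"species_{gb}": ",".join(sorted(spb))})
        else:
            g = ga if in_a else gb
            sp, d = (sa if in_a else sb)[ko]
            rows.append({"ko": ko, "direction_class": f"{d}_{g}_only",
                         "category": f"group_specific_{g}",
                         f"species_{ga}": ",".join(sorted(sp)) if in_a else "",
                         f"species_{gb}": ",".join(sorted(sp)) if in_b else ""})
    table = pd.DataFrame(rows, columns=["ko", "direction_class", "category",
                                        f"species_{ga}", f"species_{gb}"])
    summary = {}
    for dclass in ("up_in_both", "down_in_both"):
        sub = table[table["direction_class"] == dclass]
        n = len(sub)
        cats = sub["category"].value_counts().to_dict()
        differed = n - cats.get("identical_attribution", 0)
        summary[dclass] = {
            "n_kos": n,
            "categories": cats,
            "differed_in_attribution": differed,
            "differed_pct": 100.0 * differed / n if n else 0.0,
            "no_overlap": cats.get("no_overlap", 0),
            "no_overlap_pct": 100.0 * cats.get("no_overlap", 0) / n if n else 0.0,
        }
    n_spec = int(table["category"].str.startswith("group_specific").sum())
    summary["group_specific"] = {
        "n_kos": n_spec,
        ga: int((table["category"] == f"group_specific_{ga}").sum()),
        gb: int((table["category"] == f"group_specific_{gb}").sum()),
    }
    return table, summary


def species_contribution_shares(labels: pd.DataFrame) -> pd.DataFrame:
    """Percentage of genes attributed to each species within every
    label x direction cell. Percentages in a cell sum to 100."""
    sub = labels[labels["label"] != "none"]
    rows = []
    for (label, direction), cell in sub.groupby(["label", "direction"]):
        total = len(cell)
        per_sp = cell.groupby(level="species_id").size()
        for sp, n in per_sp.items():
            rows.append({"label": label, "direction": direction,
                         "species_id": sp, "n_genes": int(n),
                         "pct": 100.0 * n / total})
    return pd.DataFrame(rows, columns=["label", "direction", "species_id", "n_genes", "pct"])
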