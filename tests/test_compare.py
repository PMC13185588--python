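"""The SDE labeling rule (with the rescue window), consistency metric, KO
category tie-breaking, convergence categories, and species shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquetx.compare import (Thresholds, assign_ko_category, call_sde,
                              consistency_fraction, convergence_analysis,
                              ko_path_counts, label_genes, _label_one,
                              species_contribution_shares)

TH = Thresholds()


def _dge_from_rows(rows):
    """rows: (species, gene, ko, slfc_A, padj_A, slfc_B, padj_B)."""
    recs = []
    for sp, g, ko, la, pa, lb, pb in rows:
        recs.append({"species_id": sp, "gene_id": g, "ko_id": ko, "contrast": "AA",
                     "baseMean": 100.0, "lfc_raw": la, "lfc_shrunk": la,
                     "se": 0.2, "pvalue": pa, "padj": pa})
        recs.append({"species_id": sp, "gene_id": g, "ko_id": ko, "contrast": "LAH",
                     "baseMean": 100.0, "lfc_raw": lb, "lfc_shrunk": lb,
                     "se": 0.2, "pvalue": pb, "padj": pb})
    return pd.DataFrame(recs)


# --------------------------------------------------------------------- call_sde

@pytest.mark.parametrize("padj,slfc,want", [
    (0.04, 0.70, (True, "up")),
    (0.05, 0.58, (False, None)),   # strictly greater than the lfc cutoff
    (0.05, 0.581, (True, "up")),   # padj <= alpha is inclusive
    (0.06, 3.0, (False, None)),
    (0.01, -0.9, (True, "down")),
    (np.nan, 2.0, (False, None)),
])
def test_call_sde_thresholds(padj, slfc, want):
    assert call_sde(padj, slfc, TH) == want


# ------------------------------------------------------------------- label rule

@pytest.mark.parametrize("la,pa,lb,pb,label,direction", [
    (1.2, 0.01, 0.9, 0.01, "shared", "up"),          # SDE in both
    (1.0, 0.01, 0.6, 0.5, "shared", "up"),           # rescued: |diff| 0.4 <= 0.5
    (1.0, 0.01, 0.4, 0.5, "AA_only", "up"),          # outside window
    (1.0, 0.01, -1.0, 0.01, "shared", "opposite"),   # both SDE, opposite signs
    (-1.2, 0.01, -0.8, 0.02, "shared", "down"),
    (0.1, 0.9, 0.2, 0.8, "none", None),
    (0.2, 0.9, -1.5, 0.01, "LAH_only", "down"),
    (1.0, 0.01, -0.2, 0.5, "AA_only", "up"),         # sign guard blocks rescue
])
def test_label_rule_cases(la, pa, lb, pb, label, direction):
    dge = _dge_from_rows([("s", "g", "K", la, pa, lb, pb)])
    res = label_genes(dge, TH)
    row = res.iloc[0]
    assert row["label"] == label
    assert (row["direction"] == direction) or (direction is None and pd.isna(row["direction"]))


def test_sign_guard_flag_allows_literal_window():
    th = Thresholds(rescue_sign_guard=False)
    dge = _dge_from_rows([("s", "g", "K", 0.7, 0.01, 0.3, 0.5)])
    assert label_genes(dge, th).iloc[0]["label"] == "shared"
    dge2 = _dge_from_rows([("s", "g", "K", 0.6, 0.01, 0.2, 0.5)])
    # |diff| = 0.4 <= 0.5 but signs... both positive; make a sign-flipped case
    dge3 = _dge_from_rows([("s", "g", "K", 0.59, 0.01, 0.1, 0.5)])
    assert label_genes(dge3, th).iloc[0]["label"] == "shared"


def test_labels_partition_features(planted_run):
    labels = planted_run["labels"]
    assert labels["label"].isin(["shared", "AA_only", "LAH_only", "none"]).all()
    shared = labels[labels["label"] == "shared"]
    n_dir = shared["direction"].isin(["up", "down", "opposite"]).sum()
    assert n_dir == len(shared)


# ------------------------------------------------------------------ consistency

def test_consistency_fraction_arithmetic():
    # 3 subjects in one group; normalized pairs (4,1), (3,1), (1,1): with the
    # 0.5 pseudocount ratios are 3.0, 2.33, 1.0 -> 2 of 3 subjects >= 2-fold up
    sheet = pd.DataFrame([
        {"sample_id": f"p{i}_{c}", "subject_id": f"p{i}", "group": "AA",
         "condition": c} for i in range(3) for c in ("caries", "non_caries")])
    counts = pd.DataFrame(
        [[4, 1, 3, 1, 1, 1]],
        index=pd.MultiIndex.from_tuples([("s", "g", "K")],
                                        names=["species_id", "gene_id", "ko_id"]),
        columns=[f"p{i}_{c}" for i in range(3) for c in ("caries", "non_caries")])
    sf = pd.Series(1.0, index=counts.columns)
    frac = consistency_fraction(counts, sheet, ("s", "g", "K"), "up", sf, TH)
    assert frac["AA"] == pytest.approx(2 / 3)
    frac_dn = consistency_fraction(counts, sheet, ("s", "g", "K"), "down", sf, TH)
    assert frac_dn["AA"] == 0.0


def test_consistency_all_equal_pairs_zero():
    sheet = pd.DataFrame([
        {"sample_id": f"p{i}_{c}", "subject_id": f"p{i}", "group": "AA",
         "condition": c} for i in range(2) for c in ("caries", "non_caries")])
    counts = pd.DataFrame(
        [[5, 5, 7, 7]],
        index=pd.MultiIndex.from_tuples([("s", "g", "K")],
                                        names=["species_id", "gene_id", "ko_id"]),
        columns=sheet["sample_id"])
    sf = pd.Series(1.0, index=counts.columns)
    assert consistency_fraction(counts, sheet, ("s", "g", "K"), "up", sf, TH)["AA"] == 0.0


def test_consistency_high_for_planted_shared_up(planted_run):
    counts, sheet = planted_run["counts"], planted_run["sheet"]
    truth, labels = planted_run["truth"], planted_run["labels"]
    from plaquetx.dge import estimate_size_factors
    sf = estimate_size_factors(counts)
    up = truth[truth["klass"] == "shared_up"].index[:30]
    fracs = [consistency_fraction(counts, sheet, f, "up", sf, TH) for f in up]
    for g in ("AA", "LAH"):
        assert np.mean([f[g] for f in fracs]) >= 0.6


# ------------------------------------------------------------------ KO category

def test_ko_category_most_common_then_depth():
    hier = pd.DataFrame([
        {"ko": "K1", "levelA": "Metabolism", "levelB": "Carbohydrate", "levelC": "Glycolysis"},
        {"ko": "K1", "levelA": "Signaling", "levelB": "Two-component", "levelC": ""},
        {"ko": "K2", "levelA": "Metabolism", "levelB": "", "levelC": ""},
    ])
    counts = {("Metabolism", "Carbohydrate", "Glycolysis"): 5,
              ("Signaling", "Two-component"): 2}
    assert assign_ko_category("K1", hier, counts) == ("Metabolism", "Carbohydrate", "Glycolysis")
    # tie on counts -> deeper path wins
    tie = {("Metabolism", "Carbohydrate", "Glycolysis"): 2, ("Signaling", "Two-component"): 2}
    assert assign_ko_category("K1", hier, tie) == ("Metabolism", "Carbohydrate", "Glycolysis")
    assert assign_ko_category("K2", hier, {}) == ("Metabolism",)
    assert assign_ko_category("K404", hier, {}) == ("uncategorized",)


# ------------------------------------------------------------------ convergence

def _labels_frame(rows):
    """rows: (species, gene, ko, sde_A, slfc_A, sde_B, slfc_B, label, direction)."""
    idx = pd.MultiIndex.from_tuples([(r[0], r[1], r[2]) for r in rows],
                                    names=["species_id", "gene_id", "ko_id"])
    df = pd.DataFrame({
        "sde_A": [r[3] for r in rows], "sde_B": [r[5] for r in rows],
        "slfc_A": [r[4] for r in rows], "slfc_B": [r[6] for r in rows],
        "label": [r[7] for r in rows], "direction": [r[8] for r in rows]}, index=idx)
    df.attrs["groups"] = ("AA", "LAH")
    return df


def test_convergence_categories():
    labels = _labels_frame([
        ("X", "g1", "K1", True, 1.0, False, 0.0, "AA_only", "up"),
        ("Y", "g2", "K1", False, 0.0, True, 1.0, "LAH_only", "up"),   # no overlap
        ("X", "g3", "K2", True, 1.0, True, 1.0, "shared", "up"),      # identical
        ("X", "g4", "K3", True, 1.0, True, 1.1, "shared", "up"),
        ("Y", "g5", "K3", True, 1.0, False, 0.0, "AA_only", "up"),    # overlapping
        ("Z", "g6", "K4", True, -2.0, False, 0.0, "AA_only", "down"), # group specific
    ])
    table, summary = convergence_analysis(labels)
    cat = table.set_index("ko")["category"]
    assert cat["K1"] == "no_overlap"
    assert cat["K2"] == "identical_attribution"
    assert cat["K3"] == "overlapping_but_different"
    assert cat["K4"] == "group_specific_AA"
    up = summary["up_in_both"]
    assert up["n_kos"] == 3 and up["no_overlap"] == 1
    assert up["differed_in_attribution"] == 2
    assert summary["group_specific"]["AA"] == 1


def test_convergence_categories_exclusive_exhaustive(convergence_run):
    table = convergence_run["table"]
    assert table["ko"].is_unique
    assert table["category"].isin([
        "identical_attribution", "overlapping_but_different", "no_overlap",
        "group_specific_AA", "group_specific_LAH"]).all()


def test_planted_convergent_kos_recovered(convergence_run):
    planted = convergence_run["planted"]
    table = convergence_run["table"]
    pred = set(table.loc[(table["category"] == "no_overlap")
                         & table["direction_class"].isin(["up_in_both", "down_in_both"]), "ko"])
    tp = len(pred & planted)
    assert tp / len(planted) >= 0.9
    assert tp / max(len(pred), 1) >= 0.9
    ident = set(table.loc[table["category"] == "identical_attribution", "ko"])
    assert len(ident & convergence_run["identical"]) / len(convergence_run["identical"]) >= 0.8


# ----------------------------------------------------------------------- shares

def test_species_shares_examples():
    labels = _labels_frame([
        ("X", "g1", "K1", True, 1.0, True, 1.0, "shared", "up"),
        ("X", "g2", "K2", True, 1.0, True, 1.0, "shared", "up"),
        ("X", "g3", "K3", True, 1.0, True, 1.0, "shared", "up"),
        ("Y", "g4", "K4", True, 1.0, True, 1.0, "shared", "up"),
    ])
    shares = species_contribution_shares(labels)
    cell = shares[(shares.label == "shared") & (shares.direction == "up")]
    assert dict(zip(cell.species_id, cell.pct)) == {"X": 75.0, "Y": 25.0}


@given(st.lists(st.tuples(st.sampled_from(["X", "Y", "Z"]),
                          st.sampled_from(["shared", "AA_only", "LAH_only"]),
                          st.sampled_from(["up", "down"])),
                min_size=1, max_size=60))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_shares_sum_to_100_per_cell(cells):
    rows = [(sp, f"g{i}", f"K{i}", True, 1.0 if d == "up" else -1.0,
             lab == "shared", 1.0 if d == "up" else -1.0, lab, d)
            for i, (sp, lab, d) in enumerate(cells)]
    shares = species_contribution_shares(_labels_frame(rows))
    for _, cell in shares.groupby(["label", "direction"]):
        assert abs(cell["pct"].sum() - 100.0) < 0.1
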