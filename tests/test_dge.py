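"""Size factors, the paired NB GLM, dispersion and shrinkage estimators, and
BH adjustment, each against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquetx.dge import (LN2, bh_adjust, build_design, estimate_dispersion,
                          estimate_size_factors, fit_feature_glm,
                          fit_prior_scale, run_contrasts, shrink_lfc,
                          wald_contrast)
from plaquetx.simulate import SimDesign, generate_catalog, generate_counts, make_sample_sheet


def _sheet(n_a=3, n_b=3):
    return make_sample_sheet(SimDesign(n_subjects_per_group=(n_a, n_b)))


# ----------------------------------------------------------------- size factors

def test_size_factors_identical_columns_are_one():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
    sf = estimate_size_factors(counts)
    assert np.allclose(sf, 1.0)


def test_size_factors_doubled_column():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    sf = estimate_size_factors(counts)
    assert np.isclose(sf["s2"] / sf["s1"], 2.0)
    assert np.isclose(np.exp(np.log(sf).mean()), 1.0)


def test_size_factors_match_hand_computation():
    # 3x3 toy: geometric means per row, ratios, medians — computed by hand
    counts = pd.DataFrame({"s1": [4, 9, 25], "s2": [1, 3, 5], "s3": [16, 27, 125]})
    # row geomeans: (4*1*16)^(1/3)=4, (9*3*27)^(1/3)=9, (25*5*125)^(1/3)=25
    # ratios: s1 = (1, 1, 1) -> median 1; s2 = (1/4, 1/3, 1/5) -> median 1/4
    # s3 = (4, 3, 5) -> median 4; geometric mean of (1, 1/4, 4) is already 1
    raw = np.array([1.0, 0.25, 4.0])
    want = raw / np.exp(np.mean(np.log(raw)))
    sf = estimate_size_factors(counts)
    assert np.allclose(sf.to_numpy(), want)


def test_size_factors_reject_all_zero_sample():
    counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
    with pytest.raises(ValueError):
        estimate_size_factors(counts)


# ----------------------------------------------------------------------- design

def test_design_matrix_rank_and_contrasts():
    sheet = _sheet(3, 2)
    X, contrasts = build_design(sheet)
    assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]
    assert X.shape == (10, 5 + 2)  # intercept + 4 subject dummies + caries + interaction
    ca, cb = contrasts["AA"], contrasts["LAH"]
    assert ca[X.columns.get_loc("caries")] == 1 and ca.sum() == 1
    assert cb[X.columns.get_loc("caries")] == 1 and cb.sum() == 2


def test_sample_sheet_validation_errors():
    sheet = _sheet(3, 3)
    bad = sheet.drop(index=0)
    with pytest.raises(ValueError):
        build_design(bad)
    with pytest.raises(ValueError):
        build_design(_sheet(1, 3))


# -------------------------------------------------------------------- GLM fits

def test_flat_counts_give_zero_lfc():
    sheet = _sheet(3, 3)
    X, contrasts = build_design(sheet)
    y = np.full(len(sheet), 50.0)
    fit = fit_feature_glm(y, X.to_numpy(), np.ones(len(sheet)), dispersion=0.1)
    for c in contrasts.values():
        lfc, se, p = wald_contrast(fit, c)
        assert abs(lfc) < 0.01


def test_glm_maximizes_likelihood_against_grid():
    """Tiny instance: the returned caries coefficient beats every point of a
    brute-force grid over +-4 (step 0.01) in NB log-likelihood."""
    rng = np.random.default_rng(0)
    sheet = _sheet(2, 2)
    X, contrasts = build_design(sheet)
    Xm = X.to_numpy()
    alpha = 0.1
    mu_true = 50 * np.power(2.0, 1.0 * Xm[:, X.columns.get_loc("caries")])
    y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu_true))
    sf = np.ones(len(sheet))
    fit = fit_feature_glm(y, Xm, sf, dispersion=alpha)

    def nb_loglik(beta):
        mu = np.exp(Xm @ beta)
        r = 1 / alpha
        return float(sum(math.lgamma(yi + r) - math.lgamma(r) - math.lgamma(yi + 1)
                         + r * math.log(r / (r + m))
                         + (yi * math.log(m / (r + m)) if yi > 0 else 0.0)
                         for yi, m in zip(y, mu)))

    jc = X.columns.get_loc("caries")
    best = nb_loglik(fit.coef)
    for b in np.arange(-4, 4.001, 0.01):
        beta = fit.coef.copy()
        beta[jc] = b
        assert nb_loglik(beta) <= best + 1e-6


def test_planted_lfc_recovered_by_glm():
    """Mean estimated raw lfc within +-0.15 of the planted 1.0 over >= 200
    simulated features (10 subjects per group, baseline 100)."""
    d = SimDesign(n_species=10, genes_per_species=25, n_subjects_per_group=(10, 10),
                  frac_shared_de=1.0, frac_groupA_de=0, frac_groupB_de=0,
                  frac_opposite_de=0, planted_lfc=1.0, dispersion=0.05,
                  baseline_mean=100.0, seed=31)
    cat = generate_catalog(d)
    counts, sheet, truth = generate_counts(d, cat)
    tab = run_contrasts(counts, sheet)
    aa = tab[tab.contrast == "AA"].set_index(["species_id", "gene_id", "ko_id"])
    signed = aa["lfc_raw"] * np.sign(truth.loc[aa.index, "lfc_AA"])
    assert abs(signed.mean() - 1.0) < 0.15


# ------------------------------------------------------------------- dispersion

def test_dispersion_poisson_data_near_zero():
    d = SimDesign(n_species=10, genes_per_species=30, dispersion=0.0,
                  frac_shared_de=0, frac_groupA_de=0, frac_groupB_de=0,
                  frac_opposite_de=0, baseline_mean=200.0, seed=32)
    cat = generate_catalog(d)
    counts, sheet, _ = generate_counts(d, cat)
    sf = estimate_size_factors(counts)
    alpha = estimate_dispersion(counts, sheet, sf)
    assert alpha.median() <= 0.01


def test_dispersion_recovery():
    d = SimDesign(n_species=10, genes_per_species=30, dispersion=0.2,
                  frac_shared_de=0, frac_groupA_de=0, frac_groupB_de=0,
                  frac_opposite_de=0, baseline_mean=200.0, seed=33)
    cat = generate_catalog(d)
    counts, sheet, _ = generate_counts(d, cat)
    sf = estimate_size_factors(counts)
    alpha = estimate_dispersion(counts, sheet, sf)
    assert 0.1 <= alpha.median() <= 0.4


def test_dispersion_constant_feature_at_floor():
    sheet = _sheet(3, 3)
    counts = pd.DataFrame([[7] * len(sheet), [3, 9, 2, 8, 1, 12, 4, 6, 5, 7, 2, 9]],
                          columns=sheet["sample_id"])
    sf = pd.Series(1.0, index=sheet["sample_id"])
    alpha = estimate_dispersion(counts, sheet, sf, shrink_weight=0.0)
    assert alpha.iloc[0] <= 1e-6


# -------------------------------------------------------------------- shrinkage

def test_shrinkage_flat_prior_limit():
    assert abs(shrink_lfc(1.7, 0.4, prior_scale=1e6) - 1.7) < 1e-3


def test_shrinkage_zero_stays_zero():
    assert shrink_lfc(0.0, 0.5, prior_scale=0.5) == 0.0


def test_shrinkage_matches_grid_oracle():
    raw, se, scale = 2.0, 1.5, 0.5
    grid = np.arange(0.0, raw + 1e-9, 1e-4)
    post = (grid - raw) ** 2 / (2 * se ** 2) + np.log1p((grid / scale) ** 2)
    want = grid[np.argmin(post)]
    got = shrink_lfc(raw, se, scale)
    assert abs(got - want) < 1e-3


@given(st.floats(-5, 5), st.floats(0.05, 3), st.floats(0.05, 5))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_shrinkage_contracts_and_preserves_sign(raw, se, scale):
    b = shrink_lfc(raw, se, scale)
    assert abs(b) <= abs(raw) + 1e-9
    assert b == 0 or np.sign(b) == np.sign(raw)


def test_prior_scale_fit():
    assert fit_prior_scale([]) == 0.05
    assert fit_prior_scale([-1.0, 2.0, 0.5]) == 1.0


# --------------------------------------------------------------------------- BH

def _bh_bruteforce(p):
    """Literal definition: padj_i = min over j with p_j >= p_i of
    min(1, m * p_j / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        out[i] = min(min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i])
    return out


def test_bh_examples():
    assert np.allclose(bh_adjust([0.05]), [0.05])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_nan_passthrough():
    out = bh_adjust([0.02, np.nan, 0.04])
    assert np.isnan(out[1])
    # m = 2: adjusted = [0.04, 0.04]
    assert np.allclose(out[[0, 2]], [0.04, 0.04])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_bh_matches_bruteforce_and_order_invariant(p):
    got = bh_adjust(p)
    assert np.allclose(got, _bh_bruteforce(p))
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(bh_adjust(np.asarray(p)[perm]), got[perm])


# ------------------------------------------------------------------- contrasts

def test_group_label_swap_swaps_contrasts(small_catalog):
    d, cat = small_catalog
    counts, sheet, _ = generate_counts(d, cat)
    tab = run_contrasts(counts, sheet)
    swapped_sheet = sheet.copy()
    swapped_sheet["group"] = swapped_sheet["group"].map({"AA": "LAH", "LAH": "AA"})
    tab2 = run_contrasts(counts, swapped_sheet)
    key = ["species_id", "gene_id", "ko_id"]
    a1 = tab[tab.contrast == "AA"].set_index(key)["lfc_raw"]
    a2 = tab2[tab2.contrast == "AA"].set_index(key)["lfc_raw"]
    l1 = tab[tab.contrast == "LAH"].set_index(key)["lfc_raw"]
    l2 = tab2[tab2.contrast == "LAH"].set_index(key)["lfc_raw"]
    assert np.allclose(a1, l2, atol=1e-6) and np.allclose(l1, a2, atol=1e-6)


def test_raw_lfc_agrees_with_deseq2():
    """Independent cross-check: on a paired design, the subject-weighted
    average of the two within-group caries effects equals the single caries
    coefficient of a DESeq2 (pydeseq2) fit of ~ subject + condition."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    d = SimDesign(n_species=5, genes_per_species=20, n_subjects_per_group=(6, 5), seed=44)
    cat = generate_catalog(d)
    counts, sheet, _ = generate_counts(d, cat)
    mine = run_contrasts(counts, sheet)

    meta = sheet.set_index("sample_id")[["subject_id", "condition"]].astype(str)
    X = counts.T.copy()
    X.columns = ["|".join(c) for c in X.columns]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=X, metadata=meta,
                           design="~subject_id + condition", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "caries", "non_caries"], quiet=True)
        stat.summary()
    key = ["species_id", "gene_id", "ko_id"]
    aa = mine[mine.contrast == "AA"].set_index(key)["lfc_raw"]
    lah = mine[mine.contrast == "LAH"].set_index(key)["lfc_raw"]
    pooled = (6 * aa + 5 * lah) / 11
    pooled.index = ["|".join(c) for c in pooled.index]
    ref = stat.results_df["log2FoldChange"].loc[pooled.index]
    assert np.corrcoef(pooled, ref)[0, 1] > 0.99
    assert float((pooled - ref).abs().median()) < 0.05


def test_shrinkage_contraction_invariant(planted_run):
    tab = planted_run["dge"]
    ok = tab.dropna(subset=["lfc_raw", "lfc_shrunk"])
    assert (ok["lfc_shrunk"].abs() <= ok["lfc_raw"].abs() + 1e-9).all()


def test_groupA_only_features_flagged_in_A_not_B(planted_run):
    tab, truth = planted_run["dge"], planted_run["truth"]
    key = ["species_id", "gene_id", "ko_id"]
    aa = tab[tab.contrast == "AA"].set_index(key)
    lah = tab[tab.contrast == "LAH"].set_index(key)
    ga = truth[truth["klass"] == "groupA_only"].index
    assert (aa.loc[ga, "padj"] <= 0.05).mean() >= 0.8
    assert lah.loc[ga, "lfc_shrunk"].abs().median() < 0.3


def test_padj_at_least_p(planted_run):
    tab = planted_run["dge"].dropna(subset=["pvalue", "padj"])
    assert (tab["padj"] >= tab["pvalue"] - 1e-12).all()
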