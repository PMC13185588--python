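"""Paired negative-binomial differential expression with shrunken fold changes.

The model for each feature's counts is a negative-binomial GLM with log link,

    log mu_ij = log(sizefactor_j) + x_j' beta,    Var = mu + alpha * mu^2,

with design ~ Subject + Race + CariesStatus + Race:CariesStatus. Because
subjects are nested within the two cohorts, the Race main effect is aliased
with the subject terms and is dropped from the design matrix; the two
within-group caries contrasts — the quantities of interest — are unaffected.
The caries effect within the first (reference) group is the CariesStatus
coefficient; within the second group it is CariesStatus plus the interaction.

Per-feature dispersions are estimated by a Pearson-moment equation on a
Poisson working fit (with a residual-df correction) and shrunk in log space
toward a fitted mean-dispersion trend. Wald tests use the raw (unshrunken)
coefficients against a standard normal reference, the convention of
count-model DE tools; the df penalty is already absorbed by the dispersion
estimator's residual-df correction. Reported log2 fold changes are also
shrunk toward zero with a zero-mode Cauchy prior (posterior mode), a light
stand-in for apeglm-style shrinkage: large effects are barely moved while
noisy small ones are pulled in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

LN2 = math.log(2.0)
ALPHA_FLOOR = 1e-8
PRIOR_SCALE_FLOOR = 0.05


# ---------------------------------------------------------------- size factors

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over features with positive geometric mean of
    count_ij / geomean_i. Rejects samples with all-zero counts and tables
    with no feature positive in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        bad = counts.columns[mat.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    with np.errstate(divide="ignore"):
        loggeo = np.log(mat).mean(axis=1)
    use = np.isfinite(loggeo)
    if not use.any():
        raise ValueError("no feature has nonzero counts in every sample")
    ratios = np.log(mat[use]) - loggeo[use, None]
    logsf = np.median(ratios, axis=0)
    logsf -= logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=counts.columns, name="size_factor")


# ------------------------------------------------------------------ the design

def validate_sample_sheet(sheet: pd.DataFrame) -> tuple[str, str]:
    """Check the paired two-group layout; returns the two group labels in
    order of first appearance."""
    need = {"sample_id", "subject_id", "group", "condition"}
    if not need.issubset(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(need)}")
    groups = list(dict.fromkeys(sheet["group"]))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for subj, sub in sheet.groupby("subject_id"):
        if sorted(sub["condition"]) != ["caries", "non_caries"]:
            raise ValueError(f"subject {subj} must have exactly one caries and one non_caries sample")
        if sub["group"].nunique() != 1:
            raise ValueError(f"subject {subj} appears in more than one group")
    for g in groups:
        if sheet.loc[sheet["group"] == g, "subject_id"].nunique() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects; model unidentifiable")
    return groups[0], groups[1]


def build_design(sheet: pd.DataFrame):
    """Design matrix for ~ Subject + CariesStatus + Group:CariesStatus.

    The Race/group main effect is aliased with Subject (nested design) and is
    dropped. Returns ``(X, contrasts)`` where X is a DataFrame (samples x
    coefficients) and contrasts maps each group label to its caries-contrast
    vector.
    """
    ga, gb = validate_sample_sheet(sheet)
    subjects = list(dict.fromkeys(sheet["subject_id"]))
    cols = {"intercept": np.ones(len(sheet))}
    for s in subjects[1:]:
        cols[f"subj[{s}]"] = (sheet["subject_id"] == s).to_numpy(float)
    caries = (sheet["condition"] == "caries").to_numpy(float)
    cols["caries"] = caries
    cols[f"caries:{gb}"] = caries * (sheet["group"] == gb).to_numpy(float)
    X = pd.DataFrame(cols, index=sheet["sample_id"])
    p = X.shape[1]
    c_a = np.zeros(p)
    c_a[X.columns.get_loc("caries")] = 1.0
    c_b = c_a.copy()
    c_b[X.columns.get_loc(f"caries:{gb}")] = 1.0
    return X, {ga: c_a, gb: c_b}


# ------------------------------------------------------------------ dispersion

def _pearson_alpha(y: np.ndarray, mu: np.ndarray, resid_df: int) -> float:
    """Method-of-moments dispersion: solve
    sum (y-mu)^2 / (mu + a mu^2) = resid_df for a >= 0."""
    r2 = (y - mu) ** 2

    def g(a):
        return float(np.sum(r2 / (mu + a * mu * mu)) - resid_df)

    if g(0.0) <= 0:
        return 0.0
    hi = 1.0
    while g(hi) > 0 and hi < 1e6:
        hi *= 10
    if g(hi) > 0:
        return hi
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-10, rtol=1e-8))


def estimate_dispersion(counts: pd.DataFrame, sheet: pd.DataFrame,
                        size_factors: pd.Series,
                        shrink_weight: float = 0.5) -> pd.Series:
    """Per-feature NB dispersion alpha (variance = mu + alpha mu^2).

    A Poisson working GLM supplies fitted means; the Pearson moment equation
    gives a raw alpha per feature, which is then shrunk in log space toward a
    mean-dispersion trend a(mu) = a0 + a1/mu fitted across features.
    Alphas are floored at 1e-8.
    """
    X, _ = build_design(sheet)
    Xm = X.to_numpy()
    off = np.log(size_factors.loc[X.index].to_numpy())
    resid_df = len(sheet) - X.shape[1]
    if resid_df < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    raw = np.full(len(counts), np.nan)
    means = np.zeros(len(counts))
    for i, (_, y) in enumerate(counts.iterrows()):
        yv = y.loc[X.index].to_numpy(dtype=float)
        means[i] = np.mean(yv / np.exp(off))
        if yv.sum() == 0 or np.all(yv == yv[0] * np.ones_like(yv)) and yv.std() == 0:
            raw[i] = 0.0
            continue
        try:
            fit = sm.GLM(yv, Xm, family=sm.families.Poisson(), offset=off).fit()
            raw[i] = _pearson_alpha(yv, fit.fittedvalues, resid_df)
        except Exception:
            raw[i] = 0.0
    raw = np.maximum(raw, ALPHA_FLOOR)

    # trend a(mu) = a0 + a1/mu fit on features with informative raw alphas
    ok = (raw > 10 * ALPHA_FLOOR) & (means > 0)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0 = max(coef[0], ALPHA_FLOOR)
        a1 = max(coef[1], 0.0)
        trend = np.maximum(a0 + a1 / np.maximum(means, 1e-8), ALPHA_FLOOR)
        out = np.exp((1 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend))
    else:
        out = raw
    return pd.Series(np.maximum(out, ALPHA_FLOOR), index=counts.index, name="alpha")


# ------------------------------------------------------------------- GLM fits

@dataclass
class FeatureFit:
    coef: np.ndarray          # natural-log scale
    cov: np.ndarray
    converged: bool
    resid_df: int


def fit_feature_glm(feature_counts: np.ndarray, X: np.ndarray,
                    size_factors: np.ndarray, dispersion: float,
                    maxiter: int = 100) -> FeatureFit:
    """NB log-link GLM by IRLS with a log size-factor offset.

    ``dispersion`` is the fixed NB alpha for this feature (the Poisson family
    is used below the floor). Coefficients and covariance are on the
    natural-log scale; callers convert to log2.
    """
    y = np.asarray(feature_counts, dtype=float)
    off = np.log(np.asarray(size_factors, dtype=float))
    fam = (sm.families.Poisson() if dispersion <= ALPHA_FLOOR
           else sm.families.NegativeBinomial(alpha=float(dispersion)))
    resid_df = len(y) - X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam, offset=off).fit(maxiter=maxiter)
        converged = bool(getattr(res, "converged", True))
        return FeatureFit(res.params, res.cov_params(), converged, resid_df)
    except Exception:
        p = X.shape[1]
        return FeatureFit(np.full(p, np.nan), np.full((p, p), np.nan), False, resid_df)


def wald_contrast(fit: FeatureFit, contrast: np.ndarray):
    """(lfc_log2, se_log2, two-sided p) for a linear contrast of the fit.

    The Wald p-value uses a standard normal reference; it is two-sided and
    invariant to a sign flip of the contrast.
    """
    est = float(contrast @ fit.coef)
    var = float(contrast @ fit.cov @ contrast)
    if not fit.converged or not np.isfinite(est) or not np.isfinite(var) or var <= 0:
        return np.nan, np.nan, np.nan
    se = math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(est / se))
    return est / LN2, se / LN2, p


# ------------------------------------------------------------------- shrinkage

def fit_prior_scale(raw_lfcs) -> float:
    """Scale of the zero-centered Cauchy shrinkage prior, fit from the
    spread of raw effects: for a Cauchy, median |X| equals the scale."""
    arr = np.asarray(raw_lfcs, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return PRIOR_SCALE_FLOOR
    return float(max(np.median(np.abs(arr)), PRIOR_SCALE_FLOOR))


def shrink_lfc(raw_lfc: float, se: float, prior_scale: float) -> float:
    """Posterior-mode log2 fold change under a zero-mode Cauchy prior.

    Minimizes (b-raw)^2/(2 se^2) + log(1 + (b/s)^2) over b between 0 and raw,
    where the mode of a unimodal-at-zero prior times a Gaussian likelihood
    must lie. Contracts toward zero and preserves sign.
    """
    if not np.isfinite(raw_lfc) or not np.isfinite(se):
        return np.nan
    if se <= 0:
        raise ValueError("se must be positive")
    if raw_lfc == 0.0:
        return 0.0
    s2 = 2.0 * se * se
    s = prior_scale

    def nlp(b):
        return (b - raw_lfc) ** 2 / s2 + math.log1p((b / s) ** 2)

    lo, hi = (0.0, raw_lfc) if raw_lfc > 0 else (raw_lfc, 0.0)
    res = optimize.minimize_scalar(nlp, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    b = float(res.x)
    # the posterior can be bimodal for a heavy-tailed prior: compare against 0
    if nlp(0.0) < nlp(b):
        b = 0.0
    return b


# -------------------------------------------------------------------------- BH

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaNs pass through and are excluded from the family size m. Values outside
    [0,1] are rejected. Output is order-invariant and clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    m = int(ok.sum())
    if m == 0:
        return out
    sub = p[ok]
    order = np.argsort(sub, kind="stable")
    ranked = sub[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


# ----------------------------------------------------------------- full driver

def run_contrasts(counts: pd.DataFrame, sheet: pd.DataFrame,
                  size_factors: pd.Series | None = None,
                  dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Fit the paired NB interaction model and report both within-group
    caries contrasts per feature.

    Returns a long DGE table with columns species_id, gene_id, ko_id,
    contrast (group label), baseMean, lfc_raw, lfc_shrunk, se, pvalue, padj.
    All-zero features are excluded from fitting and from each BH family.
    BH adjustment and the shrinkage prior are applied per contrast family.
    """
    ga, gb = validate_sample_sheet(sheet)
    X, contrasts = build_design(sheet)
    counts = counts[X.index.tolist()]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.loc[X.index].to_numpy()

    nonzero = counts.sum(axis=1) > 0
    active = counts.loc[nonzero]
    if dispersions is None:
        dispersions = estimate_dispersion(active, sheet, size_factors)
    disp = dispersions.loc[active.index].to_numpy()

    base_mean = (active.to_numpy() / sf[None, :]).mean(axis=1)
    Xm = X.to_numpy()
    rows = {g: {"lfc_raw": [], "se": [], "pvalue": []} for g in (ga, gb)}
    for i, (_, y) in enumerate(active.iterrows()):
        fit = fit_feature_glm(y.to_numpy(), Xm, sf, disp[i])
        for g in (ga, gb):
            lfc, se, p = wald_contrast(fit, contrasts[g])
            rows[g]["lfc_raw"].append(lfc)
            rows[g]["se"].append(se)
            rows[g]["pvalue"].append(p)

    out = []
    ann = active.index.to_frame(index=False)
    ann.columns = ["species_id", "gene_id", "ko_id"]
    for g in (ga, gb):
        df = ann.copy()
        df["contrast"] = g
        df["baseMean"] = base_mean
        df["lfc_raw"] = rows[g]["lfc_raw"]
        df["se"] = rows[g]["se"]
        scale = fit_prior_scale(df["lfc_raw"])
        df["lfc_shrunk"] = [shrink_lfc(l, s, scale) if np.isfinite(l) and s > 0 else np.nan
                            for l, s in zip(df["lfc_raw"], df["se"])]
        df["pvalue"] = rows[g]["pvalue"]
        df["padj"] = bh_adjust(df["pvalue"])
        out.append(df)
    cols = ["species_id", "gene_id", "ko_id", "contrast", "baseMean",
            "lfc_raw", "lfc_shrunk", "se", "pvalue", "padj"]
    return pd.concat(out, ignore_index=True)[cols]
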