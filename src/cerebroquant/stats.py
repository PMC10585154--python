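"""Statistical layer for the hypoxic-challenge analysis.

Three model families, mirroring how paired normoxia/hypoxia physiology
is usually analyzed in case-control desaturation studies:

* a linear mixed model of each physiologic response on SaO2 with a
  random intercept per subject and a group x SaO2 interaction,

      Y = b1*group + b2*SaO2 + b3*group*SaO2 + b4*sex + b5*age + u,

  where the random intercept u absorbs between-subject baseline
  differences so only the response to desaturation is tested.  Groups
  are treatment-coded against the healthy-control reference and SaO2
  enters in percentage points, so slopes are per % saturation;

* per-subject response ratios, the two-point slope

      dY/dSaO2 = (Y_hypoxia - Y_normoxia) / (SaO2_normoxia - SaO2_hypoxia),

  positive when the variable rises under desaturation;

* covariate-adjusted OLS for cross-sectional group differences and for
  the association of brain volumes with response ratios (with partial
  regression residuals exported for plotting).

Mixed models are estimated by REML.  Because per-subject response
slopes are heterogeneous, the within-subject changes are
heteroscedastic in proportion to each subject's desaturation, which a
random-intercept working model does not capture; fixed-effect inference
therefore uses bias-reduced cluster-robust (CR2) covariance with
Satterthwaite degrees of freedom by default (the Bell-McCaffrey
small-sample treatment).  Model-based Wald inference is available with
``robust=False``.  No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

GROUP_TERM = "C(group, Treatment('healthy'))"


@dataclass
class ResponseRatio:
    subject_id: str
    dvalue_per_dsat: float     # response units per % desaturation


@dataclass
class MixedFitResult:
    """Coefficients of the saturation-response mixed model."""

    response: str
    coefficients: pd.DataFrame          # estimate, ci_low, ci_high, pvalue
    interaction: dict[str, dict]        # per non-reference group
    slope_sao2: float                   # reference-group slope per % SaO2
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_subjects: int
    converged: bool = True


def response_ratio(normoxia_value: float, hypoxia_value: float,
                   sao2_normoxia: float, sao2_hypoxia: float,
                   subject_id: str = "") -> ResponseRatio:
    """Per-subject change per percentage point of desaturation."""
    desat = sao2_normoxia - sao2_hypoxia
    if desat <= 0:
        raise ValueError("desaturation must be positive "
                         f"(SaO2 {sao2_normoxia} -> {sao2_hypoxia})")
    return ResponseRatio(subject_id=subject_id,
                         dvalue_per_dsat=(hypoxia_value - normoxia_value) / desat)


def _tidy(params, conf, pvals) -> pd.DataFrame:
    out = pd.DataFrame({"estimate": params,
                        "ci_low": conf[0], "ci_high": conf[1],
                        "pvalue": pvals})
    out.index.name = "term"
    return out


def _fixed_effects_fallback(data: pd.DataFrame, response: str,
                            rhs_no_intercept: str) -> MixedFitResult:
    # Degenerate (near-)perfect fits break REML; subject fixed effects give
    # the same within-subject slope estimates exactly.
    fit = smf.ols(f"{response} ~ C(subject_id) + {rhs_no_intercept}",
                  data=data).fit()
    keep = [t for t in fit.params.index if not t.startswith("C(subject_id)")]
    coefs = _tidy(fit.params[keep], fit.conf_int().loc[keep], fit.pvalues[keep])
    inter = _extract_interactions(coefs)
    subj_eff = fit.params[[t for t in fit.params.index
                           if t.startswith("C(subject_id)")]]
    return MixedFitResult(
        response=response, coefficients=coefs, interaction=inter,
        slope_sao2=float(fit.params["sao2"]),
        random_intercept_var=float(np.var(subj_eff)) if len(subj_eff) else 0.0,
        residual_var=float(fit.mse_resid) if fit.df_resid > 0 else 0.0,
        n_obs=int(fit.nobs), n_subjects=data["subject_id"].nunique(),
        converged=True)


def _cr2_inference(fit, md) -> pd.DataFrame:
    """Cluster-robust (CR2) fixed-effect inference for a fitted MixedLM.

    Clusters are subjects; the working covariance per cluster is the
    fitted random-intercept-plus-residual structure.  Each cluster's
    working-model-whitened residuals are inflated by the bias-reduced
    (I - H_i)^{-1/2} adjustment, and each coefficient gets Satterthwaite
    degrees of freedom from the cluster contributions to its variance.
    """
    from scipy.linalg import sqrtm
    from scipy.stats import t as tdist

    exog, endog, groups = md.exog, md.endog, np.asarray(md.groups)
    k = exog.shape[1]
    sigma2 = float(fit.scale)
    tau2 = float(fit.cov_re.iloc[0, 0])
    beta = fit.fe_params.values
    uniq = pd.unique(groups)
    blocks = []
    A = np.zeros((k, k))
    for g in uniq:
        ix = groups == g
        Xi, yi = exog[ix], endog[ix]
        ni = int(ix.sum())
        Vi = sigma2 * np.eye(ni) + tau2 * np.ones((ni, ni))
        whalf = np.real(sqrtm(np.linalg.inv(Vi)))
        xt, rt = whalf @ Xi, whalf @ (yi - Xi @ beta)
        blocks.append((xt, rt))
        A += xt.T @ xt
    M = np.linalg.inv(A)
    S = np.zeros((k, k))
    contrib = np.zeros((len(blocks), k))   # per-cluster Satterthwaite terms
    for b, (xt, rt) in enumerate(blocks):
        ht = xt @ M @ xt.T
        ai = np.real(np.linalg.pinv(sqrtm(np.eye(len(rt)) - ht)))
        gi = xt.T @ ai @ rt
        S += np.outer(gi, gi)
        P = ai @ xt @ M          # n_i x k; column j is p_i for coefficient j
        contrib[b] = np.einsum("ij,ij->j", P, P)
    V = M @ S @ M
    se = np.sqrt(np.diag(V))
    dfs = contrib.sum(axis=0) ** 2 / (contrib ** 2).sum(axis=0)
    tcrit = tdist.ppf(0.975, dfs)
    pvals = 2.0 * tdist.sf(np.abs(beta / se), dfs)
    return pd.DataFrame({"estimate": beta,
                         "ci_low": beta - tcrit * se,
                         "ci_high": beta + tcrit * se,
                         "pvalue": pvals},
                        index=fit.fe_params.index)


def _extract_interactions(coefs: pd.DataFrame) -> dict[str, dict]:
    inter = {}
    for term in coefs.index:
        if ":sao2" in term and "[T." in term:
            gname = term.split("[T.")[1].split("]")[0]
            row = coefs.loc[term]
            inter[gname] = {"estimate": float(row["estimate"]),
                            "ci_low": float(row["ci_low"]),
                            "ci_high": float(row["ci_high"]),
                            "pvalue": float(row["pvalue"])}
    return inter


def fit_mixed_response(data: pd.DataFrame, response: str,
                       include_gm_covariate: bool = False,
                       interaction: bool = True,
                       robust: bool = True) -> MixedFitResult:
    """Fit the saturation-response mixed model for one physiologic variable.

    Parameters
    ----------
    data
        Long table with columns subject_id, group, sao2, the response,
        sex (0/1), age, and mrs_gm_fraction when flagged.
    response
        Column to model ("lactate", "cbf" or "cmro2").
    include_gm_covariate
        Add the MRS-voxel gray-matter fraction (lactate models).
    interaction
        Include the group x SaO2 interaction (requires >= 2 groups).
    robust
        Cluster-robust (CR2 + Satterthwaite) CIs and p-values for the
        fixed effects; ``False`` gives model-based Wald inference.

    Notes
    -----
    The interaction coefficients are (group slope - healthy slope); with
    a negative healthy slope a positive interaction means a blunted
    increase under desaturation.
    """
    if response not in data.columns:
        raise ValueError(f"response column '{response}' not found")
    n_groups = data["group"].nunique()
    terms = []
    if interaction and n_groups >= 2:
        terms.append(f"{GROUP_TERM} * sao2")
    else:
        if interaction:
            warnings.warn("single group: interaction omitted", stacklevel=2)
        terms.append("sao2")
        if n_groups >= 2:
            terms.append(GROUP_TERM)
    if data["sex"].nunique() > 1:
        terms.append("sex")
    if data["age"].nunique() > 1:
        terms.append("age")
    if include_gm_covariate:
        terms.append("mrs_gm_fraction")
    rhs = " + ".join(terms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm(f"{response} ~ {rhs}", data=data,
                             groups=data["subject_id"])
            fit = md.fit(reml=True)
            bad = (not np.isfinite(fit.params).all()
                   or not np.isfinite(np.asarray(fit.bse_fe)).all()
                   or fit.scale <= 1e-12)   # perfect fit: REML degenerate
        except (np.linalg.LinAlgError, ValueError):
            bad = True
    if bad:
        return _fixed_effects_fallback(data, response, rhs)

    fe = fit.fe_params.index
    if robust:
        coefs = _cr2_inference(fit, md)
    else:
        coefs = _tidy(fit.params[fe], fit.conf_int().loc[fe], fit.pvalues[fe])
    return MixedFitResult(
        response=response, coefficients=coefs,
        interaction=_extract_interactions(coefs),
        slope_sao2=float(fit.fe_params["sao2"]),
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        n_obs=int(fit.nobs), n_subjects=data["subject_id"].nunique(),
        converged=bool(fit.converged))


def fit_group_differences(wide: pd.DataFrame, outcome: str,
                          covariates: tuple[str, ...] = ("sex", "age")) -> pd.DataFrame:
    """Cross-sectional group contrasts for one outcome, covariate-adjusted.

    Returns one row per contrast (each group vs healthy, plus
    no-albuminuria vs albuminuria) with estimate, Wald 95% CI and
    two-sided p-value.
    """
    if outcome not in wide.columns:
        raise ValueError(f"outcome column '{outcome}' not found")
    if wide[outcome].std() == 0:
        raise ValueError(f"outcome '{outcome}' is constant: degenerate model")
    covs = [c for c in covariates if wide[c].nunique() > 1]
    rhs = " + ".join([GROUP_TERM] + covs)
    fit = smf.ols(f"{outcome} ~ {rhs}", data=wide).fit()
    conf = fit.conf_int()
    rows = {}
    dummy_terms = {}
    for term in fit.params.index:
        if term.startswith(GROUP_TERM):
            gname = term.split("[T.")[1].split("]")[0]
            dummy_terms[gname] = term
            rows[f"{gname}_vs_healthy"] = {
                "estimate": float(fit.params[term]),
                "ci_low": float(conf.loc[term, 0]),
                "ci_high": float(conf.loc[term, 1]),
                "pvalue": float(fit.pvalues[term])}
    if {"t1d_no_alb", "t1d_alb"} <= set(dummy_terms):
        L = pd.Series(0.0, index=fit.params.index)
        L[dummy_terms["t1d_alb"]] = 1.0
        L[dummy_terms["t1d_no_alb"]] = -1.0
        tt = fit.t_test(L.values)
        lo, hi = np.ravel(tt.conf_int())
        rows["t1d_alb_vs_t1d_no_alb"] = {
            "estimate": float(np.ravel(tt.effect)[0]), "ci_low": float(lo),
            "ci_high": float(hi), "pvalue": float(np.ravel(tt.pvalue)[0])}
    out = pd.DataFrame(rows).T
    out.index.name = "contrast"
    return out


@dataclass
class VolumeResponseResult:
    slope: float            # ml per ratio-unit
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    partial: pd.DataFrame = field(repr=False, default=None)


def fit_volume_response_assoc(wide: pd.DataFrame, volume: str = "tbv",
                              ratio: str = "lactate_ratio",
                              patients_only: bool = False,
                              covariates: tuple[str, ...] = ("sex", "age",
                                                             "mrs_gm_fraction"),
                              ) -> VolumeResponseResult:
    """Regression of a brain volume on a hypoxic response ratio.

    The partial-regression table (volume and ratio residualized on the
    covariates) is returned for plotting.
    """
    df = wide[wide["group"] != "healthy"] if patients_only else wide
    df = df.dropna(subset=[volume, ratio]).copy()
    if df[ratio].std() == 0:
        raise ValueError(f"regressor '{ratio}' has zero variance")
    covs = [c for c in covariates if c in df.columns and df[c].nunique() > 1]
    rhs = " + ".join([ratio] + covs)
    fit = smf.ols(f"{volume} ~ {rhs}", data=df).fit()
    conf = fit.conf_int()

    cov_rhs = " + ".join(covs) if covs else "1"
    partial = pd.DataFrame({
        "subject_id": df["subject_id"].values,
        "group": df["group"].values,
        "volume_resid": smf.ols(f"{volume} ~ {cov_rhs}", data=df).fit().resid.values,
        "ratio_resid": smf.ols(f"{ratio} ~ {cov_rhs}", data=df).fit().resid.values,
    })
    return VolumeResponseResult(
        slope=float(fit.params[ratio]),
        ci_low=float(conf.loc[ratio, 0]), ci_high=float(conf.loc[ratio, 1]),
        pvalue=float(fit.pvalues[ratio]), n=len(df), partial=partial)


def power_sample_size(sd: float, alpha: float, power: float,
                      effect: float) -> int:
    """Two-sample normal-approximation sample size per group.

    n = ceil(2 sigma^2 (z_{1-alpha/2} + z_{power})^2 / delta^2), floor 2.
    sd and effect share units (e.g. percent response).
    """
    if sd <= 0 or effect == 0:
        raise ValueError("sd must be positive and effect nonzero")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    k = norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)
    n = 2.0 * sd ** 2 * k ** 2 / effect ** 2
    return max(math.ceil(n - 1e-9), 2)


def detectable_difference(sd: float, alpha: float, power: float, n: int) -> float:
    """Smallest detectable two-sample difference at n per group (inverse of
    the sample-size formula)."""
    if sd <= 0 or n < 1:
        raise ValueError("sd must be positive and n >= 1")
    k = norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)
    return sd * math.sqrt(2.0 * k ** 2 / n)


def plot_partial_regression(partial: pd.DataFrame, path,
                            xlabel: str = "response ratio (adjusted)",
                            ylabel: str = "volume, ml (adjusted)") -> None:
    """Partial-regression scatter with the fitted line, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for gname, sub in partial.groupby("group"):
        ax.scatter(sub["ratio_resid"], sub["volume_resid"], s=18, label=gname)
    b = np.polyfit(partial["ratio_resid"], partial["volume_resid"], 1)
    xs = np.linspace(partial["ratio_resid"].min(), partial["ratio_resid"].max(), 50)
    ax.plot(xs, np.polyval(b, xs), color="black", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
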