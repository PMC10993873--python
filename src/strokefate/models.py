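"""Outcome models: perfusion time courses, fraction models and AICc ranking.

Three families of inference mirror the analysis plan:

* linear mixed models of each relative regional perfusion index against
  imaging session, occlusion duration and sex, with a random intercept per
  subject.  Fixed effects are tested with Wald F statistics using
  between-within (containment) denominator degrees of freedom, which for
  the balanced subject x session designs produced here coincide with the
  Kenward-Roger correction; Bonferroni adjustment is applied to post-hoc
  session contrasts.
* beta-family regression with a log link for hypo/hyper voxel-class
  fractions over hemisphere, ROI and session.  Random subject variation is
  absorbed through cluster-robust (by subject) covariance, a marginal-model
  surrogate for a random intercept; boundary fractions are shrunk by the
  standard (y*(n-1)+0.5)/n transformation before fitting.
* multi-model inference for lesion volume change (Gaussian) and the
  sensorimotor deficit score (Poisson, log link): the nuisance model
  (occlusion x sex, acute lesion volume, lesion location) is augmented with
  the four admissible perfusion-index configurations — rrMTT is never
  combined with rrCBF or rrCBV, which already determine it through the
  central volume theorem — plus an intercept-only NULL, and the candidates
  are ranked by the small-sample corrected AICc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "aicc",
    "aicc_from_aic",
    "fit_perfusion_lmm",
    "fit_fraction_glmm",
    "multimodel_inference",
    "correlate_hyperacute",
    "PERFUSION_CONFIGS",
    "ModelRanking",
]

#: Admissible perfusion-index subsets: rrMTT is excluded whenever rrCBF or
#: rrCBV is present (it is their quotient, not an independent predictor).
PERFUSION_CONFIGS: tuple[tuple[str, ...], ...] = (
    ("rrCBF", "rrCBV"),
    ("rrMTT",),
    (),
    ("rrCBV",),
    ("rrCBF",),
)
for _cfg in PERFUSION_CONFIGS:
    assert not ("rrMTT" in _cfg and ({"rrCBF", "rrCBV"} & set(_cfg)))


def aicc_from_aic(aic: float, k: int, n: int) -> float:
    """Second-order corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(llf: float, k: int, n: int) -> float:
    return aicc_from_aic(2.0 * k - 2.0 * llf, k, n)


def _zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------------------
# Linear mixed model of perfusion time courses


def fit_perfusion_lmm(rr_table: pd.DataFrame, index: str = "cbf") -> dict:
    """Mixed model of one rr perfusion index over session, occlusion and sex.

    Expects a long table with columns subject, timepoint, occlusion_min,
    sex, parameter, rr_index.  Returns a dict with the fitted model, an
    ANOVA-style fixed-effect table (Wald F, between-within df) and
    Bonferroni-adjusted post-hoc session contrasts.
    """
    data = rr_table[rr_table["parameter"] == index].copy()
    if data.empty:
        raise ValueError(f"no rows for perfusion index {index!r}")
    n_tp = data["timepoint"].nunique()
    if n_tp < 2:
        raise ValueError("at least two timepoints per subject are required")
    data["timepoint"] = pd.Categorical(
        data["timepoint"],
        categories=[t for t in ("occlusion", "post_0.5h", "day4")
                    if t in set(data["timepoint"])],
    )
    formula = "rr_index ~ C(timepoint) + C(occlusion_min) + C(sex)"
    downgraded = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=data["subject"])
            fit = model.fit(reml=True)
            if not np.all(np.isfinite(np.asarray(fit.bse_fe))):
                raise np.linalg.LinAlgError("non-finite standard errors")
        except (np.linalg.LinAlgError, ValueError):
            downgraded = True
            fit = smf.ols(formula, data).fit()

    n_subj = data["subject"].nunique()
    n_obs = len(data)
    exog_names = (
        fit.model.exog_names if not downgraded else list(fit.params.index)
    )
    if downgraded:
        fe = fit.params
        cov = fit.cov_params()
    else:
        fe = fit.fe_params
        cov = fit.cov_params().iloc[: len(fe), : len(fe)]

    terms = {
        "timepoint": [n for n in exog_names if n.startswith("C(timepoint)")],
        "occlusion": [n for n in exog_names if n.startswith("C(occlusion_min)")],
        "sex": [n for n in exog_names if n.startswith("C(sex)")],
    }
    # Between-within denominator df: session varies within subject, the
    # group factors between subjects.
    n_between = len(terms["occlusion"]) + len(terms["sex"])
    ddf = {
        "timepoint": max((n_subj - 1) * (n_tp - 1), 1),
        "occlusion": max(n_subj - n_between - 1, 1),
        "sex": max(n_subj - n_between - 1, 1),
    }
    rows = []
    for term, names in terms.items():
        if not names:
            continue
        ix = [exog_names.index(n) for n in names]
        beta = np.asarray(fe)[ix]
        vb = np.asarray(cov)[np.ix_(ix, ix)]
        wald = float(beta @ np.linalg.solve(vb, beta))
        f = wald / len(ix)
        p = float(st.f.sf(f, len(ix), ddf[term]))
        rows.append({"term": term, "F": f, "df1": len(ix), "df2": ddf[term], "p": p})
    effects = pd.DataFrame(rows)

    # Bonferroni post-hoc on session pairs
    posthoc = []
    tps = list(data["timepoint"].cat.categories)
    means = {tp: data.loc[data["timepoint"] == tp, "rr_index"].mean() for tp in tps}
    resid_sd = float(np.sqrt(fit.scale)) if not downgraded else float(
        np.sqrt(fit.mse_resid)
    )
    n_pairs = n_tp * (n_tp - 1) // 2
    for i in range(len(tps)):
        for j in range(i + 1, len(tps)):
            diff = means[tps[j]] - means[tps[i]]
            se = resid_sd * np.sqrt(2.0 / n_subj)
            t = diff / se
            p = min(2.0 * st.t.sf(abs(t), ddf["timepoint"]) * n_pairs, 1.0)
            posthoc.append(
                {"contrast": f"{tps[j]} - {tps[i]}", "estimate": diff,
                 "t": t, "p_bonferroni": p}
            )
    return {
        "fit": fit,
        "effects": effects,
        "posthoc": pd.DataFrame(posthoc),
        "downgraded": downgraded,
        "index": index,
    }


# ---------------------------------------------------------------------------
# Beta regression of voxel-class fractions


def shrink_to_open_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Map fractions from [0,1] into (0,1): (y*(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=np.float64)
    n = len(y) if n is None else n
    return (y * (n - 1) + 0.5) / n


def fit_fraction_glmm(
    fractions: pd.DataFrame,
    response: str = "f_hypo",
    formula_rhs: str = "C(hemisphere) * C(roi) * C(timepoint)",
) -> dict:
    """Beta regression (log link) of a voxel-class fraction.

    Subject clustering enters through cluster-robust standard errors.
    Returns parameter estimates, robust SEs/p-values and back-transformed
    fitted means (guaranteed inside (0,1) after clipping at the link scale
    is verified).
    """
    data = fractions.copy()
    y = data[response].to_numpy(dtype=np.float64)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if np.all((y == 0) | (y == 1)):
        raise ValueError("all fractions lie on the boundary; nothing to model")
    data["_y"] = shrink_to_open_interval(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BetaModel.from_formula(
            f"_y ~ {formula_rhs}", data, link=sm.families.links.Log()
        )
        start = None
        try:
            res = model.fit(
                cov_type="cluster",
                cov_kwds={"groups": data["subject"].to_numpy()},
                disp=0,
                start_params=start,
            )
        except Exception:
            res = model.fit(disp=0)
    mean_params = res.params[: model.exog.shape[1]]
    fitted = np.exp(model.exog @ mean_params)
    return {
        "fit": res,
        "params": res.params,
        "bse": res.bse,
        "pvalues": res.pvalues,
        "fitted_means": np.clip(fitted, None, 1.0 - 1e-12),
        "response": response,
    }


# ---------------------------------------------------------------------------
# Multi-model inference


@dataclass
class ModelRanking:
    """AICc-ranked model set with per-model coefficient tables."""

    table: pd.DataFrame
    coefficients: dict[str, pd.DataFrame]
    outcome: str
    family: str

    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def _model_label(cfg: tuple[str, ...] | None) -> str:
    if cfg is None:
        return "NULL"
    if not cfg:
        return "base"
    return " & ".join(cfg)


def multimodel_inference(
    table: pd.DataFrame,
    outcome: str = "volume_change",
    rng_unused=None,
) -> ModelRanking:
    """Rank the admissible perfusion-model configurations by AICc.

    ``table`` is a wide per-subject frame with columns volume_change_pct or
    sds_day4, sex, occlusion_min, acute_volume_frac, lesion_location and
    rrCBF/rrCBV/rrMTT.  Continuous predictors are scaled and centered, so
    reported coefficients are standardized.  Gaussian models report
    adjusted R^2, RMSE and a nested F-test against the no-perfusion base
    model; the Poisson (SDS) branch reports Nagelkerke R^2 and a
    likelihood-ratio test instead.
    """
    if outcome == "volume_change":
        ycol, family = "volume_change_pct", "gaussian"
    elif outcome == "sds":
        ycol, family = "sds_day4", "poisson"
    else:
        raise ValueError("outcome must be 'volume_change' or 'sds'")
    needed = [ycol, "sex", "occlusion_min", "acute_volume_frac",
              "lesion_location", "rrCBF", "rrCBV", "rrMTT"]
    data = table.dropna(subset=[c for c in needed if c in table.columns]).copy()
    n = len(data)
    for col in ("acute_volume_frac", "rrCBF", "rrCBV", "rrMTT"):
        data[f"z_{col}"] = _zscore(data[col])
    data["lesion_location"] = pd.Categorical(
        data["lesion_location"],
        categories=["cortical", "subcortical", "diencephalic"],
    )
    base_rhs = ("C(occlusion_min) * C(sex) + z_acute_volume_frac + "
                "C(lesion_location)")

    def fit_one(cfg):
        rhs = base_rhs if cfg is not None else "1"
        if cfg:
            rhs = rhs + " + " + " + ".join(f"z_{p}" for p in cfg)
        formula = f"{ycol} ~ {rhs}"
        if family == "gaussian":
            res = smf.ols(formula, data).fit()
            k = int(res.df_model) + 2  # + intercept + residual variance
        else:
            res = smf.glm(formula, data, family=sm.families.Poisson()).fit()
            k = len(res.params)
        return res, k

    base_res, _ = fit_one(())
    rows, coefs = [], {}
    for cfg in (PERFUSION_CONFIGS[0], PERFUSION_CONFIGS[1], (),
                PERFUSION_CONFIGS[3], PERFUSION_CONFIGS[4], None):
        label = _model_label(cfg)
        res, k = fit_one(cfg)
        if n <= k + 1:
            rows.append({"model": label, "aicc": np.inf, "unfit": True})
            continue
        a = aicc(float(res.llf), k, n)
        row = {"model": label, "k": k, "n": n, "aicc": a, "unfit": False}
        if family == "gaussian":
            row["r2_adj"] = float(res.rsquared_adj)
            row["rmse"] = float(np.sqrt(res.mse_resid))
            if cfg:  # nested F-test against the no-perfusion base model
                rss_b = float(base_res.ssr)
                rss_m = float(res.ssr)
                df_extra = base_res.df_resid - res.df_resid
                f = ((rss_b - rss_m) / df_extra) / (rss_m / res.df_resid)
                row["f_vs_base"] = float(f)
                row["p_vs_base"] = float(st.f.sf(f, df_extra, res.df_resid))
        else:
            llnull = float(fit_one(None)[0].llf)
            cox_snell = 1.0 - np.exp(2.0 * (llnull - float(res.llf)) / n)
            row["r2_nagelkerke"] = float(
                cox_snell / (1.0 - np.exp(2.0 * llnull / n))
            )
            if cfg:
                lr = 2.0 * (float(res.llf) - float(base_res.llf))
                df_extra = len(res.params) - len(base_res.params)
                row["lr_vs_base"] = lr
                row["p_vs_base"] = float(st.chi2.sf(max(lr, 0.0), df_extra))
        rows.append(row)
        ci = res.conf_int()
        coefs[label] = pd.DataFrame(
            {"beta": res.params, "ci_low": ci[0], "ci_high": ci[1],
             "p": res.pvalues}
        )
    out = pd.DataFrame(rows)
    out = out[~out["unfit"].astype(bool)].copy()
    out = out.sort_values("aicc", kind="mergesort").reset_index(drop=True)
    base_aicc = float(out.loc[out["model"] == "base", "aicc"].iloc[0])
    out["delta_aicc_vs_base"] = out["aicc"] - base_aicc
    return ModelRanking(table=out, coefficients=coefs, outcome=outcome, family=family)


# ---------------------------------------------------------------------------
# Exploratory correlations


def correlate_hyperacute(
    x: np.ndarray,
    y: np.ndarray,
    n_comparisons: int = 1,
    correction: str = "bonferroni",
) -> dict:
    """Pearson correlation with a configurable multiplicity correction."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("at least three complete pairs are required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = st.pearsonr(x, y)
    if correction == "bonferroni":
        p_adj = min(p * n_comparisons, 1.0)
    elif correction == "none":
        p_adj = p
    else:
        raise ValueError("correction must be 'bonferroni' or 'none'")
    return {"r": float(r), "p": float(p), "p_adjusted": float(p_adj), "n": len(x)}
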