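"""Linear mixed-effects models relating windowed BOLD activity to learning
signals, with likelihood-ratio model comparison and Nakagawa R-squared.

The model family predicts a per-stop-trial window statistic y from

    fixed:   y = b0 + b1*t + b2*c + b3*dP(Stop) + b4*dRT
    random:  u1_i + u2_i*dRT + u3_i*dP(Stop) + v_j

where t is the standardized trial number, c the failed-stop indicator
(all-stop-trials family only), i indexes subjects and j waves.  Estimation is
by statsmodels MixedLM; random slopes use a diagonal (uncorrelated) covariance
by default, matching the separate per-term SDs the family's reports present,
with an optional unstructured covariance.  The wave intercept is fitted as a
wave-within-subject variance component (a single grouping factor stands in for
the crossed design; with two waves the crossed term is weakly identified
either way).

Models intended for likelihood-ratio comparison must be fitted by maximum
likelihood; REML fits are refused by :func:`lrt_compare`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


def standardize_predictors(table: pd.DataFrame, columns: Sequence[str],
                           suffix: str = "_z") -> pd.DataFrame:
    """Z-score columns over all retained rows; appends ``suffix`` columns.

    Raises on zero-variance (constant) columns, naming the offender.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col + suffix] = (x - np.nanmean(x)) / sd
    return out


@dataclass
class MixedModelFit:
    """Fitted LMM: coefficients with Wald 95% CIs, random-effect SDs, fit indices."""

    params: pd.Series
    conf_int: pd.DataFrame
    bse: pd.Series
    re_sd: dict
    llf: float
    aic: float
    bic: float
    n_params: int
    n_obs: int
    method: str
    converged: bool
    singular: bool
    r2_marginal: float
    r2_conditional: float
    formula: str
    scale: float
    random_structure: dict = field(default_factory=dict, repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "ci_low": self.conf_int[0],
            "ci_high": self.conf_int[1],
        })


@dataclass(frozen=True)
class LRTResult:
    """Chi-square comparison of nested ML fits: 2*(llf_full - llf_reduced)."""

    chi2: float
    df: int
    p: float


def nakagawa_r2_from_components(var_fixed: float, var_random: float,
                                var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R2 from variance components.

    marginal    = var_fixed / (var_fixed + var_random + var_resid)
    conditional = (var_fixed + var_random) / (same denominator)
    """
    total = var_fixed + var_random + var_resid
    if total <= 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_random) / total


def fit_lmm(data: pd.DataFrame, response: str,
            fixed: Sequence[str] = ("trial_z", "stop_failure", "dpstop_z", "drt_z"),
            random_slopes: Sequence[str] = ("dpstop_z", "drt_z"),
            subject_col: str = "subject", wave_col: str = "wave",
            method: str = "ml", full_cov: bool = False,
            wave_intercept: bool = True) -> MixedModelFit:
    """Fit the Gaussian LMM by (restricted) maximum likelihood.

    ``fixed`` are the fixed-effect columns beyond the intercept; every entry
    of ``random_slopes`` must also appear in ``fixed``.  Rows with missing
    values in any used column are dropped listwise.  ``full_cov=True`` fits an
    unstructured covariance among the subject intercept and slopes instead of
    the default diagonal one.  A converged fit with a variance component on
    the boundary is flagged ``singular``; non-convergence raises.
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    for s in random_slopes:
        if s not in fixed:
            raise ValueError(f"random slope {s!r} has no matching fixed effect")
    used = [response, *fixed, subject_col]
    if wave_intercept:
        used.append(wave_col)
    df = data.dropna(subset=used).copy()
    if df[subject_col].nunique() < 2:
        raise ValueError("need at least two subjects")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    vc = {}
    if wave_intercept:
        vc["wave"] = f"0 + C({wave_col})"
    if full_cov:
        re_formula = "1" + "".join(f" + {s}" for s in random_slopes)
    else:
        re_formula = "1"
        for s in random_slopes:
            vc[f"slope_{s}"] = f"0 + {s}"
    model = MixedLM.from_formula(formula, groups=subject_col,
                                 re_formula=re_formula,
                                 vc_formula=vc or None, data=df)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # the default optimizer chain handles boundary variance components
        # best; fall through alternatives only if it fails outright
        for optimizer in (None, "bfgs", "cg", "powell"):
            kwargs = {} if optimizer is None else {"method": optimizer}
            try:
                result = model.fit(reml=(method == "reml"), **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result.converged:
                break
    if result is None or not result.converged:
        raise RuntimeError("mixed model failed to converge")

    fe = result.fe_params
    ci_all = result.conf_int()
    ci = ci_all.loc[fe.index]
    bse = result.bse.loc[fe.index]

    q = result.cov_re.shape[0]
    n_cov = q * (q + 1) // 2
    vcomp = np.asarray(result.vcomp, dtype=float)
    k = len(fe) + n_cov + len(vcomp) + 1  # + residual variance
    n = int(result.nobs)
    llf = float(result.llf)
    aic = -2 * llf + 2 * k
    bic = -2 * llf + np.log(n) * k

    # random-effect SDs, on the response scale
    re_sd: dict[str, float] = {}
    cov_re = np.asarray(result.cov_re)
    re_names = list(result.cov_re.index) if hasattr(result.cov_re, "index") else [
        f"re{i}" for i in range(q)]
    for i, name in enumerate(re_names):
        if i == 0 and not full_cov or name in ("Group", "Intercept", subject_col):
            label = "subject_intercept"
        else:
            label = f"subject_{name}"
        re_sd[label] = float(np.sqrt(max(cov_re[i, i], 0.0)))
    vc_names = list(model.exog_vc.names) if vc else []
    for name, v in zip(vc_names, vcomp):
        label = "wave_intercept" if name == "wave" else f"subject_{name.removeprefix('slope_')}"
        re_sd[label] = float(np.sqrt(max(v, 0.0)))

    scale = float(result.scale)
    total_var_scale = scale + float(np.trace(cov_re)) + float(vcomp.sum())
    singular = bool(
        np.any(np.diag(cov_re) < 1e-8 * total_var_scale)
        or (len(vcomp) and np.any(vcomp < 1e-8 * total_var_scale)))

    r2m, r2c = _nakagawa_from_result(result, model, df, fixed, random_slopes,
                                     full_cov, wave_intercept)
    return MixedModelFit(
        params=fe, conf_int=ci, bse=bse, re_sd=re_sd, llf=llf, aic=float(aic),
        bic=float(bic), n_params=k, n_obs=n, method=method,
        converged=bool(result.converged), singular=singular,
        r2_marginal=r2m, r2_conditional=r2c, formula=formula, scale=scale,
        random_structure={"full_cov": full_cov,
                          "random_slopes": tuple(random_slopes),
                          "wave_intercept": wave_intercept,
                          "data": df, "result": result},
    )


def _nakagawa_from_result(result, model, df, fixed, random_slopes, full_cov,
                          wave_intercept) -> tuple[float, float]:
    """Nakagawa/Johnson R2: random-slope variance enters through the mean of
    the per-observation quadratic form z' Sigma z."""
    fitted_fixed = np.asarray(model.exog) @ np.asarray(result.fe_params)
    var_f = float(np.var(fitted_fixed))
    cov_re = np.asarray(result.cov_re)
    if full_cov:
        z = np.column_stack([np.ones(len(df))] +
                            [df[s].to_numpy(dtype=float) for s in random_slopes])
        var_re = float(np.mean(np.einsum("ij,jk,ik->i", z, cov_re, z)))
    else:
        var_re = float(cov_re[0, 0])
        vc_names = list(model.exog_vc.names) if model.exog_vc is not None else []
        for name, v in zip(vc_names, np.asarray(result.vcomp, dtype=float)):
            if name == "wave":
                var_re += float(v)  # 0/1 dummy: z^2 == 1
            else:
                col = name.removeprefix("slope_")
                var_re += float(v * np.mean(df[col].to_numpy(dtype=float) ** 2))
    if not full_cov and wave_intercept:
        pass  # wave already included above
    return nakagawa_r2_from_components(var_f, var_re, float(result.scale))


def nakagawa_r2(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R2 of a fitted model."""
    return fit.r2_marginal, fit.r2_conditional


def lrt_compare(full: MixedModelFit, reduced: MixedModelFit) -> LRTResult:
    """Likelihood-ratio chi-square test of nested ML fits.

    chi2 = 2*(llf_full - llf_reduced), df = parameter-count difference.
    Refuses REML fits: the restricted likelihoods of models with different
    fixed effects are not comparable.
    """
    for fit, name in ((full, "full"), (reduced, "reduced")):
        if fit.method != "ml":
            raise ValueError(
                f"{name} model was fitted by REML; refit with method='ml' "
                "before likelihood-ratio comparison")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 == 0 else 0.0)
    return LRTResult(chi2=float(chi2), df=int(df), p=p)


def model_comparison_table(fits: dict[str, MixedModelFit],
                           full_label: str = "full") -> pd.DataFrame:
    """Report table: fit indices per model plus chi-square rows vs the full model."""
    full = fits[full_label]
    rows = []
    for label, fit in fits.items():
        row = {"model": label, "n_params": fit.n_params, "logLik": fit.llf,
               "AIC": fit.aic, "BIC": fit.bic,
               "r2_marginal": fit.r2_marginal,
               "r2_conditional": fit.r2_conditional,
               "chi2": np.nan, "df": np.nan, "p": np.nan}
        if label != full_label:
            lrt = lrt_compare(full, fit)
            row.update({"chi2": lrt.chi2, "df": lrt.df, "p": lrt.p})
        rows.append(row)
    return pd.DataFrame(rows)
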