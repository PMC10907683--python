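"""Mixed-effects fusion of passive features with self-report components.

One linear mixed-effects model is fitted per independent component:

    y_ijk = beta0 + b_i + b_ij + beta1' x_ijk + eps_ijk

where i indexes participants, j weeks within participant, and k the day
within the week. b_i ~ N(0, sigma1^2) is a participant random intercept,
b_ij ~ N(0, sigma2^2) a week-within-participant random intercept (week
nested in participant), and eps_ijk ~ N(0, sigma^2) the residual. x_ijk is
the standardized daily feature vector (three IKD statistics, autocorrect
and backspace rates, log total keypresses, movement and upright rates).

Random-effects structure is chosen by forwards fitting with ML likelihood-
ratio tests and the selected model refit with REML for reporting. Because
one model is fitted per component, p values are Bonferroni-corrected with
the family-wise factor CF = n_IC * n_fixed (n_fixed = 8 fixed-effect terms,
excluding the intercept).

Estimation uses statsmodels' MixedLM with a variance-component term for the
nested week intercepts. Wald 95% CIs and p values use the normal
approximation; exact small-sample degree-of-freedom corrections are out of
scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

__all__ = [
    "FIXED_TERMS",
    "N_FIXED",
    "CorrectionSpec",
    "ComponentModelFit",
    "DiagnosticsBundle",
    "align_modalities",
    "enforce_week_identifiability",
    "fit_component_model",
    "forward_fit_random_effects",
    "bonferroni_correct",
    "model_diagnostics",
]

#: the 8 fixed-effect terms of every component model (intercept excluded)
FIXED_TERMS = (
    "median_ikd",
    "p95_ikd",
    "mad_ikd",
    "autocorrect_rate",
    "backspace_rate",
    "total_keypresses",
    "movement_rate",
    "upright_rate",
)
N_FIXED = len(FIXED_TERMS)


@dataclass
class CorrectionSpec:
    """Family-wise Bonferroni factor CF = n_IC * n_fixed."""

    n_ic: int
    n_fixed: int = N_FIXED

    @property
    def cf(self) -> int:
        return self.n_ic * self.n_fixed


@dataclass
class ComponentModelFit:
    component: str
    beta0: float
    beta: pd.Series  # fixed-effect estimates, indexed by term
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_uncorrected: pd.Series
    p_corrected: Optional[pd.Series]
    sigma1_sq: float  # participant-intercept variance
    sigma2_sq: float  # week-within-participant variance
    sigma_sq: float  # residual variance
    loglike: float
    converged: bool
    method: str  # "ML" or "REML"
    result: object = field(repr=False, default=None)  # statsmodels results

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_uncorrected": self.p_uncorrected,
            }
        )
        if self.p_corrected is not None:
            out["p_corrected"] = self.p_corrected
        out.index.name = "term"
        return out


@dataclass
class DiagnosticsBundle:
    residual_qq: pd.DataFrame  # theoretical vs observed quantiles
    participant_effect_qq: pd.DataFrame
    week_effect_qq: pd.DataFrame
    resid_vs_fitted: pd.DataFrame
    normality: dict  # set name -> {"statistic": W, "pvalue": p}


def align_modalities(
    daily_keyboard: pd.DataFrame,
    daily_accel: pd.DataFrame,
    sources: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join the three modalities on (participant, date); complete
    cases only.

    Keyboard rows must carry the volume-filter ``included`` flag; only
    included days survive. Week index j = 1 + floor((date - participant's
    first retained date) / 7) and k is the day's position within that
    7-day block (1..7).

    ``sources`` has columns participant_id, date, IC_1..IC_q.
    """
    kb = daily_keyboard[daily_keyboard["included"]] if "included" in daily_keyboard else daily_keyboard
    merged = kb.merge(daily_accel, on=["participant_id", "date"], how="inner")
    merged = merged.merge(sources, on=["participant_id", "date"], how="inner")
    if merged.empty:
        raise ValueError(
            "empty complete-case join: "
            f"keyboard={len(kb)} rows, accel={len(daily_accel)} rows, "
            f"self-report={len(sources)} rows share no (participant, date)"
        )
    merged = merged.sort_values(["participant_id", "date"], kind="stable").reset_index(
        drop=True
    )
    dates = pd.to_datetime(merged["date"])
    first = dates.groupby(merged["participant_id"]).transform("min")
    offset = (dates - first).dt.days
    merged["week"] = 1 + offset // 7
    merged["day_of_week"] = 1 + offset % 7
    return merged


def enforce_week_identifiability(
    data: pd.DataFrame, policy: str = "drop-week"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove participant-weeks with fewer than two observations.

    The nested week intercept is unidentifiable from singleton weeks. Under
    ``drop-week`` (default) only the offending weeks go; ``drop-participant``
    removes the whole participant as soon as any week is deficient. Returns
    the reduced data and an exclusion log with one row per dropped unit.
    """
    if policy not in ("drop-week", "drop-participant"):
        raise ValueError(f"unknown policy {policy!r}")
    counts = data.groupby(["participant_id", "week"], sort=False)["week"].transform(
        "size"
    )
    bad = counts < 2
    log_rows = []
    if policy == "drop-week":
        keep = ~bad
        for (pid, wk), sub in data[bad].groupby(["participant_id", "week"]):
            log_rows.append(
                {"participant_id": pid, "week": wk, "n_rows": len(sub), "policy": policy}
            )
    else:
        bad_pids = data.loc[bad, "participant_id"].unique()
        keep = ~data["participant_id"].isin(bad_pids)
        for pid in bad_pids:
            log_rows.append(
                {
                    "participant_id": pid,
                    "week": None,
                    "n_rows": int((data["participant_id"] == pid).sum()),
                    "policy": policy,
                }
            )
    log = pd.DataFrame(log_rows, columns=["participant_id", "week", "n_rows", "policy"])
    return data[keep].reset_index(drop=True), log


def _check_identifiable(data: pd.DataFrame) -> None:
    counts = data.groupby(["participant_id", "week"]).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()[:5]
        raise ValueError(
            f"participant-weeks with < 2 observations present (e.g. {bad}); "
            "run enforce_week_identifiability first"
        )


def _mixed_model(data: pd.DataFrame, component: str):
    formula = f"{component} ~ " + " + ".join(FIXED_TERMS)
    return smf.mixedlm(
        formula,
        data,
        groups="participant_id",
        re_formula="1",
        vc_formula={"week": "0 + C(week)"},
    )


#: optimizer fallback chain; lbfgs is fast but fails near variance
#: boundaries, where the derivative-free methods are reliable
_OPTIMIZERS = ("lbfgs", "powell", "nm", "bfgs")


def _fit_mixedlm(model, reml: bool):
    """Fit a MixedLM, falling back through optimizers until one converges.

    Returns the first converged result, or the last result obtained if none
    converged (callers inspect ``.converged``). Raises RuntimeError only if
    every optimizer errors out.
    """
    last = None
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt in _OPTIMIZERS:
            try:
                res = model.fit(reml=reml, method=opt)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{opt}: {exc}")
                continue
            if res.converged:
                return res
            last = res
    if last is not None:
        return last
    raise RuntimeError(
        "mixed-model fit failed with every optimizer ("
        + "; ".join(errors)
        + "); consider a simpler random-effects structure"
    )


def fit_component_model(
    data: pd.DataFrame,
    component: str,
    method: str = "REML",
    correction: Optional[CorrectionSpec] = None,
) -> ComponentModelFit:
    """Fit the nested random-intercept model for one component.

    ``data`` is an aligned, identifiability-enforced dataset whose feature
    columns are standardized. Returns estimates with Wald 95% CIs, variance
    components, and (if ``correction`` is given) Bonferroni-corrected
    p values. Convergence failure raises with the optimizer message and a
    hint to simplify the random structure.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be ML or REML, got {method!r}")
    _check_identifiable(data)
    model = _mixed_model(data, component)
    try:
        res = _fit_mixedlm(model, reml=(method == "REML"))
    except RuntimeError as exc:
        raise RuntimeError(f"mixed model for {component}: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"mixed model for {component} did not converge "
            f"(method={method}); consider a simpler random-effects structure"
        )
    params = res.params
    bse = res.bse
    terms = list(FIXED_TERMS)
    beta = params[terms]
    se = bse[terms]
    z = st.norm.ppf(0.975)
    pvals = pd.Series(res.pvalues[terms], index=terms)
    fit = ComponentModelFit(
        component=component,
        beta0=float(params["Intercept"]),
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        p_uncorrected=pvals,
        p_corrected=bonferroni_correct(pvals, correction) if correction else None,
        sigma1_sq=float(res.cov_re.iloc[0, 0]),
        sigma2_sq=float(res.vcomp[0]),
        sigma_sq=float(res.scale),
        loglike=float(res.llf),
        converged=bool(res.converged),
        method=method,
        result=res,
    )
    return fit


def _fit_candidate(data: pd.DataFrame, component: str, structure: str, reml: bool):
    """structure: 'none' (OLS), 'participant', 'participant+week'."""
    formula = f"{component} ~ " + " + ".join(FIXED_TERMS)
    if structure == "none":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.ols(formula, data).fit()
    if structure == "participant":
        m = smf.mixedlm(formula, data, groups="participant_id", re_formula="1")
    elif structure == "participant+week":
        m = _mixed_model(data, component)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return _fit_mixedlm(m, reml=reml)


RANDOM_STRUCTURES = ("none", "participant", "participant+week")


def forward_fit_random_effects(
    data: pd.DataFrame,
    component: str,
    structures: Sequence[str] = RANDOM_STRUCTURES,
) -> tuple[pd.DataFrame, ComponentModelFit]:
    """Forwards-fit the random-effects structure, simplest first.

    Each candidate is fit with ML and compared to its predecessor with a
    1-df chi-square likelihood-ratio test (conservative at the variance
    boundary; no mixture correction). The final structure is refit with
    REML for reporting. Returns the LRT table and the REML fit of the full
    nested model.

    Comparing a structure to itself yields statistic 0 and p = 1.
    """
    structures = list(structures)
    for s in structures:
        if s not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown structure {s!r}")
    order = [RANDOM_STRUCTURES.index(s) for s in structures]
    if order != sorted(order):
        raise ValueError("structures must be ordered simplest first (nested sequence)")
    rows = []
    prev_llf = None
    prev_name = None
    for s in structures:
        res = _fit_candidate(data, component, s, reml=False)
        llf = float(res.llf)
        if prev_llf is None or s == prev_name:
            stat, p = np.nan, np.nan
            if s == prev_name:
                stat, p = 0.0, 1.0
        else:
            stat = max(0.0, 2.0 * (llf - prev_llf))
            p = float(st.chi2.sf(stat, df=1))
        rows.append(
            {"structure": s, "loglike": llf, "lrt_stat": stat, "p_value": p}
        )
        prev_llf, prev_name = llf, s
    table = pd.DataFrame(rows)
    final = fit_component_model(data, component, method="REML")
    return table, final


def bonferroni_correct(
    p_uncorrected: pd.Series | np.ndarray,
    spec: CorrectionSpec,
) -> pd.Series | np.ndarray:
    """Family-wise correction across all component models:
    p_corrected = min(1, CF * p), CF = n_IC * n_fixed."""
    p = np.asarray(p_uncorrected, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    corrected = np.minimum(1.0, spec.cf * p)
    if isinstance(p_uncorrected, pd.Series):
        return pd.Series(corrected, index=p_uncorrected.index)
    return corrected


def _qq_frame(values: np.ndarray) -> pd.DataFrame:
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    probs = (np.arange(1, n + 1) - 0.5) / n
    sd = values.std(ddof=1) if n > 1 else 1.0
    theo = st.norm.ppf(probs, loc=values.mean(), scale=sd if sd > 0 else 1.0)
    return pd.DataFrame({"theoretical": theo, "observed": values})


def _normality(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        return {"statistic": np.nan, "pvalue": np.nan}
    if len(values) > 4500:  # Shapiro-Wilk p values degrade for huge n
        values = np.random.default_rng(0).choice(values, 4500, replace=False)
    stat, p = st.shapiro(values)
    return {"statistic": float(stat), "pvalue": float(p)}


def model_diagnostics(fit: ComponentModelFit, data: pd.DataFrame) -> DiagnosticsBundle:
    """Residual and random-effect tables for assumption checking.

    Emits QQ tables (theoretical normal vs observed quantiles) for
    residuals and both random-effect sets, a standardized-residual vs
    fitted-value table for heteroskedasticity assessment, and a
    Shapiro-Wilk summary per set. Tables are meant for rendering; no plot
    is produced here.
    """
    res = fit.result
    if res is None or not fit.converged:
        raise ValueError("diagnostics require a converged fit with results attached")
    resid = np.asarray(res.resid)
    fitted = np.asarray(res.fittedvalues)
    re = res.random_effects
    participant_effects = np.array([v.iloc[0] for v in re.values()])
    week_effects = np.concatenate([v.iloc[1:].to_numpy() for v in re.values()])
    std_resid = resid / np.sqrt(fit.sigma_sq)
    return DiagnosticsBundle(
        residual_qq=_qq_frame(resid),
        participant_effect_qq=_qq_frame(participant_effects),
        week_effect_qq=_qq_frame(week_effects),
        resid_vs_fitted=pd.DataFrame(
            {"fitted": fitted, "standardized_residual": std_resid}
        ),
        normality={
            "residuals": _normality(resid),
            "participant_effects": _normality(participant_effects),
            "week_effects": _normality(week_effects),
        },
    )
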