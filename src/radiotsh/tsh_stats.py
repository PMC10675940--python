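"""The tumor-stroma heterogeneity (TSH) statistic and survival analysis.

The TSH value of a cell population is the relative abundance difference
between tumor and stroma, (A_tumor - A_stroma) / A_stroma.  Patients are
stratified into good- and poor-survival groups by thresholding TSH, and
the groups are compared with Kaplan-Meier curves, log-rank tests and
(adjusted) Cox proportional-hazards models, with Benjamini-Hochberg
control of the false-discovery rate across cell populations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Default TSH stratification threshold.  Shipped as a constant of the
#: published workflow; how it was derived (e.g. an optimal cut-point
#: search) is not part of this package.
TSH_THRESHOLD = 0.3512

#: Default administrative censoring horizon in years.
CENSOR_HORIZON_YEARS = 10.0


class UndefinedRatioError(ValueError):
    """Raised when a stromal abundance is too close to zero for the ratio."""


def tsh_score(a_tumor, a_stroma, eps: float = 1e-8):
    """Relative tumor-vs-stroma abundance: (A_tumor - A_stroma) / A_stroma.

    Accepts scalars or aligned array-likes; labelled inputs (Series) keep
    their index.  Stromal abundances with \\|A_stroma\\| < ``eps`` raise
    :class:`UndefinedRatioError` naming the offending entries.
    """
    a_t = np.asarray(a_tumor, dtype=float)
    a_s = np.asarray(a_stroma, dtype=float)
    bad = np.abs(a_s) < eps
    if np.any(bad):
        if isinstance(a_stroma, pd.Series):
            names = list(a_stroma.index[np.nonzero(bad)[0]])
        else:
            names = list(np.nonzero(np.atleast_1d(bad))[0])
        raise UndefinedRatioError(
            f"stromal abundance below eps={eps} for: {names[:10]}"
        )
    out = (a_t - a_s) / a_s
    if isinstance(a_tumor, pd.Series):
        return pd.Series(out, index=a_tumor.index, name="tsh")
    return out if out.ndim else float(out)


def tsh_table(
    tumor_abundance: pd.DataFrame, stroma_abundance: pd.DataFrame, eps: float = 1e-8
) -> pd.DataFrame:
    """TSH per patient and cell population from paired abundance tables."""
    tumor_abundance, stroma_abundance = tumor_abundance.align(
        stroma_abundance, join="inner"
    )
    out = {}
    for ct in tumor_abundance.columns:
        out[ct] = tsh_score(tumor_abundance[ct], stroma_abundance[ct], eps=eps)
    return pd.DataFrame(out)


def stratify(tsh_values, threshold: float = TSH_THRESHOLD) -> pd.Series:
    """Label each patient good (tsh > threshold) or poor (ties go to poor)."""
    s = pd.Series(tsh_values, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("non-finite TSH values")
    return pd.Series(np.where(s > threshold, "good", "poor"), index=s.index, name="group")


def censor_at(records: pd.DataFrame, horizon_years: float = CENSOR_HORIZON_YEARS) -> pd.DataFrame:
    """Administratively censor all follow-up beyond the horizon."""
    out = records.copy()
    late = out["time"] > horizon_years
    out.loc[late, "time"] = horizon_years
    out.loc[late, "event"] = 0
    return out


def _split_two_groups(records: pd.DataFrame, groups: pd.Series):
    groups = groups.reindex(records.index)
    if groups.isna().any():
        raise ValueError("group labels missing for some records")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels} (degenerate grouping)")
    return [(lv, records.loc[groups == lv]) for lv in levels]


def km_curve(records: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curve per group.

    Returns one DataFrame per group with columns ``time`` and ``survival``
    (the right-continuous step function evaluated at each event time).
    """
    curves = {}
    for level, sub in _split_two_groups(records, groups):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[level] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p value."""
    (la, a), (lb, b) = _split_two_groups(records, groups)
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


class CoxFitError(RuntimeError):
    """Cox partial-likelihood maximization failed (separation / collinearity)."""


def cox_fit(records: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, float]:
    """Multivariate Cox proportional-hazards fit (Breslow tie handling).

    Returns (summary table, maximized partial log-likelihood).  The summary
    has one row per covariate with columns ``beta``, ``hr``, ``ci_lower``,
    ``ci_upper``, ``wald`` (the squared z statistic, chi-square on 1 df)
    and ``p``.
    """
    if records["event"].sum() < 2 or records.loc[records.event == 1, "time"].nunique() < 2:
        raise CoxFitError("need at least two distinct event times")
    df = records[["time", "event", *covariates]].astype(float)
    if (df[covariates].nunique() <= 1).any():
        raise CoxFitError("constant covariate in the design matrix")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise CoxFitError(f"Cox model did not converge: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame(
        {
            "beta": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "wald": s["z"] ** 2,
            "p": s["p"],
        }
    )
    return table, float(cph.log_likelihood_)


def null_partial_loglik(records: pd.DataFrame) -> float:
    """Breslow partial log-likelihood of the covariate-free (null) Cox model."""
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    ll = 0.0
    for ti in np.unique(t[e == 1]):
        d = int(((t == ti) & (e == 1)).sum())
        ll -= d * np.log((t >= ti).sum())
    return float(ll)


def lr_test(loglik_null: float, loglik_full: float, df_diff: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested Cox models: 2*Δlog L vs chi-square."""
    if df_diff < 0:
        raise ValueError("df_diff must be >= 0")
    stat = max(2.0 * (loglik_full - loglik_null), 0.0)
    if df_diff == 0:
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df_diff))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Zero differences are discarded before ranking; the exact null
    distribution is used for n <= 25 remaining pairs, the normal
    approximation with continuity correction above.  All-zero differences
    are degenerate: a warning is emitted and p = 1 returned.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; test is degenerate", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def univariate_tsh_sweep(
    tsh: pd.DataFrame, survival: pd.DataFrame, horizon_years: float = CENSOR_HORIZON_YEARS
) -> pd.DataFrame:
    """Univariate Cox association of each cell population's TSH with survival.

    One row per cell population: beta, HR with 95% CI, Wald chi-square,
    p, and BH-corrected p across the populations tested.
    """
    records = censor_at(survival, horizon_years)
    rows = []
    for ct in tsh.columns:
        df = records.join(tsh[[ct]], how="inner").rename(columns={ct: "tsh"})
        table, _ = cox_fit(df, ["tsh"])
        row = table.loc["tsh"].rename(ct)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["corrected_p"] = bh_adjust(out["p"].to_numpy())
    return out
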