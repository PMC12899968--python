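"""Group-level inference: demographics tests, repeated-measures ANCOVA,
ROI correlations, and the nested covariate sensitivity ladder.

The central model is a 2 (group: RPG vs IAG, between) x 2 (stimulus type:
food vs neutral, within) repeated-measures ANCOVA with between-subject
covariates (age, sex, BMI, depression score, composite appetite by
default). It is computed as the classical split-plot decomposition:

* between-subject stratum — OLS of the subject means on group plus
  mean-centered covariates; the group F has (1, N - 2 - p) denominator df;
* within-subject stratum — OLS of orthonormal within-contrast scores on
  group (effect-coded), testing the within main effect (intercepts) and
  the group x within interaction (slopes), with (k-1)(N-2) error df.

Covariates do not enter the within stratum (no covariate x within
interactions are modeled). Greenhouse-Geisser epsilon is estimated from
the pooled contrast-score residual covariance and applied when sphericity
is violated; with two within levels epsilon is identically 1. Effect sizes
are partial eta squared by default (classical eta squared also computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    pass


class RankDeficientError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Demographics


def demographics_tests(
    participants: pd.DataFrame,
    continuous: list[str] | None = None,
    group_col: str = "group",
    sex_col: str = "sex",
    equal_var: bool = True,
    chi2_correction: bool = False,
) -> pd.DataFrame:
    """Independent-samples t-tests per continuous variable and a chi-square
    test on the 2x2 group x sex table.

    Pooled-variance t by default (``equal_var=False`` for Welch);
    chi-square without Yates continuity correction by default.
    """
    groups = sorted(participants[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    g0 = participants[participants[group_col] == groups[0]]
    g1 = participants[participants[group_col] == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need n >= 2 per group")

    continuous = continuous or [
        "age", "bmi", "waist_cm", "visceral_fat_cm2", "mets", "bdi_ii",
        "composite_appetite",
    ]
    rows = []
    for var in continuous:
        a, b = g0[var].dropna().to_numpy(), g1[var].dropna().to_numpy()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            raise DegenerateInputError(f"{var}: zero variance in both groups")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        df = (
            len(a) + len(b) - 2
            if equal_var
            else _welch_df(a, b)
        )
        rows.append(
            {"variable": var, "test": "t" if equal_var else "welch-t",
             "statistic": float(t), "df": float(df), "p": float(p)}
        )

    table = pd.crosstab(participants[group_col], participants[sex_col])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=chi2_correction)
    rows.append(
        {"variable": sex_col, "test": "chi2", "statistic": float(chi2),
         "df": float(dof), "p": float(p)}
    )
    return pd.DataFrame(rows)


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


# ---------------------------------------------------------------------------
# Repeated-measures ANCOVA

DEFAULT_COVARIATES = ["age", "sex", "bmi", "bdi_ii", "composite_appetite"]


@dataclass
class AncovaSpec:
    """Configuration of one repeated-measures ANCOVA."""

    dv: str = "ssrt_ms"
    between: str = "group"
    within: str = "condition"
    subject: str = "participant_id"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    alpha: float = 0.05
    posthoc_k: int | None = None  # Bonferroni multiplier; default = n within levels
    sphericity_correction: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class AncovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_sq: float          # partial eta squared (default report)
    eta_sq_classical: float
    gg_epsilon: float | None = None


def _design_columns(df: pd.DataFrame, spec: AncovaSpec) -> np.ndarray:
    """Covariate block: mean-centered; sex-like string columns become a
    centered binary indicator."""
    cols = []
    for c in spec.covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has >2 levels: {levels}")
            v = (v == levels[-1]).astype(float)
        v = v.astype(float)
        cols.append((v - v.mean()).to_numpy())
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the collinearity
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise RankDeficientError(f"design matrix rank deficient; collinear columns: {bad}")


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def rm_ancova(
    long_table: pd.DataFrame,
    spec: AncovaSpec | None = None,
    return_posthoc: bool = False,
):
    """Mixed group x within-factor ANCOVA on a long table (one row per
    subject x within level).

    Returns a list of :class:`AncovaResult` for the between main effect,
    within main effect and interaction; with ``return_posthoc`` also a
    DataFrame of Bonferroni-adjusted group comparisons per within level.
    Incomplete subjects are dropped listwise (count recorded on the
    returned posthoc frame's attrs / printed report).
    """
    spec = spec or AncovaSpec()
    df = long_table.copy()

    wide = df.pivot_table(
        index=spec.subject, columns=spec.within, values=spec.dv, aggfunc="first",
        dropna=False,
    )
    levels = list(wide.columns)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two within-factor levels")
    meta = (
        df.drop_duplicates(spec.subject)
        .set_index(spec.subject)[[spec.between] + spec.covariates]
    )
    data = wide.join(meta)
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)
    n = len(data)

    groups = sorted(data[spec.between].unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, got {groups}")
    g = np.where(data[spec.between] == groups[1], 0.5, -0.5)  # effect coding
    Y = data[levels].to_numpy(dtype=float)
    cov = _design_columns(data.reset_index(), spec)
    p_cov = cov.shape[1]

    # --- between stratum: subject means ~ 1 + group + covariates
    m = Y.mean(axis=1)
    Xb = np.column_stack([np.ones(n), g, cov])
    _check_rank(Xb, ["intercept", spec.between] + spec.covariates)
    rss_full = _ols_rss(Xb, m)
    rss_nog = _ols_rss(np.delete(Xb, 1, axis=1), m)
    df_den_b = n - 2 - p_cov
    ss_g, ss_e_b = (rss_nog - rss_full), rss_full
    F_g = (ss_g / 1.0) / (ss_e_b / df_den_b)
    p_g = float(stats.f.sf(F_g, 1, df_den_b))
    ss_tot_b = float(np.var(m, ddof=0) * n)

    # --- within stratum: orthonormal contrast scores ~ 1 + group
    C = _orthonormal_contrasts(k)
    Z = Y @ C  # n x (k-1)
    Xw = np.column_stack([np.ones(n), g])
    ss_w = ss_int = ss_e_w = 0.0
    resid = np.empty((n, k - 1))
    for j in range(k - 1):
        z = Z[:, j]
        rss = _ols_rss(Xw, z)
        ss_e_w += rss
        ss_w += _ols_rss(Xw[:, [1]], z) - rss        # drop intercept
        ss_int += _ols_rss(Xw[:, [0]], z) - rss      # drop group
        beta, *_ = np.linalg.lstsq(Xw, z, rcond=None)
        resid[:, j] = z - Xw @ beta
    df_e_w = (k - 1) * (n - 2)
    eps = _gg_epsilon(resid)
    F_w = (ss_w / (k - 1)) / (ss_e_w / df_e_w)
    F_i = (ss_int / (k - 1)) / (ss_e_w / df_e_w)

    adj = eps if (spec.sphericity_correction and eps < 1.0 - 1e-12) else 1.0
    dfn, dfd = (k - 1) * adj, df_e_w * adj
    p_w = float(stats.f.sf(F_w, dfn, dfd))
    p_i = float(stats.f.sf(F_i, dfn, dfd))

    within_name = spec.within
    results = [
        AncovaResult(
            effect=spec.between, F=float(F_g), df_num=1.0, df_den=float(df_den_b),
            p=p_g, eta_sq=_safe_div(ss_g, ss_g + ss_e_b),
            eta_sq_classical=_safe_div(ss_g, ss_tot_b),
        ),
        AncovaResult(
            effect=within_name, F=float(F_w), df_num=float(dfn), df_den=float(dfd),
            p=p_w, eta_sq=_safe_div(ss_w, ss_w + ss_e_w),
            eta_sq_classical=_safe_div(ss_w, ss_w + ss_int + ss_e_w),
            gg_epsilon=float(eps),
        ),
        AncovaResult(
            effect=f"{spec.between}:{within_name}", F=float(F_i), df_num=float(dfn),
            df_den=float(dfd), p=p_i, eta_sq=_safe_div(ss_int, ss_int + ss_e_w),
            eta_sq_classical=_safe_div(ss_int, ss_w + ss_int + ss_e_w),
            gg_epsilon=float(eps),
        ),
    ]
    if not return_posthoc:
        return results

    k_bonf = spec.posthoc_k or k
    ph_rows = []
    for lev in levels:
        y = data[lev].to_numpy(dtype=float)
        rss_f = _ols_rss(Xb, y)
        rss_r = _ols_rss(np.delete(Xb, 1, axis=1), y)
        F = (rss_r - rss_f) / (rss_f / df_den_b)
        p_raw = float(stats.f.sf(F, 1, df_den_b))
        diff = float(
            data.loc[data[spec.between] == groups[1], lev].mean()
            - data.loc[data[spec.between] == groups[0], lev].mean()
        )
        ph_rows.append(
            {
                "level": lev,
                "comparison": f"{groups[1]} - {groups[0]}",
                "mean_diff": diff,
                "F": float(F),
                "p_raw": p_raw,
                "p_bonferroni": bonferroni(p_raw, k_bonf),
            }
        )
    posthoc = pd.DataFrame(ph_rows)
    posthoc.attrs["n_dropped_listwise"] = n_dropped
    posthoc.attrs["bonferroni_k"] = k_bonf
    return results, posthoc


def bonferroni(p_raw: float, k: int) -> float:
    """Bonferroni adjustment: min(1, k x raw p)."""
    return float(min(1.0, k * p_raw))


def _safe_div(a: float, b: float) -> float:
    return float(a / b) if b > 0 else 0.0


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal within-subject contrasts (orthonormalized
    Helmert); each column sums to zero and has unit norm."""
    H = np.zeros((k, k - 1))
    for j in range(k - 1):
        H[: j + 1, j] = 1.0
        H[j + 1, j] = -(j + 1.0)
    H /= np.linalg.norm(H, axis=0, keepdims=True)
    return H


def _gg_epsilon(resid: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled covariance of the
    orthonormal contrast-score residuals; 1 exactly when k = 2."""
    q = resid.shape[1]
    if q == 1:
        return 1.0
    S = resid.T @ resid / max(1, resid.shape[0] - 1)
    return float(np.trace(S) ** 2 / (q * np.sum(S * S)))


# ---------------------------------------------------------------------------
# ROI correlations


def roi_correlations(
    summaries: pd.DataFrame,
    roi_values: pd.DataFrame,
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlations of ROI contrast values against SSRT and
    MET-minutes, per ROI x stimulus condition.

    Exploratory by design: p-values are raw, with no multiplicity
    correction, and flagged as such.
    """
    mets = participants.set_index("participant_id")["mets"]
    ssrt = summaries.set_index(["participant_id", "condition"])["ssrt_ms"]
    rows = []
    for (roi, cond), sub in roi_values.groupby(["roi", "condition"]):
        sub = sub.set_index("participant_id")
        for other_name, other in (("ssrt_ms", None), ("mets", mets)):
            if other is None:
                try:
                    other = ssrt.xs(cond, level="condition")
                except KeyError:
                    continue
            common = sub.index.intersection(other.index)
            if len(common) < 3:
                raise ValueError(
                    f"need n >= 3 for correlation, got {len(common)} "
                    f"({roi}, {cond}, {other_name})"
                )
            r, p = stats.pearsonr(sub.loc[common, "value"], other.loc[common])
            rows.append(
                {
                    "roi": roi,
                    "condition": cond,
                    "against": other_name,
                    "r": float(r),
                    "p": float(p),
                    "n": int(len(common)),
                    "exploratory": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity ladder

SENSITIVITY_MODELS: dict[int, list[str]] = {
    1: ["age", "sex", "bmi", "bdi_ii", "composite_appetite"],
    2: ["age", "sex", "bdi_ii", "composite_appetite"],          # minus BMI
    3: ["age", "bmi", "bdi_ii", "composite_appetite"],          # minus sex
    4: ["age", "bdi_ii", "composite_appetite"],                 # minimal
}


def sensitivity_ladder(
    long_table: pd.DataFrame, spec: AncovaSpec | None = None
) -> pd.DataFrame:
    """Re-run the repeated-measures ANCOVA under the four nested covariate
    models and tabulate F, p and partial eta squared per effect per model."""
    base = spec or AncovaSpec()
    rows = []
    for model_id, covs in SENSITIVITY_MODELS.items():
        mspec = AncovaSpec(
            dv=base.dv, between=base.between, within=base.within,
            subject=base.subject, covariates=list(covs), alpha=base.alpha,
            sphericity_correction=base.sphericity_correction,
        )
        for res in rm_ancova(long_table, mspec):
            rows.append(
                {
                    "model": model_id,
                    "n_covariates": len(covs),
                    "covariates": "+".join(covs),
                    "effect": res.effect,
                    "F": res.F,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "p": res.p,
                    "eta_sq_partial": res.eta_sq,
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[AncovaResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
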