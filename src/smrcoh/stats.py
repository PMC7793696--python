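"""Within/between-session trend statistics.

The training outcome (e.g. SMR-band coherence) is modeled per group as

    value ~ session + run + session:run            (fixed, linear covariates)
          + (1 | subject) + (0 + session | subject) + (0 + run | subject)

i.e. a linear mixed model with session 1..10 and run 1..7 (run 1 = the
baseline run) entered as numeric covariates, and per-subject random
intercepts plus independent random slopes for session and run.  Fixed
effects are tested sequentially (Type I order: session, run, session:run).
The primary backend (statsmodels MixedLM) does not provide Satterthwaite
denominator degrees of freedom; the reported F tests therefore use the
between-subject fallback df (n_subjects - 1), labeled as such in the
result.  A two-stage estimator -- per-subject OLS slopes followed by a
one-sample t across subjects -- is exposed as an internal cross-check and
used automatically when the mixed fit is singular.

Within-subject error bars use the Cousineau-Morey procedure: remove each
subject's mean, add back the grand mean, take per-condition SEs and
inflate by sqrt(C/(C-1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats as sst

__all__ = [
    "EffectTest",
    "TrendResult",
    "PrePostResult",
    "fit_trend",
    "two_stage_trend",
    "cousineau_morey_se",
    "prepost_tests",
    "slopes_by_label",
]

_EFFECTS = ("session", "run", "session:run")


@dataclass
class EffectTest:
    """One fixed effect: slope estimate, SE, F test, degrees of freedom."""

    effect: str
    estimate: float
    se: float
    F: float
    df_num: int
    df_den: float
    mse: float
    p: float


@dataclass
class TrendResult:
    effects: dict[str, EffectTest]
    model: str                     # 'mixed' or 'two-stage'
    df_method: str                 # 'between-subject fallback' for both paths
    n_subjects: int
    converged: bool
    fallback: "TrendResult | None" = None
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> EffectTest:
        return self.effects[name]


@dataclass
class PrePostResult:
    outcome: str
    pre_mean: float
    pre_se: float
    post_mean: float
    post_se: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    family_size: int
    degenerate: bool = False


def _check_dataset(dataset: pd.DataFrame, value_col: str) -> pd.DataFrame:
    needed = {"subject", "session", "run", value_col}
    missing = needed - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset lacks columns {sorted(missing)}")
    df = dataset[["subject", "session", "run", value_col]].dropna().copy()
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if df["session"].nunique() < 2 or df["run"].nunique() < 2:
        raise ValueError("need at least 2 sessions and 2 runs")
    df["value"] = df[value_col].astype(float)
    return df


def two_stage_trend(dataset: pd.DataFrame, value_col: str = "band_imcoh") -> TrendResult:
    """Per-subject OLS of value on session, run and session*run, then
    one-sample t tests of the subject-level coefficients against zero."""
    df = _check_dataset(dataset, value_col)
    coefs = {name: [] for name in _EFFECTS}
    for _, sub in df.groupby("subject"):
        X = np.column_stack([
            np.ones(len(sub)),
            sub["session"].to_numpy(float),
            sub["run"].to_numpy(float),
            sub["session"].to_numpy(float) * sub["run"].to_numpy(float),
        ])
        beta, *_ = np.linalg.lstsq(X, sub["value"].to_numpy(), rcond=None)
        for name, b in zip(_EFFECTS, beta[1:]):
            coefs[name].append(b)
    n = len(coefs["session"])
    effects = {}
    for name in _EFFECTS:
        vals = np.asarray(coefs[name])
        est = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        if se > 0:
            t = est / se
            p = float(2 * sst.t.sf(abs(t), n - 1))
        else:
            t = np.inf if est != 0 else 0.0
            p = 0.0 if est != 0 else 1.0
        effects[name] = EffectTest(
            effect=name, estimate=est, se=se, F=float(t**2), df_num=1,
            df_den=float(n - 1), mse=float(vals.var(ddof=1)) if n > 1 else np.nan,
            p=p,
        )
    return TrendResult(
        effects=effects, model="two-stage", df_method="between-subject t (n-1)",
        n_subjects=n, converged=True,
    )


def fit_trend(dataset: pd.DataFrame, value_col: str = "band_imcoh") -> TrendResult:
    """Mixed-model linear trend fit with the two-stage estimator attached.

    Falls back to the two-stage result (flagged in ``notes``) when the mixed
    fit fails or is singular, e.g. on noise-free data.
    """
    import statsmodels.formula.api as smf

    df = _check_dataset(dataset, value_col)
    fallback = two_stage_trend(dataset, value_col)
    n = df["subject"].nunique()
    notes: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ session + run + session:run",
                data=df,
                groups="subject",
                re_formula="1",
                vc_formula={"session": "0 + session", "run": "0 + run"},
            )
            # optimizer robustness: accept the first converged fit
            fit = None
            for method in ("powell", "lbfgs", "bfgs"):
                candidate = model.fit(reml=True, method=method, maxiter=500)
                if candidate.converged:
                    fit = candidate
                    break
            if fit is None:
                fit = candidate
                notes.append("mixed-model optimizer did not report convergence")
        params = fit.params
        bse = fit.bse
        scale = float(fit.scale)
        if not np.all(np.isfinite([params.get(k, np.nan) for k in
                                   ("session", "run", "session:run")])) or \
           not np.all(np.isfinite([bse.get(k, np.nan) for k in
                                   ("session", "run", "session:run")])):
            raise np.linalg.LinAlgError("non-finite mixed-model estimates")
    except Exception as err:
        result = TrendResult(
            effects=fallback.effects, model="two-stage",
            df_method="between-subject t (n-1)", n_subjects=n, converged=False,
            fallback=fallback,
            notes=[f"mixed fit failed ({type(err).__name__}); two-stage fallback used"],
        )
        return result

    effects = {}
    df_den = float(n - 1)
    for name in _EFFECTS:
        est = float(params[name])
        se = float(bse[name])
        t = est / se if se > 0 else np.inf
        F = float(t**2)
        p = float(2 * sst.t.sf(abs(t), df_den))
        effects[name] = EffectTest(
            effect=name, estimate=est, se=se, F=F, df_num=1, df_den=df_den,
            mse=scale, p=p,
        )
    return TrendResult(
        effects=effects, model="mixed",
        df_method="between-subject fallback (n_subjects - 1); "
                  "Satterthwaite unavailable in backend",
        n_subjects=n, converged=bool(getattr(fit, "converged", True)),
        fallback=fallback, notes=notes,
    )


def cousineau_morey_se(matrix: NDArray[np.float64]) -> NDArray[np.float64]:
    """Within-subject (Cousineau-Morey) standard errors per condition.

    ``matrix`` is subjects x conditions, complete.  Each row is centred on
    its own mean and the grand mean added back; per-condition SEs of the
    normalized values are inflated by sqrt(C/(C-1)).
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(y)):
        raise ValueError("matrix contains missing values; complete data required")
    n, C = y.shape
    normalized = y - y.mean(axis=1, keepdims=True) + y.mean()
    se = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    return se * np.sqrt(C / (C - 1))


def prepost_tests(
    pre: NDArray[np.float64],
    post: NDArray[np.float64],
    family_size: int = 1,
    outcome: str = "outcome",
) -> PrePostResult:
    """Paired t test with Bonferroni adjustment (p_adj = min(1, p * family))."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be paired 1-D arrays of equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    diff = post - pre
    degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
    if degenerate:
        t = np.inf if diff.mean() != 0 else 0.0
        p = 0.0 if diff.mean() != 0 else 1.0
    else:
        t, p = sst.ttest_rel(post, pre)
        t, p = float(t), float(p)
    return PrePostResult(
        outcome=outcome,
        pre_mean=float(pre.mean()), pre_se=float(pre.std(ddof=1) / np.sqrt(n)),
        post_mean=float(post.mean()), post_se=float(post.std(ddof=1) / np.sqrt(n)),
        t=t, df=n - 1, p_raw=p, p_adjusted=float(min(1.0, p * family_size)),
        family_size=family_size, degenerate=degenerate,
    )


def slopes_by_label(
    dataset: pd.DataFrame,
    value_col: str = "band_imcoh",
    label_col: str = "strategy",
) -> pd.DataFrame:
    """Mean within-session slope of the outcome on run number, per label.

    The slope is the per-(subject, session) OLS regression of the outcome on
    run 1..7; a subject reporting k labels for a session contributes that
    session's slope to all k label means.  Labels may be a string or an
    iterable of strings per row.
    """
    needed = {"subject", "session", "run", value_col, label_col}
    missing = needed - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset lacks columns {sorted(missing)}")
    rows = []
    for (subject, session), sub in dataset.groupby(["subject", "session"]):
        if sub["run"].nunique() < 3:
            raise ValueError(
                f"subject {subject} session {session}: need >= 3 runs for a slope"
            )
        slope = float(np.polyfit(sub["run"].astype(float), sub[value_col].astype(float), 1)[0])
        labels = sub[label_col].iloc[0]
        if isinstance(labels, str):
            labels = [labels]
        for label in labels:
            rows.append((label, subject, session, slope))
    if not rows:
        warnings.warn("no labeled observations; empty result")
        return pd.DataFrame(columns=["label", "mean_slope", "n"])
    long = pd.DataFrame(rows, columns=["label", "subject", "session", "slope"])
    out = long.groupby("label")["slope"].agg(mean_slope="mean", n="size").reset_index()
    return out
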