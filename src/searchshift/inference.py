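"""Statistical inference chain: mixed-effect regressions, proportion tests,
and bootstrap mediation.

Four analyses, mirroring how trial-level within-subject choice data are
conventionally analyzed:

* ``fit_choice_model`` -- mixed-effect logistic regression of EV-consistent
  choice on task (ALT = 1, DIM = 0) with crossed random intercepts for
  participant and item.  Estimated by Laplace-approximate (MAP) posterior
  mode/SD; if that fails, a flagged plain-logistic fallback with
  participant-clustered robust errors keeps the pipeline total.
* ``fit_rt_model`` -- linear mixed model of log decision time on task,
  |EV difference| and |outcome difference|, same crossed intercepts
  (REML); flagged cluster-robust OLS fallback.
* ``compare_classification_proportions`` -- pooled two-proportion z test,
  one-tailed, for strategy-label distributions across tasks.
* ``mediation_analysis`` -- linear-probability path models of
  task -> SM -> EV-consistent choice.  Paths are OLS on the pooled trials,
  so the decomposition c = c' + a*b holds exactly; uncertainty comes from a
  participant-level (cluster) percentile bootstrap, which is what carries
  the within-subject dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import (
    DegenerateDataError,
    InsufficientClustersError,
    SeparationError,
)

__all__ = [
    "RegressionResult",
    "MediationResult",
    "fit_choice_model",
    "fit_rt_model",
    "compare_classification_proportions",
    "mediation_analysis",
    "add_ev_consistent",
]

_Z95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass(frozen=True)
class RegressionResult:
    """One model term: estimate, 95% CI, test statistic, p value."""

    term: str
    b: float
    ci95: tuple[float, float]
    statistic: float
    p_value: float
    model_label: str
    odds_ratio: float | None = None
    degraded: bool = False

    def as_dict(self) -> dict:
        d = {
            "term": self.term,
            "estimate": self.b,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "statistic": self.statistic,
            "p": self.p_value,
            "model": self.model_label,
            "degraded": self.degraded,
        }
        if self.odds_ratio is not None:
            d["odds_ratio"] = self.odds_ratio
        return d


@dataclass(frozen=True)
class MediationResult:
    """Path estimates of the task -> SM -> choice mediation model.

    ``a`` is the task effect on the mediator, ``b_path`` the mediator effect
    on the outcome holding task, ``c_total`` / ``c_prime`` the total and
    direct task effects, and ``ab = a * b_path`` the indirect effect; all on
    the probability-difference scale.  ``ci95_ab`` is the participant-level
    percentile bootstrap interval (None when ``n_boot == 0``).
    """

    a: float
    b_path: float
    c_total: float
    c_prime: float
    ab: float
    ci95_ab: tuple[float, float] | None
    n_boot: int
    z_ab: float | None = None
    n_participants: int = 0
    n_trials: int = 0

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b_path,
            "c_total": self.c_total,
            "c_prime": self.c_prime,
            "ab": self.ab,
            "ci95_ab": list(self.ci95_ab) if self.ci95_ab is not None else None,
            "z_ab": self.z_ab,
            "n_boot": self.n_boot,
            "n_participants": self.n_participants,
            "n_trials": self.n_trials,
        }


# ---------------------------------------------------------------------------
# helpers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"{what} missing columns: {missing}")


def _task01(df: pd.DataFrame) -> np.ndarray:
    bad = set(df["task"]) - {"ALT", "DIM"}
    if bad:
        raise ValueError(f"unknown task codes: {sorted(bad)}")
    if df["task"].nunique() < 2:
        raise DegenerateDataError("both tasks must be present")
    return (df["task"] == "ALT").to_numpy(dtype=float)


def add_ev_consistent(trials: pd.DataFrame, pairs) -> pd.DataFrame:
    """Return a copy of the trial table with a 0/1 ``ev_consistent`` column."""
    from .strategy import ev_consistent

    by_id = {p.pair_id: p for p in pairs}
    out = trials.copy()
    out["ev_consistent"] = [
        int(ev_consistent(by_id[r.pair_id], r.choice)) for r in trials.itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# mixed-effect logistic regression (choice model)


def fit_choice_model(trials: pd.DataFrame) -> RegressionResult:
    """Task effect on EV-consistent choice, with participant and item intercepts.

    Expects columns ``participant_id``, ``pair_id``, ``task``,
    ``ev_consistent``.  Returns the task term (ALT = 1): log-odds ``b``,
    ``odds_ratio = exp(b)``, 95% CI, z and two-sided p.
    """
    _require_columns(trials, ["participant_id", "pair_id", "task", "ev_consistent"], "trial table")
    if trials["participant_id"].nunique() < 2 or trials["pair_id"].nunique() < 2:
        raise DegenerateDataError("need >= 2 participants and >= 2 items")
    y = trials["ev_consistent"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("ev_consistent is constant; logistic model is separated")
    df = trials.copy()
    df["task01"] = _task01(df)

    b = sd = None
    degraded = False
    try:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        # statsmodels draws its variance-parameter starting values from the
        # global RandomState; pin it locally so fits are reproducible.
        state = np.random.get_state()
        try:
            np.random.seed(0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM.from_formula(
                    "ev_consistent ~ task01",
                    {"participant": "0 + C(participant_id)", "item": "0 + C(pair_id)"},
                    df,
                )
                fit = model.fit_map()
        finally:
            np.random.set_state(state)
        i = fit.model.exog_names.index("task01")
        b, sd = float(fit.fe_mean[i]), float(fit.fe_sd[i])
        if not (np.isfinite(b) and np.isfinite(sd) and sd > 0):
            raise RuntimeError("non-finite MAP estimate")
        label = "mixed_logistic_map"
    except Exception:
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(df)), df["task01"].to_numpy()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(
                disp=0, cov_type="cluster", cov_kwds={"groups": df["participant_id"]}
            )
        b, sd = float(fit.params[1]), float(fit.bse[1])
        degraded = True
        label = "logistic_cluster_robust_fallback"

    z = b / sd
    return RegressionResult(
        term="task",
        b=b,
        ci95=(b - _Z95 * sd, b + _Z95 * sd),
        statistic=z,
        p_value=float(2.0 * norm.sf(abs(z))),
        model_label=label,
        odds_ratio=float(np.exp(b)),
        degraded=degraded,
    )


# ---------------------------------------------------------------------------
# linear mixed model (decision time)


def fit_rt_model(trials: pd.DataFrame, pairs) -> dict[str, RegressionResult]:
    """Log decision time on task, |dEV| and |d outcome|, crossed intercepts.

    Returns a mapping term -> :class:`RegressionResult` for ``task``,
    ``ev_diff`` and ``outcome_diff``.
    """
    from .gambles import ev_value

    _require_columns(trials, ["participant_id", "pair_id", "task", "rt_s"], "trial table")
    rt = trials["rt_s"].to_numpy(dtype=float)
    if np.any(~(rt > 0)):
        raise DegenerateDataError("all response times must be strictly positive")
    by_id = {p.pair_id: p for p in pairs}
    df = trials.copy()
    df["task01"] = _task01(df)
    df["ln_rt"] = np.log(rt)
    df["ev_diff"] = [abs(ev_value(by_id[i].option_a) - ev_value(by_id[i].option_b)) for i in df["pair_id"]]
    df["outcome_diff"] = [
        abs(by_id[i].option_a.outcome - by_id[i].option_b.outcome) for i in df["pair_id"]
    ]

    terms = {"task01": "task", "ev_diff": "ev_diff", "outcome_diff": "outcome_diff"}
    degraded = False
    try:
        import statsmodels.formula.api as smf

        df["_all"] = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "ln_rt ~ task01 + ev_diff + outcome_diff",
                df,
                groups="_all",
                vc_formula={
                    "participant": "0 + C(participant_id)",
                    "item": "0 + C(pair_id)",
                },
            )
            fit = model.fit(reml=True)
        params = {k: float(fit.params[k]) for k in terms}
        bses = {k: float(fit.bse[k]) for k in terms}
        if not all(np.isfinite(v) and v > 0 for v in bses.values()):
            raise RuntimeError("non-finite mixed-model standard errors")
        label = "linear_mixed_reml"
    except Exception:
        import statsmodels.api as sm

        X = np.column_stack(
            [np.ones(len(df))] + [df[k].to_numpy(dtype=float) for k in terms]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.OLS(df["ln_rt"].to_numpy(), X).fit(
                cov_type="cluster", cov_kwds={"groups": df["participant_id"]}
            )
        params = {k: float(fit.params[j + 1]) for j, k in enumerate(terms)}
        bses = {k: float(fit.bse[j + 1]) for j, k in enumerate(terms)}
        degraded = True
        label = "ols_cluster_robust_fallback"

    out: dict[str, RegressionResult] = {}
    for key, name in terms.items():
        b, sd = params[key], bses[key]
        t = b / sd
        out[name] = RegressionResult(
            term=name,
            b=b,
            ci95=(b - _Z95 * sd, b + _Z95 * sd),
            statistic=t,
            p_value=float(2.0 * norm.sf(abs(t))),
            model_label=label,
            degraded=degraded,
        )
    return out


# ---------------------------------------------------------------------------
# two-proportion z test


def compare_classification_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """Pooled two-proportion z statistic and one-tailed p = P(Z > z).

    Sample 1 is the condition expected to show the larger proportion (here
    the alternative-wise task), so a positive z supports the directional
    hypothesis.  Identical proportions give z = 0, p = 0.5.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = 0.0 if se == 0.0 else (p1 - p2) / se
    return float(z), float(norm.sf(z))


# ---------------------------------------------------------------------------
# mediation


def _ols_paths(task: np.ndarray, sm: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(a, b, c_total, c_prime) from the three least-squares path models."""
    one = np.ones_like(task)
    X2 = np.column_stack([one, task])
    X3 = np.column_stack([one, task, sm])
    coef_a = np.linalg.lstsq(X2, sm, rcond=None)[0]
    coef_c = np.linalg.lstsq(X2, y, rcond=None)[0]
    coef_bc = np.linalg.lstsq(X3, y, rcond=None)[0]
    return float(coef_a[1]), float(coef_bc[2]), float(coef_c[1]), float(coef_bc[1])


def mediation_analysis(
    data: pd.DataFrame,
    *,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Bootstrap mediation of task -> SM index -> EV-consistent choice.

    Expects columns ``participant_id``, ``task``, ``sm``, ``ev_consistent``
    (one row per trial; rows with missing SM are dropped).  Task is dummy
    coded ALT = 1.  Paths are linear-probability OLS fits, so
    ``c_total == c_prime + a * b`` exactly; the CI for the indirect effect
    resamples whole participants with replacement (percentile method,
    seeded).  With ``n_boot = 0`` only point estimates are returned.

    Raises
    ------
    InsufficientClustersError
        With fewer than 3 participants after dropping missing SM.
    """
    _require_columns(data, ["participant_id", "task", "sm", "ev_consistent"], "mediation table")
    df = data.dropna(subset=["sm"]).copy()
    if df.empty:
        raise DegenerateDataError("no rows with a defined SM index")
    participants = df["participant_id"].unique()
    if len(participants) < 3:
        raise InsufficientClustersError(
            f"mediation needs >= 3 participants, got {len(participants)}"
        )
    task = _task01(df)
    sm = df["sm"].to_numpy(dtype=float)
    y = df["ev_consistent"].to_numpy(dtype=float)

    a, b, c_total, c_prime = _ols_paths(task, sm, y)
    ab = a * b

    ci = None
    z_ab = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        codes = pd.factorize(df["participant_id"])[0]
        idx_by_p = [np.flatnonzero(codes == i) for i in range(len(participants))]
        boots = np.empty(n_boot)
        n_p = len(participants)
        for bi in range(n_boot):
            pick = rng.integers(0, n_p, size=n_p)
            rows = np.concatenate([idx_by_p[i] for i in pick])
            a_s, b_s, _, _ = _ols_paths(task[rows], sm[rows], y[rows])
            boots[bi] = a_s * b_s
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        ci = (float(lo), float(hi))
        sd = float(np.std(boots, ddof=1))
        z_ab = ab / sd if sd > 0 else None

    return MediationResult(
        a=a,
        b_path=b,
        c_total=c_total,
        c_prime=c_prime,
        ab=ab,
        ci95_ab=ci,
        n_boot=n_boot,
        z_ab=z_ab,
        n_participants=len(participants),
        n_trials=len(df),
    )
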