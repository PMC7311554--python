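"""Choice, attention and effort models, and simulation-based power analysis.

Three model families are fitted on the trial-metrics table produced by the
gaze pipeline or the cohort simulator:

* **choice** — repeated-measures logistic regression of the prosocial
  choice on SVO angle, group setting (0 = outgroup, 1 = ingroup) and their
  interaction, controlling for the percentage of monetary disadvantage of
  the prosocial option and the efficiency (joint-outcome) difference;
* **attention** — linear model of the percentage of payoff attention on
  own outcomes, on SVO angle x group setting plus a trial-order control;
* **effort** — linear models of log response time, log fixation count and
  the proportion of inspected information, same predictors.

All predictors are centered before fitting.  Participant-level dependence
is handled by a random intercept (variational-Bayes mixed logistic for the
binary outcome, REML linear mixed model otherwise); population-averaged
GEE and plain GLM/OLS backends are available where speed or a closed-form
check matters.

The power stage follows the Monte-Carlo recipe: draw a synthetic cohort of
``n`` participants from a generative sampling frame, refit the model,
record which effects reject at the nominal level, and repeat (500
replications by default) across at least two base seeds to gauge
stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "derive_regressors",
    "ModelSpec",
    "FitResult",
    "fit_models",
    "PowerFrame",
    "power_simulation",
]

_OUTCOMES = {
    # outcome key -> (source column, family, transform)
    "prosocial_choice": ("choice_prosocial", "binary", None),
    "attention_own": ("attention_own_pct", "linear", None),
    "log_rt": ("response_time_ms", "linear", "log"),
    "log_nfix": ("n_fixations", "linear", "log"),
    "prop_inspected": ("prop_inspected", "linear", None),
}


def derive_regressors(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the choice-model control variables to a trial table.

    ``percentage_disadvantage`` is the relative own-payoff cost of choosing
    prosocially, ``100 * (own_selfish - own_prosocial) / own_selfish``;
    ``efficiency`` is the joint-outcome difference
    ``(own_p + other_p) - (own_s + other_s)``.  Rows with a zero selfish
    own-payoff get a NaN disadvantage and are flagged.
    """
    df = trials.copy()
    own_s = df["own_selfish"].to_numpy(dtype=float)
    own_p = df["own_prosocial"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dis = np.where(own_s != 0, 100.0 * (own_s - own_p) / own_s, np.nan)
    df["percentage_disadvantage"] = dis
    df["disadvantage_undefined"] = own_s == 0
    df["efficiency"] = (df["own_prosocial"] + df["other_prosocial"]) - (
        df["own_selfish"] + df["other_selfish"]
    )
    return df


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one regression model.

    ``backend`` defaults to the family-appropriate mixed model
    ("bglmm" for binary outcomes, "mixedlm" for linear ones); "gee"
    requests population-averaged estimation with exchangeable clustering,
    and "glm"/"ols" fit without participant-level structure (useful for
    closed-form checks).
    """

    outcome: str = "prosocial_choice"
    controls: tuple[str, ...] = ()
    center: bool = True
    random_slope: bool = False
    backend: Optional[str] = None
    #: subset of {"svo", "group", "interaction"}; None = all three
    terms: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; choose from {sorted(_OUTCOMES)}")
        if self.terms is not None:
            bad = set(self.terms) - {"svo", "group", "interaction"}
            if bad:
                raise ValueError(f"unknown model terms: {sorted(bad)}")

    @classmethod
    def choice(cls, **kw) -> "ModelSpec":
        return cls(
            outcome="prosocial_choice",
            controls=("percentage_disadvantage", "efficiency"),
            **kw,
        )

    @classmethod
    def attention(cls, **kw) -> "ModelSpec":
        return cls(outcome="attention_own", controls=("trial_index",), **kw)

    @classmethod
    def effort(cls, outcome: str = "log_rt", **kw) -> "ModelSpec":
        return cls(outcome=outcome, controls=("trial_index",), **kw)


@dataclass
class FitResult:
    """Coefficient estimates with uncertainties for one fitted model."""

    outcome: str
    backend: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    n_obs: int
    n_participants: int
    converged: bool
    odds_ratios: Optional[pd.Series] = None

    def summary(self) -> pd.DataFrame:
        """Tabular summary; odds-ratio column for logistic models."""
        out = pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )
        if self.odds_ratios is not None:
            out.insert(0, "OR", self.odds_ratios)
        out.attrs["outcome"] = self.outcome
        out.attrs["n_obs"] = self.n_obs
        return out

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "backend": self.backend,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "converged": self.converged,
            "estimates": self.params.to_dict(),
            "z": self.zvalues.to_dict(),
            "p": self.pvalues.to_dict(),
        }
        if self.odds_ratios is not None:
            d["odds_ratios"] = self.odds_ratios.to_dict()
        return d


def _prepare(metrics: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str, str]:
    col, family, transform = _OUTCOMES[spec.outcome]
    df = metrics.copy()
    if col not in df.columns:
        raise ValueError(f"metrics table lacks column {col!r} for outcome {spec.outcome!r}")
    y = df[col].astype(float)
    if transform == "log":
        if (y <= 0).any():
            raise ValueError(f"cannot log-transform non-positive values of {col!r}")
        y = np.log(y)
    df["_y"] = y
    wanted = spec.terms if spec.terms is not None else ("svo", "group", "interaction")
    predictors, terms = [], []
    if "svo" in wanted or "interaction" in wanted:
        df["_svo"] = df["svo_angle"].astype(float)
        predictors.append("_svo")
    if "group" in wanted or "interaction" in wanted:
        df["_group"] = (df["context"] == "ingroup").astype(float)
        predictors.append("_group")
    if "svo" in wanted:
        terms.append("_svo")
    if "group" in wanted:
        terms.append("_group")
    if "interaction" in wanted:
        terms.append("_svo:_group")
    for c in spec.controls:
        if c not in df.columns:
            raise ValueError(f"control column {c!r} missing from metrics table")
        df[f"_c_{c}"] = df[c].astype(float)
        predictors.append(f"_c_{c}")
        terms.append(f"_c_{c}")
    df = df.dropna(subset=["_y"] + predictors).reset_index(drop=True)
    if spec.center:
        for c in predictors:
            df[c] = df[c] - df[c].mean()
    formula = "_y ~ " + " + ".join(terms)
    return df, formula, family


_PRETTY = {
    "Intercept": "intercept",
    "_svo": "svo_angle",
    "_group": "group",
    "_svo:_group": "svo_angle:group",
}


def _rename(s: pd.Series) -> pd.Series:
    return s.rename(index=lambda k: _PRETTY.get(k, k.replace("_c_", "")))


def fit_models(metrics: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one model spec on a (filtered) trial-metrics table.

    Non-convergence is reported through the ``converged`` flag rather than
    raised, so batch refits (power, recovery) can keep going.
    """
    df, formula, family = _prepare(metrics, spec)
    backend = spec.backend or ("bglmm" if family == "binary" else "mixedlm")
    n_part = df["participant"].nunique() if "participant" in df.columns else 0
    converged = True

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if backend == "bglmm":
            model = BinomialBayesMixedGLM.from_formula(
                formula, {"participant": "0 + C(participant)"}, df
            )
            res = model.fit_vb()
            k = len(res.fe_mean)
            names = model.exog_names
            params = pd.Series(res.fe_mean, index=names)
            bse = pd.Series(res.fe_sd, index=names)
        elif backend == "gee":
            fam = sm.families.Binomial() if family == "binary" else sm.families.Gaussian()
            model = smf.gee(
                formula,
                groups="participant",
                data=df,
                family=fam,
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            res = model.fit(cov_type="bias_reduced")
            params, bse = res.params, res.bse
        elif backend == "mixedlm":
            if family != "linear":
                raise ValueError("mixedlm backend requires a linear outcome")
            re_formula = "~_group" if spec.random_slope else "~1"
            model = smf.mixedlm(formula, df, groups=df["participant"], re_formula=re_formula)
            res = model.fit(reml=True)
            converged = bool(res.converged)
            params = res.fe_params
            bse = res.bse.loc[params.index]
        elif backend in ("glm", "ols"):
            fam = sm.families.Binomial() if family == "binary" else sm.families.Gaussian()
            res = smf.glm(formula, df, family=fam).fit()
            params, bse = res.params, res.bse
        else:
            raise ValueError(f"unknown backend {backend!r}")

    z = params / bse
    if backend == "gee":
        # small-sample correction: t reference with cluster-based df
        dof = max(n_part - len(params), 1)
        pvals = 2.0 * sps.t.sf(np.abs(z), dof)
    else:
        pvals = 2.0 * sps.norm.sf(np.abs(z))
    pvalues = pd.Series(pvals, index=params.index)
    return FitResult(
        outcome=spec.outcome,
        backend=backend,
        params=_rename(params),
        bse=_rename(bse),
        zvalues=_rename(z),
        pvalues=_rename(pvalues),
        n_obs=int(len(df)),
        n_participants=int(n_part),
        converged=converged,
        odds_ratios=_rename(np.exp(params)) if family == "binary" else None,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo power


@dataclass(frozen=True)
class PowerFrame:
    """Generative sampling frame for the power simulation.

    A random-intercept model on the linear-predictor scale:
    ``eta = b0 + b_group*group + b_svo*svo_c + b_interaction*svo_c*group + u_i``
    with ``u_i ~ N(0, sd_intercept)`` and centered SVO angles drawn from
    ``N(0, svo_sd)``.  ``kind`` selects a Bernoulli(logit) or Gaussian
    outcome; each participant contributes ``trials_per_context`` trials in
    each group context.
    """

    kind: str = "binary"
    b0: float = 0.0
    b_group: float = 0.0
    b_svo: float = 0.0
    b_interaction: float = 0.0
    sd_intercept: float = 0.5
    sd_resid: float = 1.0
    svo_sd: float = 14.0
    trials_per_context: int = 28

    def simulate(self, n_participants: int, rng: np.random.Generator) -> pd.DataFrame:
        m = self.trials_per_context
        pid = np.repeat(np.arange(n_participants), 2 * m)
        svo = np.repeat(rng.normal(0.0, self.svo_sd, size=n_participants), 2 * m)
        u = np.repeat(rng.normal(0.0, self.sd_intercept, size=n_participants), 2 * m)
        group = np.tile(np.r_[np.ones(m), np.zeros(m)], n_participants)
        eta = self.b0 + self.b_group * group + self.b_svo * svo + self.b_interaction * svo * group + u
        if self.kind == "binary":
            y = rng.random(eta.size) < 1.0 / (1.0 + np.exp(-eta))
            y = y.astype(float)
        elif self.kind == "linear":
            y = eta + rng.normal(0.0, self.sd_resid, size=eta.size)
        else:
            raise ValueError(f"unknown frame kind {self.kind!r}")
        return pd.DataFrame(
            {"participant": pid, "svo": svo, "group": group, "y": y}
        )


_EFFECTS = ("group", "svo", "interaction")
_TERM_OF = {"group": "group_c", "svo": "svo_c", "interaction": "svo_c:group_c"}


def _fit_frame_pvalues(df: pd.DataFrame, kind: str) -> dict:
    """Cluster-aware p-values for the three effects on one simulated cohort.

    Uses exchangeable GEE with the bias-reduced (Mancl-DeRouen) sandwich
    covariance and a t reference on cluster-count degrees of freedom —
    fast enough for hundreds of refits and near nominal level at the
    cohort sizes used here.
    """
    df = df.copy()
    df["svo_c"] = df["svo"] - df["svo"].mean()
    df["group_c"] = df["group"] - df["group"].mean()
    fam = sm.families.Binomial() if kind == "binary" else sm.families.Gaussian()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.gee(
            "y ~ svo_c*group_c",
            groups="participant",
            data=df,
            family=fam,
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit(cov_type="bias_reduced")
    ncl = df["participant"].nunique()
    dof = max(ncl - len(res.params), 1)
    z = res.params / res.bse
    p = 2.0 * sps.t.sf(np.abs(z), dof)
    p = pd.Series(p, index=res.params.index)
    return {e: float(p[_TERM_OF[e]]) for e in _EFFECTS}


def power_simulation(
    frame: PowerFrame,
    n_grid: Sequence[int],
    n_reps: int = 500,
    alpha: float = 0.05,
    seeds: Sequence[int] = (0, 1),
    progress: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo power per effect per sample size.

    For each base seed and each ``n`` in ``n_grid``, simulates ``n_reps``
    cohorts from ``frame``, refits the model and records the rejection
    rate at level ``alpha`` for the group main effect, the SVO main effect
    and their interaction.  Returns a tidy frame with columns
    ``seed, n, effect, power, n_reps``; the spread across seeds indicates
    Monte-Carlo stability.
    """
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        for n in n_grid:
            rej = {e: 0 for e in _EFFECTS}
            for _ in range(n_reps):
                df = frame.simulate(n, rng)
                pv = _fit_frame_pvalues(df, frame.kind)
                for e in _EFFECTS:
                    rej[e] += pv[e] < alpha
            for e in _EFFECTS:
                rows.append(
                    {
                        "seed": seed,
                        "n": int(n),
                        "effect": e,
                        "power": rej[e] / n_reps,
                        "n_reps": n_reps,
                    }
                )
    return pd.DataFrame(rows)
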