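"""Gaze-contingent drift-diffusion simulation of allocation choices.

Evidence for one option over the other (the relative decision value, RDV)
accumulates from zero until it crosses one of two boundaries at ``+a``
(choose A) or ``-a`` (choose B).  While option A is fixated the drift is
``d * (U_A - theta * U_B)``; while B is fixated it is
``-d * (U_B - theta * U_A)``.  With ``theta = 1`` the drift reduces to the
gaze-independent ``d * (U_A - U_B)`` of a plain drift-diffusion model, for
which the first-passage choice probability has the closed form
``P(A) = 1 / (1 + exp(-2 a d (U_A - U_B) / sigma^2))``.

Utilities come from :mod:`intergaze.social_utility`; larger absolute utility
differences yield steeper drift, hence faster and less effortful decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .social_utility import (
    AllocationOption,
    GroupContext,
    SocialPreference,
    utility,
)
from .svo_slider import angle_to_weights

__all__ = [
    "ADDMParams",
    "TrialSim",
    "simulate_trial",
    "simulate_trials",
    "ddm_choice_probability",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ADDMParams:
    """Simulator configuration.

    Attributes
    ----------
    drift_scale : float
        Evidence gained per ms per unit of utility difference (``d``).
    noise : float
        Diffusion coefficient ``sigma`` (evidence per sqrt-ms).
    theta : float
        Attentional discount on the unattended option's utility, in [0, 1].
        ``theta = 1`` disables gaze contingency (plain DDM), which is the
        default regime; set ``theta < 1`` for gaze-weighted accumulation.
    boundary : float
        Absorbing boundaries at ``+/- boundary``.
    non_decision_ms : float
        Constant non-decision component added to the response time.
    fix_meanlog, fix_sdlog : float
        Log-normal parameters of the option-fixation duration distribution
        (ms); defaults give a median fixation of ~350 ms.
    dt_ms : float
        Euler time step.
    max_time_ms : float
        Accumulation horizon; trials not absorbed by then are censored.
    """

    drift_scale: float = 0.002
    noise: float = 0.018
    theta: float = 1.0
    boundary: float = 1.0
    non_decision_ms: float = 300.0
    fix_meanlog: float = math.log(350.0)
    fix_sdlog: float = 0.4
    dt_ms: float = 1.0
    max_time_ms: float = 20_000.0

    def __post_init__(self) -> None:
        if self.drift_scale <= 0 or self.noise <= 0 or self.boundary <= 0:
            raise ValueError("drift_scale, noise and boundary must be positive")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1], got {self.theta!r}")
        if self.dt_ms <= 0 or self.max_time_ms <= 0 or self.non_decision_ms < 0:
            raise ValueError("invalid time parameters")


@dataclass
class TrialSim:
    """Result of one simulated trial."""

    choice: str  # "A" or "B"
    rt_ms: float
    fixations: list = field(default_factory=list)  # (side, duration_ms)
    censored: bool = False


def ddm_choice_probability(delta_u: float, params: ADDMParams) -> float:
    """Closed-form P(choose A) of the gaze-independent DDM (theta = 1)."""
    z = 2.0 * params.boundary * params.drift_scale * delta_u / params.noise**2
    return 1.0 / (1.0 + math.exp(-z))


def simulate_trial(
    opt_a: AllocationOption,
    opt_b: AllocationOption,
    pref: SocialPreference,
    ctx: GroupContext,
    params: ADDMParams,
    rng: np.random.Generator,
    single_fixation: bool = False,
    first_side: Optional[str] = None,
) -> TrialSim:
    """Simulate one trial, returning choice, RT and the fixation sequence.

    Fixation targets alternate between the options; the first fixated side
    is drawn uniformly unless ``first_side`` is given.  With
    ``single_fixation=True`` the first fixation never ends (useful for the
    plain-DDM limit).
    """
    ua = utility(opt_a, pref, ctx)
    ub = utility(opt_b, pref, ctx)
    out = simulate_trials(
        np.array([ua]), np.array([ub]), params, rng,
        single_fixation=single_fixation,
        first_side=None if first_side is None else np.array([0 if first_side == "A" else 1]),
        track_sequences=True,
    )
    return TrialSim(
        choice="A" if out["choice_a"][0] else "B",
        rt_ms=float(out["rt_ms"][0]),
        fixations=out["sequences"][0],
        censored=bool(out["censored"][0]),
    )


def simulate_trials(
    ua: np.ndarray,
    ub: np.ndarray,
    params: ADDMParams,
    rng: np.random.Generator,
    single_fixation: bool = False,
    first_side: Optional[np.ndarray] = None,
    track_sequences: bool = False,
) -> dict:
    """Vectorised first-passage simulation over many trials.

    Parameters
    ----------
    ua, ub : arrays
        Utilities of options A and B per trial.
    first_side : array of {0, 1}, optional
        Initially attended option per trial (0 = A); uniform when omitted.
    track_sequences : bool
        Also return the full (side, duration) fixation sequence per trial;
        intended for small batches.

    Returns a dict of per-trial arrays: ``choice_a`` (bool), ``rt_ms``
    (includes the non-decision time), ``censored``, ``n_fix_a``,
    ``n_fix_b``, ``dwell_a_ms``, ``dwell_b_ms`` and, when requested,
    ``sequences``.
    """
    ua = np.asarray(ua, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = ua.size
    d, sig, th = params.drift_scale, params.noise, params.theta
    dt = params.dt_ms
    sq = sig * math.sqrt(dt)
    drift_att_a = d * (ua - th * ub) * dt
    drift_att_b = -d * (ub - th * ua) * dt

    # continuity correction for discrete barrier monitoring: a path can cross
    # and return between Euler steps, so the discrete threshold is lowered by
    # 0.5826 * sigma * sqrt(dt) to match continuous first-passage behaviour
    thresh = max(params.boundary - 0.5826 * sig * math.sqrt(dt), 0.5 * params.boundary)

    side = (
        rng.integers(0, 2, size=n) if first_side is None else np.asarray(first_side, dtype=int)
    ).copy()
    rdv = np.zeros(n)
    rt = np.full(n, np.nan)
    choice_a = np.zeros(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)
    n_fix = np.zeros((n, 2), dtype=int)
    n_fix[np.arange(n), side] = 1
    dwell = np.zeros((n, 2))
    next_switch = (
        np.full(n, np.inf)
        if single_fixation
        else rng.lognormal(params.fix_meanlog, params.fix_sdlog, size=n)
    )
    sequences: list[list] = [[] for _ in range(n)] if track_sequences else []
    fix_start = np.zeros(n)

    active = np.arange(n)
    t = 0.0
    nsteps = int(round(params.max_time_ms / dt))
    for _ in range(nsteps):
        if active.size == 0:
            break
        s = side[active]
        step = np.where(s == 0, drift_att_a[active], drift_att_b[active])
        rdv[active] += step + sq * rng.standard_normal(active.size)
        dwell[active, s] += dt
        t += dt

        absorbed = np.abs(rdv[active]) >= thresh
        if absorbed.any():
            idx = active[absorbed]
            rt[idx] = t + params.non_decision_ms
            choice_a[idx] = rdv[idx] >= thresh
            if track_sequences:
                for i in idx:
                    sequences[i].append(("A" if side[i] == 0 else "B", t - fix_start[i]))
            active = active[~absorbed]

        if not single_fixation and active.size:
            switching = t >= next_switch[active]
            if switching.any():
                idx = active[switching]
                if track_sequences:
                    for i in idx:
                        sequences[i].append(("A" if side[i] == 0 else "B", t - fix_start[i]))
                        fix_start[i] = t
                side[idx] = 1 - side[idx]
                n_fix[idx, side[idx]] += 1
                next_switch[idx] = t + rng.lognormal(
                    params.fix_meanlog, params.fix_sdlog, size=idx.size
                )

    if active.size:
        censored[active] = True
        rt[active] = params.max_time_ms + params.non_decision_ms
        choice_a[active] = rdv[active] >= 0
        if track_sequences:
            for i in active:
                sequences[i].append(("A" if side[i] == 0 else "B", t - fix_start[i]))

    return {
        "choice_a": choice_a,
        "rt_ms": rt,
        "censored": censored,
        "n_fix_a": n_fix[:, 0],
        "n_fix_b": n_fix[:, 1],
        "dwell_a_ms": dwell[:, 0],
        "dwell_b_ms": dwell[:, 1],
        "sequences": sequences,
    }


# ---------------------------------------------------------------------------
# cohort simulation


def _category_probs(pref: SocialPreference, beta: float) -> np.ndarray:
    """Within-option attention bias over (own, other, difference, sum) cells.

    Attention is assumed to follow decision weights: the own-payoff cell
    draws fixations in proportion to ``w_own`` and the partner cell in
    proportion to the discounted ``beta * w_other``; the derived difference
    and sum cells receive a small constant share.
    """
    p = np.array([pref.w_own, max(beta * pref.w_other, 0.02), 0.15, 0.15])
    return p / p.sum()


def simulate_cohort(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    params: ADDMParams,
    rng: np.random.Generator,
    beta_out: float = 0.5,
    identity_bias: Sequence[float] = (3.0, 1.0, 1.0),
    identity_fix_mean_ms: float = 250.0,
    p_skip_identity: float = 0.02,
) -> pd.DataFrame:
    """Simulate choices, RTs and attention metrics for a whole cohort.

    Parameters
    ----------
    trials : DataFrame
        One row per trial with columns ``participant``, ``trial``,
        ``trial_index``, ``context`` ("ingroup"/"outgroup"), ``is_filler``,
        ``own_selfish``, ``other_selfish``, ``own_prosocial``,
        ``other_prosocial`` (and any extra columns, carried through).
    participants : DataFrame
        Columns ``participant`` and ``svo_angle``; utility weights are
        derived via the cos/sin mapping.
    beta_out : float
        Outgroup discount applied to the partner-payoff weight.
    identity_bias : sequence of 3 floats
        Relative dwell bias over the identity boxes (group, coin, code).
    p_skip_identity : float
        Probability that a trial receives no identity-box gaze at all
        (those trials are flagged as group-unattended).

    The output schema matches :func:`intergaze.gaze_pipeline.preprocess_gaze`
    so downstream analysis is agnostic to whether metrics came from raw
    gaze or from simulation.
    """
    from .gaze_pipeline import TOTAL_AOIS

    angles = dict(zip(participants["participant"], participants["svo_angle"]))
    prefs = {p: angle_to_weights(a) for p, a in angles.items()}

    beta = np.where(trials["context"].to_numpy() == "ingroup", 1.0, beta_out)
    w_own = np.array([prefs[p].w_own for p in trials["participant"]])
    w_other = np.array([prefs[p].w_other for p in trials["participant"]])
    u_pro = w_own * trials["own_prosocial"].to_numpy() + beta * w_other * trials[
        "other_prosocial"
    ].to_numpy()
    u_self = w_own * trials["own_selfish"].to_numpy() + beta * w_other * trials[
        "other_selfish"
    ].to_numpy()

    # option A = prosocial, option B = selfish
    sim = simulate_trials(u_pro, u_self, params, rng)

    id_bias = np.asarray(identity_bias, dtype=float)
    id_bias = id_bias / id_bias.sum()

    rows = []
    for k, tr in enumerate(trials.itertuples(index=False)):
        pref = prefs[tr.participant]
        b = beta[k]
        n_a, n_b = int(sim["n_fix_a"][k]), int(sim["n_fix_b"][k])
        dwell_a, dwell_b = float(sim["dwell_a_ms"][k]), float(sim["dwell_b_ms"][k])
        pcat = _category_probs(pref, b)

        dwell_cat = np.zeros(4)  # own, other, difference, sum
        inspected = 0
        for n_side, dwell_side in ((n_a, dwell_a), (n_b, dwell_b)):
            if n_side == 0:
                continue
            counts = rng.multinomial(n_side, pcat)
            dwell_cat += dwell_side * counts / n_side
            inspected += int((counts > 0).sum())

        # identity-box gaze precedes the payoff comparison
        if rng.random() < p_skip_identity:
            id_counts = np.zeros(3, dtype=int)
            id_durs = np.zeros(0)
        else:
            k_id = int(rng.integers(3, 6))
            id_counts = rng.multinomial(k_id, id_bias)
            id_durs = rng.lognormal(math.log(identity_fix_mean_ms), 0.3, size=k_id)
        id_dwell = np.zeros(3)
        pos = np.repeat(np.arange(3), id_counts)
        for j, dur in zip(pos, id_durs):
            id_dwell[j] += dur
        id_total = float(id_dwell.sum())
        inspected += int((id_counts > 0).sum())

        n_label = int(rng.binomial(2, 0.3))
        label_dwell = float(rng.lognormal(math.log(180.0), 0.3, size=n_label).sum())
        inspected += n_label  # distinct row labels (at most 2 sampled)
        n_off = int(rng.binomial(2, 0.1))

        n_fix_total = n_a + n_b + int(id_counts.sum()) + n_label + n_off
        on_info = (n_a + n_b + int(id_counts.sum())) / n_fix_total if n_fix_total else 0.0
        own_d, other_d = dwell_cat[0], dwell_cat[1]
        att_own = 100.0 * own_d / (own_d + other_d) if own_d + other_d > 0 else np.nan
        rt = float(sim["rt_ms"][k]) + id_total + label_dwell

        rows.append(
            {
                **tr._asdict(),
                "svo_angle": angles[tr.participant],
                "beta": float(b),
                "choice_prosocial": bool(sim["choice_a"][k]),
                "censored": bool(sim["censored"][k]),
                "response_time_ms": rt,
                "n_fixations": n_fix_total,
                "n_inspected": min(inspected, TOTAL_AOIS),
                "prop_inspected": min(inspected, TOTAL_AOIS) / TOTAL_AOIS,
                "attention_own_pct": att_own,
                "dwell_payoff_own_ms": own_d,
                "dwell_payoff_other_ms": other_d,
                "dwell_identity_ms": id_total,
                "share_group_id": id_dwell[0] / id_total if id_total > 0 else np.nan,
                "share_coin": id_dwell[1] / id_total if id_total > 0 else np.nan,
                "share_code": id_dwell[2] / id_total if id_total > 0 else np.nan,
                "on_info_fixation_share": on_info,
                "group_info_attended": bool(id_counts[0] > 0),
            }
        )
    return pd.DataFrame(rows)


def single_fixation_params(params: ADDMParams) -> ADDMParams:
    """Convenience: parameters for the single-fixation (plain DDM) limit."""
    return replace(params, theta=1.0)
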