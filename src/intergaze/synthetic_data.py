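"""Synthetic experiments with known ground truth.

Generates every layer of the emulated experimental design so the full pipeline can be
exercised without any external data: participants with sampled social
preferences, trial tables (two within-subject group contexts x 40 trials,
28 target + 12 filler each), counterbalanced AOI screen layouts on a
1280x1024 display, and raw 120 Hz gaze streams produced as the inverse of
the preprocessing stage (samples jittered around planted fixation
centroids with short saccadic transitions between them).

Payoff law
----------
Target-trial payoffs are drawn from truncated normal laws on the design
ranges (own 2.40-10 EUR, partner 0.10-7.80 EUR).  Per trial, two own draws
are sorted (larger -> selfish option) and two partner draws are
anti-sorted (larger -> prosocial option) so that each trial is a genuine
trade-off; pairs violating dictator dominance (own > partner in both
options) are redrawn.  The underlying location/scale parameters are
calibrated so the *emitted* marginals match the design means (own 7.18,
partner 3.03).  The emitted SDs (about 1.85 and 1.89) are the closest a
range-respecting truncated normal can get to the design dispersion; a
wider spread is unattainable inside these ranges at those means.  Filler
trials use the same law and are flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_pipeline import AOI, SCREEN_SIZE, validate_layout

__all__ = [
    "ExperimentSpec",
    "COUNTERBALANCE_CELLS",
    "generate_participants",
    "generate_trials",
    "generate_layout",
    "generate_gaze",
    "generate_experiment",
]

# underlying truncated-normal location/scale, calibrated so emitted
# target-trial payoffs have means 7.18 (own) and 3.03 (partner)
_OWN_LOC, _OWN_SCALE = 8.90, 8.0
_OTHER_LOC, _OTHER_SCALE = 2.19, 8.0

#: Counterbalancing cells: (payoff_block_position, identity_block_position).
COUNTERBALANCE_CELLS: tuple[tuple[str, str], ...] = tuple(
    (p, i) for p, i in itertools.permutations(("top", "middle", "bottom"), 2)
)

_PAYOFF_BAND_Y = {"top": 40.0, "middle": 300.0, "bottom": 554.0}
_IDENTITY_BAND_Y = {"top": 40.0, "middle": 462.0, "bottom": 884.0}
_ROW_ORDER = ("own", "other", "difference", "sum")
_ROW_CATEGORY = {
    "own": "payoff_own",
    "other": "payoff_other",
    "difference": "difference",
    "sum": "sum",
}
_FRAME_MS = 1000.0 / 120.0


@dataclass(frozen=True)
class ExperimentSpec:
    """Design parameters of a synthetic experiment.

    Defaults emulate the experimental design: 80 participants, two group
    contexts with 28 target and 12 filler trials each, an outgroup
    discount of 0.5, a prosocial/individualist mixture of social value
    orientations, and 120 Hz gaze sampling on a 1280x1024 screen.
    """

    n_participants: int = 80
    n_target: int = 28
    n_filler: int = 12
    beta_out: float = 0.5
    #: SVO mixture components: (weight, mean angle deg, sd deg)
    svo_mixture: tuple[tuple[float, float, float], ...] = (
        (0.65, 32.0, 8.0),
        (0.35, 8.0, 8.0),
    )
    own_range: tuple[float, float] = (2.40, 10.0)
    other_range: tuple[float, float] = (0.10, 7.80)
    sampling_hz: float = 120.0
    gaze_sigma_px: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_target <= 0 or self.n_filler < 0:
            raise ValueError("counts must be positive")
        if not (0.0 < self.beta_out < 1.0):
            raise ValueError("beta_out must lie in (0, 1)")
        w = sum(m[0] for m in self.svo_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("svo_mixture weights must sum to 1")


def generate_participants(spec: ExperimentSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample participants with SVO angles from the mixture spec.

    Angles are clipped to the measurable range of the slider-based angle
    (just inside (-90, 90)).  Manipulation-check flags are all False; tests
    flip them explicitly when exercising the exclusion rules.
    """
    weights = np.array([m[0] for m in spec.svo_mixture])
    comp = rng.choice(len(weights), size=spec.n_participants, p=weights)
    means = np.array([m[1] for m in spec.svo_mixture])[comp]
    sds = np.array([m[2] for m in spec.svo_mixture])[comp]
    angles = np.clip(rng.normal(means, sds), -89.0, 89.0)
    return pd.DataFrame(
        {
            "participant": [f"P{i:03d}" for i in range(spec.n_participants)],
            "svo_angle": angles,
            "wrong_outgroup": False,
            "outgroup_preferred": False,
            "demand_check_failed": False,
            "cell": [
                "+".join(COUNTERBALANCE_CELLS[i % len(COUNTERBALANCE_CELLS)])
                for i in range(spec.n_participants)
            ],
        }
    )


def _sample_option_pairs(spec: ExperimentSpec, n: int, rng: np.random.Generator):
    """Draw n trade-off trials satisfying the design constraints."""
    lo_o, hi_o = spec.own_range
    lo_t, hi_t = spec.other_range
    a_o, b_o = (lo_o - _OWN_LOC) / _OWN_SCALE, (hi_o - _OWN_LOC) / _OWN_SCALE
    a_t, b_t = (lo_t - _OTHER_LOC) / _OTHER_SCALE, (hi_t - _OTHER_LOC) / _OTHER_SCALE
    out = np.empty((0, 4))
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]) + 16, 64)
        own = stats.truncnorm.rvs(a_o, b_o, loc=_OWN_LOC, scale=_OWN_SCALE, size=(m, 2), random_state=rng)
        oth = stats.truncnorm.rvs(a_t, b_t, loc=_OTHER_LOC, scale=_OTHER_SCALE, size=(m, 2), random_state=rng)
        own.sort(axis=1)
        oth.sort(axis=1)
        own_s, own_p = own[:, 1], own[:, 0]  # selfish option pays self more
        oth_s, oth_p = oth[:, 0], oth[:, 1]  # prosocial option pays partner more
        ok = (
            (own_p > oth_p)  # dictator dominance in the prosocial option too
            & (own_s > own_p)
            & (oth_p > oth_s)
            & (own_s + oth_s != own_p + oth_p)  # sums must differ
        )
        out = np.vstack([out, np.column_stack([own_s, oth_s, own_p, oth_p])[ok]])
    return out[:n]


def generate_trials(
    spec: ExperimentSpec, rng: np.random.Generator, participants: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-participant trial tables: 40 ingroup + 40 outgroup allocations.

    Each context block holds ``n_target`` target and ``n_filler`` filler
    trials; the 80 trials are presented in randomised order and the
    prosocial option's screen side is drawn per trial.
    """
    if participants is None:
        participants = generate_participants(spec, rng)
    per_ctx = spec.n_target + spec.n_filler
    rows = []
    for p in participants.itertuples(index=False):
        pay = _sample_option_pairs(spec, 2 * per_ctx, rng)
        contexts = np.repeat(["ingroup", "outgroup"], per_ctx)
        filler = np.tile(
            np.r_[np.zeros(spec.n_target, dtype=bool), np.ones(spec.n_filler, dtype=bool)], 2
        )
        order = rng.permutation(2 * per_ctx)
        sides = rng.choice(["left", "right"], size=2 * per_ctx)
        for rank, k in enumerate(order):
            rows.append(
                {
                    "participant": p.participant,
                    "trial": int(rank + 1),
                    "trial_index": int(rank + 1),
                    "context": contexts[k],
                    "is_filler": bool(filler[k]),
                    "own_selfish": pay[k, 0],
                    "other_selfish": pay[k, 1],
                    "own_prosocial": pay[k, 2],
                    "other_prosocial": pay[k, 3],
                    "prosocial_side": sides[k],
                    "cell": p.cell,
                }
            )
    return pd.DataFrame(rows)


def generate_layout(cell: tuple[str, str] | str) -> list[AOI]:
    """Deterministic 15-AOI layout for one counterbalancing cell.

    ``cell`` is ``(payoff_position, identity_position)`` with distinct
    positions from {top, middle, bottom} (or the same pair joined by "+").
    The layout comprises 8 payoff-information AOIs (100x100 px; rows: own
    payoff, partner payoff, difference, sum; columns: left/right option),
    4 row-label AOIs (190x100 px at the left screen edge) and 3
    identity-box AOIs (100x100 px; group membership, coin toss, personal
    code).
    """
    if isinstance(cell, str):
        parts = tuple(cell.split("+"))
        if len(parts) != 2:
            raise ValueError(f"malformed counterbalance cell {cell!r}")
        cell = parts  # type: ignore[assignment]
    if cell not in COUNTERBALANCE_CELLS:
        raise ValueError(f"unknown counterbalance cell {cell!r}")
    payoff_pos, identity_pos = cell
    y_pay = _PAYOFF_BAND_Y[payoff_pos]
    y_id = _IDENTITY_BAND_Y[identity_pos]

    layout: list[AOI] = []
    for i, row in enumerate(_ROW_ORDER):
        y = y_pay + 110.0 * i
        layout.append(AOI(f"label_{row}", "row_label", 40.0, y, 190.0, 100.0))
        layout.append(AOI(f"{row}_left", _ROW_CATEGORY[row], 400.0, y, 100.0, 100.0))
        layout.append(AOI(f"{row}_right", _ROW_CATEGORY[row], 800.0, y, 100.0, 100.0))
    for x, (label, cat) in zip(
        (950.0, 1060.0, 1170.0), (("group_id", "group_id"), ("coin", "coin"), ("code", "code"))
    ):
        layout.append(AOI(label, cat, x, y_id, 100.0, 100.0))
    validate_layout(layout, SCREEN_SIZE)
    return layout


def aoi_centroid(layout: Sequence[AOI], label: str) -> tuple[float, float]:
    for a in layout:
        if a.label == label:
            return (a.x0 + a.width / 2.0, a.y0 + a.height / 2.0)
    raise KeyError(label)


def generate_gaze(
    planted: Sequence[tuple[str, float]],
    layout: Sequence[AOI],
    rng: np.random.Generator,
    sigma_px: float = 3.0,
    clip_px: float = 7.0,
    hz: float = 120.0,
    t0_ms: float = 0.0,
) -> pd.DataFrame:
    """Raw gaze samples realising a planted fixation sequence.

    ``planted`` is a list of (AOI label, duration ms).  Each fixation emits
    ``round(duration / frame)`` samples jittered around the AOI centroid;
    the jitter is truncated at ``clip_px`` per axis so a planted fixation
    can never exceed the 30 px summed-dispersion tolerance by itself.
    Between consecutive fixations, two un-jittered samples are placed at
    1/3 and 2/3 of the saccade path — too far from either endpoint cluster
    to join a fixation window, and too far apart to form one.

    The round trip ``generate_gaze -> detect_fixations -> assign_fixations``
    therefore recovers the planted AOI dwell sequence (fixations shorter
    than the 50 ms detector minimum are planted but not recoverable).
    """
    dt = 1000.0 / hz
    ts: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    t = t0_ms
    prev_c: Optional[tuple[float, float]] = None
    for label, dur in planted:
        cx, cy = aoi_centroid(layout, label)
        if prev_c is not None and (prev_c[0] != cx or prev_c[1] != cy):
            for frac in (1.0 / 3.0, 2.0 / 3.0):
                ts.append(t)
                xs.append(prev_c[0] + frac * (cx - prev_c[0]))
                ys.append(prev_c[1] + frac * (cy - prev_c[1]))
                t += dt
        n = max(1, int(round(dur / dt)))
        jit = np.clip(rng.normal(0.0, sigma_px, size=(n, 2)), -clip_px, clip_px)
        for j in range(n):
            ts.append(t)
            xs.append(cx + jit[j, 0])
            ys.append(cy + jit[j, 1])
            t += dt
        prev_c = (cx, cy)
    return pd.DataFrame({"t_ms": ts, "x": xs, "y": ys, "valid": True})


def _merge_consecutive(planted: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    for label, dur in planted:
        if out and out[-1][0] == label:
            out[-1] = (label, out[-1][1] + dur)
        else:
            out.append((label, dur))
    return out


def generate_experiment(
    spec: ExperimentSpec,
    seed: int,
    with_gaze: bool = True,
    addm_params=None,
) -> dict:
    """End-to-end synthetic dataset with ground truth.

    Simulates participants and trials, drives each trial through the
    drift-diffusion simulator to obtain a choice, response time and
    option-level fixation sequence, maps fixations to concrete AOIs (cells
    within the fixated option, biased by the decision weights), and — when
    ``with_gaze`` — renders raw gaze streams per trial.

    Returns a dict with ``participants``, ``trials`` (including simulated
    choice and response time), ``layouts`` (per counterbalance cell),
    ``gaze`` (single table, empty when ``with_gaze=False``) and ``truth``
    (planted fixation sequences and the generating parameters).
    """
    from .addm_simulator import ADDMParams, simulate_trial
    from .social_utility import AllocationOption, GroupContext
    from .svo_slider import angle_to_weights

    rng = np.random.default_rng(seed)
    params = addm_params or ADDMParams()
    participants = generate_participants(spec, rng)
    trials = generate_trials(spec, rng, participants)
    layouts = {"+".join(c): generate_layout(c) for c in COUNTERBALANCE_CELLS}
    prefs = {
        p: angle_to_weights(a)
        for p, a in zip(participants["participant"], participants["svo_angle"])
    }

    truth: dict = {"seed": seed, "beta_out": spec.beta_out, "planted": {}}
    gaze_frames = []
    sim_rows = []
    for tr in trials.itertuples(index=False):
        pref = prefs[tr.participant]
        ctx = (
            GroupContext.ingroup()
            if tr.context == "ingroup"
            else GroupContext.outgroup(spec.beta_out)
        )
        pro = AllocationOption(tr.own_prosocial, tr.other_prosocial, side=tr.prosocial_side)
        sel_side = "left" if tr.prosocial_side == "right" else "right"
        sel = AllocationOption(tr.own_selfish, tr.other_selfish, side=sel_side)
        sim = simulate_trial(pro, sel, pref, ctx, params, rng)
        layout = layouts[tr.cell]

        pcat = np.array([pref.w_own, max(ctx.beta * pref.w_other, 0.02), 0.15, 0.15])
        pcat = pcat / pcat.sum()
        planted: list[tuple[str, float]] = []
        k_id = int(rng.integers(3, 6))
        id_labels = rng.choice(["group_id", "coin", "code"], size=k_id, p=[0.6, 0.2, 0.2])
        for lab in id_labels:
            planted.append((str(lab), float(rng.lognormal(np.log(250.0), 0.3))))
        id_dwell = sum(d for _, d in planted)
        for side, dur in sim.fixations:
            opt_side = tr.prosocial_side if side == "A" else sel_side
            row = _ROW_ORDER[rng.choice(4, p=pcat)]
            planted.append((f"{row}_{opt_side}", float(dur)))
        planted = _merge_consecutive(planted)

        rt = sim.rt_ms + id_dwell
        sim_rows.append(
            {
                "participant": tr.participant,
                "trial": tr.trial,
                "choice_prosocial": sim.choice == "A",
                "response_time_ms": rt,
                "censored": sim.censored,
            }
        )
        truth["planted"][f"{tr.participant}/{tr.trial}"] = planted
        if with_gaze:
            g = generate_gaze(planted, layout, rng, sigma_px=spec.gaze_sigma_px, hz=spec.sampling_hz)
            g.insert(0, "trial", tr.trial)
            g.insert(0, "participant", tr.participant)
            gaze_frames.append(g)

    sims = pd.DataFrame(sim_rows)
    trials = trials.merge(sims, on=["participant", "trial"])
    gaze = (
        pd.concat(gaze_frames, ignore_index=True)
        if gaze_frames
        else pd.DataFrame(columns=["participant", "trial", "t_ms", "x", "y", "valid"])
    )
    return {
        "participants": participants,
        "trials": trials,
        "layouts": layouts,
        "gaze": gaze,
        "truth": truth,
    }
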