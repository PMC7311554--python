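"""Gaze preprocessing: fixation detection, AOI metrics, trial exclusions.

Raw gaze streams (120 Hz samples of screen coordinates) are reduced to
fixations with a dispersion-threshold (I-DT) detector, fixations are
assigned to labelled areas of interest (AOIs), trial-level attention and
effort metrics are derived, and the preregistered-style exclusion rules are
applied to the resulting metrics table.

Detector semantics
------------------
Greedy left-to-right maximal windows: starting from the current sample, the
window grows while the summed dispersion ``(max x - min x) + (max y - min y)``
stays within the tolerance (30 px).  A maximal window is emitted as a
fixation when its duration reaches the minimum (50 ms, inclusive).  Duration
counts each sample as one nominal frame: ``t_last - t_first + frame_ms``, so
at 120 Hz six samples span exactly 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fixation",
    "AOI",
    "SCREEN_SIZE",
    "detect_fixations",
    "validate_layout",
    "assign_fixations",
    "trial_metrics",
    "apply_exclusions",
    "diagnostic_attention_contrast",
    "preprocess_gaze",
]

#: Native screen resolution of the decision display (px).
SCREEN_SIZE = (1280, 1024)

#: Summed x+y dispersion tolerance for a fixation window (px).
DISPERSION_PX = 30.0
#: Minimum fixation duration (ms), inclusive.
MIN_DURATION_MS = 50.0
#: Nominal inter-sample interval at 120 Hz (ms).
FRAME_MS = 1000.0 / 120.0

#: AOI categories counted as task-relevant ("payoffs and identifying
#: information") for the fixation-share exclusion and inspection counts.
PAYOFF_CATEGORIES = ("payoff_own", "payoff_other", "difference", "sum")
IDENTITY_CATEGORIES = ("group_id", "coin", "code")
INFO_CATEGORIES = PAYOFF_CATEGORIES + IDENTITY_CATEGORIES
#: Full on-screen AOI inventory used as the denominator of the
#: proportion-of-inspected-information measure.
TOTAL_AOIS = 15


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: centroid, onset and duration."""

    x: float
    y: float
    onset_ms: float
    duration_ms: float
    sample_count: int


@dataclass(frozen=True)
class AOI:
    """A labelled half-open screen rectangle ``[x0, x0+w) x [y0, y0+h)``."""

    label: str
    category: str
    x0: float
    y0: float
    width: float
    height: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x0 + self.width and self.y0 <= y < self.y0 + self.height


def average_eyes(gaze: pd.DataFrame) -> pd.DataFrame:
    """Collapse binocular gaze to one stream per timestamp.

    If per-eye columns (``x_left``, ``y_left``, ``x_right``, ``y_right``,
    optionally ``valid_left``/``valid_right``) are present, valid eyes are
    averaged; when only one eye is valid its position is used alone, and
    samples with no valid eye are marked invalid.  Tables already carrying
    plain ``x``/``y`` columns pass through unchanged.
    """
    if "x" in gaze.columns and "x_left" not in gaze.columns:
        return gaze
    required = {"x_left", "y_left", "x_right", "y_right"}
    if not required <= set(gaze.columns):
        raise ValueError("binocular input needs x_left/y_left/x_right/y_right columns")
    out = gaze.copy()
    vl = out["valid_left"].astype(bool) if "valid_left" in out.columns else out["x_left"].notna()
    vr = out["valid_right"].astype(bool) if "valid_right" in out.columns else out["x_right"].notna()
    for axis in ("x", "y"):
        left = out[f"{axis}_left"].where(vl)
        right = out[f"{axis}_right"].where(vr)
        out[axis] = pd.concat([left, right], axis=1).mean(axis=1)
    out["valid"] = vl | vr
    return out


def detect_fixations(
    t: Sequence[float],
    x: Sequence[float],
    y: Sequence[float],
    dispersion_px: float = DISPERSION_PX,
    min_duration_ms: float = MIN_DURATION_MS,
    frame_ms: Optional[float] = None,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Parameters
    ----------
    t, x, y : sequences
        Time-ordered sample timestamps (ms) and screen coordinates (px).
        Invalid samples must be dropped beforehand.
    dispersion_px : float
        Maximum summed x+y range of a fixation window.
    min_duration_ms : float
        Minimum window duration (inclusive) for a fixation to be emitted.
    frame_ms : float, optional
        Nominal inter-sample interval used to count the last sample's frame
        into the duration; inferred as the median timestamp difference when
        omitted (120 Hz default for a single sample).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    if n == 0:
        return []
    if not (x.size == n and y.size == n):
        raise ValueError("t, x, y must have equal length")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing within a trial")
    if frame_ms is None:
        frame_ms = float(np.median(dt)) if n > 1 else FRAME_MS

    fixations: list[Fixation] = []
    i = 0
    while i < n:
        # grow the window greedily while the summed dispersion holds
        min_x = max_x = x[i]
        min_y = max_y = y[i]
        j = i
        while j + 1 < n:
            nx, ny = x[j + 1], y[j + 1]
            mnx, mxx = min(min_x, nx), max(max_x, nx)
            mny, mxy = min(min_y, ny), max(max_y, ny)
            if (mxx - mnx) + (mxy - mny) > dispersion_px:
                break
            min_x, max_x, min_y, max_y = mnx, mxx, mny, mxy
            j += 1
        duration = t[j] - t[i] + frame_ms
        if duration >= min_duration_ms:
            fixations.append(
                Fixation(
                    x=float(np.mean(x[i : j + 1])),
                    y=float(np.mean(y[i : j + 1])),
                    onset_ms=float(t[i]),
                    duration_ms=float(duration),
                    sample_count=int(j - i + 1),
                )
            )
            i = j + 1
        else:
            i += 1
    return fixations


def validate_layout(layout: Sequence[AOI], screen=SCREEN_SIZE) -> None:
    """Check that AOIs fit on screen and are pairwise non-overlapping."""
    w, h = screen
    for a in layout:
        if a.width <= 0 or a.height <= 0:
            raise ValueError(f"AOI {a.label!r} has non-positive size")
        if a.x0 < 0 or a.y0 < 0 or a.x0 + a.width > w or a.y0 + a.height > h:
            raise ValueError(f"AOI {a.label!r} extends beyond the {w}x{h} screen")
    for i, a in enumerate(layout):
        for b in layout[i + 1 :]:
            if (
                a.x0 < b.x0 + b.width
                and b.x0 < a.x0 + a.width
                and a.y0 < b.y0 + b.height
                and b.y0 < a.y0 + a.height
            ):
                raise ValueError(f"AOIs {a.label!r} and {b.label!r} overlap")


def assign_fixations(
    fixations: Iterable[Fixation], layout: Sequence[AOI]
) -> list[tuple[Fixation, str]]:
    """Label each fixation with the AOI containing its centroid.

    Rectangles are half-open, so a centroid exactly on an AOI's top-left
    corner belongs to it while one on the far edge does not.  Fixations
    outside every AOI are labelled ``"none"``.
    """
    validate_layout(layout)
    out = []
    for f in fixations:
        label = "none"
        for a in layout:
            if a.contains(f.x, f.y):
                label = a.label
                break
        out.append((f, label))
    return out


def trial_metrics(
    assigned: Sequence[tuple[Fixation, str]],
    layout: Sequence[AOI],
    response_time_ms: float,
    group_gaze_attended: Optional[bool] = None,
) -> dict:
    """Trial-level attention and effort metrics from assigned fixations.

    Returns a dict with response time, fixation counts, number and
    proportion of distinct inspected AOIs, the share of attention on own vs
    partner payoffs (percent), identity-box dwell shares, and the on-AOI
    fixation share used by the exclusion stage.

    ``group_gaze_attended`` overrides the fixation-based group-attendance
    flag when raw-sample information is available (any gaze sample in the
    group AOI counts, regardless of fixation status).
    """
    cat_of = {a.label: a.category for a in layout}
    dwell: dict[str, float] = {}
    counts: dict[str, int] = {}
    inspected: set[str] = set()
    n_on_info = 0
    for f, label in assigned:
        cat = cat_of.get(label, "none")
        dwell[cat] = dwell.get(cat, 0.0) + f.duration_ms
        counts[cat] = counts.get(cat, 0) + 1
        if cat != "none":
            inspected.add(label)
        if cat in INFO_CATEGORIES:
            n_on_info += 1

    n_fix = len(assigned)
    own = dwell.get("payoff_own", 0.0)
    other = dwell.get("payoff_other", 0.0)
    attention_own = 100.0 * own / (own + other) if own + other > 0 else np.nan
    id_dwell = {c: dwell.get(c, 0.0) for c in IDENTITY_CATEGORIES}
    id_total = sum(id_dwell.values())
    shares = {
        f"share_{c}": (id_dwell[c] / id_total if id_total > 0 else np.nan)
        for c in IDENTITY_CATEGORIES
    }
    if group_gaze_attended is None:
        group_gaze_attended = id_dwell["group_id"] > 0

    return {
        "response_time_ms": float(response_time_ms),
        "n_fixations": n_fix,
        "n_inspected": len(inspected),
        "prop_inspected": len(inspected) / TOTAL_AOIS,
        "attention_own_pct": attention_own,
        "dwell_payoff_own_ms": own,
        "dwell_payoff_other_ms": other,
        "dwell_identity_ms": id_total,
        "on_info_fixation_share": (n_on_info / n_fix if n_fix else 0.0),
        "group_info_attended": bool(group_gaze_attended),
        **shares,
    }


def apply_exclusions(
    metrics: pd.DataFrame,
    participants: Optional[pd.DataFrame] = None,
    require_group_attended: bool = False,
    rt_stats: Optional[tuple[float, float]] = None,
    min_rt_ms: float = 200.0,
    min_info_share: float = 0.5,
    sd_multiplier: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Apply trial- and participant-level exclusion rules.

    Rules, in order:

    1. participant flags (columns of ``participants`` when given):
       ``wrong_outgroup``, ``outgroup_preferred`` (identified with or liked
       the outgroup at least as much as the ingroup), ``demand_check_failed``
       — remove all trials of flagged participants;
    2. trials with less than ``min_info_share`` of fixations on payoff and
       identity AOIs (column ``on_info_fixation_share``);
    3. trials with response time below ``min_rt_ms`` or above the pooled
       mean + ``sd_multiplier`` * SD; the mean and SD are computed over the
       trials surviving rule 2 (pass ``rt_stats`` to freeze them, which
       makes the filter idempotent);
    4. optionally (process analyses), trials where the group-membership AOI
       received no gaze at all (column ``group_info_attended``).

    Returns the retained table and a report dict with per-rule counts and
    the RT threshold used.
    """
    report: dict = {"n_input": int(len(metrics))}
    df = metrics.copy()

    if participants is not None:
        flags = [
            c
            for c in ("wrong_outgroup", "outgroup_preferred", "demand_check_failed")
            if c in participants.columns
        ]
        bad = participants.loc[
            participants[flags].any(axis=1) if flags else [], "participant"
        ]
        bad = set(bad)
        report["participants_excluded"] = sorted(str(b) for b in bad)
        report["n_participant_flag"] = int(df["participant"].isin(bad).sum())
        df = df[~df["participant"].isin(bad)]
    else:
        report["participants_excluded"] = []
        report["n_participant_flag"] = 0

    low_share = df["on_info_fixation_share"] < min_info_share
    report["n_fixation_share"] = int(low_share.sum())
    df = df[~low_share]

    if rt_stats is None:
        rt_mean = float(df["response_time_ms"].mean()) if len(df) else 0.0
        rt_sd = float(df["response_time_ms"].std(ddof=1)) if len(df) > 1 else 0.0
    else:
        rt_mean, rt_sd = rt_stats
    upper = rt_mean + sd_multiplier * rt_sd
    bad_rt = (df["response_time_ms"] < min_rt_ms) | (df["response_time_ms"] > upper)
    report["rt_upper_ms"] = upper
    report["n_rt"] = int(bad_rt.sum())
    df = df[~bad_rt]

    if require_group_attended:
        unattended = ~df["group_info_attended"].astype(bool)
        report["n_group_unattended"] = int(unattended.sum())
        df = df[~unattended]

    report["n_retained"] = int(len(df))
    report["prop_retained"] = report["n_retained"] / report["n_input"] if report["n_input"] else 1.0
    return df.reset_index(drop=True), report


def diagnostic_attention_contrast(metrics: pd.DataFrame) -> dict:
    """Diagnostic vs undiagnostic identity information: dwell-share contrast.

    On group-attended trials, computes each participant's mean dwell share
    on the group-membership box versus the two undiagnostic boxes (coin
    toss, personal code), and a paired t-test of the group share against
    the mean of the two undiagnostic shares.
    """
    from scipy import stats

    df = metrics[metrics["group_info_attended"].astype(bool)]
    df = df.dropna(subset=["share_group_id", "share_coin", "share_code"])
    per = df.groupby("participant")[["share_group_id", "share_coin", "share_code"]].mean()
    out = {
        "mean_share_group_id": float(per["share_group_id"].mean()),
        "mean_share_coin": float(per["share_coin"].mean()),
        "mean_share_code": float(per["share_code"].mean()),
        "n_participants": int(len(per)),
    }
    if len(per) > 1:
        undiag = (per["share_coin"] + per["share_code"]) / 2.0
        tt = stats.ttest_rel(per["share_group_id"], undiag)
        out["t_statistic"] = float(tt.statistic)
        out["p_value"] = float(tt.pvalue)
    return out


def preprocess_gaze(
    gaze: pd.DataFrame,
    layout: Sequence[AOI],
    trials: pd.DataFrame,
    frame_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Run detection, assignment and metric extraction over a gaze table.

    ``gaze`` columns: participant, trial, t_ms, x, y and optionally
    ``valid`` (invalid samples are dropped); binocular per-eye columns are
    averaged first via :func:`average_eyes`.  ``trials`` columns must
    include participant, trial and response_time_ms; extra columns are
    carried through to the output.  Returns one metrics row per trial.
    """
    gaze = average_eyes(gaze)
    if "valid" in gaze.columns:
        gaze = gaze[gaze["valid"].astype(bool)]
    cat_of = {a.label: a for a in layout}
    group_aois = [a for a in layout if a.category == "group_id"]
    rows = []
    trials_idx = trials.set_index(["participant", "trial"])
    for (pid, tid), g in gaze.groupby(["participant", "trial"], sort=False):
        g = g.sort_values("t_ms")
        fixations = detect_fixations(
            g["t_ms"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy(), frame_ms=frame_ms
        )
        assigned = assign_fixations(fixations, layout)
        # any raw sample in the group AOI counts as attendance
        attended = any(
            a.contains(xx, yy)
            for a in group_aois
            for xx, yy in zip(g["x"].to_numpy(), g["y"].to_numpy())
        )
        try:
            tr = trials_idx.loc[(pid, tid)]
        except KeyError:
            raise ValueError(f"trial table has no row for participant {pid!r}, trial {tid!r}")
        m = trial_metrics(
            assigned, layout, float(tr["response_time_ms"]), group_gaze_attended=attended
        )
        extra = {k: tr[k] for k in trials_idx.columns if k != "response_time_ms"}
        rows.append({"participant": pid, "trial": tid, **extra, **m})
    _ = cat_of
    return pd.DataFrame(rows)
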