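"""Social Value Orientation slider measure: angle, classification, weights.

The slider measure presents six primary allocation items; on each, the
respondent picks one of nine (self, other) point allocations.  The
continuous orientation score is the angle of the mean allocation relative
to the item-grid centre at (50, 50):

    SVO_angle = arctan( (mean_other - 50) / (mean_self - 50) )   [degrees]

Larger angles indicate greater weight on the partner's outcome.  The
conventional category cutoffs are: altruistic above 57.15 deg, prosocial in
(22.45, 57.15), individualist in (-12.04, 22.45), competitive below -12.04.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .social_utility import SocialPreference

__all__ = [
    "SliderResponse",
    "slider_items",
    "svo_angle",
    "classify",
    "angle_to_weights",
    "read_responses",
    "score_participants",
]

#: Classification cutoffs in degrees (open intervals on both sides).
CUTOFF_COMPETITIVE = -12.04
CUTOFF_PROSOCIAL = 22.45
CUTOFF_ALTRUISTIC = 57.15

_N_PRIMARY_ITEMS = 6


@dataclass(frozen=True)
class SliderResponse:
    """One chosen allocation on one primary slider item."""

    item_id: int
    alloc_self: float
    alloc_other: float


def slider_items() -> pd.DataFrame:
    """The packaged six-item allocation table.

    Columns: ``item_id`` (1..6), ``alloc_index`` (1..9), ``alloc_self``,
    ``alloc_other``.  Every valid :class:`SliderResponse` must pick one of
    the nine listed allocations of its item.
    """
    with resources.files("intergaze.data").joinpath("svo_slider_items.csv").open() as fh:
        return pd.read_csv(fh)


def _validate_responses(responses: Sequence[SliderResponse], items: pd.DataFrame) -> None:
    if len(responses) != _N_PRIMARY_ITEMS:
        raise ValueError(f"expected {_N_PRIMARY_ITEMS} primary-item responses, got {len(responses)}")
    seen = set()
    for r in responses:
        if r.item_id in seen:
            raise ValueError(f"duplicate response for item {r.item_id}")
        seen.add(r.item_id)
        rows = items[items["item_id"] == r.item_id]
        if rows.empty:
            raise ValueError(f"unknown item_id {r.item_id}")
        ok = ((rows["alloc_self"] == r.alloc_self) & (rows["alloc_other"] == r.alloc_other)).any()
        if not ok:
            raise ValueError(
                f"allocation ({r.alloc_self}, {r.alloc_other}) is not one of the nine "
                f"listed allocations of item {r.item_id}"
            )


def svo_angle(responses: Sequence[SliderResponse], validate: bool = True) -> float:
    """SVO angle (degrees) from six primary-item responses.

    The angle is ``arctan((mean_other - 50) / (mean_self - 50))`` where the
    means are taken over the six chosen allocations.  If ``mean_self`` is
    exactly 50 the slope is undefined; by convention 90 deg is returned when
    ``mean_other > 50``, otherwise a :class:`ValueError` is raised.
    """
    if validate:
        _validate_responses(responses, slider_items())
    mean_self = float(np.mean([r.alloc_self for r in responses]))
    mean_other = float(np.mean([r.alloc_other for r in responses]))
    dx = mean_self - 50.0
    dy = mean_other - 50.0
    if dx == 0.0:
        if dy > 0.0:
            return 90.0
        raise ValueError("undefined SVO angle: mean self-allocation is exactly 50")
    return math.degrees(math.atan(dy / dx))


def classify(angle: float) -> str:
    """Categorise an SVO angle with the conventional open-interval cutoffs.

    Returns one of ``{"altruistic", "prosocial", "individualist",
    "competitive", "boundary"}``; angles falling exactly on a cutoff are
    reported as ``"boundary"`` since the intervals are open.
    """
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle!r}")
    if angle in (CUTOFF_COMPETITIVE, CUTOFF_PROSOCIAL, CUTOFF_ALTRUISTIC):
        return "boundary"
    if angle > CUTOFF_ALTRUISTIC:
        return "altruistic"
    if angle > CUTOFF_PROSOCIAL:
        return "prosocial"
    if angle > CUTOFF_COMPETITIVE:
        return "individualist"
    return "competitive"


def angle_to_weights(angle: float) -> SocialPreference:
    """Map an SVO angle to utility weights ``(w_own, w_other)``.

    Uses the angle-preserving mapping ``w_own = cos(angle)``,
    ``w_other = sin(angle)``, so that ``arctan(w_other / w_own)`` recovers
    the angle exactly on (-90, 90) degrees.  The weights are not normalised
    to sum to one; only their ratio is identified by the angle.
    """
    if not (-90.0 < angle < 90.0):
        raise ValueError(f"angle must lie in (-90, 90) degrees, got {angle!r}")
    rad = math.radians(angle)
    return SocialPreference(w_own=math.cos(rad), w_other=math.sin(rad), svo_angle=angle)


def read_responses(path) -> dict[str, list[SliderResponse]]:
    """Read slider responses from CSV.

    Expected columns: ``participant``, ``item_id``, ``alloc_self``,
    ``alloc_other``.  Returns a mapping participant -> list of responses.
    """
    df = pd.read_csv(path)
    required = {"participant", "item_id", "alloc_self", "alloc_other"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response table is missing columns: {sorted(missing)}")
    out: dict[str, list[SliderResponse]] = {}
    for pid, grp in df.groupby("participant", sort=False):
        out[str(pid)] = [
            SliderResponse(int(r.item_id), float(r.alloc_self), float(r.alloc_other))
            for r in grp.itertuples()
        ]
    return out


def score_participants(responses: dict[str, Iterable[SliderResponse]]) -> pd.DataFrame:
    """Angle, category and utility weights per participant, as a tidy table."""
    rows = []
    for pid, resp in responses.items():
        angle = svo_angle(list(resp))
        pref = angle_to_weights(angle)
        rows.append(
            {
                "participant": pid,
                "svo_angle": angle,
                "svo_class": classify(angle),
                "w_own": pref.w_own,
                "w_other": pref.w_other,
            }
        )
    return pd.DataFrame(rows)
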