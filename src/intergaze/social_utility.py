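"""Social utility of two-party money allocations with group-dependent discounting.

The model represents the value of an allocation option as a weighted sum of
the decision maker's own payoff and the matched partner's payoff,

    U = w_own * u(own) + beta * w_other * u(other),

where ``(w_own, w_other)`` encode the decision maker's social preference and
``beta`` multiplicatively discounts the partner's payoff when the partner
belongs to an outgroup (``beta = 1`` for ingroup partners, ``0 < beta < 1``
for outgroup partners).  The payoff transform ``u`` is the identity by
default; the hook exists so curvature could be added without changing any
call sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "AllocationOption",
    "SocialPreference",
    "GroupContext",
    "utility",
    "utility_difference",
    "predict_choice",
    "context_shift",
]

#: Utility differences below this magnitude are treated as ties.
TIE_TOLERANCE = 1e-9

_TRANSFORMS = {"identity": lambda x: x}


@dataclass(frozen=True)
class AllocationOption:
    """One of the two payoff options on an allocation trial.

    Parameters
    ----------
    own_payoff : float
        Payoff to the decision maker (EUR), non-negative.
    other_payoff : float
        Payoff to the matched partner (EUR), non-negative.
    side : {"left", "right"}, optional
        Screen side the option was displayed on.
    role_label : {"selfish", "prosocial"}, optional
        Design annotation: the selfish option carries the larger own payoff,
        the prosocial option the larger partner payoff.
    """

    own_payoff: float
    other_payoff: float
    side: Optional[Literal["left", "right"]] = None
    role_label: Optional[Literal["selfish", "prosocial"]] = None

    def __post_init__(self) -> None:
        for name in ("own_payoff", "other_payoff"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass(frozen=True)
class SocialPreference:
    """Decision weights on own and partner payoffs.

    ``w_own`` must be non-negative; ``w_other`` may be negative (competitive
    orientations).  ``svo_angle`` is an optional record of the angle the
    weights were derived from (degrees).
    """

    w_own: float
    w_other: float
    svo_angle: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.w_own) or not math.isfinite(self.w_other):
            raise ValueError("weights must be finite")
        if self.w_own < 0:
            raise ValueError(f"w_own must be non-negative, got {self.w_own!r}")


@dataclass(frozen=True)
class GroupContext:
    """Group membership of the matched partner and the associated discount.

    ``beta`` multiplies the weight on the partner's payoff: 1 for ingroup
    partners, strictly between 0 and 1 for outgroup partners.
    """

    membership: Literal["ingroup", "outgroup"]
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.membership not in ("ingroup", "outgroup"):
            raise ValueError(f"membership must be 'ingroup' or 'outgroup', got {self.membership!r}")
        if not math.isfinite(self.beta) or not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta!r}")
        if self.membership == "ingroup" and self.beta != 1.0:
            raise ValueError("ingroup context requires beta = 1")
        if self.membership == "outgroup" and self.beta == 1.0:
            raise ValueError("outgroup context requires beta < 1")

    @classmethod
    def ingroup(cls) -> "GroupContext":
        return cls("ingroup", 1.0)

    @classmethod
    def outgroup(cls, beta: float) -> "GroupContext":
        return cls("outgroup", beta)


def _u(transform: str):
    try:
        return _TRANSFORMS[transform]
    except KeyError:
        raise ValueError(f"unknown payoff transform {transform!r}") from None


def utility(
    option: AllocationOption,
    pref: SocialPreference,
    ctx: GroupContext,
    transform: str = "identity",
) -> float:
    """Utility of ``option`` for a decision maker ``pref`` facing ``ctx``.

    Returns ``w_own * u(own) + beta * w_other * u(other)``; with an ingroup
    context (beta = 1) this is the undiscounted social utility.
    """
    u = _u(transform)
    return pref.w_own * u(option.own_payoff) + ctx.beta * pref.w_other * u(option.other_payoff)


def utility_difference(
    opt_a: AllocationOption,
    opt_b: AllocationOption,
    pref: SocialPreference,
    ctx: GroupContext,
    transform: str = "identity",
) -> tuple[float, float]:
    """Signed and absolute utility difference ``U(A) - U(B)``.

    The signed difference is antisymmetric under swapping the options.
    """
    d = utility(opt_a, pref, ctx, transform) - utility(opt_b, pref, ctx, transform)
    return d, abs(d)


def predict_choice(
    opt_a: AllocationOption,
    opt_b: AllocationOption,
    pref: SocialPreference,
    ctx: GroupContext,
    tie_rule: Literal["random", "first", "abstain"] = "random",
    rng: Optional[np.random.Generator] = None,
    tol: float = TIE_TOLERANCE,
    transform: str = "identity",
):
    """Deterministic utility-maximising choice between two options.

    Returns the higher-utility option.  When ``|U(A) - U(B)| < tol`` the
    ``tie_rule`` applies: ``"random"`` picks uniformly (seeded via ``rng``),
    ``"first"`` returns ``opt_a`` and ``"abstain"`` returns ``None``.
    """
    if tie_rule not in ("random", "first", "abstain"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    d, ad = utility_difference(opt_a, opt_b, pref, ctx, transform)
    if ad < tol:
        if tie_rule == "first":
            return opt_a
        if tie_rule == "abstain":
            return None
        rng = np.random.default_rng() if rng is None else rng
        return opt_a if rng.random() < 0.5 else opt_b
    return opt_a if d > 0 else opt_b


def context_shift(
    opt_a: AllocationOption,
    opt_b: AllocationOption,
    pref: SocialPreference,
    beta_out: float,
    transform: str = "identity",
) -> float:
    """Change in the absolute utility difference between group contexts.

    Evaluates ``| |U(A)-U(B)|_ingroup - |U(A)-U(B)|_outgroup |`` for an
    outgroup discount ``beta_out``.  Under the identity transform this
    equals ``|1 - beta_out| * |w_other| * |other_A - other_B|`` whenever the
    signed difference does not change sign between contexts.
    """
    if not (0.0 < beta_out < 1.0) and beta_out != 1.0:
        raise ValueError(f"beta_out must lie in (0, 1], got {beta_out!r}")
    _, ad_in = utility_difference(opt_a, opt_b, pref, GroupContext.ingroup(), transform)
    if beta_out == 1.0:
        return 0.0
    _, ad_out = utility_difference(opt_a, opt_b, pref, GroupContext.outgroup(beta_out), transform)
    return abs(ad_in - ad_out)
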