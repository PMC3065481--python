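"""Deterministic incremental cost-effectiveness analysis.

Conventions follow the standard cost-effectiveness plane: incremental effect
(difference in FIR probability, intervention minus comparator) on the
horizontal axis, incremental cost on the vertical.  In the SW and NW
quadrants a signed cost/effect ratio is ambiguous, so the ICER is reported
as an absolute ratio together with its quadrant and a plain-language
interpretation (e.g. SW: dollars saved per FIR forgone).

Costs here are annual per person; effects are FIR probabilities over the
~13-month follow-up.  No time alignment between the two is applied, matching
the source analysis (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_params import DecisionModel, Perspective, perspective_total

__all__ = ["ICERResult", "NMBResult", "incremental", "icer", "nmb"]

_INTERPRETATION = {
    "NE": "intervention more effective and more costly: ICER is the extra "
    "cost per additional FIR",
    "SE": "intervention more effective and less costly: intervention dominates",
    "SW": "intervention less effective and less costly: ICER is the savings "
    "per FIR forgone",
    "NW": "intervention less effective and more costly: comparator dominates",
    "axis": "increments lie on a plane axis",
}


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost, effect, absolute ICER and plane quadrant."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    quadrant: str
    interpretation: str


@dataclass(frozen=True)
class NMBResult:
    """Net monetary benefit (wtp·effect − cost) per strategy at one WTP."""

    wtp: float
    nmb_per_strategy: dict[str, float]
    preferred: str


def incremental(
    model: DecisionModel, persp: Perspective, use_override: bool = True
) -> tuple[float, float]:
    """(ΔC, ΔE): intervention minus comparator cost and FIR probability."""
    dc = perspective_total(
        model.intervention.costs, persp, use_override
    ) - perspective_total(model.comparator.costs, persp, use_override)
    de = model.intervention.p_fir - model.comparator.p_fir
    return dc, de


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Absolute incremental cost-effectiveness ratio with quadrant semantics.

    The ratio is undefined (``None``) exactly when the incremental effect is
    zero; increments falling on either axis are labelled ``axis``.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise ValueError("increments must be finite")
    if delta_effect == 0.0 or delta_cost == 0.0:
        quadrant = "axis"
    elif delta_effect > 0:
        quadrant = "NE" if delta_cost > 0 else "SE"
    else:
        quadrant = "NW" if delta_cost > 0 else "SW"
    ratio = None if delta_effect == 0.0 else abs(delta_cost / delta_effect)
    return ICERResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=ratio,
        quadrant=quadrant,
        interpretation=_INTERPRETATION[quadrant],
    )


def nmb(model: DecisionModel, persp: Perspective, wtp: float) -> NMBResult:
    """Net monetary benefit of each strategy at willingness-to-pay ``wtp``.

    The strategy with the larger NMB is preferred; an exact tie goes to the
    comparator (the conservative default, relevant only at a single WTP).
    """
    if wtp < 0:
        raise ValueError(f"willingness to pay must be non-negative, got {wtp}")
    values = {
        s.name: wtp * s.p_fir - perspective_total(s.costs, persp)
        for s in (model.comparator, model.intervention)
    }
    if values[model.intervention.name] > values[model.comparator.name]:
        preferred = model.intervention.name
    else:
        preferred = model.comparator.name
    return NMBResult(wtp=wtp, nmb_per_strategy=values, preferred=preferred)
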