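"""One-way and probabilistic sensitivity analysis.

Range construction follows the source analysis: every cost estimate is
halved and doubled, every probability shifted ±20% (capped at 1), and the
resulting range is treated as a 95% confidence interval to derive a standard
error, se = (high − low) / (2 × 1.959964).  Probabilities get beta
distributions and costs gamma distributions, fitted by moment matching so
each distribution's mean and SD equal the point estimate and derived SE
exactly.

The Monte Carlo engine samples cost *components*; by default the categories
shared between arms (ART, other drugs, radiology, laboratory, overhead,
transport) use a single draw applied to both arms, while arm-specific
categories (personnel, lost patient time) are drawn independently per arm —
the only correlation structure under which an intervention cheaper in every
differing component is cheaper in every replicate.  The residual
reconciliation category is an accounting device rather than a measured cost,
so it stays at its base value during the PSA by default (it is still swung
in the tornado); ``sample_residual=True`` gives it a gamma like any other
component, and ``shared_costs=False`` switches every category to
independent per-arm draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea_core import incremental
from .model_params import (
    CostCategory,
    DecisionModel,
    Perspective,
    included_categories,
)

__all__ = [
    "UncertainParam",
    "TornadoRow",
    "PSAResult",
    "se_from_range",
    "fit_beta",
    "fit_gamma",
    "build_ranges",
    "one_way",
    "run_psa",
    "plane_summary",
    "ceac",
    "ceac_crossover",
    "DEFAULT_WTP_GRID",
]

Z_95 = 1.959964

#: Willingness-to-pay grid (US$/FIR) for acceptability curves.
DEFAULT_WTP_GRID = np.arange(0.0, 30_001.0, 100.0)

#: Cost categories identical across arms in the base case, drawn once per
#: iteration under shared sampling.
SHARED_CATEGORIES = (
    CostCategory.ART,
    CostCategory.OTHER_DRUGS,
    CostCategory.RADIOLOGY,
    CostCategory.LABORATORY,
    CostCategory.OVERHEAD_CAPITAL,
    CostCategory.TRANSPORT,
)


def se_from_range(low: float, high: float) -> float:
    """Standard error treating (low, high) as a 95% confidence interval."""
    if high <= low:
        raise ValueError(f"range must have high > low, got ({low}, {high})")
    return (high - low) / (2.0 * Z_95)


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta parameters (alpha, beta) for a probability."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"variance {se * se:.4g} too large for a beta with mean {mean}: "
            f"requires se^2 < mean*(1-mean) = {mean * (1 - mean):.4g}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters (shape, scale) for a cost."""
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma fit needs positive mean and se, got ({mean}, {se})")
    shape = (mean / se) ** 2
    return shape, se * se / mean


@dataclass(frozen=True)
class UncertainParam:
    """A model parameter with its one-way range and fitted distribution.

    ``name`` encodes the role: ``cost:<category>`` for a shared cost,
    ``cost:<category>:<arm>`` for an arm-specific cost, ``p_fir:<arm>`` for
    an arm's FIR probability.
    """

    name: str
    role: str  # "cost" | "probability"
    mean: float
    low: float
    high: float
    se: float
    dist: tuple  # ("beta", alpha, beta) | ("gamma", shape, scale)
    category: CostCategory | None = None
    arm: str | None = None  # "prp" | "soc" | None (shared)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        kind, p1, p2 = self.dist
        if kind == "beta":
            return rng.beta(p1, p2, size=n)
        return rng.gamma(shape=p1, scale=p2, size=n)


@dataclass(frozen=True)
class TornadoRow:
    """One-way swing of a single parameter on an incremental outcome."""

    name: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _make_cost_param(
    name: str,
    mean: float,
    low_factor: float,
    high_factor: float,
    category: CostCategory,
    arm: str | None,
) -> UncertainParam | None:
    low, high = low_factor * mean, high_factor * mean
    if high <= low:
        warnings.warn(
            f"{name}: degenerate range at mean {mean}; parameter excluded",
            stacklevel=3,
        )
        return None
    se = se_from_range(low, high)
    return UncertainParam(
        name=name,
        role="cost",
        mean=mean,
        low=low,
        high=high,
        se=se,
        dist=("gamma", *fit_gamma(mean, se)),
        category=category,
        arm=arm,
    )


def build_ranges(
    model: DecisionModel, shared_costs: bool = True
) -> list[UncertainParam]:
    """Uncertain parameters with one-way ranges and fitted distributions.

    Cost ranges use the model's sensitivity factors (default halved/doubled)
    and probability ranges ±prob_delta (default 20%, high capped at 1).
    Under ``shared_costs`` each base-case-identical shared category yields
    one parameter; otherwise every category is arm-specific.  Zero-mean
    costs have no range and are excluded with a warning.
    """
    sens = model.sensitivity
    params: list[UncertainParam] = []
    arm_costs = {
        "prp": model.intervention.costs.category_costs,
        "soc": model.comparator.costs.category_costs,
    }
    for cat in CostCategory:
        shared_here = (
            shared_costs
            and cat in SHARED_CATEGORIES
            and arm_costs["prp"][cat] == arm_costs["soc"][cat]
        )
        if shared_here:
            p = _make_cost_param(
                f"cost:{cat.value}",
                arm_costs["prp"][cat],
                sens.cost_low_factor,
                sens.cost_high_factor,
                cat,
                None,
            )
            if p is not None:
                params.append(p)
        else:
            for arm in ("prp", "soc"):
                p = _make_cost_param(
                    f"cost:{cat.value}:{arm}",
                    arm_costs[arm][cat],
                    sens.cost_low_factor,
                    sens.cost_high_factor,
                    cat,
                    arm,
                )
                if p is not None:
                    params.append(p)
    for arm, strat in (("prp", model.intervention), ("soc", model.comparator)):
        mean = strat.p_fir
        low = (1.0 - sens.prob_delta) * mean
        high = min(1.0, (1.0 + sens.prob_delta) * mean)
        se = se_from_range(low, high)
        params.append(
            UncertainParam(
                name=f"p_fir:{arm}",
                role="probability",
                mean=mean,
                low=low,
                high=high,
                se=se,
                dist=("beta", *fit_beta(mean, se)),
                arm=arm,
            )
        )
    return params


def _component_increments(
    costs_by_arm: dict[str, dict[CostCategory, float]],
    p_fir_by_arm: dict[str, float],
    persp: Perspective,
) -> tuple[float, float]:
    cats = included_categories(persp)
    dc = sum(costs_by_arm["prp"][c] for c in cats) - sum(
        costs_by_arm["soc"][c] for c in cats
    )
    de = p_fir_by_arm["prp"] - p_fir_by_arm["soc"]
    return dc, de


def one_way(
    model: DecisionModel,
    persp: Perspective,
    target: str = "delta_cost",
    shared_costs: bool = True,
    params: list[UncertainParam] | None = None,
) -> list[TornadoRow]:
    """Tornado analysis: swing each parameter to its bounds, others at base.

    ``target`` selects the incremental outcome: ``delta_cost`` or
    ``delta_effect``.  Incremental outcomes are computed from component
    sums, so a shared cost parameter (moved in both arms at once) produces
    zero swing on incremental cost — only arm-specific parameters can move
    the difference.  Rows are sorted by descending swing.
    """
    if target not in ("delta_cost", "delta_effect"):
        raise ValueError(f"unknown tornado target: {target}")
    persp = Perspective(persp)
    if params is None:
        params = build_ranges(model, shared_costs=shared_costs)
    base_costs = {
        "prp": dict(model.intervention.costs.category_costs),
        "soc": dict(model.comparator.costs.category_costs),
    }
    base_p = {"prp": model.intervention.p_fir, "soc": model.comparator.p_fir}
    idx = 0 if target == "delta_cost" else 1

    def outcome_with(param: UncertainParam, value: float) -> float:
        costs = {arm: dict(c) for arm, c in base_costs.items()}
        p_fir = dict(base_p)
        if param.role == "cost":
            arms = (param.arm,) if param.arm else ("prp", "soc")
            for arm in arms:
                costs[arm][param.category] = value
        else:
            p_fir[param.arm] = value
        return _component_increments(costs, p_fir, persp)[idx]

    rows = [
        TornadoRow(p.name, outcome_with(p, p.low), outcome_with(p, p.high))
        for p in params
    ]
    return sorted(rows, key=lambda r: r.swing, reverse=True)


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws plus the settings that produced them."""

    draws: pd.DataFrame  # one row per iteration
    perspective: Perspective
    seed: int
    shared_costs: bool
    sample_residual: bool


def _quadrants(delta_cost: np.ndarray, delta_effect: np.ndarray) -> np.ndarray:
    quad = np.full(delta_cost.shape, "axis", dtype=object)
    quad[(delta_effect > 0) & (delta_cost > 0)] = "NE"
    quad[(delta_effect > 0) & (delta_cost < 0)] = "SE"
    quad[(delta_effect < 0) & (delta_cost < 0)] = "SW"
    quad[(delta_effect < 0) & (delta_cost > 0)] = "NW"
    return quad


def run_psa(
    model: DecisionModel,
    persp: Perspective,
    n_iter: int | None = None,
    seed: int | None = None,
    shared_costs: bool = True,
    sample_residual: bool = False,
) -> PSAResult:
    """Probabilistic sensitivity analysis by Monte Carlo.

    Each iteration samples every uncertain parameter once from its fitted
    distribution (parameters in sorted-name order from a single seeded
    generator, so runs are bit-reproducible), rebuilds per-strategy annual
    costs from component sums under the perspective, and records the
    per-strategy and incremental cost/effect pair with its plane quadrant.
    """
    persp = Perspective(persp)
    if n_iter is None:
        n_iter = model.psa.n_iter
    if seed is None:
        seed = model.psa.seed
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    params = build_ranges(model, shared_costs=shared_costs)
    if not sample_residual:
        params = [p for p in params if p.category is not CostCategory.RESIDUAL]

    rng = np.random.default_rng(seed)
    samples = {p.name: p.sample(n_iter, rng) for p in sorted(params, key=lambda p: p.name)}

    cats = included_categories(persp)
    base_costs = {
        "prp": model.intervention.costs.category_costs,
        "soc": model.comparator.costs.category_costs,
    }
    cost = {}
    effect = {}
    for arm in ("prp", "soc"):
        total = np.zeros(n_iter)
        for cat in cats:
            shared_name = f"cost:{cat.value}"
            arm_name = f"cost:{cat.value}:{arm}"
            if shared_name in samples:
                total += samples[shared_name]
            elif arm_name in samples:
                total += samples[arm_name]
            else:  # unsampled category stays at its base value
                total += base_costs[arm][cat]
        cost[arm] = total
        effect[arm] = samples[f"p_fir:{arm}"]
    delta_cost = cost["prp"] - cost["soc"]
    delta_effect = effect["prp"] - effect["soc"]
    draws = pd.DataFrame(
        {
            "iteration": np.arange(n_iter),
            "cost_prp": cost["prp"],
            "cost_soc": cost["soc"],
            "effect_prp": effect["prp"],
            "effect_soc": effect["soc"],
            "delta_cost": delta_cost,
            "delta_effect": delta_effect,
            "quadrant": _quadrants(delta_cost, delta_effect),
        }
    )
    return PSAResult(
        draws=draws,
        perspective=persp,
        seed=seed,
        shared_costs=shared_costs,
        sample_residual=sample_residual,
    )


def plane_summary(draws: pd.DataFrame) -> dict[str, float]:
    """Fraction of Monte Carlo replicates in each cost-effectiveness quadrant."""
    if draws.empty:
        raise ValueError("no draws")
    frac = draws["quadrant"].value_counts(normalize=True).to_dict()
    return {q: float(frac.get(q, 0.0)) for q in ("NE", "SE", "SW", "NW", "axis")}


def ceac(draws: pd.DataFrame, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves for both strategies.

    At each willingness-to-pay λ, the intervention is cost-effective in a
    draw when its incremental net monetary benefit λ·ΔE − ΔC is strictly
    positive (ties favor the comparator, consistently with the
    deterministic decision rule).
    """
    if draws.empty:
        raise ValueError("no draws")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("wtp grid must be strictly increasing")
    de = draws["delta_effect"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    inmb = wtp_grid[:, None] * de[None, :] - dc[None, :]
    p_prp = (inmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "p_prp_ce": p_prp, "p_soc_ce": 1.0 - p_prp})


def ceac_crossover(curve: pd.DataFrame, threshold: float = 0.5) -> float | None:
    """WTP at which the intervention's acceptability falls to ``threshold``.

    Linear interpolation between the bracketing grid points; ``None`` when
    the curve never crosses on the grid.
    """
    wtp = curve["wtp"].to_numpy()
    p = curve["p_prp_ce"].to_numpy()
    below = np.nonzero(p <= threshold)[0]
    if below.size == 0 or below[0] == 0:
        return None
    j = below[0]
    i = j - 1
    if p[i] == p[j]:
        return float(wtp[j])
    frac = (p[i] - threshold) / (p[i] - p[j])
    return float(wtp[i] + frac * (wtp[j] - wtp[i]))
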