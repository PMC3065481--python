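"""Decision-model data types, the canonical parameter set, and config I/O.

The decision model compares two ART-delivery strategies at a large urban
HIV clinic: a Pharmacy-only Refill Program (PRP, monthly pharmacy pick-up)
against the Standard of Care (SOC, monthly physician visits).  Each strategy
carries an annual per-patient cost profile broken into standard costing
categories and a probability of Favorable Immune Response (FIR, follow-up
CD4 count > 500 cells/µL).  Costs are 2009 US$ per person-year; no
discounting is applied over the ~13-month horizon.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CostCategory",
    "Perspective",
    "CostProfile",
    "StrategyParams",
    "PSASettings",
    "SensitivitySettings",
    "DecisionModel",
    "ConfigError",
    "ValidationError",
    "perspective_total",
    "included_categories",
    "load_config",
    "paper_model",
    "paper_config_path",
]


class ConfigError(ValueError):
    """A configuration file is missing keys, has unknown keys, or cannot parse."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


class CostCategory(str, enum.Enum):
    """Annual per-patient cost categories of ART delivery.

    ``TRANSPORT`` and ``LOST_PATIENT_TIME`` are direct non-medical costs
    (borne by the patient); every other category is direct medical.
    ``RESIDUAL`` is an accounting category carrying the gap between the
    itemized component costs and a strategy's published total, so that
    component-level sensitivity analysis and headline totals coexist.
    """

    ART = "art"
    OTHER_DRUGS = "other_drugs"
    RADIOLOGY = "radiology"
    LABORATORY = "laboratory"
    PERSONNEL = "personnel"
    OVERHEAD_CAPITAL = "overhead_capital"
    TRANSPORT = "transport"
    LOST_PATIENT_TIME = "lost_patient_time"
    RESIDUAL = "residual"

    @property
    def direct_non_medical(self) -> bool:
        return self in _DIRECT_NON_MEDICAL


_DIRECT_NON_MEDICAL = frozenset(
    {CostCategory.TRANSPORT, CostCategory.LOST_PATIENT_TIME}
)


class Perspective(str, enum.Enum):
    """Costing perspective.

    ``LIMITED_SOCIETAL`` counts direct medical plus direct non-medical costs
    (patient transport, lost patient time) but no productivity losses;
    ``MOH`` (Ministry of Health, the payer) counts direct medical costs only.
    """

    LIMITED_SOCIETAL = "limited_societal"
    MOH = "moh"


def included_categories(persp: Perspective) -> tuple[CostCategory, ...]:
    """Cost categories counted under a perspective."""
    if persp is Perspective.LIMITED_SOCIETAL:
        return tuple(CostCategory)
    return tuple(c for c in CostCategory if not c.direct_non_medical)


@dataclass(frozen=True)
class CostProfile:
    """Per-category annual per-patient costs (2009 US$) for one strategy.

    ``total_override_by_perspective`` pins a perspective's total to a published
    figure even when the components do not sum to it exactly; the gap beyond
    $1 triggers a reconciliation warning at lookup time.
    """

    strategy_name: str
    category_costs: Mapping[CostCategory, float]
    total_override_by_perspective: Mapping[Perspective, float] | None = None

    def __post_init__(self) -> None:
        costs = {CostCategory(k): float(v) for k, v in self.category_costs.items()}
        missing = [c.value for c in CostCategory if c not in costs]
        if missing:
            raise ConfigError(
                f"{self.strategy_name}: missing cost categories: {', '.join(missing)}"
            )
        for cat, val in costs.items():
            if val < 0:
                raise ValidationError(
                    f"{self.strategy_name}: negative cost for {cat.value}: {val}"
                )
        object.__setattr__(self, "category_costs", costs)
        if self.total_override_by_perspective is not None:
            overrides = {
                Perspective(k): float(v)
                for k, v in self.total_override_by_perspective.items()
            }
            object.__setattr__(self, "total_override_by_perspective", overrides)

    def component_sum(self, persp: Perspective) -> float:
        return sum(self.category_costs[c] for c in included_categories(persp))


def perspective_total(
    profile: CostProfile, persp: Perspective, use_override: bool = True
) -> float:
    """Total annual per-patient cost of a strategy under a perspective.

    Returns the published override when one is set for ``persp`` (warning if
    it disagrees with the category sum by more than $1), else the sum of the
    categories included under the perspective.
    """
    persp = Perspective(persp)
    comp = profile.component_sum(persp)
    overrides = profile.total_override_by_perspective
    if use_override and overrides is not None and persp in overrides:
        total = overrides[persp]
        if abs(total - comp) > 1.0:
            warnings.warn(
                f"{profile.strategy_name}/{persp.value}: override total {total:.0f} "
                f"differs from category sum {comp:.0f} by "
                f"${abs(total - comp):.0f}; using the override",
                stacklevel=2,
            )
        return total
    return comp


@dataclass(frozen=True)
class StrategyParams:
    """One strategy: its FIR probability, cost profile and follow-up length."""

    name: str
    p_fir: float
    costs: CostProfile
    followup_months: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fir <= 1.0:
            raise ValidationError(
                f"{self.name}: p_fir must lie in [0, 1], got {self.p_fir}"
            )
        if self.followup_months <= 0:
            raise ValidationError(
                f"{self.name}: followup_months must be > 0, got {self.followup_months}"
            )


@dataclass(frozen=True)
class PSASettings:
    n_iter: int = 10_000
    seed: int = 20110328


@dataclass(frozen=True)
class SensitivitySettings:
    """One-way ranges: costs scaled by the two factors, probabilities by ±delta."""

    cost_low_factor: float = 0.5
    cost_high_factor: float = 2.0
    prob_delta: float = 0.2


@dataclass(frozen=True)
class DecisionModel:
    """Two-strategy decision model: SOC comparator vs PRP intervention."""

    comparator: StrategyParams
    intervention: StrategyParams
    n_comparator: int
    n_intervention: int
    psa: PSASettings = field(default_factory=PSASettings)
    sensitivity: SensitivitySettings = field(default_factory=SensitivitySettings)

    def __post_init__(self) -> None:
        if self.n_comparator <= 0 or self.n_intervention <= 0:
            raise ValidationError("patient counts must be positive")

    def strategy(self, name: str) -> StrategyParams:
        for s in (self.comparator, self.intervention):
            if s.name == name:
                return s
        raise KeyError(name)


# --- configuration reading ------------------------------------------------

_STRATEGY_KEYS = {"n", "p_fir", "followup_months", "costs", "totals"}
_TOP_KEYS = {"strategies", "psa", "sensitivity"}


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing key '{key}' in {where}")
    return mapping[key]


def _reject_unknown(mapping: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _parse_strategy(name: str, raw: Mapping) -> tuple[StrategyParams, int]:
    _reject_unknown(raw, _STRATEGY_KEYS, f"strategies.{name}")
    costs_raw = dict(_require(raw, "costs", f"strategies.{name}"))
    known = {c.value for c in CostCategory}
    _reject_unknown(costs_raw, known, f"strategies.{name}.costs")
    try:
        costs = {CostCategory(k): float(v) for k, v in costs_raw.items()}
    except ValueError as exc:  # pragma: no cover - guarded by _reject_unknown
        raise ConfigError(str(exc)) from exc
    overrides = None
    if "totals" in raw and raw["totals"] is not None:
        totals = dict(raw["totals"])
        _reject_unknown(
            totals, {p.value for p in Perspective}, f"strategies.{name}.totals"
        )
        overrides = {Perspective(k): float(v) for k, v in totals.items()}
    profile = CostProfile(name.upper(), costs, overrides)
    params = StrategyParams(
        name=name.upper(),
        p_fir=float(_require(raw, "p_fir", f"strategies.{name}")),
        costs=profile,
        followup_months=float(_require(raw, "followup_months", f"strategies.{name}")),
    )
    return params, int(_require(raw, "n", f"strategies.{name}"))


def load_config(path: str | Path) -> DecisionModel:
    """Read and validate a YAML/JSON model configuration.

    Raises :class:`ConfigError` for missing or unknown keys and
    :class:`ValidationError` for out-of-range values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _reject_unknown(raw, _TOP_KEYS, "config")
    strategies = _require(raw, "strategies", "config")
    _reject_unknown(strategies, {"soc", "prp"}, "strategies")
    soc, n_soc = _parse_strategy("soc", _require(strategies, "soc", "strategies"))
    prp, n_prp = _parse_strategy("prp", _require(strategies, "prp", "strategies"))

    psa = PSASettings()
    if "psa" in raw and raw["psa"] is not None:
        _reject_unknown(raw["psa"], {"n_iter", "seed"}, "psa")
        psa = PSASettings(
            n_iter=int(raw["psa"].get("n_iter", psa.n_iter)),
            seed=int(raw["psa"].get("seed", psa.seed)),
        )
    sens = SensitivitySettings()
    if "sensitivity" in raw and raw["sensitivity"] is not None:
        _reject_unknown(
            raw["sensitivity"],
            {"cost_low_factor", "cost_high_factor", "prob_delta"},
            "sensitivity",
        )
        s = raw["sensitivity"]
        sens = SensitivitySettings(
            cost_low_factor=float(s.get("cost_low_factor", sens.cost_low_factor)),
            cost_high_factor=float(s.get("cost_high_factor", sens.cost_high_factor)),
            prob_delta=float(s.get("prob_delta", sens.prob_delta)),
        )
    return DecisionModel(
        comparator=soc,
        intervention=prp,
        n_comparator=n_soc,
        n_intervention=n_prp,
        psa=psa,
        sensitivity=sens,
    )


def paper_config_path() -> Path:
    """Path of the bundled published parameter set."""
    return Path(resources.files("refill_cea").joinpath("data/paper_params.yaml"))


def paper_model() -> DecisionModel:
    """The published base-case decision model (Table-3 parameter set)."""
    return load_config(paper_config_path())
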