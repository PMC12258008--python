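"""Uncertainty model and error-scenario set construction.

A scenario is one realization of the uncertainty model: a rigid setup shift
(mm, per axis), a range-error pair (absolute offset ``c_abs`` in mm and
relative factor ``c_rel``) applied to radiological depths as
``rd = rd_nominal * c_rel + c_abs``, a 4D phase index, and an importance
weight.  Scenario sets always carry normalized weights (sum 1 within 1e-12).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import NumericalError, ValidationError
from .phantoms import Phantom4D

__all__ = [
    "UncertaintyModel",
    "Scenario",
    "ScenarioSet",
    "sample_random_scenarios",
    "build_worstcase_scenarios",
    "compute_importance_weights",
    "build_4d_scenario_set",
    "nominal_scenario",
]


@dataclass(frozen=True)
class UncertaintyModel:
    """Gaussian setup/range uncertainty model.

    Defaults: 2.25 mm setup SD per axis, 1 mm absolute and 3.5% relative
    range SD; worst-case scenarios are collected at +-2 sigma.
    """

    sigma_setup: float = 2.25
    sigma_range_abs: float = 1.0
    sigma_range_rel: float = 0.035
    wc_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if min(self.sigma_setup, self.sigma_range_abs, self.sigma_range_rel) < 0:
            raise ValidationError("uncertainty sigmas must be >= 0")
        if self.wc_multiplier <= 0:
            raise ValidationError("wc_multiplier must be > 0")


@dataclass(frozen=True)
class Scenario:
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    c_abs: float = 0.0
    c_rel: float = 1.0
    phase: int = 0
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", tuple(float(s) for s in self.shift))
        if self.weight < 0:
            raise ValidationError("scenario weight must be >= 0")
        if self.c_rel <= 0:
            raise ValidationError("c_rel must be > 0")

    @property
    def is_nominal(self) -> bool:
        return (
            all(s == 0 for s in self.shift)
            and self.c_abs == 0
            and self.c_rel == 1
        )


def nominal_scenario(phase: int = 0, weight: float = 1.0) -> Scenario:
    return Scenario(phase=phase, weight=weight)


@dataclass
class ScenarioSet:
    scenarios: list[Scenario]
    sampling_mode: str = "random"
    seed: int | None = None
    pooling_mode: str | None = None

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValidationError("a scenario set may not be empty")
        w = self.weights
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("scenario weights must sum to 1 within 1e-12")

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.scenarios])


def sample_random_scenarios(
    n: int,
    model: UncertaintyModel = UncertaintyModel(),
    seed: int | None = None,
    phase: int = 0,
) -> ScenarioSet:
    """Draw n i.i.d. scenarios; all five error coordinates independent.

    Shift components ~ N(0, sigma_setup), c_abs ~ N(0, sigma_range_abs),
    c_rel ~ N(1, sigma_range_rel); uniform weights 1/n (random sampling
    already represents frequency, so every scenario counts equally).
    """
    if n < 1:
        raise ValidationError("need at least one scenario")
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, model.sigma_setup, size=(n, 3))
    c_abs = rng.normal(0.0, model.sigma_range_abs, size=n)
    c_rel = rng.normal(1.0, model.sigma_range_rel, size=n)
    c_rel = np.clip(c_rel, 1e-6, None)  # c_rel must stay positive
    scens = [
        Scenario(tuple(shifts[i]), float(c_abs[i]), float(c_rel[i]), phase, 1.0 / n)
        for i in range(n)
    ]
    return ScenarioSet(scens, sampling_mode="random", seed=seed)


def build_worstcase_scenarios(
    model: UncertaintyModel = UncertaintyModel(), phase: int = 0
) -> ScenarioSet:
    """Deterministic 29-scenario worst-case grid.

    26 setup shifts (all +-2 sigma / 0 combinations per axis except all-zero),
    2 pure range scenarios (simultaneous over-/under-shoot of the absolute
    and relative components at +-2 sigma), and the nominal scenario.  Weights
    follow the Gaussian density product (``compute_importance_weights``).
    """
    m = model.wc_multiplier
    amp = m * model.sigma_setup
    scens = [nominal_scenario(phase=phase)]
    for combo in itertools.product((-amp, 0.0, amp), repeat=3):
        if combo == (0.0, 0.0, 0.0):
            continue
        scens.append(Scenario(shift=combo, phase=phase))
    for sgn in (+1.0, -1.0):
        scens.append(
            Scenario(
                c_abs=sgn * m * model.sigma_range_abs,
                c_rel=1.0 + sgn * m * model.sigma_range_rel,
                phase=phase,
            )
        )
    sset = ScenarioSet(
        [replace(s, weight=1.0 / len(scens)) for s in scens],
        sampling_mode="worst_case",
    )
    return compute_importance_weights(sset, "worst_case", model)


def compute_importance_weights(
    scenario_set: ScenarioSet,
    mode: str,
    model: UncertaintyModel = UncertaintyModel(),
) -> ScenarioSet:
    """Assign normalized importance weights.

    random: uniform 1/n.  worst_case: weight proportional to the product of
    the per-component Gaussian densities at the scenario's coordinates
    (normalization constants cancel in the global normalization).
    """
    n = len(scenario_set)
    if mode == "random":
        w = np.full(n, 1.0 / n)
    elif mode == "worst_case":
        w = np.empty(n)
        for i, s in enumerate(scenario_set):
            dens = 1.0
            for comp in s.shift:
                dens *= stats.norm.pdf(comp, 0.0, model.sigma_setup)
            dens *= stats.norm.pdf(s.c_abs, 0.0, model.sigma_range_abs)
            dens *= stats.norm.pdf(s.c_rel, 1.0, model.sigma_range_rel)
            w[i] = dens
        if not np.any(w > 0):
            raise NumericalError("all scenario densities are zero")
        w = w / w.sum()
    else:
        raise ValidationError(f"unknown weighting mode {mode!r}")
    scens = [replace(s, weight=float(wi)) for s, wi in zip(scenario_set, w)]
    # renormalize exactly against accumulated rounding
    total = sum(s.weight for s in scens)
    scens = [replace(s, weight=s.weight / total) for s in scens]
    return ScenarioSet(
        scens, sampling_mode=scenario_set.sampling_mode, seed=scenario_set.seed
    )


def build_4d_scenario_set(
    phantom4d: Phantom4D,
    errors_per_phase: ScenarioSet,
    pooling_mode: str = "pooled",
) -> ScenarioSet:
    """Cartesian product of CT phases and error scenarios.

    Member weight = phase weight x error weight; the pooling mode tag
    ("pooled" or "within_phase") steers the downstream 4D accumulation.
    """
    if pooling_mode not in ("pooled", "within_phase"):
        raise ValidationError(f"unknown pooling mode {pooling_mode!r}")
    if phantom4d.n_phases < 1 or len(errors_per_phase) < 1:
        raise ValidationError("empty phases or error set")
    scens = []
    for k in range(phantom4d.n_phases):
        wk = float(phantom4d.phase_weights[k])
        for e in errors_per_phase:
            scens.append(replace(e, phase=k, weight=wk * e.weight))
    total = sum(s.weight for s in scens)
    scens = [replace(s, weight=s.weight / total) for s in scens]
    return ScenarioSet(
        scens,
        sampling_mode="grid_4d",
        seed=errors_per_phase.seed,
        pooling_mode=pooling_mode,
    )
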