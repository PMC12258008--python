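"""Objective/constraint zoo and the three fluence optimizers.

Modes
-----
scenario_free
    Dosimetric objectives are evaluated on the expected dose ``E[D] x``;
    robustness enters through ``mean_variance`` terms ``x^T Omega_v x / |v|``.
    One forward/adjoint product with E[D] plus one Omega product per variance
    term per evaluation — independent of the scenario count.
stochastic
    The scenario-weighted sum of per-scenario objective values (the
    traditional expected-value approach); one forward/adjoint product per
    scenario per evaluation.  ``mean_variance`` objectives are rejected here
    (they require Omega).
nominal
    A single (nominal) influence matrix with margin-based (PTV) objectives.

All dose objectives are normalized by the structure voxel count.  The solver
is projected quasi-Newton (L-BFGS-B) for the bound ``x >= 0``; constraints
are handled by an augmented-Lagrangian outer loop.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
import numpy as np
from scipy import optimize, sparse

from .exceptions import ValidationError
from .probabilistic import ProbabilisticModel

__all__ = [
    "ObjectiveSpec",
    "ConstraintSpec",
    "PlanProblem",
    "FluenceSolution",
    "eval_objective",
    "eval_constraint",
    "solve_plan",
    "dose_objective_value",
]

_OBJ_KINDS = {"sq_dev", "sq_over", "mean_dose", "max_dvh", "mean_variance"}
_CON_KINDS = {"mean_variance_max", "mean_dose_max"}


@dataclass(frozen=True)
class ObjectiveSpec:
    kind: str
    voi: str
    penalty: float
    dref: float = 0.0
    dvh_volume_pct: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _OBJ_KINDS:
            raise ValidationError(f"unknown objective kind {self.kind!r}")
        if self.penalty < 0:
            raise ValidationError("penalty must be >= 0")
        if self.dref < 0:
            raise ValidationError("dref must be >= 0")
        if self.kind == "max_dvh":
            if self.dvh_volume_pct is None or not 0 < self.dvh_volume_pct < 100:
                raise ValidationError("max_dvh needs dvh_volume_pct in (0, 100)")


@dataclass(frozen=True)
class ConstraintSpec:
    kind: str
    voi: str
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in _CON_KINDS:
            raise ValidationError(f"unknown constraint kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValidationError("constraint threshold must be > 0")


@dataclass
class PlanProblem:
    """Optimization problem: objectives + constraints on one substrate.

    substrate by mode: scenario_free -> ProbabilisticModel; stochastic ->
    list of (DoseInfluence | sparse matrix, weight); nominal -> one matrix.
    ``structures`` maps VOI name -> flat voxel indices; for 4D stochastic
    problems ``scenario_structures`` gives one such map per scenario.
    """

    objectives: list[ObjectiveSpec]
    mode: str
    substrate: object
    structures: dict[str, np.ndarray]
    constraints: list[ConstraintSpec] = field(default_factory=list)
    scenario_structures: list[dict[str, np.ndarray]] | None = None
    l2_reg: float = 0.0
    maxiter: int = 1000
    ftol: float = 1e-12
    gtol: float = 1e-7
    store_iterates: bool = False

    def __post_init__(self) -> None:
        if not self.objectives:
            raise ValidationError("at least one objective required")
        if self.mode not in ("scenario_free", "stochastic", "nominal"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "scenario_free" and not isinstance(
            self.substrate, ProbabilisticModel
        ):
            raise ValidationError("scenario_free mode needs a ProbabilisticModel")
        if self.mode != "scenario_free":
            for spec in self.objectives:
                if spec.kind == "mean_variance":
                    raise ValidationError(
                        "mean_variance objectives require scenario_free mode"
                    )
            if self.constraints and any(
                c.kind == "mean_variance_max" for c in self.constraints
            ):
                raise ValidationError(
                    "mean_variance_max constraints require scenario_free mode"
                )


@dataclass
class FluenceSolution:
    x: np.ndarray
    objective_trace: list[float]
    iteration_times: list[float]
    status: str
    n_iterations: int
    constraint_residuals: dict[int, float] = field(default_factory=dict)
    product_counts: dict[str, int] = field(default_factory=dict)
    n_evaluations: int = 0
    iterates: list[np.ndarray] | None = None

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def tpi(self) -> float:
        """Mean wall time per optimizer iteration (s)."""
        if not self.iteration_times:
            raise ValidationError("empty iteration log")
        return float(np.mean(self.iteration_times))


# ---------------------------------------------------------------------------
# objective / constraint primitives
# ---------------------------------------------------------------------------

def dose_objective_value(
    spec: ObjectiveSpec, d_voi: np.ndarray
) -> tuple[float, np.ndarray]:
    """Value and gradient (w.r.t. the structure dose vector) of a dose objective."""
    n = d_voi.size
    if n == 0:
        raise ValidationError(f"structure {spec.voi!r} is empty")
    g = np.zeros(n)
    if spec.kind == "sq_dev":
        r = d_voi - spec.dref
        return float(r @ r) / n, 2.0 * r / n
    if spec.kind == "sq_over":
        r = np.maximum(d_voi - spec.dref, 0.0)
        return float(r @ r) / n, 2.0 * r / n
    if spec.kind == "mean_dose":
        m = float(d_voi.mean()) - spec.dref
        g[:] = 2.0 * m / n
        return m * m, g
    if spec.kind == "max_dvh":
        # volume above dref must fall to dvh_volume_pct; penalize the excess
        # voxels coldest-first (the cheapest ones to push below dref).
        above = np.flatnonzero(d_voi > spec.dref)
        allowed = int(np.floor(spec.dvh_volume_pct / 100.0 * n))
        excess = above.size - allowed
        if excess <= 0:
            return 0.0, g
        coldest = above[np.argsort(d_voi[above], kind="stable")[:excess]]
        r = d_voi[coldest] - spec.dref
        g[coldest] = 2.0 * r / n
        return float(r @ r) / n, g
    raise ValidationError(f"{spec.kind!r} is not a dose-based objective")


def eval_objective(
    spec: ObjectiveSpec,
    dose_or_model: np.ndarray | ProbabilisticModel,
    x: np.ndarray | None = None,
    structures: dict[str, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Evaluate one objective.

    Dose-based kinds take a full dose vector plus ``structures`` and return
    the gradient w.r.t. dose (nonzero only on the structure).  The
    ``mean_variance`` kind takes a ProbabilisticModel plus ``x`` and returns
    the gradient w.r.t. fluence.
    """
    if spec.kind == "mean_variance":
        model: ProbabilisticModel = dose_or_model  # type: ignore[assignment]
        size = model.voi_sizes[spec.voi]
        val = model.total_variance(spec.voi, x) / size
        grad = model.variance_gradient(spec.voi, x) / size
        return val, grad
    dose = np.asarray(dose_or_model, dtype=float).ravel()
    idx = structures[spec.voi]
    val, gv = dose_objective_value(spec, dose[idx])
    g = np.zeros_like(dose)
    g[idx] = gv
    return val, g


def eval_constraint(
    spec: ConstraintSpec,
    model: ProbabilisticModel,
    x: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Residual (feasible iff <= 0) and its gradient w.r.t. fluence."""
    x = np.asarray(x, dtype=float).ravel()
    size = model.voi_sizes.get(spec.voi)
    if spec.kind == "mean_variance_max":
        val = model.total_variance(spec.voi, x) / size - spec.threshold
        jac = model.variance_gradient(spec.voi, x) / size
        return val, jac
    # mean_dose_max on the expected dose
    idx = model.vois[spec.voi]
    if isinstance(idx, dict):
        raise ValidationError("mean_dose_max needs a static structure")
    rows = model.expected_influence[np.asarray(idx, dtype=np.int64)]
    mean_row = np.asarray(rows.mean(axis=0)).ravel()
    return float(mean_row @ x) - spec.threshold, mean_row


# ---------------------------------------------------------------------------
# global objective closures
# ---------------------------------------------------------------------------

class _GlobalObjective:
    """Mode-specific global weighted-sum objective with product counters."""

    def __init__(self, problem: PlanProblem):
        self.p = problem
        self.counters = {"forward": 0, "adjoint": 0, "omega": 0, "evals": 0}
        if problem.mode == "stochastic":
            subs = []
            for item in problem.substrate:
                mat, w = item
                mat = getattr(mat, "matrix", mat)
                subs.append((sparse.csr_matrix(mat), float(w)))
            self._scen = subs
        elif problem.mode == "nominal":
            mat = getattr(problem.substrate, "matrix", problem.substrate)
            self._scen = [(sparse.csr_matrix(mat), 1.0)]
        else:
            self._model: ProbabilisticModel = problem.substrate  # type: ignore

    def __call__(self, x: np.ndarray, count: bool = True) -> tuple[float, np.ndarray]:
        if count:
            self.counters["evals"] += 1
        if self.p.mode == "scenario_free":
            val, grad = self._scenario_free(x, count)
        else:
            val, grad = self._scenario_sum(x, count)
        if self.p.l2_reg:
            val += self.p.l2_reg * float(x @ x)
            grad = grad + 2.0 * self.p.l2_reg * x
        return val, grad

    def value(self, x: np.ndarray) -> float:
        return self(x, count=False)[0]

    def _scenario_free(self, x, count):
        model = self._model
        d = model.expected_dose(x)
        if count:
            self.counters["forward"] += 1
        val = 0.0
        gdose = np.zeros_like(d)
        gx = np.zeros_like(x, dtype=float)
        for spec in self.p.objectives:
            if spec.kind == "mean_variance":
                size = model.voi_sizes[spec.voi]
                val += spec.penalty * model.total_variance(spec.voi, x) / size
                gx += spec.penalty * model.variance_gradient(spec.voi, x) / size
                if count:
                    self.counters["omega"] += 1
            else:
                idx = self.p.structures[spec.voi]
                v, gv = dose_objective_value(spec, d[idx])
                val += spec.penalty * v
                gdose[idx] += spec.penalty * gv
        grad = model.expected_influence.T @ gdose + gx
        if count:
            self.counters["adjoint"] += 1
        return val, np.asarray(grad).ravel()

    def _scenario_sum(self, x, count):
        val = 0.0
        grad = np.zeros_like(x, dtype=float)
        for i, (mat, w) in enumerate(self._scen):
            structures = self.p.structures
            if self.p.scenario_structures is not None:
                structures = self.p.scenario_structures[i]
            d = mat @ x
            if count:
                self.counters["forward"] += 1
            gdose = np.zeros_like(d)
            for spec in self.p.objectives:
                idx = structures[spec.voi]
                v, gv = dose_objective_value(spec, d[idx])
                val += w * spec.penalty * v
                gdose[idx] += w * spec.penalty * gv
            grad += mat.T @ gdose
            if count:
                self.counters["adjoint"] += 1
        return val, grad


def default_initial_fluence(problem: PlanProblem) -> np.ndarray:
    """Uniform fluence scaled so the (expected/nominal) target mean hits dref."""
    if problem.mode == "scenario_free":
        model: ProbabilisticModel = problem.substrate  # type: ignore
        mat = model.expected_influence
        nb = model.n_beamlets
    elif problem.mode == "nominal":
        mat = sparse.csr_matrix(getattr(problem.substrate, "matrix", problem.substrate))
        nb = mat.shape[1]
    else:
        mat = sparse.csr_matrix(
            getattr(problem.substrate[0][0], "matrix", problem.substrate[0][0])
        )
        nb = mat.shape[1]
    x0 = np.ones(nb)
    target_specs = [
        s for s in problem.objectives if s.kind in ("sq_dev", "sq_over") and s.dref > 0
    ]
    if target_specs:
        spec = max(target_specs, key=lambda s: s.dref)
        idx = problem.structures[spec.voi]
        mean0 = float((mat[idx] @ x0).mean())
        if mean0 > 0:
            x0 *= spec.dref / mean0
    return x0


def _run_lbfgsb(fun, x0, problem, log):
    """Projected quasi-Newton descent with per-iteration logging."""
    t_last = [time.perf_counter()]

    def wrapped(x):
        return fun(x)

    def cb(xk):
        now = time.perf_counter()
        log["times"].append(now - t_last[0])
        t_last[0] = now
        log["trace"].append(fun(xk, count=False)[0])
        if problem.store_iterates:
            log["iterates"].append(xk.copy())

    res = optimize.minimize(
        wrapped,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size,
        callback=cb,
        options={
            "maxiter": problem.maxiter,
            "ftol": problem.ftol,
            "gtol": problem.gtol,
            "maxcor": 20,
        },
    )
    return res


def solve_plan(problem: PlanProblem, x0: np.ndarray | None = None) -> FluenceSolution:
    """Optimize nonnegative beamlet fluences for a plan problem.

    Unconstrained problems run one projected quasi-Newton descent;
    constrained problems wrap it in an augmented-Lagrangian outer loop until
    every residual satisfies ``c <= 1e-3 * threshold``.  Non-convergence is
    reported through ``FluenceSolution.status``, not raised.
    """
    obj = _GlobalObjective(problem)
    if x0 is None:
        x0 = default_initial_fluence(problem)
    x0 = np.maximum(np.asarray(x0, dtype=float).ravel(), 0.0)

    log = {"trace": [obj.value(x0)], "times": [], "iterates": [x0.copy()]}
    if not problem.constraints:
        res = _run_lbfgsb(obj, x0, problem, log)
        status = "converged" if res.success or res.status == 1 else "not_converged"
        return FluenceSolution(
            x=res.x,
            objective_trace=log["trace"],
            iteration_times=log["times"],
            status=status,
            n_iterations=int(res.nit),
            product_counts=dict(obj.counters),
            n_evaluations=obj.counters["evals"],
            iterates=log["iterates"] if problem.store_iterates else None,
        )

    # augmented Lagrangian for inequality constraints c(x) <= 0
    model: ProbabilisticModel = problem.substrate  # type: ignore
    cons = problem.constraints
    lam = np.zeros(len(cons))
    f0 = abs(log["trace"][0]) + 1.0
    rho = np.array([f0 / max(c.threshold, 1e-12) ** 2 for c in cons])
    rho = np.clip(rho, 1.0, 1e12)
    x = x0
    n_iter = 0
    residuals = {}
    status = "not_converged"
    for outer in range(12):
        def al_fun(xv, count=True, _lam=lam.copy(), _rho=rho.copy()):
            val, grad = obj(xv, count=count)
            for j, c in enumerate(cons):
                cv, cj = eval_constraint(c, model, xv)
                t = _lam[j] + _rho[j] * cv
                if t > 0:
                    val += (t * t - _lam[j] ** 2) / (2.0 * _rho[j])
                    grad = grad + t * cj
                else:
                    val -= _lam[j] ** 2 / (2.0 * _rho[j])
            return val, grad

        res = _run_lbfgsb(al_fun, x, problem, log)
        x = res.x
        n_iter += int(res.nit)
        cvals = np.array([eval_constraint(c, model, x)[0] for c in cons])
        residuals = {j: float(cv) for j, cv in enumerate(cvals)}
        if all(
            cv <= 1e-3 * c.threshold for cv, c in zip(cvals, cons)
        ):
            status = "converged"
            break
        lam = np.maximum(0.0, lam + rho * cvals)
        rho = np.where(cvals > 1e-3 * np.array([c.threshold for c in cons]),
                       rho * 10.0, rho)

    return FluenceSolution(
        x=x,
        objective_trace=log["trace"],
        iteration_times=log["times"],
        status=status,
        n_iterations=n_iter,
        constraint_residuals=residuals,
        product_counts=dict(obj.counters),
        n_evaluations=obj.counters["evals"],
        iterates=log["iterates"] if problem.store_iterates else None,
    )
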