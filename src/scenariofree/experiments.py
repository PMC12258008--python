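"""End-to-end desk-scale experiment drivers on the synthetic box phantoms.

The :class:`BoxStudy` pipeline reproduces, at desk scale, the canonical
validation studies of scenario-free robust optimization:

* ``validation``  — pure penalized least-squares objectives; the scenario-free
  and the traditional stochastic optimizers are then mathematically
  equivalent and their expected-dose and SD maps are compared by gamma
  analysis (plus a nominal non-robust reference plan);
* ``constrained`` — scenario-free optimization under a mean-variance upper
  bound on the target;
* ``sampling``    — scenario-free plans accumulated from nested random
  training pools of growing size, evaluated on one shared pool.

Study conditions (fixed defaults): 120 mm water box at 3 mm spacing (40^3
voxels), 36 mm cubic target, distal OAR, two proton fields at 0/90 deg,
9 random training scenarios, 100-scenario random evaluation pool, 60 Gy
prescription.  Penalties: target 100, OAR 10, with matching mean-variance
penalties per structure.  A 1e-7 L2 fluence regularizer (identical across
modes) makes the convex validation problem's minimizer unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .dose import Beam, KernelParams, PencilBeamEngine
from .evaluation import (
    GammaCriteria,
    gamma_pass_rate,
    measure_tpi,
    scenario_analysis,
)
from .phantoms import (
    Phantom4D,
    build_itv,
    expand_margin,
    make_4d_box,
    make_box_phantom,
)
from .planning import (
    ConstraintSpec,
    ObjectiveSpec,
    PlanProblem,
    solve_plan,
)
from .probabilistic import PhaseAccumulator, accumulate, combine_phase_accumulators
from .scenarios import (
    ScenarioSet,
    UncertaintyModel,
    build_4d_scenario_set,
    build_worstcase_scenarios,
    nominal_scenario,
    sample_random_scenarios,
)

__all__ = ["BoxStudy", "FourDBoxStudy"]

_EVAL_SEED_OFFSET = 7919  # evaluation pools use a seed distinct from training

P_TARGET = 100.0
P_OAR = 10.0
L2_REG = 1e-7
PRESCRIPTION = 60.0
OAR_OVER_DREF = 30.0


@dataclass
class BoxStudy:
    """Shared 3D box-phantom workspace with lazily computed heavy pieces."""

    seed: int = 1
    n_train: int = 9
    n_eval: int = 100
    uncertainty: UncertaintyModel = field(default_factory=UncertaintyModel)
    kernel: KernelParams = field(default_factory=KernelParams)

    @cached_property
    def phantom(self):
        return make_box_phantom()

    @cached_property
    def beams(self) -> list[Beam]:
        grid, _ = self.phantom
        iso = tuple(d * s / 2.0 for d, s in zip(grid.dims, grid.spacing))
        return [
            Beam("proton", 0.0, iso),
            Beam("proton", 90.0, iso),
        ]

    @cached_property
    def engine(self) -> PencilBeamEngine:
        return PencilBeamEngine([self.phantom], self.beams, self.kernel,
                                reference_phase=0)

    @cached_property
    def structures(self) -> dict[str, np.ndarray]:
        return dict(self.phantom[1].structures)

    @cached_property
    def training_set(self) -> ScenarioSet:
        return sample_random_scenarios(self.n_train, self.uncertainty,
                                       seed=self.seed)

    @cached_property
    def eval_set(self) -> ScenarioSet:
        return sample_random_scenarios(self.n_eval, self.uncertainty,
                                       seed=self.seed + _EVAL_SEED_OFFSET)

    @cached_property
    def training_influences(self):
        return [
            (self.engine.influence(s).matrix, s.weight) for s in self.training_set
        ]

    @cached_property
    def model(self):
        vois = {"target": self.structures["target"], "oar": self.structures["oar"]}
        return accumulate(iter(self.training_influences), vois)

    # -- problem builders --------------------------------------------------
    def ls_objectives_sf(self) -> list[ObjectiveSpec]:
        """Pure penalized least squares plus the matching variance terms."""
        return [
            ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("mean_variance", "target", P_TARGET),
            ObjectiveSpec("sq_dev", "oar", P_OAR, 0.0),
            ObjectiveSpec("mean_variance", "oar", P_OAR),
        ]

    def ls_objectives_dose(self) -> list[ObjectiveSpec]:
        return [
            ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("sq_dev", "oar", P_OAR, 0.0),
        ]

    def problem_scenario_free(self, objectives=None, constraints=(),
                              store_iterates=False) -> PlanProblem:
        return PlanProblem(
            objectives=objectives or self.ls_objectives_sf(),
            constraints=list(constraints),
            mode="scenario_free",
            substrate=self.model,
            structures=self.structures,
            l2_reg=L2_REG,
            store_iterates=store_iterates,
        )

    def problem_stochastic(self) -> PlanProblem:
        return PlanProblem(
            objectives=self.ls_objectives_dose(),
            mode="stochastic",
            substrate=self.training_influences,
            structures=self.structures,
            l2_reg=L2_REG,
        )

    def problem_nominal(self) -> PlanProblem:
        D_nom = self.engine.influence(nominal_scenario()).matrix
        return PlanProblem(
            objectives=self.ls_objectives_dose(),
            mode="nominal",
            substrate=D_nom,
            structures=self.structures,
            l2_reg=L2_REG,
        )

    # -- experiments -------------------------------------------------------
    def validation(self, n_identity_iterates: int = 20) -> dict:
        """Scenario-free vs stochastic equivalence under pure least squares.

        Returns gamma pass rates between the two expected-dose and SD maps,
        per-plan robustness reports, the objective-identity record at shared
        iterates, and the TPI table.
        """
        from .planning import _GlobalObjective  # shared closure, counted off

        prob_sf = self.problem_scenario_free(store_iterates=True)
        prob_st = self.problem_stochastic()
        sol_sf = solve_plan(prob_sf)
        sol_st = solve_plan(prob_st)
        sol_nom = solve_plan(self.problem_nominal())

        reports = scenario_analysis(
            {
                "scenario_free": sol_sf.x,
                "stochastic": sol_st.x,
                "nominal": sol_nom.x,
            },
            self.eval_set,
            self.engine,
            structure_names=["target", "oar"],
        )
        grid = self.phantom[0]
        crit = GammaCriteria()
        gamma_dose = gamma_pass_rate(
            reports["scenario_free"].expected_volume(),
            reports["stochastic"].expected_volume(),
            grid.spacing,
            crit,
        )
        gamma_sd = gamma_pass_rate(
            reports["scenario_free"].sd_volume(),
            reports["stochastic"].sd_volume(),
            grid.spacing,
            crit,
        )

        # objective identity at shared iterates
        f_sf = _GlobalObjective(prob_sf)
        f_st = _GlobalObjective(prob_st)
        iters = sol_sf.iterates or [sol_sf.x]
        pick = np.unique(
            np.linspace(0, len(iters) - 1, n_identity_iterates).astype(int)
        )
        identity = []
        for k in pick:
            xk = iters[k]
            v1 = f_sf(xk, count=False)[0]
            v2 = f_st(xk, count=False)[0]
            identity.append(
                {"iterate": int(k), "sf": v1, "stochastic": v2,
                 "rel_diff": abs(v1 - v2) / max(abs(v1), abs(v2), 1e-300)}
            )

        tpi = measure_tpi(
            {"scenario_free": sol_sf, "stochastic": sol_st, "nominal": sol_nom},
            reference="nominal",
        )
        return {
            "gamma_dose": gamma_dose,
            "gamma_sd": gamma_sd,
            "reports": reports,
            "identity": identity,
            "tpi": tpi,
            "solutions": {
                "scenario_free": sol_sf,
                "stochastic": sol_st,
                "nominal": sol_nom,
            },
        }

    def constrained(self, thresholds=(2.9e-2, 2.9e-3)) -> dict:
        """Mean-variance-constrained scenario-free plans, one per threshold.

        For each threshold the target carries a squared-deviation objective
        and a mean-variance upper bound; the OAR keeps its least-squares and
        variance objectives.
        """
        sols = {}
        for tau in thresholds:
            objectives = [
                ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
                ObjectiveSpec("sq_dev", "oar", P_OAR, 0.0),
                ObjectiveSpec("mean_variance", "oar", P_OAR),
            ]
            prob = self.problem_scenario_free(
                objectives=objectives,
                constraints=[ConstraintSpec("mean_variance_max", "target", tau)],
            )
            sols[tau] = solve_plan(prob)
        reports = scenario_analysis(
            {str(tau): sol.x for tau, sol in sols.items()},
            self.eval_set, self.engine, structure_names=["target"],
        )
        return {
            tau: {
                "solution": sol,
                "achieved_mean_variance": self.model.mean_variance(
                    "target", sol.x
                ),
                "target_mean_sd": reports[str(tau)].structures["target"].mean_sd,
                "report": reports[str(tau)],
            }
            for tau, sol in sols.items()
        }

    def sampling(self, sizes=(5, 29, 50, 100)) -> dict:
        """Sample-size analysis with nested training pools.

        One seeded pool of max(sizes) scenarios is drawn; size-k training
        uses its first k members with uniform weights, isolating the
        sample-size effect from draw-to-draw noise.  All plans share the
        evaluation pool.
        """
        pool = sample_random_scenarios(max(sizes), self.uncertainty,
                                       seed=self.seed)
        objectives = [
            ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("mean_variance", "target", P_TARGET),
            ObjectiveSpec("sq_over", "oar", P_OAR, OAR_OVER_DREF),
            ObjectiveSpec("mean_variance", "oar", P_OAR),
        ]
        vois = {"target": self.structures["target"], "oar": self.structures["oar"]}
        sols = {}
        for k in sizes:
            stream = (
                (self.engine.influence(s).matrix, 1.0 / k)
                for s in list(pool)[:k]
            )
            model = accumulate(stream, vois)
            prob = PlanProblem(
                objectives=objectives,
                mode="scenario_free",
                substrate=model,
                structures=self.structures,
                l2_reg=L2_REG,
            )
            sols[k] = solve_plan(prob)
        reports = scenario_analysis(
            {str(k): sol.x for k, sol in sols.items()},
            self.eval_set, self.engine, structure_names=["target"],
        )
        return {
            k: {
                "solution": sol,
                "target_mean_sd": reports[str(k)].structures["target"].mean_sd,
            }
            for k, sol in sols.items()
        }

    def worstcase_vs_random(self) -> dict:
        """Scenario-free plans from 29 worst-case vs 29 random scenarios."""
        vois = {"target": self.structures["target"], "oar": self.structures["oar"]}
        objectives = [
            ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("mean_variance", "target", P_TARGET),
            ObjectiveSpec("sq_over", "oar", P_OAR, OAR_OVER_DREF),
            ObjectiveSpec("mean_variance", "oar", P_OAR),
        ]
        out = {}
        sets = {
            "worst_case": build_worstcase_scenarios(self.uncertainty),
            "random": sample_random_scenarios(29, self.uncertainty,
                                              seed=self.seed),
        }
        for name, sset in sets.items():
            stream = ((self.engine.influence(s).matrix, s.weight) for s in sset)
            model = accumulate(stream, vois)
            prob = PlanProblem(
                objectives=objectives, mode="scenario_free", substrate=model,
                structures=self.structures, l2_reg=L2_REG,
            )
            sol = solve_plan(prob)
            report = scenario_analysis(
                sol.x, self.eval_set, self.engine, structure_names=["target", "oar"]
            )
            out[name] = {
                "solution": sol,
                "target_mean_sd": report.structures["target"].mean_sd,
                "oar_mean_sd": report.structures["oar"].mean_sd,
            }
        return out


@dataclass
class FourDBoxStudy:
    """10-phase 4D box with rigid 3 mm-step motion; proton fields 0/90 deg.

    Training combines each phase with ``n_errors_per_phase`` random error
    scenarios; accumulation supports both the pooled and the within-phase
    strategies related by the law of total variance.
    """

    seed: int = 1
    n_phases: int = 10
    step_mm: float = 3.0
    n_errors_per_phase: int = 3
    n_eval_errors: int = 10
    itv_margin_mm: float = 4.0
    uncertainty: UncertaintyModel = field(default_factory=UncertaintyModel)
    kernel: KernelParams = field(default_factory=KernelParams)

    @cached_property
    def phantom4d(self) -> Phantom4D:
        return make_4d_box(make_box_phantom(), self.n_phases, self.step_mm, axis=0)

    @cached_property
    def beams(self) -> list[Beam]:
        grid = self.phantom4d.phases[0][0]
        iso = tuple(d * s / 2.0 for d, s in zip(grid.dims, grid.spacing))
        return [Beam("proton", 0.0, iso), Beam("proton", 90.0, iso)]

    @cached_property
    def engine(self) -> PencilBeamEngine:
        return PencilBeamEngine(
            list(self.phantom4d.phases), self.beams, self.kernel,
            reference_phase=self.phantom4d.reference_index,
        )

    @cached_property
    def vois(self) -> dict:
        """Phase-dependent CTV rows (aligned by the rigid shifts) + static OAR."""
        target = {
            k: sset.structures["target"]
            for k, (_, sset) in enumerate(self.phantom4d.phases)
        }
        oar = {
            k: sset.structures["oar"]
            for k, (_, sset) in enumerate(self.phantom4d.phases)
        }
        return {"target": target, "oar": oar}

    @cached_property
    def training_set(self) -> ScenarioSet:
        errors = sample_random_scenarios(
            self.n_errors_per_phase, self.uncertainty, seed=self.seed
        )
        return build_4d_scenario_set(self.phantom4d, errors, "pooled")

    @cached_property
    def eval_set(self) -> ScenarioSet:
        errors = sample_random_scenarios(
            self.n_eval_errors, self.uncertainty,
            seed=self.seed + _EVAL_SEED_OFFSET,
        )
        return build_4d_scenario_set(self.phantom4d, errors, "pooled")

    def model(self, mode: str = "pooled"):
        accs = []
        errors = sample_random_scenarios(
            self.n_errors_per_phase, self.uncertainty, seed=self.seed
        )
        for k in range(self.phantom4d.n_phases):
            acc = PhaseAccumulator(self.vois)
            for e in errors:
                scen = replace(e, phase=k)
                acc.add(self.engine.influence(scen), e.weight, phase=k)
            accs.append(acc)
        return combine_phase_accumulators(
            accs, self.phantom4d.phase_weights, mode
        )

    def reference_structures(self) -> dict[str, np.ndarray]:
        return dict(self.phantom4d.reference[1].structures)

    def ptv(self) -> np.ndarray:
        grid = self.phantom4d.phases[0][0]
        itv = build_itv(self.phantom4d, "target")
        return expand_margin(itv, self.itv_margin_mm, grid)

    def plan_scenario_free(self, mode: str = "pooled"):
        model = self.model(mode)
        objectives = [
            ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("mean_variance", "target", P_TARGET),
            ObjectiveSpec("sq_over", "oar", P_OAR, OAR_OVER_DREF),
            ObjectiveSpec("mean_variance", "oar", P_OAR),
        ]
        prob = PlanProblem(
            objectives=objectives,
            mode="scenario_free",
            substrate=model,
            structures=self.reference_structures(),
            l2_reg=L2_REG,
        )
        return solve_plan(prob)

    def plan_stochastic(self):
        subs = [
            (self.engine.influence(s).matrix, s.weight) for s in self.training_set
        ]
        scen_structs = []
        for s in self.training_set:
            sset = self.phantom4d.phases[s.phase][1]
            scen_structs.append(dict(sset.structures))
        objectives = [
            ObjectiveSpec("sq_dev", "target", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("sq_over", "oar", P_OAR, OAR_OVER_DREF),
        ]
        prob = PlanProblem(
            objectives=objectives,
            mode="stochastic",
            substrate=subs,
            structures=self.reference_structures(),
            scenario_structures=scen_structs,
            l2_reg=L2_REG,
        )
        return solve_plan(prob)

    def plan_margin_based(self):
        """Nominal optimization of the PTV (ITV + margin) on the reference CT."""
        ref_phase = self.phantom4d.reference_index
        D_nom = self.engine.influence(nominal_scenario(phase=ref_phase)).matrix
        structures = self.reference_structures()
        structures["ptv"] = self.ptv()
        objectives = [
            ObjectiveSpec("sq_dev", "ptv", P_TARGET, PRESCRIPTION),
            ObjectiveSpec("sq_over", "oar", P_OAR, OAR_OVER_DREF),
        ]
        prob = PlanProblem(
            objectives=objectives,
            mode="nominal",
            substrate=D_nom,
            structures=structures,
            l2_reg=L2_REG,
        )
        return solve_plan(prob)

    def compare(self) -> dict:
        sols = {
            "scenario_free": self.plan_scenario_free("pooled"),
            "scenario_free_within": self.plan_scenario_free("within_phase"),
            "stochastic": self.plan_stochastic(),
            "margin_based": self.plan_margin_based(),
        }
        reports = scenario_analysis(
            {k: s.x for k, s in sols.items()},
            self.eval_set,
            self.engine,
            structure_names=["target", "oar"],
        )
        tpi = measure_tpi(sols, reference="margin_based")
        return {"solutions": sols, "reports": reports, "tpi": tpi}
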