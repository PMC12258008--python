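"""Post-optimization robustness analysis.

Recomputes per-scenario doses for an optimized fluence vector, derives the
expected dose and the voxelwise dose SD (weighted population variance, no
Bessel correction — consistent with the importance-weight formalism), and
summarizes robustness via DVH bands, SDVH curves, gamma pass rates and
time-per-iteration (TPI) accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .dose import PencilBeamEngine
from .exceptions import ValidationError
from .planning import FluenceSolution
from .scenarios import ScenarioSet

__all__ = [
    "DVHCurve",
    "SDVHCurve",
    "GammaCriteria",
    "StructureRobustness",
    "RobustnessReport",
    "compute_dvh",
    "compute_sdvh",
    "gamma_pass_rate",
    "scenario_analysis",
    "measure_tpi",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: volume (%) receiving >= axis dose."""

    axis: np.ndarray
    volume_pct: np.ndarray
    structure: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volume_pct, dtype=float)
        if v.size and (v.min() < -1e-9 or v.max() > 100 + 1e-9):
            raise ValidationError("volume fraction must lie in [0, 100]")
        if v.size and np.any(np.diff(v) > 1e-9):
            raise ValidationError("DVH must be monotone non-increasing")

    def at(self, value: float) -> float:
        """Volume % at one axis value (step-function lookup)."""
        k = np.searchsorted(self.axis, value, side="right") - 1
        return float(self.volume_pct[max(k, 0)])


SDVHCurve = DVHCurve  # SD-volume histograms share the cumulative convention


@dataclass(frozen=True)
class GammaCriteria:
    """Global gamma criteria; dose_diff and low_dose_threshold are % of the
    reference maximum."""

    dta: float = 1.0
    dose_diff: float = 1.0
    low_dose_threshold: float = 1.0
    subsample_factor: int = 3

    def __post_init__(self) -> None:
        if min(self.dta, self.dose_diff, self.low_dose_threshold) <= 0:
            raise ValidationError("gamma criteria must be positive")
        if self.subsample_factor < 1:
            raise ValidationError("subsample_factor must be >= 1")


def _cumulative_curve(values: np.ndarray, bin_width: float,
                      max_value: float | None, structure: str) -> DVHCurve:
    if values.size == 0:
        raise ValidationError("empty structure")
    if bin_width <= 0:
        raise ValidationError("bin width must be > 0")
    top = max_value if max_value is not None else float(values.max())
    axis = np.arange(0.0, top + 2 * bin_width, bin_width)
    pct = 100.0 * (values[None, :] >= axis[:, None]).mean(axis=1)
    return DVHCurve(axis=axis, volume_pct=pct, structure=structure)


def compute_dvh(
    dose: np.ndarray,
    voi: np.ndarray,
    bin_width: float = 0.1,
    max_value: float | None = None,
    structure: str = "",
) -> DVHCurve:
    """Cumulative DVH of one dose distribution over one structure."""
    d = np.asarray(dose, dtype=float).ravel()
    return _cumulative_curve(d[np.asarray(voi, dtype=np.int64)], bin_width,
                             max_value, structure)


def compute_sdvh(
    sd_map: np.ndarray,
    voi: np.ndarray,
    bin_width: float = 0.02,
    max_value: float | None = None,
    structure: str = "",
) -> tuple[SDVHCurve, float]:
    """Cumulative SD-volume histogram and the structure-mean SD."""
    s = np.asarray(sd_map, dtype=float).ravel()[np.asarray(voi, dtype=np.int64)]
    return (
        _cumulative_curve(s, bin_width, max_value, structure),
        float(s.mean()),
    )


def gamma_pass_rate(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing: tuple[float, float, float],
    criteria: GammaCriteria = GammaCriteria(),
) -> float:
    """Global 3D gamma pass rate (%) of ``evaluated`` against ``reference``.

    Dose difference is normalized to ``dose_diff`` % of the reference
    maximum; only reference voxels above ``low_dose_threshold`` % of that
    maximum are considered.  The evaluated distribution is trilinearly
    interpolated on a sub-voxel offset lattice (``spacing /
    subsample_factor`` steps) within a search radius of 3 x dta; a voxel
    passes iff min gamma <= 1.  Asymmetric in (reference, evaluated).
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape or ref.ndim != 3:
        raise ValidationError("reference and evaluated must share one 3D grid")
    sp = np.asarray(spacing, dtype=float)
    dmax = float(ref.max())
    if dmax <= 0:
        raise ValidationError("reference distribution has no positive dose")
    dd = criteria.dose_diff / 100.0 * dmax
    thr = criteria.low_dose_threshold / 100.0 * dmax

    considered = np.flatnonzero(ref.ravel() > thr)
    if considered.size == 0:
        raise ValidationError("no reference voxels above the low-dose threshold")
    coords = np.array(np.unravel_index(considered, ref.shape), dtype=float)
    ref_vals = ref.ravel()[considered]

    radius = 3.0 * criteria.dta
    steps = [sp[a] / criteria.subsample_factor for a in range(3)]
    offs_axes = [
        np.arange(-int(np.floor(radius / st)), int(np.floor(radius / st)) + 1) * st
        for st in steps
    ]
    gx, gy, gz = np.meshgrid(*offs_axes, indexing="ij")
    offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    offs, dist = offs[order], dist[order]

    remaining = np.arange(considered.size)
    for off, r in zip(offs, dist):
        if remaining.size == 0:
            break
        dist_term = (r / criteria.dta) ** 2
        if dist_term > 1.0:
            break  # farther offsets cannot bring gamma below 1
        pts = coords[:, remaining] + (off / sp)[:, None]
        ev_vals = map_coordinates(ev, pts, order=1, mode="nearest")
        g2 = ((ref_vals[remaining] - ev_vals) / dd) ** 2 + dist_term
        remaining = remaining[g2 > 1.0]
    return 100.0 * (considered.size - remaining.size) / considered.size


@dataclass
class StructureRobustness:
    dvh_expected: DVHCurve
    band_lo_5: np.ndarray
    band_lo_25: np.ndarray
    band_hi_75: np.ndarray
    band_hi_95: np.ndarray
    dvh_axis: np.ndarray
    sdvh: SDVHCurve
    mean_sd: float

    def __post_init__(self) -> None:
        if np.any(self.band_lo_5 > self.band_lo_25 + 1e-9) or np.any(
            self.band_hi_95 < self.band_hi_75 - 1e-9
        ):
            raise ValidationError("5-95 percentile band must contain the 25-75 band")


@dataclass
class RobustnessReport:
    expected_dose: np.ndarray
    sd: np.ndarray
    structures: dict[str, StructureRobustness]
    n_scenarios: int
    grid_dims: tuple[int, int, int]

    def expected_volume(self) -> np.ndarray:
        return self.expected_dose.reshape(self.grid_dims)

    def sd_volume(self) -> np.ndarray:
        return self.sd.reshape(self.grid_dims)


def scenario_analysis(
    fluences: dict[str, np.ndarray] | np.ndarray,
    eval_set: ScenarioSet,
    engine: PencilBeamEngine,
    structure_names: list[str] | None = None,
    bin_width: float = 0.25,
    sd_bin_width: float = 0.02,
) -> dict[str, RobustnessReport] | RobustnessReport:
    """Recompute per-scenario doses for one or more plans and summarize.

    Each evaluation scenario's influence matrix is built once and applied to
    every supplied fluence vector.  DVHs are evaluated on the scenario's
    phase-specific structures (4D evaluation uses the per-phase CTV);
    expected dose and SD are voxelwise over the common room-frame grid.
    """
    single = not isinstance(fluences, dict)
    plans = {"plan": fluences} if single else dict(fluences)
    nb = engine.n_beamlets
    for name, x in plans.items():
        x = np.asarray(x, dtype=float).ravel()
        if x.size != nb:
            raise ValidationError(
                f"plan {name!r}: fluence length {x.size} != beamlet count {nb}"
            )
        plans[name] = x
    w = eval_set.weights
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("evaluation weights must sum to 1")
    if structure_names is None:
        structure_names = list(engine.phases[0][1].structures)

    nvox = engine.phases[0][0].nvox
    acc1 = {n: np.zeros(nvox) for n in plans}
    acc2 = {n: np.zeros(nvox) for n in plans}
    voi_doses: dict[str, dict[str, list[np.ndarray]]] = {
        n: {s: [] for s in structure_names} for n in plans
    }
    for scen in eval_set:
        D = engine.influence(scen).matrix
        sset = engine.phases[scen.phase][1]
        for name, x in plans.items():
            d = D @ x
            acc1[name] += scen.weight * d
            acc2[name] += scen.weight * d * d
            for s in structure_names:
                voi_doses[name][s].append(d[sset.structures[s]])

    reports = {}
    dims = engine.phases[0][0].dims
    for name in plans:
        exp = acc1[name]
        var = np.maximum(acc2[name] - exp * exp, 0.0)
        sd = np.sqrt(var)
        structs = {}
        for s in structure_names:
            per_scen = voi_doses[name][s]
            top = max(float(d.max()) for d in per_scen)
            top = max(top, float(exp.max()))
            axis = np.arange(0.0, top + 2 * bin_width, bin_width)
            curves = np.stack(
                [
                    100.0 * (d[None, :] >= axis[:, None]).mean(axis=1)
                    for d in per_scen
                ]
            )
            ref_sset = engine.phases[engine.reference_phase][1]
            dvh_exp = compute_dvh(
                exp, ref_sset.structures[s], bin_width, max_value=top, structure=s
            )
            sdvh, mean_sd = compute_sdvh(
                sd, ref_sset.structures[s], sd_bin_width, structure=s
            )
            structs[s] = StructureRobustness(
                dvh_expected=dvh_exp,
                band_lo_5=np.percentile(curves, 5, axis=0),
                band_lo_25=np.percentile(curves, 25, axis=0),
                band_hi_75=np.percentile(curves, 75, axis=0),
                band_hi_95=np.percentile(curves, 95, axis=0),
                dvh_axis=axis,
                sdvh=sdvh,
                mean_sd=mean_sd,
            )
        reports[name] = RobustnessReport(
            expected_dose=exp,
            sd=sd,
            structures=structs,
            n_scenarios=len(eval_set),
            grid_dims=dims,
        )
    return reports["plan"] if single else reports


def measure_tpi(
    solutions: dict[str, FluenceSolution], reference: str
) -> pd.DataFrame:
    """TPI/rTPI table: mean per-iteration wall time relative to a reference
    plan, plus instrumented influence/Omega product counts per evaluation."""
    if reference not in solutions:
        raise ValidationError(f"reference plan {reference!r} not among solutions")
    ref_tpi = solutions[reference].tpi
    rows = []
    for name, sol in solutions.items():
        counts = sol.product_counts
        evals = max(sol.n_evaluations, 1)
        rows.append(
            {
                "plan": name,
                "tpi_s": sol.tpi,
                "rtpi": sol.tpi / ref_tpi,
                "forward_per_eval": counts.get("forward", 0) / evals,
                "adjoint_per_eval": counts.get("adjoint", 0) / evals,
                "omega_per_eval": counts.get("omega", 0) / evals,
                "n_iterations": sol.n_iterations,
            }
        )
    return pd.DataFrame(rows).set_index("plan")
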