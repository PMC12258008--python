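"""Streaming accumulation of E[D] and per-structure total-variance matrices.

This is the scenario-free optimization substrate.  Given scenario
dose-influence matrices :math:`D_s` with importance weights :math:`\\pi_s`
(summing to 1), the package accumulates

* the expected dose-influence matrix :math:`E[D] = \\sum_s \\pi_s D_s`
  (sparse, voxels x beamlets), and
* per structure v the total-variance-influence matrix

  .. math::

     \\Omega_v = \\sum_s \\pi_s D_{s,v}^T D_{s,v}
                - \\Big(\\sum_s \\pi_s D_{s,v}\\Big)^T
                  \\Big(\\sum_s \\pi_s D_{s,v}\\Big)

  (dense symmetric, beamlets x beamlets), where :math:`D_{s,v}` is the row
  restriction of :math:`D_s` to v.  The quadratic form
  :math:`x^T \\Omega_v x` is the summed voxelwise dose variance in v; divided
  by the structure volume it is the *mean variance*.

Accumulation is streaming: one scenario matrix is held at a time, so peak
memory is independent of the scenario count.  Second moments are accumulated
in double precision and :math:`\\Omega_v` is formed once at finalization to
limit cancellation error.  Penalties are never baked in: one accumulation
serves any later penalty tuning.

4D phase handling: per-phase accumulators can be combined either *pooled*
(raw moments summed across phases before forming Omega, so inter-phase
motion contributes to the variance) or *within_phase* (Omega formed per
phase, then averaged with the phase weights, capturing only intra-phase
error variance).  The two are related by the law of total variance:
Omega_pooled - Omega_within equals the weighted covariance of the per-phase
mean matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .dose import DoseInfluence
from .exceptions import NumericalError, ValidationError

__all__ = [
    "ProbabilisticModel",
    "PhaseAccumulator",
    "accumulate",
    "combine_phase_accumulators",
]

VoiMap = Mapping[str, np.ndarray]


def _voi_rows(vois: VoiMap, name: str, phase: int) -> np.ndarray:
    """Resolve a VOI row-index set, optionally phase-dependent.

    A VOI value may be a plain index array (static geometry) or a mapping
    ``phase -> index array`` whose per-phase arrays are row-aligned (equal
    length, consistent ordering), as produced by rigid whole-voxel motion.
    """
    v = vois[name]
    if isinstance(v, Mapping):
        return np.asarray(v[phase], dtype=np.int64)
    return np.asarray(v, dtype=np.int64)


class PhaseAccumulator:
    """Running weighted first/second moments for one CT phase (or one pool)."""

    def __init__(self, vois: VoiMap):
        self.vois = vois
        self.mean_: sparse.spmatrix | None = None
        self.mean_rows_: dict[str, np.ndarray] = {}
        self.second_: dict[str, np.ndarray] = {}
        self.weight_ = 0.0
        self.n_scenarios_ = 0

    def add(self, influence: DoseInfluence | sparse.spmatrix, weight: float,
            phase: int = 0) -> None:
        if isinstance(influence, DoseInfluence):
            phase = influence.scenario.phase
            mat = influence.matrix
        else:
            mat = sparse.csr_matrix(influence)
        mat = sparse.csr_matrix(mat)
        if self.mean_ is not None and mat.shape != self.mean_.shape:
            raise ValidationError(
                f"scenario matrix shape {mat.shape} does not match accumulator "
                f"shape {self.mean_.shape}"
            )
        wmat = mat.multiply(weight)
        self.mean_ = wmat if self.mean_ is None else self.mean_ + wmat
        nb = mat.shape[1]
        for name in self.vois:
            rows = _voi_rows(self.vois, name, phase)
            Mv = mat[rows].toarray()
            if name not in self.second_:
                self.second_[name] = np.zeros((nb, nb))
                self.mean_rows_[name] = np.zeros((rows.size, nb))
            self.second_[name] += weight * (Mv.T @ Mv)
            self.mean_rows_[name] += weight * Mv
        self.weight_ += float(weight)
        self.n_scenarios_ += 1

    def extend(self, stream: Iterable[tuple]) -> "PhaseAccumulator":
        for item in stream:
            self.add(*item)
        return self

    def finalize(self, pooling_mode: str = "pooled",
                 check_weight: bool = True) -> "ProbabilisticModel":
        if self.mean_ is None:
            raise ValidationError("no scenarios accumulated")
        if check_weight and abs(self.weight_ - 1.0) > 1e-9:
            raise ValidationError(
                f"scenario weights sum to {self.weight_}, expected 1 within 1e-9"
            )
        omega = {}
        sizes = {}
        for name, second in self.second_.items():
            m = self.mean_rows_[name] / self.weight_
            O = second / self.weight_ - m.T @ m
            omega[name] = 0.5 * (O + O.T)
            sizes[name] = m.shape[0]
        ED = sparse.csr_matrix(self.mean_ / self.weight_)
        ED.data = np.maximum(ED.data, 0.0)  # guard rounding on nonnegativity
        return ProbabilisticModel(
            expected_influence=ED,
            omega=omega,
            voi_sizes=sizes,
            vois={n: self.vois[n] for n in self.vois},
            n_scenarios=self.n_scenarios_,
            pooling_mode=pooling_mode,
        )


def accumulate(
    scenario_stream: Iterable[tuple],
    vois: VoiMap,
    weight_tol: float = 1e-9,
) -> "ProbabilisticModel":
    """Stream (DoseInfluence | sparse matrix, weight) pairs into a model.

    The stream is consumed exactly once and only one scenario matrix is alive
    at a time; weights must sum to 1 within ``weight_tol``.
    """
    acc = PhaseAccumulator(vois)
    for item in scenario_stream:
        acc.add(*item)
    if abs(acc.weight_ - 1.0) > weight_tol:
        raise ValidationError(
            f"scenario weights sum to {acc.weight_}, expected 1 within {weight_tol}"
        )
    return acc.finalize()


@dataclass
class ProbabilisticModel:
    """E[D] plus per-VOI Omega matrices: the scenario-free substrate."""

    expected_influence: sparse.spmatrix
    omega: dict[str, np.ndarray]
    voi_sizes: dict[str, int]
    vois: dict[str, np.ndarray] = field(default_factory=dict)
    n_scenarios: int = 0
    pooling_mode: str = "pooled"

    def __post_init__(self) -> None:
        self.expected_influence = sparse.csr_matrix(self.expected_influence)
        if self.expected_influence.nnz and self.expected_influence.data.min() < 0:
            raise ValidationError("expected influence entries must be >= 0")
        for name, O in self.omega.items():
            O = np.asarray(O, dtype=float)
            if O.shape[0] != O.shape[1]:
                raise ValidationError(f"omega[{name!r}] must be square")
            rel = np.abs(O - O.T).max() / max(np.abs(O).max(), 1e-300)
            if rel > 1e-10:
                raise ValidationError(f"omega[{name!r}] asymmetric beyond 1e-10")
            self.omega[name] = O

    @property
    def n_beamlets(self) -> int:
        return self.expected_influence.shape[1]

    def expected_dose(self, x: np.ndarray) -> np.ndarray:
        """E[d] = E[D] x."""
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n_beamlets:
            raise ValidationError(
                f"fluence length {x.size} != beamlet count {self.n_beamlets}"
            )
        return self.expected_influence @ x

    def total_variance(self, voi: str, x: np.ndarray) -> float:
        """x^T Omega_v x (Gy^2); tiny negative rounding residues clamp to 0."""
        O = self._omega(voi)
        x = np.asarray(x, dtype=float).ravel()
        val = float(x @ (O @ x))
        if val < 0:
            tol = 1e-8 * max(np.trace(O), 0.0) * float(x @ x)
            if val < -tol - 1e-30:
                raise NumericalError(
                    f"omega[{voi!r}] quadratic form {val} below PSD tolerance"
                )
            val = 0.0
        return val

    def mean_variance(self, voi: str, x: np.ndarray) -> float:
        """Total variance normalized by the structure volume."""
        return self.total_variance(voi, x) / self.voi_sizes[voi]

    def variance_gradient(self, voi: str, x: np.ndarray) -> np.ndarray:
        """Gradient of the quadratic form: 2 Omega_v x."""
        return 2.0 * (self._omega(voi) @ np.asarray(x, dtype=float).ravel())

    def _omega(self, voi: str) -> np.ndarray:
        if voi not in self.omega:
            raise KeyError(f"no omega accumulated for VOI {voi!r}")
        return self.omega[voi]


def combine_phase_accumulators(
    per_phase: list[PhaseAccumulator],
    phase_weights: np.ndarray,
    mode: str = "pooled",
) -> ProbabilisticModel:
    """Combine per-phase moment accumulators into one model.

    pooled: raw moments are pooled across phases before Omega is formed, so
    the variance includes inter-phase motion.  within_phase: Omega is formed
    per phase and averaged with the phase weights (within-phase variance
    only).  The expected influence is identical in both modes.
    """
    if mode not in ("pooled", "within_phase"):
        raise ValidationError(f"unknown pooling mode {mode!r}")
    w = np.asarray(phase_weights, dtype=float)
    if w.size != len(per_phase) or np.any(w < 0):
        raise ValidationError("need one nonnegative weight per phase")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("phase weights must sum to 1")
    if not per_phase:
        raise ValidationError("no phase accumulators given")

    names = list(per_phase[0].second_.keys())
    for acc in per_phase:
        if acc.mean_ is None:
            raise ValidationError("empty phase accumulator")
        if list(acc.second_.keys()) != names:
            raise ValidationError("phase accumulators disagree on VOIs")
        if abs(acc.weight_ - 1.0) > 1e-9:
            raise ValidationError("per-phase scenario weights must sum to 1")
        if acc.mean_.shape != per_phase[0].mean_.shape:
            raise ValidationError("phase accumulators have inconsistent shapes")

    ED = sum(wk * acc.mean_ for wk, acc in zip(w, per_phase))
    ED = sparse.csr_matrix(ED)
    ED.data = np.maximum(ED.data, 0.0)
    omega: dict[str, np.ndarray] = {}
    sizes = {n: per_phase[0].mean_rows_[n].shape[0] for n in names}
    for name in names:
        if mode == "pooled":
            second = sum(wk * acc.second_[name] for wk, acc in zip(w, per_phase))
            mean = sum(wk * acc.mean_rows_[name] for wk, acc in zip(w, per_phase))
            O = second - mean.T @ mean
        else:
            O = np.zeros_like(per_phase[0].second_[name])
            for wk, acc in zip(w, per_phase):
                m = acc.mean_rows_[name]
                O += wk * (acc.second_[name] - m.T @ m)
        omega[name] = 0.5 * (O + O.T)

    n_scen = sum(acc.n_scenarios_ for acc in per_phase)
    return ProbabilisticModel(
        expected_influence=ED,
        omega=omega,
        voi_sizes=sizes,
        vois=dict(per_phase[0].vois),
        n_scenarios=n_scen,
        pooling_mode=mode,
    )
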