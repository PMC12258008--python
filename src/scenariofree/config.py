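"""Run-configuration schema: YAML/JSON -> validated package objects.

A config is a mapping with the sections below (all optional unless a
subcommand needs them); unknown keys raise, so typos fail loudly.

phantom:      dims_mm, spacing_mm, target_halfwidth_mm, target_density_delta,
              oar: {offset_mm, halfwidth_mm}, fourd: {n_phases, step_mm, axis}
beams:        list of {modality, gantry_angle, isocenter (optional; defaults
              to the phantom center), beamlet_spacing, field_halfwidth, ranges}
kernel:       KernelParams fields
uncertainty:  UncertaintyModel fields
scenarios:    {mode: random|worst_case, n, seed}
pooling:      pooled | within_phase (4D only)
objectives:   list of {kind, voi, penalty, dref, dvh_volume_pct}
constraints:  list of {kind, voi, threshold}
solver:       {mode, l2_reg, maxiter}
evaluation:   {n, seed}
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .dose import Beam, KernelParams
from .exceptions import ConfigError
from .phantoms import OarSpec, make_4d_box, make_box_phantom
from .planning import ConstraintSpec, ObjectiveSpec
from .scenarios import (
    UncertaintyModel,
    build_worstcase_scenarios,
    sample_random_scenarios,
)

__all__ = ["load_config", "RunConfig"]

_SECTIONS = {
    "phantom", "beams", "kernel", "uncertainty", "scenarios", "pooling",
    "objectives", "constraints", "solver", "evaluation", "output",
}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


class RunConfig:
    """Validated configuration; builders construct package objects on demand."""

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        _check_keys(raw, _SECTIONS, "config")
        self.raw = raw

    # -- builders ----------------------------------------------------------
    def build_phantom(self):
        spec = dict(self.raw.get("phantom", {}))
        _check_keys(
            spec,
            {"dims_mm", "spacing_mm", "target_halfwidth_mm",
             "target_density_delta", "oar", "fourd"},
            "phantom",
        )
        fourd = spec.pop("fourd", None)
        oar = spec.pop("oar", None)
        kwargs = {}
        if "dims_mm" in spec:
            kwargs["dims_mm"] = tuple(spec["dims_mm"])
        for key in ("spacing_mm", "target_halfwidth_mm", "target_density_delta"):
            if key in spec:
                kwargs[key] = spec[key]
        if oar is not None:
            _check_keys(oar, {"offset_mm", "halfwidth_mm"}, "phantom.oar")
            kwargs["oar_spec"] = OarSpec(
                tuple(oar.get("offset_mm", (33.0, 0.0, 0.0))),
                oar.get("halfwidth_mm", 9.0),
            )
        try:
            base = make_box_phantom(**kwargs)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"phantom: {exc}") from exc
        if fourd is None:
            return base
        _check_keys(fourd, {"n_phases", "step_mm", "axis"}, "phantom.fourd")
        return make_4d_box(
            base,
            n_phases=int(fourd.get("n_phases", 10)),
            step_mm=float(fourd.get("step_mm", 3.0)),
            axis=int(fourd.get("axis", 0)),
        )

    def build_beams(self, grid) -> list[Beam]:
        specs = self.raw.get("beams")
        if not specs:
            raise ConfigError("beams: at least one beam required")
        default_iso = tuple(d * s / 2.0 for d, s in zip(grid.dims, grid.spacing))
        beams = []
        for i, b in enumerate(specs):
            _check_keys(
                b,
                {"modality", "gantry_angle", "isocenter", "beamlet_spacing",
                 "field_halfwidth", "ranges"},
                f"beams[{i}]",
            )
            try:
                beams.append(
                    Beam(
                        modality=b["modality"],
                        gantry_angle=float(b["gantry_angle"]),
                        isocenter=tuple(b.get("isocenter", default_iso)),
                        beamlet_spacing=float(b.get("beamlet_spacing", 7.0)),
                        field_halfwidth=float(b.get("field_halfwidth", 21.0)),
                        ranges=tuple(b.get("ranges", ())),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"beams[{i}]: {exc}") from exc
        return beams

    def build_kernel(self) -> KernelParams:
        spec = self.raw.get("kernel", {})
        try:
            return KernelParams(**spec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"kernel: {exc}") from exc

    def build_uncertainty(self) -> UncertaintyModel:
        spec = self.raw.get("uncertainty", {})
        try:
            return UncertaintyModel(**spec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"uncertainty: {exc}") from exc

    def build_scenarios(self, phase: int = 0):
        spec = dict(self.raw.get("scenarios", {}))
        _check_keys(spec, {"mode", "n", "seed"}, "scenarios")
        mode = spec.get("mode", "random")
        model = self.build_uncertainty()
        if mode == "worst_case":
            return build_worstcase_scenarios(model, phase=phase)
        if mode == "random":
            if "seed" not in spec:
                raise ConfigError("scenarios: random sampling needs an explicit seed")
            return sample_random_scenarios(
                int(spec.get("n", 9)), model, seed=int(spec["seed"]), phase=phase
            )
        raise ConfigError(f"scenarios: unknown mode {mode!r}")

    def build_objectives(self, structures) -> list[ObjectiveSpec]:
        specs = self.raw.get("objectives")
        if not specs:
            raise ConfigError("objectives: at least one objective required")
        out = []
        for i, o in enumerate(specs):
            _check_keys(
                o, {"kind", "voi", "penalty", "dref", "dvh_volume_pct"},
                f"objectives[{i}]",
            )
            if o.get("voi") not in structures:
                raise ConfigError(
                    f"objectives[{i}]: unknown structure {o.get('voi')!r}"
                )
            try:
                out.append(
                    ObjectiveSpec(
                        o["kind"], o["voi"], float(o["penalty"]),
                        float(o.get("dref", 0.0)), o.get("dvh_volume_pct"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"objectives[{i}]: {exc}") from exc
        return out

    def build_constraints(self, structures) -> list[ConstraintSpec]:
        out = []
        for i, c in enumerate(self.raw.get("constraints", [])):
            _check_keys(c, {"kind", "voi", "threshold"}, f"constraints[{i}]")
            if c.get("voi") not in structures:
                raise ConfigError(
                    f"constraints[{i}]: unknown structure {c.get('voi')!r}"
                )
            try:
                out.append(ConstraintSpec(c["kind"], c["voi"], float(c["threshold"])))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"constraints[{i}]: {exc}") from exc
        return out

    @property
    def solver(self) -> dict:
        spec = dict(self.raw.get("solver", {}))
        _check_keys(spec, {"mode", "l2_reg", "maxiter"}, "solver")
        spec.setdefault("mode", "scenario_free")
        spec.setdefault("l2_reg", 0.0)
        spec.setdefault("maxiter", 1000)
        return spec

    @property
    def pooling(self) -> str:
        mode = self.raw.get("pooling", "pooled")
        if mode not in ("pooled", "within_phase"):
            raise ConfigError(f"pooling: unknown mode {mode!r}")
        return mode

    @property
    def evaluation(self) -> dict:
        spec = dict(self.raw.get("evaluation", {}))
        _check_keys(spec, {"n", "seed"}, "evaluation")
        spec.setdefault("n", 100)
        if "seed" not in spec:
            raise ConfigError("evaluation: needs an explicit seed")
        return spec


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse ({exc})") from exc
    return RunConfig(raw or {})
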