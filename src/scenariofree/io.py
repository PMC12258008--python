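"""Serialization: NRRD volumes, RLE structure JSON, Matrix Market models.

All formats are plain text so artifacts stay portable and diffable:

* volumes (density, dose, SD maps): NRRD with ascii encoding (a minimal
  reader/writer covering exactly the fields this package emits);
* structure sets: JSON mapping name -> run-length-encoded flat-index list;
* scenario sets: CSV, one row per scenario;
* probabilistic models: E[D] and each Omega_v in Matrix Market format plus a
  JSON manifest (VOIs, sizes, scenario count, pooling mode).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .exceptions import ValidationError
from .phantoms import StructureSet, VoxelGrid
from .probabilistic import ProbabilisticModel
from .scenarios import Scenario, ScenarioSet

__all__ = [
    "write_nrrd",
    "read_nrrd",
    "write_structures",
    "read_structures",
    "write_phantom",
    "read_phantom",
    "write_scenarios",
    "read_scenarios",
    "export_model",
    "import_model",
    "write_influence",
    "read_influence",
    "provenance_manifest",
]


# ---------------------------------------------------------------------------
# NRRD (ascii encoding only)
# ---------------------------------------------------------------------------

def write_nrrd(path: str | Path, volume: np.ndarray,
               spacing: tuple[float, float, float],
               origin: tuple[float, float, float]) -> None:
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValidationError("NRRD writer expects a 3D volume")
    with open(path, "w") as fh:
        fh.write("NRRD0004\n")
        fh.write("type: double\n")
        fh.write("dimension: 3\n")
        fh.write(f"sizes: {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n")
        fh.write("encoding: ascii\n")
        fh.write("space: left-posterior-superior\n")
        fh.write(
            "space directions: ({},0,0) (0,{},0) (0,0,{})\n".format(*spacing)
        )
        fh.write("space origin: ({},{},{})\n".format(*origin))
        fh.write("\n")
        # flat C order (x fastest-varying axis is the first index here)
        np.savetxt(fh, vol.ravel()[None, :], fmt="%.17g")


def read_nrrd(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    header: dict[str, str] = {}
    with open(path) as fh:
        magic = fh.readline()
        if not magic.startswith("NRRD"):
            raise ValidationError(f"{path}: not an NRRD file")
        for line in fh:
            line = line.strip()
            if not line:
                break
            if ":" in line:
                k, v = line.split(":", 1)
                header[k.strip()] = v.strip()
        data = np.loadtxt(fh).ravel()
    if header.get("encoding") != "ascii":
        raise ValidationError(f"{path}: only ascii encoding is supported")
    sizes = tuple(int(s) for s in header["sizes"].split())
    def _triple(text: str) -> tuple[float, ...]:
        return tuple(
            float(t) for t in text.replace("(", " ").replace(")", " ")
            .replace(",", " ").split()
        )
    dirs = _triple(header.get("space directions", "(1,0,0) (0,1,0) (0,0,1)"))
    spacing = (dirs[0], dirs[4], dirs[8])
    origin = _triple(header.get("space origin", "(0,0,0)"))
    return data.reshape(sizes), spacing, origin


# ---------------------------------------------------------------------------
# structures (run-length encoded JSON)
# ---------------------------------------------------------------------------

def _rle_encode(idx: np.ndarray) -> list[list[int]]:
    idx = np.asarray(idx, dtype=np.int64)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [[int(idx[s]), int(idx[e] - idx[s] + 1)] for s, e in zip(starts, ends)]


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    if not runs:
        return np.empty(0, dtype=np.int64)
    return np.concatenate([np.arange(s, s + n, dtype=np.int64) for s, n in runs])


def write_structures(path: str | Path, sset: StructureSet) -> None:
    payload = {
        "roles": dict(sset.roles),
        "structures": {n: _rle_encode(i) for n, i in sset.structures.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_structures(path: str | Path) -> StructureSet:
    payload = json.loads(Path(path).read_text())
    return StructureSet(
        {n: _rle_decode(r) for n, r in payload["structures"].items()},
        payload["roles"],
    )


def write_phantom(outdir: str | Path, grid: VoxelGrid, sset: StructureSet) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_nrrd(outdir / "density.nrrd", grid.density, grid.spacing, grid.origin)
    write_structures(outdir / "structures.json", sset)


def read_phantom(outdir: str | Path) -> tuple[VoxelGrid, StructureSet]:
    outdir = Path(outdir)
    vol, spacing, origin = read_nrrd(outdir / "density.nrrd")
    grid = VoxelGrid(vol.shape, spacing, origin, vol)
    sset = read_structures(outdir / "structures.json")
    sset.validate_against(grid)
    return grid, sset


# ---------------------------------------------------------------------------
# scenario sets (CSV)
# ---------------------------------------------------------------------------

def write_scenarios(path: str | Path, sset: ScenarioSet) -> None:
    rows = [
        {
            "shift_x": s.shift[0],
            "shift_y": s.shift[1],
            "shift_z": s.shift[2],
            "c_abs": s.c_abs,
            "c_rel": s.c_rel,
            "phase": s.phase,
            "weight": s.weight,
        }
        for s in sset
    ]
    df = pd.DataFrame(rows)
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# sampling_mode={sset.sampling_mode} seed={sset.seed}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_scenarios(path: str | Path) -> ScenarioSet:
    with open(path) as fh:
        meta = fh.readline().strip().lstrip("# ").split()
        df = pd.read_csv(fh)
    kv = dict(item.split("=", 1) for item in meta)
    scens = [
        Scenario(
            (r.shift_x, r.shift_y, r.shift_z), r.c_abs, r.c_rel, int(r.phase),
            r.weight,
        )
        for r in df.itertuples()
    ]
    seed = None if kv.get("seed") in (None, "None") else int(kv["seed"])
    return ScenarioSet(scens, sampling_mode=kv.get("sampling_mode", "random"),
                       seed=seed)


# ---------------------------------------------------------------------------
# probabilistic model (Matrix Market + JSON manifest)
# ---------------------------------------------------------------------------

def export_model(model: ProbabilisticModel, outdir: str | Path,
                 extra_manifest: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "expected_influence.mtx",
                sparse.coo_matrix(model.expected_influence))
    vois_payload = {}
    for name in model.omega:
        sio.mmwrite(outdir / f"omega_{name}.mtx", model.omega[name])
        v = model.vois.get(name)
        if isinstance(v, dict):
            vois_payload[name] = {str(k): _rle_encode(iv) for k, iv in v.items()}
        elif v is not None:
            vois_payload[name] = _rle_encode(np.asarray(v))
    manifest = {
        "vois": list(model.omega.keys()),
        "voi_sizes": {k: int(v) for k, v in model.voi_sizes.items()},
        "voi_indices": vois_payload,
        "n_scenarios": int(model.n_scenarios),
        "pooling_mode": model.pooling_mode,
        "n_beamlets": int(model.n_beamlets),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def import_model(outdir: str | Path) -> ProbabilisticModel:
    outdir = Path(outdir)
    mpath = outdir / "manifest.json"
    if not mpath.exists():
        raise IOError(f"missing model manifest: {mpath}")
    manifest = json.loads(mpath.read_text())
    epath = outdir / "expected_influence.mtx"
    if not epath.exists():
        raise IOError(f"missing expected-influence matrix: {epath}")
    ED = sparse.csr_matrix(sio.mmread(epath))
    omega = {}
    for name in manifest["vois"]:
        opath = outdir / f"omega_{name}.mtx"
        if not opath.exists():
            raise IOError(f"missing omega matrix: {opath}")
        raw = sio.mmread(opath)
        omega[name] = np.asarray(
            raw.todense() if sparse.issparse(raw) else raw, dtype=float
        )
    vois = {}
    for name, payload in manifest.get("voi_indices", {}).items():
        if isinstance(payload, dict):
            vois[name] = {int(k): _rle_decode(v) for k, v in payload.items()}
        else:
            vois[name] = _rle_decode(payload)
    return ProbabilisticModel(
        expected_influence=ED,
        omega=omega,
        voi_sizes=manifest["voi_sizes"],
        vois=vois,
        n_scenarios=manifest["n_scenarios"],
        pooling_mode=manifest["pooling_mode"],
    )


# ---------------------------------------------------------------------------
# dose influence (Matrix Market + JSON sidecar)
# ---------------------------------------------------------------------------

def write_influence(prefix: str | Path, influence, grid_dims) -> None:
    from .dose import DoseInfluence  # local import avoids a cycle

    prefix = Path(prefix)
    sio.mmwrite(prefix.with_suffix(".mtx"), sparse.coo_matrix(influence.matrix))
    s = influence.scenario
    sidecar = {
        "grid_dims": list(grid_dims),
        "scenario": {
            "shift": list(s.shift),
            "c_abs": s.c_abs,
            "c_rel": s.c_rel,
            "phase": s.phase,
            "weight": s.weight,
        },
        "beamlets": [
            [b, a, bb, r] for (b, a, bb, r) in influence.beamlets
        ],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_influence(prefix: str | Path):
    from .dose import DoseInfluence

    prefix = Path(prefix)
    for suffix in (".mtx", ".json"):
        if not prefix.with_suffix(suffix).exists():
            raise IOError(f"missing influence file: {prefix.with_suffix(suffix)}")
    mat = sparse.csc_matrix(sio.mmread(prefix.with_suffix(".mtx")))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    sc = sidecar["scenario"]
    scen = Scenario(tuple(sc["shift"]), sc["c_abs"], sc["c_rel"], sc["phase"],
                    sc["weight"])
    beamlets = [(int(b), float(a), float(bb), None if r is None else float(r))
                for b, a, bb, r in sidecar["beamlets"]]
    return DoseInfluence(mat, scen, beamlets), tuple(sidecar["grid_dims"])


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance_manifest(outdir: str | Path, config: dict | None,
                        seeds: dict | None = None, command: str = "") -> None:
    """Machine-readable provenance: config hash, package version, seeds."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    payload = {
        "package": "scenariofree",
        "version": __version__,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds or {},
        "command": command,
    }
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=1))
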