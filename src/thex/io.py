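"""Run configuration (TOML) and trajectory file I/O (TSV + HDF5).

Config files use friendly scanner units (mm, mT/m, T/m/s, ms, us) and are
converted to SI on load; range sanity checks catch the classic
meters-vs-millimeters mistakes.  Trajectory containers carry a format
version and every array plus the metadata needed to rebuild the full
:class:`~thex.spiral.TrajectorySet` losslessly: HDF5 for bit-wise
round-trips, TSV (with repr-exact floats) for text pipelines.
"""

from __future__ import annotations

import json
import os
import tomllib
from dataclasses import dataclass

import numpy as np

from .gradients import GradientWaveform, SystemLimits
from .hexlattice import TiltIndex, shot_geometry
from .spiral import SequenceGeometry, TrajectorySet

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
]

_TRAJ_VERSION = "thex-trajectory-1"


@dataclass
class RunConfig:
    """Everything needed to design (and optionally simulate) one run."""

    geometry: SequenceGeometry
    tilt: TiltIndex
    limits: SystemLimits
    kind: str = "spiral"  # "spiral" | "epi"
    output: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("spiral", "epi"):
            raise ValueError(f"kind must be 'spiral' or 'epi', got {self.kind!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


# config schema: section -> key -> (required, sanity range or None)
_SCHEMA = {
    "geometry": {
        "fov_mm": True,
        "resolution_mm": True,
        "R": False,
        "TE_ms": False,
        "overhead_ms": False,
        "TR_ms": False,
        "elliptical_fov": False,
        "n_shots": False,
        "anisotropy": False,
    },
    "tilt": {"M1": True, "M2": True},
    "limits": {"gmax_mT_m": True, "smax_T_m_s": True, "raster_us": False},
    "run": {"kind": False, "output": False, "seed": False},
}


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(
            f"config value {name} = {value} outside the sane range "
            f"[{lo}, {hi}] — check the units"
        )


def read_config(path: str | os.PathLike) -> RunConfig:
    """Parse a TOML run config; unknown keys are rejected by name."""
    with open(path, "rb") as f:
        doc = tomllib.load(f)
    for section, keys in doc.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(keys, dict):
            raise ValueError(f"[{section}] must be a table")
        for key in keys:
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown config key {section}.{key}")
    for section, keys in _SCHEMA.items():
        for key, required in keys.items():
            if required and (section not in doc or key not in doc[section]):
                raise ValueError(f"missing required config key {section}.{key}")

    g = doc["geometry"]
    fov_mm = g["fov_mm"]
    res_mm = g["resolution_mm"]
    if len(fov_mm) != 3 or len(res_mm) != 3:
        raise ValueError("geometry.fov_mm and geometry.resolution_mm need 3 entries")
    for v in fov_mm:
        _check_range("geometry.fov_mm", v, 10.0, 2000.0)
    for v in res_mm:
        _check_range("geometry.resolution_mm", v, 0.05, 50.0)
    te_ms = g.get("TE_ms", 0.0)
    oh_ms = g.get("overhead_ms", 0.0)
    tr_ms = g.get("TR_ms")
    for nm, v, hi in (("TE_ms", te_ms, 1000.0), ("overhead_ms", oh_ms, 1000.0)):
        _check_range(f"geometry.{nm}", v, 0.0, hi)
    if tr_ms is not None:
        _check_range("geometry.TR_ms", tr_ms, 0.1, 10000.0)
    geometry = SequenceGeometry(
        fov=tuple(v * 1e-3 for v in fov_mm),
        resolution=tuple(v * 1e-3 for v in res_mm),
        R=float(g.get("R", 1.0)),
        TE=te_ms * 1e-3,
        overhead=oh_ms * 1e-3,
        TR=None if tr_ms is None else tr_ms * 1e-3,
        elliptical_fov=bool(g.get("elliptical_fov", True)),
        n_shots=g.get("n_shots"),
        anisotropy=float(g.get("anisotropy", 1.0)),
    )
    tilt = TiltIndex(int(doc["tilt"]["M1"]), int(doc["tilt"]["M2"]))
    lim = doc["limits"]
    _check_range("limits.gmax_mT_m", lim["gmax_mT_m"], 1.0, 500.0)
    _check_range("limits.smax_T_m_s", lim["smax_T_m_s"], 1.0, 5000.0)
    raster_us = lim.get("raster_us", 10.0)
    _check_range("limits.raster_us", raster_us, 0.1, 100.0)
    limits = SystemLimits(
        gmax=float(lim["gmax_mT_m"]),
        smax=float(lim["smax_T_m_s"]),
        raster=raster_us * 1e-6,
    )
    run = doc.get("run", {})
    return RunConfig(
        geometry=geometry,
        tilt=tilt,
        limits=limits,
        kind=run.get("kind", "spiral"),
        output=run.get("output", "."),
        seed=int(run.get("seed", 0)),
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def write_config(path: str | os.PathLike, config: RunConfig) -> None:
    """Write a RunConfig as TOML.

    Round-trips with :func:`read_config` up to floating-point error in the
    SI <-> scanner-unit conversions (relative error ~1e-16).
    """
    geo = config.geometry
    lines = ["[geometry]"]
    lines.append(f"fov_mm = {_toml_value([v * 1e3 for v in geo.fov])}")
    lines.append(f"resolution_mm = {_toml_value([v * 1e3 for v in geo.resolution])}")
    lines.append(f"R = {_toml_value(float(geo.R))}")
    lines.append(f"TE_ms = {_toml_value(geo.TE * 1e3)}")
    lines.append(f"overhead_ms = {_toml_value(geo.overhead * 1e3)}")
    if geo.TR is not None:
        lines.append(f"TR_ms = {_toml_value(geo.TR * 1e3)}")
    lines.append(f"elliptical_fov = {_toml_value(geo.elliptical_fov)}")
    if geo.n_shots is not None:
        lines.append(f"n_shots = {_toml_value(int(geo.n_shots))}")
    lines.append(f"anisotropy = {_toml_value(float(geo.anisotropy))}")
    lines += ["", "[tilt]", f"M1 = {config.tilt.m1}", f"M2 = {config.tilt.m2}"]
    lines += [
        "",
        "[limits]",
        f"gmax_mT_m = {_toml_value(float(config.limits.gmax))}",
        f"smax_T_m_s = {_toml_value(float(config.limits.smax))}",
        f"raster_us = {_toml_value(config.limits.raster * 1e6)}",
    ]
    lines += [
        "",
        "[run]",
        f"kind = {_toml_value(config.kind)}",
        f"output = {_toml_value(config.output)}",
        f"seed = {config.seed}",
    ]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory containers


def _traj_meta(traj: TrajectorySet) -> dict:
    geo = traj.geometry
    return {
        "version": _TRAJ_VERSION,
        "kind": traj.kind,
        "tilt": [traj.tilt.m1, traj.tilt.m2],
        "geometry": {
            "fov": list(geo.fov),
            "resolution": list(geo.resolution),
            "R": geo.R,
            "TE": geo.TE,
            "overhead": geo.overhead,
            "TR": geo.TR,
            "elliptical_fov": geo.elliptical_fov,
            "n_shots": geo.n_shots,
            "anisotropy": geo.anisotropy,
        },
        "limits": {
            "gmax": traj.limits.gmax,
            "smax": traj.limits.smax,
            "raster": traj.limits.raster,
            "gamma_bar": traj.limits.gamma_bar,
        },
        "d": traj.d,
        "h": traj.h,
        "scale1": traj.scale1,
        "scale2": traj.scale2,
        "t_aq": traj.t_aq,
        "esp": traj.esp,
        "wf_raster": traj.waveform.raster,
        "wf_gamma_bar": traj.waveform.gamma_bar,
    }


def _traj_from_meta(meta: dict, arrays: dict) -> TrajectorySet:
    if meta.get("version") != _TRAJ_VERSION:
        raise ValueError(
            f"trajectory container version {meta.get('version')!r} unsupported "
            f"(expected {_TRAJ_VERSION!r})"
        )
    g = meta["geometry"]
    geometry = SequenceGeometry(
        fov=tuple(g["fov"]),
        resolution=tuple(g["resolution"]),
        R=g["R"],
        TE=g["TE"],
        overhead=g["overhead"],
        TR=g["TR"],
        elliptical_fov=g["elliptical_fov"],
        n_shots=g["n_shots"],
        anisotropy=g["anisotropy"],
    )
    tilt = TiltIndex(*meta["tilt"])
    lim = meta["limits"]
    limits = SystemLimits(
        gmax=lim["gmax"], smax=lim["smax"], raster=lim["raster"], gamma_bar=lim["gamma_bar"]
    )
    wf = GradientWaveform(
        G=arrays["wf_G"],
        k=arrays["wf_k"],
        t=arrays["wf_t"],
        raster=meta["wf_raster"],
        gamma_bar=meta["wf_gamma_bar"],
    )
    los = arrays.get("line_of_sample")
    return TrajectorySet(
        kind=meta["kind"],
        geometry=geometry,
        tilt=tilt,
        shot_geom=shot_geometry(tilt, dk=1.0),
        limits=limits,
        d=meta["d"],
        h=meta["h"],
        scale1=meta["scale1"],
        scale2=meta["scale2"],
        base_k=arrays["base_k"],
        base_t=arrays["base_t"],
        rotations=arrays["rotations"],
        shifts=arrays["shifts"],
        kz=arrays["kz"],
        te_shifts=arrays["te_shifts"],
        waveform=wf,
        t_aq=meta["t_aq"],
        esp=meta["esp"],
        line_of_sample=None if los is None else los.astype(np.int64),
    )


_ARRAY_NAMES = [
    "base_k",
    "base_t",
    "rotations",
    "shifts",
    "kz",
    "te_shifts",
    "wf_G",
    "wf_k",
    "wf_t",
    "line_of_sample",
]


def _traj_arrays(traj: TrajectorySet) -> dict:
    arrays = {
        "base_k": traj.base_k,
        "base_t": traj.base_t,
        "rotations": traj.rotations,
        "shifts": traj.shifts,
        "kz": traj.kz,
        "te_shifts": traj.te_shifts,
        "wf_G": traj.waveform.G,
        "wf_k": traj.waveform.k,
        "wf_t": traj.waveform.t,
    }
    if traj.line_of_sample is not None:
        arrays["line_of_sample"] = traj.line_of_sample
    return arrays


def write_trajectory(path: str | os.PathLike, traj: TrajectorySet) -> None:
    """Write a trajectory container: HDF5 (.h5/.hdf5) or TSV otherwise."""
    if str(path).endswith((".h5", ".hdf5")):
        _write_h5(path, traj)
    else:
        _write_tsv(path, traj)


def read_trajectory(path: str | os.PathLike) -> TrajectorySet:
    """Read a trajectory container written by :func:`write_trajectory`."""
    if str(path).endswith((".h5", ".hdf5")):
        return _read_h5(path)
    return _read_tsv(path)


def _write_h5(path, traj: TrajectorySet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = _TRAJ_VERSION
        f.attrs["meta"] = json.dumps(_traj_meta(traj))
        for name, arr in _traj_arrays(traj).items():
            f.create_dataset(name, data=np.asarray(arr))


def _read_h5(path) -> TrajectorySet:
    import h5py

    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != _TRAJ_VERSION:
            raise ValueError(
                f"trajectory container version {version!r} unsupported "
                f"(expected {_TRAJ_VERSION!r})"
            )
        meta = json.loads(f.attrs["meta"])
        arrays = {name: f[name][...] for name in _ARRAY_NAMES if name in f}
    return _traj_from_meta(meta, arrays)


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_tsv(path, traj: TrajectorySet) -> None:
    arrays = _traj_arrays(traj)
    lines = [f"# {_TRAJ_VERSION}", f"# meta\t{json.dumps(_traj_meta(traj))}"]
    for name, arr in arrays.items():
        a = np.asarray(arr)
        flat2d = a.reshape(len(a), -1) if a.ndim > 1 else a.reshape(-1, 1)
        lines.append(f"# section\t{name}\t{a.shape[0]}\t{'x'.join(map(str, a.shape))}")
        for row in flat2d:
            lines.append("\t".join(_fmt(v) for v in row))
    lines.append("# end")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def _read_tsv(path) -> TrajectorySet:
    with open(path) as f:
        raw = f.read().splitlines()
    if not raw or raw[0].strip() != f"# {_TRAJ_VERSION}":
        raise ValueError(
            f"not a {_TRAJ_VERSION} TSV container (bad or missing header line)"
        )
    if raw[-1].strip() != "# end":
        raise ValueError("truncated trajectory TSV: missing '# end' terminator")
    if not raw[1].startswith("# meta\t"):
        raise ValueError("trajectory TSV missing metadata line")
    meta = json.loads(raw[1].split("\t", 1)[1])
    arrays: dict[str, np.ndarray] = {}
    i = 2
    while i < len(raw) - 1:
        parts = raw[i].split("\t")
        if parts[0] != "# section" or len(parts) != 4:
            raise ValueError(f"malformed section header at line {i + 1}")
        name, nrows = parts[1], int(parts[2])
        shape = tuple(int(s) for s in parts[3].split("x"))
        rows = raw[i + 1 : i + 1 + nrows]
        if len(rows) != nrows:
            raise ValueError(f"truncated section {name!r}: expected {nrows} rows")
        data = np.array([[float(v) for v in r.split("\t")] for r in rows])
        arrays[name] = data.reshape(shape)
        i += 1 + nrows
    for required in _ARRAY_NAMES[:-1]:
        if required not in arrays:
            raise ValueError(f"trajectory TSV missing section {required!r}")
    return _traj_from_meta(meta, arrays)
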