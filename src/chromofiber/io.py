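"""Configuration, coordinate formats, trajectories and run manifests.

Text formats store coordinates in nm with 6 decimal places; HDF5
trajectories keep full binary precision.  Simulation code works in rs
units (1 rs = 3.57 nm); conversion happens here.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import NM_PER_RS, ModelParams, ParameterError

_KIND_ELEMENT = {0: "C", 1: "N", 2: "P"}       # DNA, nucleosome, protein
_ELEMENT_KIND = {v: k for k, v in _KIND_ELEMENT.items()}


class FormatError(ValueError):
    """Malformed input file."""


# -- configuration ----------------------------------------------------------


def load_config(path) -> ModelParams:
    """Load a flat YAML mapping of ModelParams fields.

    Unknown keys raise :class:`ParameterError` naming the key; invalid
    values raise with the offending field name.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"{path}: not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a flat key/value mapping")
    return ModelParams.from_dict(data)


def save_config(params: ModelParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


# -- XYZ --------------------------------------------------------------------


def write_xyz(path, frames_rs, kinds=None, comment: str = "") -> None:
    """Write one or more frames in XYZ format (coordinates in nm).

    ``kinds`` is an optional per-bead integer array (0 DNA, 1
    nucleosome, 2 protein joint) mapped to element tags C/N/P.
    """
    frames = np.asarray(frames_rs, float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if kinds is None:
        kinds = np.zeros(n, dtype=int)
    elems = [_KIND_ELEMENT[int(k)] for k in kinds]
    with open(path, "w", encoding="utf-8") as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"{n}\n")
            fh.write(f"frame={fi} unit=nm {comment}".rstrip() + "\n")
            for e, r in zip(elems, frame * NM_PER_RS):
                fh.write(f"{e} {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an XYZ file; returns (frames in rs units (F, n, 3), kinds)."""
    frames = []
    kinds = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}:{i + 1}: expected an atom count") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise FormatError(f"{path}:{i + 1}: truncated frame")
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}:{i + 1}: truncated frame")
        coords = np.empty((n, 3))
        kk = np.empty(n, dtype=int)
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{i + 3 + j}: malformed record")
            kk[j] = _ELEMENT_KIND.get(parts[0], 0)
            coords[j] = [float(x) for x in parts[1:4]]
        frames.append(coords / NM_PER_RS)
        kinds = kk
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return np.array(frames), kinds


# -- CSV --------------------------------------------------------------------


def write_chain_csv(path, positions_rs, kinds=None) -> None:
    """Flat CSV (index, kind, x, y, z in nm) of one coordinate set."""
    pos = np.asarray(positions_rs, float) * NM_PER_RS
    n = len(pos)
    if kinds is None:
        kinds = np.zeros(n, dtype=int)
    df = pd.DataFrame({
        "index": np.arange(n),
        "kind": [_KIND_ELEMENT[int(k)] for k in kinds],
        "x_nm": np.round(pos[:, 0], 6),
        "y_nm": np.round(pos[:, 1], 6),
        "z_nm": np.round(pos[:, 2], 6),
    })
    df.to_csv(path, index=False)


def read_chain_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm", "z_nm"):
        if col not in df:
            raise FormatError(f"{path}: missing column {col}")
    pos = df[["x_nm", "y_nm", "z_nm"]].to_numpy() / NM_PER_RS
    kinds = np.array([_ELEMENT_KIND.get(str(k), 0)
                      for k in df.get("kind", ["C"] * len(df))])
    return pos, kinds


# -- PDB (single-frame visualization export) --------------------------------


def write_pdb(path, positions_rs, kinds=None) -> None:
    """Single-frame PDB export for molecular viewers (coordinates in
    Angstrom, one pseudo-atom per bead)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pos = np.asarray(positions_rs, float) * NM_PER_RS * 10.0
    n = len(pos)
    if kinds is None:
        kinds = np.zeros(n, dtype=int)
    arr = struc.AtomArray(n)
    arr.coord = pos
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["DNA", "NUC", "PRO"])[np.asarray(kinds)]
    arr.atom_name = np.full(n, "CA")
    arr.element = np.array([_KIND_ELEMENT[int(k)] for k in kinds])
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


# -- HDF5 trajectories ------------------------------------------------------


def write_trajectory_h5(path, frames_rs, params: ModelParams, seed: int,
                        energies: pd.DataFrame | None = None,
                        sample_every: int | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions_rs", data=np.asarray(frames_rs))
        h5.attrs["params_json"] = json.dumps(params.to_dict())
        h5.attrs["seed"] = int(seed)
        h5.attrs["nm_per_rs"] = NM_PER_RS
        if sample_every is not None:
            h5.attrs["sample_every"] = int(sample_every)
        if energies is not None:
            g = h5.create_group("energies")
            for col in energies.columns:
                g.create_dataset(col, data=energies[col].to_numpy())


def read_trajectory_h5(path):
    with h5py.File(path, "r") as h5:
        frames = h5["positions_rs"][...]
        params = ModelParams.from_dict(json.loads(h5.attrs["params_json"]))
        seed = int(h5.attrs["seed"])
        energies = None
        if "energies" in h5:
            energies = pd.DataFrame(
                {k: h5["energies"][k][...] for k in h5["energies"]})
    return frames, params, seed, energies


# -- run manifest -----------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, module: str, params: ModelParams, seed: int,
                   realizations: int | None = None,
                   extra: dict | None = None,
                   started: float | None = None) -> Path:
    """Write the run manifest (parameters, seeds, realization counts,
    output inventory with checksums, wall-clock metadata) into
    ``out_dir/manifest.json``."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    now = time.time()
    inventory = {}
    for f in sorted(out_dir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            inventory[f.name] = {"sha256": _sha256(f),
                                 "bytes": f.stat().st_size}
    manifest = {
        "module": module,
        "version": __version__,
        "seed": int(seed),
        "realizations": realizations,
        "params": params.to_dict(),
        "outputs": inventory,
        "wall_clock_s": None if started is None else round(now - started, 3),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(now)),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
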