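"""HDF5 prepared-data and reconstruction files, plus config ingest.

Two file kinds make up the on-disk pipeline:

* the *prepared-data* file, written by the data preparator: one group
  per scan holding the intensity stack and the scan positions, next to
  a shared detector group with the geometry, e.g. ::

      /                      (attr: format_version)
      /detector              (attrs: wavelength, distance_z, ...)
      /detector/valid_mask
      /scans/scan_000/data        (position, y, x)
      /scans/scan_000/positions   (n, 2; row = y, x  [object px])

* the *reconstruction* file: probes and objects stored exactly once
  under ``/reconstruction/p``, per-scan access provided through soft
  links (no redundant copies), and the prepared data attached as an
  external link so results and raw data stay co-located but separate.

The group/dataset names are this package's documented dialect; the
layout (per-scan groups + shared detector settings, single-copy
probe/object storage with links) is the contract.

Intensities may be stored through the variance-stabilized codec; the
quantization step and bit depth then travel as dataset attributes.

Templates are YAML: an ordered list of engine blocks (any order, any
repetition) plus optional simulation/output settings.  Unknown keys
are rejected loudly — silent typos in engine settings are the classic
way to lose a beamtime.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import yaml

from .compression import CompressedStack, compress, decompress
from .datamodel import (
    DiffractionStack,
    ExperimentGeometry,
    ObjectStore,
    ProbeStack,
    ReconstructionState,
    ScanPositions,
    ShareMap,
    effective_pixel_size,
)
from .engine_dm import DMSettings
from .engine_ml import MLSettings

__all__ = [
    "FORMAT_VERSION",
    "write_prepared",
    "read_prepared",
    "write_reconstruction",
    "read_reconstruction",
    "read_positions",
    "load_template",
]

FORMAT_VERSION = "1.0"

_GEOMETRY_ATTRS = ("wavelength", "distance_z", "detector_pixel", "frame_size_N")


def _scan_name(s: int) -> str:
    return f"scan_{s:03d}"


def write_prepared(
    state: ReconstructionState,
    path: Union[str, os.PathLike],
    compress_qs: Optional[float] = None,
    compress_bits: Optional[int] = None,
) -> None:
    """Write the prepared-data file for a state (one group per scan).

    With ``compress_qs`` set, intensities are stored as codec codes
    with ``quantization_step``/``bits`` attributes; otherwise as
    float64, bitwise round-trippable.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        det = f.create_group("detector")
        for name in _GEOMETRY_ATTRS:
            det.attrs[name] = getattr(state.geometry, name)
        det.create_dataset("valid_mask", data=state.data.valid_mask.astype(np.uint8))
        scans = f.create_group("scans")
        for s in range(state.positions.n_scans):
            sel = state.positions.scan_id == s
            grp = scans.create_group(_scan_name(s))
            frames = state.data.intensities[sel]
            if compress_qs is not None:
                packed = compress(frames, qs=compress_qs, bits=compress_bits)
                ds = grp.create_dataset(
                    "data", data=packed.codes, chunks=(1,) + frames.shape[1:]
                )
                ds.attrs["compressed"] = True
                ds.attrs["quantization_step"] = packed.quantization_step
                ds.attrs["bits"] = packed.bits
                ds.attrs["n_saturated"] = packed.n_saturated
            else:
                ds = grp.create_dataset(
                    "data", data=frames, chunks=(1,) + frames.shape[1:]
                )
                ds.attrs["compressed"] = False
            grp.create_dataset("positions", data=state.positions.positions[sel])


def read_prepared(
    path: Union[str, os.PathLike],
) -> Tuple[DiffractionStack, ScanPositions, ExperimentGeometry]:
    """Read a prepared-data file back (decompressing if needed)."""
    with h5py.File(path, "r") as f:
        det = f["detector"]
        geometry = ExperimentGeometry(
            wavelength=float(det.attrs["wavelength"]),
            distance_z=float(det.attrs["distance_z"]),
            detector_pixel=float(det.attrs["detector_pixel"]),
            frame_size_N=int(det.attrs["frame_size_N"]),
        )
        mask = det["valid_mask"][()].astype(bool)
        frames: List[np.ndarray] = []
        positions: List[np.ndarray] = []
        scan_ids: List[np.ndarray] = []
        names = sorted(f["scans"])
        for s, name in enumerate(names):
            grp = f["scans"][name]
            ds = grp["data"]
            if ds.attrs.get("compressed", False):
                packed = CompressedStack(
                    ds[()],
                    float(ds.attrs["quantization_step"]),
                    int(ds.attrs["bits"]),
                )
                frames.append(decompress(packed))
            else:
                frames.append(ds[()])
            pos = grp["positions"][()]
            positions.append(pos)
            scan_ids.append(np.full(pos.shape[0], s, dtype=np.int64))
    data = DiffractionStack(np.concatenate(frames), mask, geometry)
    scan_positions = ScanPositions(np.concatenate(positions), np.concatenate(scan_ids))
    return data, scan_positions, geometry


def write_reconstruction(
    state: ReconstructionState,
    prepared_path: Union[str, os.PathLike],
    out_path: Union[str, os.PathLike],
) -> None:
    """Write probes/objects once, linked per scan, + external data link."""
    with h5py.File(out_path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        p = f.create_group("reconstruction/p")
        p.create_dataset("probes", data=state.probes.values)
        objs = p.create_group("objects")
        for oid in state.objects.ids():
            ds = objs.create_dataset(f"object_{oid}", data=state.objects.objects[oid])
            ds.attrs["origin"] = np.asarray(state.objects.origins[oid])
        p.create_dataset("probe_share_ID", data=state.share.probe_share_ID)
        p.create_dataset("object_share_ID", data=state.share.object_share_ID)
        if state.error_history:
            engines, iters, values = zip(*state.error_history)
            hist = f.create_group("reconstruction/error_history")
            hist.create_dataset(
                "engine", data=np.array(engines, dtype=h5py.string_dtype())
            )
            hist.create_dataset("iteration", data=np.asarray(iters, dtype=np.int64))
            hist.create_dataset("value", data=np.asarray(values, dtype=float))
        scans = f.create_group("reconstruction/scans")
        for s in range(state.positions.n_scans):
            grp = scans.create_group(_scan_name(s))
            grp["probe"] = h5py.SoftLink("/reconstruction/p/probes")
            oid = state.share.object_id(s)
            grp["object"] = h5py.SoftLink(f"/reconstruction/p/objects/object_{oid}")
        # raw data stays in the prepared file; link, never copy
        rel = os.path.relpath(os.fspath(prepared_path), os.path.dirname(os.fspath(out_path)) or ".")
        f["prepared_data"] = h5py.ExternalLink(rel, "/")


def read_reconstruction(path: Union[str, os.PathLike]) -> ReconstructionState:
    """Rebuild a ReconstructionState from a reconstruction file.

    Resolves the external link to the co-located prepared-data file for
    intensities and positions.
    """
    with h5py.File(path, "r") as f:
        p = f["reconstruction/p"]
        probes = ProbeStack(p["probes"][()])
        objects: Dict[int, np.ndarray] = {}
        origins: Dict[int, Tuple[int, int]] = {}
        for name in p["objects"]:
            oid = int(name.split("_")[1])
            ds = p["objects"][name]
            objects[oid] = ds[()]
            origins[oid] = tuple(int(v) for v in ds.attrs["origin"])
        share = ShareMap(p["probe_share_ID"][()], p["object_share_ID"][()])
        history: List[Tuple[str, int, float]] = []
        if "reconstruction/error_history" in f:
            hist = f["reconstruction/error_history"]
            engines = [e.decode() if isinstance(e, bytes) else str(e) for e in hist["engine"][()]]
            history = list(
                zip(engines, hist["iteration"][()].tolist(), hist["value"][()].tolist())
            )
        prepared = f["prepared_data"]  # resolves the external link
        det = prepared["detector"]
        geometry = ExperimentGeometry(
            wavelength=float(det.attrs["wavelength"]),
            distance_z=float(det.attrs["distance_z"]),
            detector_pixel=float(det.attrs["detector_pixel"]),
            frame_size_N=int(det.attrs["frame_size_N"]),
        )
        mask = det["valid_mask"][()].astype(bool)
        frames, positions, scan_ids = [], [], []
        for s, name in enumerate(sorted(prepared["scans"])):
            grp = prepared["scans"][name]
            ds = grp["data"]
            if ds.attrs.get("compressed", False):
                frames.append(
                    decompress(
                        CompressedStack(
                            ds[()],
                            float(ds.attrs["quantization_step"]),
                            int(ds.attrs["bits"]),
                        )
                    )
                )
            else:
                frames.append(ds[()])
            pos = grp["positions"][()]
            positions.append(pos)
            scan_ids.append(np.full(pos.shape[0], s, dtype=np.int64))
    data = DiffractionStack(np.concatenate(frames), mask, geometry)
    return ReconstructionState(
        geometry=geometry,
        data=data,
        positions=ScanPositions(np.concatenate(positions), np.concatenate(scan_ids)),
        probes=probes,
        objects=ObjectStore(objects, origins),
        share=share,
        error_history=history,
    )


def read_positions(
    path: Union[str, os.PathLike],
    format: str = "ascii",
    units: str = "px",
    geometry: Optional[ExperimentGeometry] = None,
    dataset: str = "positions",
) -> np.ndarray:
    """Read a two-column (y, x) position table, converted to object px.

    ASCII tables are whitespace- or comma-separated, one position per
    line, ``#`` comments allowed.  With ``units='m'`` the values are
    divided by the geometry's effective pixel size.
    """
    if units not in ("px", "m"):
        raise ValueError("units must be 'px' or 'm'")
    if format == "ascii":
        rows: List[Tuple[float, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.split("#", 1)[0].strip()
                if not text:
                    continue
                parts = text.replace(",", " ").split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                    )
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
        if not rows:
            raise ValueError(f"{path}: no positions found")
        pos = np.asarray(rows, dtype=float)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise ValueError(f"{path}: missing dataset {dataset!r}")
            pos = np.asarray(f[dataset][()], dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError(f"{path}: dataset {dataset!r} is not (n, 2)")
        if pos.shape[0] == 0:
            raise ValueError(f"{path}: no positions found")
    else:
        raise ValueError("format must be 'ascii' or 'hdf5'")
    if units == "m":
        if geometry is None:
            raise ValueError("geometry is required to convert metres to pixels")
        pos = pos / effective_pixel_size(geometry)
    return pos


# ----------------------------------------------------------------------
# template / config
# ----------------------------------------------------------------------

_DM_KEYS = {
    "iterations": "n_iterations",
    "eps": "regularization_eps",
    "probe_update_start": "probe_update_start",
    "clip_object_amplitude": "clip_object_amplitude",
    "block_size": "block_size",
    "error_metric": "error_metric",
}
_ML_KEYS = {
    "max_iterations": "max_iterations",
    "error_target": "error_target",
    "armijo_c1": "armijo_c1",
    "powell_threshold": "powell_threshold",
    "bracket_growth": "bracket_growth",
    "max_line_evals": "max_line_evals",
    "block_size": "block_size",
}
_TOP_KEYS = {"engines", "simulation", "output"}


def load_template(path: Union[str, os.PathLike]):
    """Parse a YAML template into an ordered engine chain.

    Returns ``(chain, extras)`` where ``chain`` is a list of
    ``(name, settings)`` pairs — ``DMSettings`` or ``MLSettings`` in
    the order written, with arbitrary repetition — and ``extras``
    holds any ``simulation``/``output`` blocks verbatim.  Unknown
    top-level keys, engine names or engine parameters raise with a
    message naming the offender.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: template must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    engines = doc.get("engines")
    if not isinstance(engines, list) or not engines:
        raise ValueError(f"{path}: 'engines' must be a non-empty list")
    chain = []
    for i, block in enumerate(engines):
        if not isinstance(block, dict) or "name" not in block:
            raise ValueError(f"{path}: engine {i} must be a mapping with a 'name'")
        name = block["name"]
        params = {k: v for k, v in block.items() if k != "name"}
        if name == "dm":
            keymap = _DM_KEYS
            cls = DMSettings
        elif name == "ml":
            keymap = _ML_KEYS
            cls = MLSettings
        else:
            raise ValueError(f"{path}: engine {i}: unknown engine name {name!r}")
        bad = set(params) - set(keymap)
        if bad:
            raise ValueError(
                f"{path}: engine {i} ({name}): unknown parameters {sorted(bad)}"
            )

        def coerce(v):
            # YAML 1.1 reads '1e-6' (no dot) as a string; accept it as a number
            if isinstance(v, str):
                try:
                    return float(v)
                except ValueError:
                    return v
            return v

        chain.append((name, cls(**{keymap[k]: coerce(v) for k, v in params.items()})))
    extras = {k: doc[k] for k in ("simulation", "output") if k in doc}
    return chain, extras
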