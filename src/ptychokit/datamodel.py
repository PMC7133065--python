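"""Shared domain types for ptychographic reconstruction.

A ptychographic data set couples four things: the experiment geometry
(wavelength, detector distance and pixel size, frame size), a stack of
measured diffraction intensities with a valid-pixel mask, the scan
positions at which the illumination visited the sample, and the complex
fields being solved for — the probe (illumination) and the object
(sample transmissivity).  Several scans may be reconstructed jointly
while pointing at common probe or object storage slices; the share maps
below record that wiring.

Conventions used throughout the package:

* coordinates are 0-based ``(row=y, col=x)``, origin at the top-left of
  each object array;
* scan positions are stored in object-plane pixels (conversion from
  metres happens at ingest, via :func:`effective_pixel_size`);
* fractional positions are rounded to the nearest pixel for view
  extraction, with ties rounding to even;
* probes are stored as a 4-D array ``(y, x, probe_ID, mode)`` and
  objects as a mapping ``object_ID -> (y, x, mode, layer)``.  Only
  object mode 1 / layer 1 is solved; the extra axes are storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ExperimentGeometry",
    "ScanPositions",
    "DiffractionStack",
    "ProbeStack",
    "ObjectStore",
    "ShareMap",
    "ReconstructionState",
    "effective_pixel_size",
    "resolve_share",
    "validate_state",
    "round_half_even",
]


def round_half_even(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties to even (numpy's default)."""
    return np.rint(np.asarray(values)).astype(np.int64)


@dataclass(frozen=True)
class ExperimentGeometry:
    """Far-field measurement geometry.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in metres.
    distance_z : float
        Sample-to-detector distance in metres.
    detector_pixel : float
        Detector pixel pitch in metres.
    frame_size_N : int
        Detector readout size (frames are ``N x N`` pixels).
    """

    wavelength: float
    distance_z: float
    detector_pixel: float
    frame_size_N: int

    def __post_init__(self) -> None:
        for name in ("wavelength", "distance_z", "detector_pixel"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if int(self.frame_size_N) != self.frame_size_N or self.frame_size_N <= 0:
            raise ValueError(f"frame_size_N must be a positive integer, got {self.frame_size_N!r}")

    @property
    def effective_pixel_size(self) -> float:
        return effective_pixel_size(self)


def effective_pixel_size(geometry: ExperimentGeometry) -> float:
    """Real-space sampling of the reconstruction, ``lambda * z / (N * dd)``.

    This is the pixel size at the sample plane implied by the far-field
    geometry: finer detector sampling (larger ``N`` or pixel ``dd``)
    means a coarser angular range per pixel and hence a smaller
    real-space pixel.
    """
    g = geometry
    return g.wavelength * g.distance_z / (g.frame_size_N * g.detector_pixel)


@dataclass
class ScanPositions:
    """Scan positions in object-plane pixels.

    ``positions`` is an ``(n, 2)`` float array of ``(y, x)`` pairs;
    ``scan_id`` labels which scan each position belongs to (0-based).
    """

    positions: np.ndarray
    scan_id: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of (y, x) pairs")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.scan_id = np.asarray(self.scan_id, dtype=np.int64)
        if self.scan_id.shape != (self.positions.shape[0],):
            raise ValueError("scan_id must have one entry per position")
        if self.positions.shape[0] < 1:
            raise ValueError("at least one position is required")

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]

    @property
    def n_scans(self) -> int:
        return int(self.scan_id.max()) + 1 if self.scan_id.size else 0

    def rounded(self) -> np.ndarray:
        """Integer (y, x) corners, ties-to-even."""
        return round_half_even(self.positions)


@dataclass
class DiffractionStack:
    """Measured intensities ``(position, y, x)`` plus valid-pixel mask.

    The mask may be a single ``(y, x)`` frame shared by all positions or
    a full ``(position, y, x)`` stack; it excludes dead or shadowed
    detector pixels from every constraint and error metric.
    """

    intensities: np.ndarray
    valid_mask: np.ndarray
    geometry: ExperimentGeometry

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (position, y, x)")
        n = self.geometry.frame_size_N
        if self.intensities.shape[1:] != (n, n):
            raise ValueError(
                f"frame shape {self.intensities.shape[1:]} does not match geometry N={n}"
            )
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape not in (self.intensities.shape, self.intensities.shape[1:]):
            raise ValueError("valid_mask must be (y, x) or (position, y, x)")
        if not self.valid_mask.any():
            raise ValueError("valid_mask must have a nonzero True fraction")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    def mask_for(self, j: int) -> np.ndarray:
        """Valid-pixel mask for frame ``j`` (handles shared masks)."""
        if self.valid_mask.ndim == 2:
            return self.valid_mask
        return self.valid_mask[j]


@dataclass
class ProbeStack:
    """Complex probes stored as ``(y, x, probe_ID, mode)``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 4:
            raise ValueError("probe values must be (y, x, probe_ID, mode)")

    @property
    def shape_yx(self) -> Tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_probes(self) -> int:
        return self.values.shape[2]

    @property
    def n_modes(self) -> int:
        return self.values.shape[3]

    def slice(self, probe_id: int) -> np.ndarray:
        """All modes of one probe slice, shape ``(y, x, mode)`` (a view)."""
        return self.values[:, :, probe_id, :]

    def energies(self) -> np.ndarray:
        """Total |P|^2 per (probe_ID, mode)."""
        return np.sum(np.abs(self.values) ** 2, axis=(0, 1))


@dataclass
class ObjectStore:
    """Container of complex objects, ``object_ID -> (y, x, mode, layer)``.

    ``origins`` maps each object ID to the (y, x) pixel offset of its
    top-left corner in the common scan coordinate frame, so objects of
    different extents can coexist.
    """

    objects: Dict[int, np.ndarray]
    origins: Dict[int, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for oid, arr in list(self.objects.items()):
            arr = np.asarray(arr, dtype=complex)
            if arr.ndim == 2:
                arr = arr[:, :, None, None]
            if arr.ndim != 4:
                raise ValueError(f"object {oid} must be (y, x, mode, layer)")
            if arr.size == 0:
                raise ValueError(f"object {oid} is empty")
            self.objects[oid] = arr
            self.origins.setdefault(oid, (0, 0))

    def field2d(self, oid: int) -> np.ndarray:
        """Solved component (mode 1, layer 1) of an object, as a 2-D view."""
        return self.objects[oid][:, :, 0, 0]

    def set_field2d(self, oid: int, values: np.ndarray) -> None:
        self.objects[oid][:, :, 0, 0] = values

    def ids(self) -> List[int]:
        return sorted(self.objects)


def _renumber(vec: np.ndarray) -> np.ndarray:
    """Renumber arbitrary positive labels to dense 1..K, order of first use."""
    out = np.empty_like(vec)
    mapping: Dict[int, int] = {}
    for i, v in enumerate(vec):
        if v <= 0:
            raise ValueError(f"share IDs must be positive, got {v} at index {i}")
        mapping.setdefault(int(v), len(mapping) + 1)
        out[i] = mapping[int(v)]
    return out


@dataclass
class ShareMap:
    """Pointers from scans to probe/object storage slices.

    ``probe_share_ID[s]`` names the probe slice scan ``s`` reads and
    updates; likewise for objects.  E.g. ``probe_share_ID = (1, 2, 1)``
    over three scans allocates two probes, with scans 1 and 3 sharing
    the first.  IDs are renumbered to dense ``1..K`` on construction, so
    ``(2, 7, 2)`` is equivalent to ``(1, 2, 1)``.
    """

    probe_share_ID: np.ndarray
    object_share_ID: np.ndarray

    def __post_init__(self) -> None:
        self.probe_share_ID = _renumber(np.asarray(self.probe_share_ID, dtype=np.int64))
        self.object_share_ID = _renumber(np.asarray(self.object_share_ID, dtype=np.int64))
        if self.probe_share_ID.shape != self.object_share_ID.shape:
            raise ValueError("probe and object share vectors must have equal length")

    @property
    def n_scans(self) -> int:
        return self.probe_share_ID.shape[0]

    @property
    def n_probe_slices(self) -> int:
        return int(self.probe_share_ID.max())

    @property
    def n_object_slices(self) -> int:
        return int(self.object_share_ID.max())

    def probe_index(self, scan: int) -> int:
        """0-based probe slice index for a 0-based scan index."""
        return int(self.probe_share_ID[scan]) - 1

    def object_id(self, scan: int) -> int:
        """Object ID (1-based, as stored in ObjectStore) for a scan."""
        return int(self.object_share_ID[scan])


def resolve_share(share_map: ShareMap, n_scans: int) -> Tuple[int, int]:
    """Count distinct probe and object slices for ``n_scans`` scans.

    Raises if the share vectors do not have one entry per scan.
    """
    if share_map.n_scans != n_scans:
        raise ValueError(
            f"share vectors have length {share_map.n_scans}, expected {n_scans}"
        )
    return share_map.n_probe_slices, share_map.n_object_slices


@dataclass
class ReconstructionState:
    """The full mutable reconstruction record (the toolkit's 'p structure').

    Bundles geometry, measured data, positions, probes, objects, share
    maps, engine settings and the accumulated error history.  Engines
    take and return this record; shapes never change across an engine
    step unless the engine declares a resize.
    """

    geometry: ExperimentGeometry
    data: DiffractionStack
    positions: ScanPositions
    probes: ProbeStack
    objects: ObjectStore
    share: ShareMap
    settings: dict = field(default_factory=dict)
    error_history: List[Tuple[str, int, float]] = field(default_factory=list)

    def record_error(self, engine: str, iteration: int, value: float) -> None:
        self.error_history.append((engine, int(iteration), float(value)))

    def copy(self) -> "ReconstructionState":
        """Deep copy of the mutable numerical content."""
        return ReconstructionState(
            geometry=self.geometry,
            data=DiffractionStack(
                self.data.intensities.copy(), self.data.valid_mask.copy(), self.geometry
            ),
            positions=ScanPositions(self.positions.positions.copy(), self.positions.scan_id.copy()),
            probes=ProbeStack(self.probes.values.copy()),
            objects=ObjectStore(
                {k: v.copy() for k, v in self.objects.objects.items()},
                dict(self.objects.origins),
            ),
            share=ShareMap(self.share.probe_share_ID.copy(), self.share.object_share_ID.copy()),
            settings=dict(self.settings),
            error_history=list(self.error_history),
        )


def validate_state(state: ReconstructionState) -> List[str]:
    """Check every structural invariant; return a list of violations.

    Report-only: never raises.  An empty list means the state is
    consistent and ready for any engine.
    """
    v: List[str] = []
    n = state.geometry.frame_size_N

    ints = state.data.intensities
    if ints.shape[1:] != (n, n):
        v.append(f"frame shape {ints.shape[1:]} != geometry ({n}, {n})")
    neg = np.argwhere(ints < 0)
    if neg.size:
        v.append(f"negative intensity in frame {int(neg[0, 0])}")
    if not state.data.valid_mask.any():
        v.append("valid mask is empty")

    if ints.shape[0] != state.positions.n_positions:
        v.append(
            f"{ints.shape[0]} frames but {state.positions.n_positions} positions"
        )

    try:
        resolve_share(state.share, state.positions.n_scans)
    except ValueError as exc:
        v.append(str(exc))

    if state.probes.n_probes < state.share.n_probe_slices:
        v.append(
            f"{state.probes.n_probes} probe slices allocated, "
            f"{state.share.n_probe_slices} required by share map"
        )
    energies = state.probes.energies()
    for pid in range(state.probes.n_probes):
        if not np.any(energies[pid] > 0):
            v.append(f"probe slice {pid} has no mode with nonzero energy")

    py, px = state.probes.shape_yx
    corners = state.positions.rounded()
    for j in range(state.positions.n_positions):
        scan = int(state.positions.scan_id[j])
        oid = state.share.object_id(scan)
        if oid not in state.objects.objects:
            v.append(f"scan {scan} references missing object {oid}")
            continue
        oy, ox = state.objects.origins[oid]
        h, w = state.objects.objects[oid].shape[:2]
        y, x = corners[j] - (oy, ox)
        if y < 0 or x < 0 or y + py > h or x + px > w:
            v.append(
                f"position {j} (scan {scan}) footprint outside object {oid} extent"
            )
    return v
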