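"""The ptychographic measurement model.

An exit wave at scan position ``r_j`` is the product of the (shifted)
probe and the object transmissivity, ``Psi_j(r) = P(r - r_j) O(r)``,
one per incoherent probe mode.  The detector sees the incoherent sum of
the propagated mode intensities, ``I_j(q) = sum_m |F Psi_jm|^2``.

Views are handled in blocks: a :class:`ViewBlock` bundles probe-sized
object patches (or exit waves) for a contiguous run of positions.
Blocking exists purely to bound memory — results are identical for any
partition, because every accumulation below walks positions in index
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import ObjectStore, ProbeStack, ScanPositions, ShareMap
from .propagators import fft2c

__all__ = [
    "ViewBlock",
    "extract_views",
    "exit_waves",
    "model_intensity",
    "iter_blocks",
    "block_size_for_budget",
]


@dataclass
class ViewBlock:
    """Probe-sized complex patches for a run of scan positions.

    ``views`` has shape ``(position, y, x, mode)``; ``corners`` are the
    rounded top-left (y, x) pixels of each patch in object coordinates;
    ``scan_ids`` names the owning scan of each position; ``indices``
    are the global position indices this block covers.
    """

    views: np.ndarray
    corners: np.ndarray
    scan_ids: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=complex)
        if self.views.ndim == 3:
            self.views = self.views[..., None]
        if self.views.ndim != 4:
            raise ValueError("views must be (position, y, x, mode)")

    @property
    def n_views(self) -> int:
        return self.views.shape[0]

    @property
    def n_modes(self) -> int:
        return self.views.shape[3]


def iter_blocks(n_positions: int, block_size: Optional[int] = None) -> Iterator[np.ndarray]:
    """Yield contiguous runs of position indices of at most ``block_size``."""
    if block_size is None or block_size >= n_positions:
        yield np.arange(n_positions)
        return
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    for start in range(0, n_positions, block_size):
        yield np.arange(start, min(start + block_size, n_positions))


def block_size_for_budget(memory_budget_bytes: int, probe_shape: Tuple[int, int], n_modes: int) -> int:
    """Largest block size whose exit-wave storage fits the byte budget."""
    per_view = probe_shape[0] * probe_shape[1] * n_modes * np.dtype(complex).itemsize
    return max(1, int(memory_budget_bytes // per_view))


def extract_views(
    objects: ObjectStore,
    positions: ScanPositions,
    share: ShareMap,
    probe_shape: Tuple[int, int],
    indices: Optional[np.ndarray] = None,
) -> ViewBlock:
    """Read the object patch under the probe at each scan position.

    Positions are rounded to the nearest pixel (ties to even).  The
    returned patches are copies — mutating them never aliases object
    storage.  Raises if any footprint leaves its object's extent.
    """
    if indices is None:
        indices = np.arange(positions.n_positions)
    indices = np.asarray(indices, dtype=np.int64)
    py, px = probe_shape
    corners = positions.rounded()[indices]
    scan_ids = positions.scan_id[indices]
    out = np.empty((indices.size, py, px, 1), dtype=complex)
    for k, j in enumerate(indices):
        oid = share.object_id(int(scan_ids[k]))
        oy, ox = objects.origins[oid]
        obj = objects.field2d(oid)
        y, x = corners[k] - (oy, ox)
        if y < 0 or x < 0 or y + py > obj.shape[0] or x + px > obj.shape[1]:
            raise ValueError(
                f"position {int(indices[k])} footprint [{y}:{y+py}, {x}:{x+px}] "
                f"outside object {oid} extent {obj.shape}"
            )
        out[k, :, :, 0] = obj[y : y + py, x : x + px]
    return ViewBlock(out, corners, scan_ids, indices)


def exit_waves(probe: ProbeStack, patches: ViewBlock, share: ShareMap) -> ViewBlock:
    """Multiply each object patch by its scan's shared probe, per mode."""
    py, px = probe.shape_yx
    if patches.views.shape[1:3] != (py, px):
        raise ValueError("patch extent does not match probe extent")
    n = patches.n_views
    out = np.empty((n, py, px, probe.n_modes), dtype=complex)
    for k in range(n):
        pid = share.probe_index(int(patches.scan_ids[k]))
        out[k] = probe.values[:, :, pid, :] * patches.views[k, :, :, 0:1]
    return ViewBlock(out, patches.corners, patches.scan_ids, patches.indices)


def model_intensity(exit: ViewBlock) -> np.ndarray:
    """Detector-plane intensities ``sum_m |F Psi_m|^2``, shape (position, y, x)."""
    spectra = fft2c(np.moveaxis(exit.views, 3, 1))  # (pos, mode, y, x)
    return np.sum(np.abs(spectra) ** 2, axis=1)
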