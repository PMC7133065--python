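"""Difference-map reconstruction engine.

The difference map solves the phase problem by combining two
projections of the exit-wave stack:

* Fourier projection ``P_F`` — propagate each exit-wave mode to the
  detector, rescale all modes at valid pixels so the modelled modal
  intensity matches the measurement, leave invalid pixels untouched,
  propagate back.
* overlap projection ``P_O`` — find the probe and object that best
  explain all exit waves in the least-squares sense, then replace the
  exit waves by the consistent products ``P * O``.

This engine applies the Fourier projection first and the overlap
projection second; with a good initial guess this ordering skips the
redundant first overlap projection.  One iteration updates the
exit-wave stack as::

    Psi <- Psi + P_O(2 P_F(Psi) - Psi) - P_F(Psi)

The error metric is the summed squared difference between modelled and
measured detector-plane amplitudes over valid pixels (an absolute-value
variant is available via ``error_metric='abs'``), reported raw and
normalized by the measured flux.

Updates are accumulated position-by-position in index order, so results
are independent of the view-block partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .datamodel import DiffractionStack, ObjectStore, ProbeStack, ReconstructionState
from .forward import ViewBlock, exit_waves, extract_views, iter_blocks, model_intensity
from .propagators import fft2c, ifft2c

__all__ = [
    "DMSettings",
    "fourier_projection",
    "overlap_projection",
    "dm_error",
    "dm_iterate",
]


@dataclass
class DMSettings:
    """Difference-map engine parameters.

    ``regularization_eps`` is relative: the denominator of each overlap
    quotient is floored at ``regularization_eps * max(denominator)``,
    which leaves well-illuminated pixels exactly at their least-squares
    value while damping the unconstrained ones.  The probe update is
    frozen for the first ``probe_update_start`` iterations so the
    object can settle first.
    """

    n_iterations: int = 100
    regularization_eps: float = 1e-4
    probe_update_start: int = 3
    clip_object_amplitude: Optional[float] = None
    block_size: Optional[int] = None
    error_metric: str = "squared"  # or "abs"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.regularization_eps <= 0:
            raise ValueError("regularization_eps must be positive")
        if self.error_metric not in ("squared", "abs"):
            raise ValueError("error_metric must be 'squared' or 'abs'")


def fourier_projection(exit: ViewBlock, data: DiffractionStack) -> ViewBlock:
    """Impose the measured modal amplitudes at valid detector pixels.

    All modes of a view are rescaled by the same factor
    ``sqrt(I_meas / sum_m |psi_hat_m|^2)`` (0/0 -> 0), so their
    incoherent sum matches the measurement while relative mode content
    is preserved.  Invalid pixels keep the modelled values.
    """
    spectra = fft2c(np.moveaxis(exit.views, 3, 1))  # (pos, mode, y, x)
    out = np.empty_like(spectra)
    for k in range(exit.n_views):
        j = int(exit.indices[k])
        mask = data.mask_for(j)
        total = np.sum(np.abs(spectra[k]) ** 2, axis=0)
        factor = np.ones_like(total)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.sqrt(data.intensities[j] / total)
        ratio[~np.isfinite(ratio)] = 0.0  # 0/0 and I/0 both collapse to 0
        factor[mask] = ratio[mask]
        with np.errstate(invalid="ignore"):  # non-finite iterates pass through
            out[k] = spectra[k] * factor[None]
    return ViewBlock(np.moveaxis(ifft2c(out), 1, 3), exit.corners, exit.scan_ids, exit.indices)


def _object_extents(objects: ObjectStore) -> Dict[int, Tuple[int, int]]:
    return {oid: objects.objects[oid].shape[:2] for oid in objects.ids()}


def overlap_projection(
    state: ReconstructionState,
    exit: ViewBlock,
    settings: Optional[DMSettings] = None,
    update_probe: bool = True,
) -> Tuple[ProbeStack, ObjectStore, ViewBlock]:
    """Least-squares consistent probe and object for an exit-wave stack.

    The object update ``O <- sum_j P* Psi_j / sum_j |P|^2`` accumulates
    over every view of every scan sharing the object slice (summing
    over probe modes); the probe update then uses the refreshed object,
    per mode, over every scan sharing the probe slice.  Each quotient's
    denominator is floored at ``eps_rel * max(denominator)``.  Returns
    the new probe, object and the consistent views ``P * O``.
    """
    settings = settings or DMSettings()
    probes = state.probes
    share = state.share
    py, px = probes.shape_yx
    if exit.n_views == 0:
        raise ValueError("overlap projection needs at least one view")

    # --- object update -------------------------------------------------
    num: Dict[int, np.ndarray] = {}
    den: Dict[int, np.ndarray] = {}
    for oid, shape in _object_extents(state.objects).items():
        num[oid] = np.zeros(shape, dtype=complex)
        den[oid] = np.zeros(shape, dtype=float)
    for k in range(exit.n_views):
        scan = int(exit.scan_ids[k])
        oid = share.object_id(scan)
        pid = share.probe_index(scan)
        oy, ox = state.objects.origins[oid]
        y, x = exit.corners[k] - (oy, ox)
        p = probes.values[:, :, pid, :]
        num[oid][y : y + py, x : x + px] += np.sum(np.conj(p) * exit.views[k], axis=2)
        den[oid][y : y + py, x : x + px] += np.sum(np.abs(p) ** 2, axis=2)

    new_objects = ObjectStore(
        {oid: arr.copy() for oid, arr in state.objects.objects.items()},
        dict(state.objects.origins),
    )
    for oid in new_objects.ids():
        floor = settings.regularization_eps * max(den[oid].max(), np.finfo(float).tiny)
        o = num[oid] / np.maximum(den[oid], floor)
        if settings.clip_object_amplitude is not None:
            mag = np.abs(o)
            over = mag > settings.clip_object_amplitude
            o[over] *= settings.clip_object_amplitude / mag[over]
        new_objects.set_field2d(oid, o)

    # --- probe update ---------------------------------------------------
    if update_probe:
        pnum = np.zeros_like(probes.values)
        pden = np.zeros((py, px, probes.n_probes), dtype=float)
        for k in range(exit.n_views):
            scan = int(exit.scan_ids[k])
            oid = share.object_id(scan)
            pid = share.probe_index(scan)
            oy, ox = new_objects.origins[oid]
            y, x = exit.corners[k] - (oy, ox)
            patch = new_objects.field2d(oid)[y : y + py, x : x + px]
            pnum[:, :, pid, :] += np.conj(patch)[:, :, None] * exit.views[k]
            pden[:, :, pid] += np.abs(patch) ** 2
        new_values = np.empty_like(probes.values)
        for pid in range(probes.n_probes):
            floor = settings.regularization_eps * max(pden[:, :, pid].max(), np.finfo(float).tiny)
            new_values[:, :, pid, :] = pnum[:, :, pid, :] / np.maximum(
                pden[:, :, pid], floor
            )[:, :, None]
        new_probes = ProbeStack(new_values)
    else:
        new_probes = ProbeStack(probes.values.copy())

    # --- refreshed consistent views ------------------------------------
    refreshed = np.empty_like(exit.views)
    for k in range(exit.n_views):
        scan = int(exit.scan_ids[k])
        oid = share.object_id(scan)
        pid = share.probe_index(scan)
        oy, ox = new_objects.origins[oid]
        y, x = exit.corners[k] - (oy, ox)
        patch = new_objects.field2d(oid)[y : y + py, x : x + px]
        refreshed[k] = new_probes.values[:, :, pid, :] * patch[:, :, None]
    return new_probes, new_objects, ViewBlock(refreshed, exit.corners, exit.scan_ids, exit.indices)


def dm_error(
    state: ReconstructionState,
    block_size: Optional[int] = None,
    metric: str = "squared",
) -> Tuple[float, float]:
    """Detector-plane amplitude mismatch over valid pixels and positions.

    Returns ``(raw, normalized)`` where raw is
    ``sum_k sum_l (sqrt(I_model) - sqrt(I_meas))^2`` (or the absolute
    difference when ``metric='abs'``) and normalized divides by the
    measured flux over valid pixels.
    """
    raw = 0.0
    flux = 0.0
    probe_shape = state.probes.shape_yx
    for idx in iter_blocks(state.positions.n_positions, block_size):
        patches = extract_views(state.objects, state.positions, state.share, probe_shape, idx)
        views = exit_waves(state.probes, patches, state.share)
        i_model = model_intensity(views)
        for k, j in enumerate(idx):
            mask = state.data.mask_for(int(j))
            diff = np.sqrt(i_model[k][mask]) - np.sqrt(state.data.intensities[j][mask])
            raw += float(np.sum(diff**2 if metric == "squared" else np.abs(diff)))
            flux += float(np.sum(state.data.intensities[j][mask]))
    return raw, raw / flux if flux > 0 else raw


def _full_views(state: ReconstructionState) -> ViewBlock:
    patches = extract_views(
        state.objects, state.positions, state.share, state.probes.shape_yx
    )
    return exit_waves(state.probes, patches, state.share)


def dm_iterate(state: ReconstructionState, settings: DMSettings) -> ReconstructionState:
    """Run ``n_iterations`` of the difference map on a copy of ``state``.

    The exit-wave stack is initialized from the current probe and
    object.  The normalized error of the refreshed model is recorded in
    the state's error history every iteration.  Raises ``FloatingPointError``
    if the iterate diverges to NaN/Inf.
    """
    state = state.copy()
    psi = _full_views(state).views.copy()
    n_pos = state.positions.n_positions
    corners = state.positions.rounded()
    scan_ids = state.positions.scan_id

    for it in range(settings.n_iterations):
        update_probe = it >= settings.probe_update_start
        # P_F blockwise on the full stack
        pf = np.empty_like(psi)
        for idx in iter_blocks(n_pos, settings.block_size):
            block = ViewBlock(psi[idx], corners[idx], scan_ids[idx], idx)
            pf[idx] = fourier_projection(block, state.data).views
        # P_O on the reflected stack 2*P_F(psi) - psi
        reflected = ViewBlock(2.0 * pf - psi, corners, scan_ids, np.arange(n_pos))
        new_probes, new_objects, refreshed = overlap_projection(
            state, reflected, settings, update_probe=update_probe
        )
        psi += refreshed.views - pf
        state.probes = new_probes
        state.objects = new_objects
        if not np.all(np.isfinite(psi)):
            raise FloatingPointError(
                f"difference map diverged (NaN/Inf in exit waves) at iteration {it}"
            )
        raw, norm = dm_error(state, settings.block_size, settings.error_metric)
        state.record_error("dm", it, norm)
    return state
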