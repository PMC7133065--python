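"""Synthetic ptychography data and ground-truth scoring.

Generates everything the engines and the codec need for end-to-end
testing without real beamline data: a focused-aperture complex probe
(optionally with incoherent modes), a disc-phantom transmissivity
object, a jittered raster or Fermat-spiral scan, and far-field
diffraction stacks with optional Poisson counting noise at a
controllable flux.

Because probe and object are only determined up to a global complex
scale and an affine phase (a phase offset plus a linear ramp traded
against the probe), scoring utilities here remove those ambiguities
over the well-illuminated region before computing phase RMSE or SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .datamodel import (
    DiffractionStack,
    ExperimentGeometry,
    ObjectStore,
    ProbeStack,
    ReconstructionState,
    ScanPositions,
    ShareMap,
)
from .forward import exit_waves, extract_views, model_intensity
from .propagators import Wavefield, propagate_asm

__all__ = [
    "SimulationSpec",
    "make_probe",
    "make_object",
    "make_scan",
    "simulate_measurement",
    "initial_state",
    "well_illuminated_mask",
    "align_object",
    "phase_rmse",
    "snr_db",
    "frc_resolution",
]

# Default geometry: 0.1 nm illumination, 7.2 m camera distance, 112.5 um
# detector pixels at a 64-pixel readout -> 100 nm effective pixel size.
_DEFAULT_GEOMETRY = ExperimentGeometry(
    wavelength=1e-10, distance_z=7.2, detector_pixel=1.125e-4, frame_size_N=64
)


@dataclass
class SimulationSpec:
    """All knobs of one synthetic experiment.

    Defaults describe a desk-scale far-field scan: a 3.2 um aperture
    (32 object pixels) slightly defocused, a 7x7 raster with 60%
    linear overlap (step = 0.4 x aperture diameter) and 10% jitter,
    1e6 photons per frame on average, one coherent mode, Poisson noise.
    """

    geometry: ExperimentGeometry = field(default_factory=lambda: _DEFAULT_GEOMETRY)
    aperture_diameter: float = 3.2e-6  # [m]
    defocus: float = 2.4e-4  # [m]
    phantom: str = "discs"
    amplitude_range: Tuple[float, float] = (0.7, 1.0)
    phase_range: float = 1.0  # [rad], phases drawn in [-phase_range, +phase_range]
    scan_pattern: str = "raster"  # or "fermat"
    scan_step: float = 12.8  # [object px]; 0.4 * aperture -> 60% overlap
    grid_size: Tuple[int, int] = (7, 7)
    jitter_fraction: float = 0.1
    flux: float = 1e6  # mean total counts per frame
    modes: int = 1
    mode_fractions: Optional[Tuple[float, ...]] = None
    noise: str = "poisson"  # or "none"
    dead_pixel_fraction: float = 0.0
    pad: int = 8  # object padding beyond the scan footprint [px]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flux <= 0:
            raise ValueError("flux must be positive")
        if not 0 <= self.jitter_fraction < 0.5:
            raise ValueError("jitter fraction must lie in [0, 0.5)")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.modes < 1:
            raise ValueError("at least one probe mode is required")


def make_probe(spec: SimulationSpec) -> ProbeStack:
    """Focused-aperture illumination with optional incoherent modes.

    A binary circular aperture is propagated by the defocus distance
    with the angular spectrum method and normalized to unit energy.
    Additional modes are phase-ramped copies of the aperture,
    orthonormalized against the earlier modes, carrying energy
    fractions proportional to ``4**-k`` (0.8/0.2 for two modes),
    renormalized to unit total energy.
    """
    g = spec.geometry
    n = g.frame_size_N
    dr = g.effective_pixel_size
    radius_px = spec.aperture_diameter / (2 * dr)
    if 2 * radius_px >= n:
        raise ValueError("aperture diameter must be smaller than the field of view")
    yy, xx = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
    disc = (yy**2 + xx**2 <= radius_px**2).astype(complex)

    def focus(fld: np.ndarray) -> np.ndarray:
        if spec.defocus == 0:
            return fld
        return propagate_asm(Wavefield(fld, dr), spec.defocus, g.wavelength).values

    modes = []
    for m in range(spec.modes):
        ramp = np.exp(2j * np.pi * (m * xx + (m % 2) * m * yy) / (4 * radius_px))
        fld = focus(disc * ramp)
        for prev in modes:  # Gram-Schmidt against existing modes
            fld = fld - np.vdot(prev, fld) * prev
        norm = np.linalg.norm(fld)
        if norm == 0:
            raise ValueError(f"probe mode {m} degenerated to zero")
        modes.append(fld / norm)

    if spec.mode_fractions is not None:
        fractions = np.asarray(spec.mode_fractions, dtype=float)
        if fractions.size != spec.modes or np.any(fractions <= 0):
            raise ValueError("mode_fractions must be positive, one per mode")
    else:
        fractions = 4.0 ** -np.arange(spec.modes)
    fractions = fractions / fractions.sum()
    values = np.stack(
        [np.sqrt(fr) * fld for fr, fld in zip(fractions, modes)], axis=-1
    )
    return ProbeStack(values[:, :, None, :])


def _disc_phantom(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Overlapping-discs texture in [0, 1], deterministic given the rng."""
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    tex = np.zeros((h, w))
    n_discs = max(12, (h * w) // 900)
    for _ in range(n_discs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(0.04, 0.18) * min(h, w)
        weight = rng.uniform(-1.0, 1.0)
        tex += weight * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (r / 2) ** 2))
    lo, hi = tex.min(), tex.max()
    if hi > lo:
        tex = (tex - lo) / (hi - lo)
    else:
        tex = np.zeros_like(tex)
    return tex


def make_object(spec: SimulationSpec, shape: Tuple[int, int]) -> ObjectStore:
    """Deterministic complex phantom of the requested extent.

    Amplitude lies in ``[a_min, a_max]`` and phase in
    ``[-phase_range, +phase_range]``; two independent disc textures
    drive the two channels so they decorrelate.
    """
    a_min, a_max = spec.amplitude_range
    if not (0 <= a_min <= a_max <= 1):
        raise ValueError("amplitude range must satisfy 0 <= a_min <= a_max <= 1")
    rng = np.random.default_rng(spec.seed)
    amp_tex = _disc_phantom(shape, rng)
    phase_tex = _disc_phantom(shape, rng)
    amplitude = a_max - (a_max - a_min) * amp_tex
    phase = spec.phase_range * (2 * phase_tex - 1)
    obj = amplitude * np.exp(1j * phase)
    return ObjectStore({1: obj[:, :, None, None]}, {1: (0, 0)})


def make_scan(spec: SimulationSpec) -> ScanPositions:
    """Scan positions for one scan, in object-plane pixels.

    Raster scans get uniform jitter of up to ``jitter_fraction * step``
    per axis (seeded) to break the raster-grid ambiguity; the Fermat
    spiral is quasi-uniform by construction and gets none.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if spec.scan_pattern == "raster":
        rows, cols = spec.grid_size
        gy, gx = np.meshgrid(
            np.arange(rows) * spec.scan_step, np.arange(cols) * spec.scan_step, indexing="ij"
        )
        pos = np.column_stack([gy.ravel(), gx.ravel()])
        if spec.jitter_fraction > 0:
            pos = pos + rng.uniform(
                -spec.jitter_fraction * spec.scan_step,
                spec.jitter_fraction * spec.scan_step,
                size=pos.shape,
            )
    elif spec.scan_pattern == "fermat":
        n_points = spec.grid_size[0] * spec.grid_size[1]
        k = np.arange(n_points)
        golden = np.pi * (3 - np.sqrt(5))
        r = spec.scan_step * 0.57 * np.sqrt(k)
        pos = np.column_stack([r * np.sin(k * golden), r * np.cos(k * golden)])
        pos -= pos.min(axis=0)
    else:
        raise ValueError(f"unknown scan pattern {spec.scan_pattern!r}")
    return ScanPositions(pos, np.zeros(pos.shape[0], dtype=np.int64))


def simulate_measurement(
    spec: SimulationSpec,
) -> Tuple[ReconstructionState, Dict[str, np.ndarray]]:
    """Simulate one scan end to end.

    Builds probe, object and positions, evaluates the far-field modal
    intensity model, scales the probe so the mean total per frame
    equals ``flux``, and applies Poisson sampling if requested.  The
    returned state carries the *true* probe and object (callers
    re-initialize before reconstructing); the ground-truth record holds
    copies of both plus the positions.
    """
    g = spec.geometry
    n = g.frame_size_N
    probe = make_probe(spec)
    positions = make_scan(spec)
    # shift positions so every probe footprint fits the padded object
    shifted = positions.positions - positions.positions.min(axis=0) + spec.pad
    positions = ScanPositions(shifted, positions.scan_id)
    extent = (
        int(np.ceil(shifted[:, 0].max())) + n + spec.pad,
        int(np.ceil(shifted[:, 1].max())) + n + spec.pad,
    )
    objects = make_object(spec, extent)
    share = ShareMap([1], [1])

    patches = extract_views(objects, positions, share, (n, n))
    views = exit_waves(probe, patches, share)
    intensities = model_intensity(views)
    scale = spec.flux / intensities.sum(axis=(1, 2)).mean()
    probe = ProbeStack(probe.values * np.sqrt(scale))
    intensities = intensities * scale

    rng = np.random.default_rng(spec.seed + 2)
    if spec.noise == "poisson":
        intensities = rng.poisson(intensities).astype(float)
    if spec.dead_pixel_fraction > 0:
        mask = rng.random((n, n)) >= spec.dead_pixel_fraction
    else:
        mask = np.ones((n, n), dtype=bool)

    data = DiffractionStack(intensities, mask, g)
    state = ReconstructionState(
        geometry=g,
        data=data,
        positions=positions,
        probes=probe,
        objects=objects,
        share=share,
    )
    truth = {
        "probe": probe.values.copy(),
        "object": objects.field2d(1).copy(),
        "positions": positions.positions.copy(),
    }
    return state, truth


def initial_state(
    state: ReconstructionState,
    probe_init: Optional[np.ndarray] = None,
    n_modes: Optional[int] = None,
) -> ReconstructionState:
    """Reconstruction starting point: flat object, model probe.

    The object is reset to ones; the probe defaults to the state's
    current probe (the illumination model).  ``n_modes`` truncates or
    keeps the probe's mode count, e.g. to attempt a single-mode
    reconstruction of mixed-state data.
    """
    out = state.copy()
    for oid in out.objects.ids():
        out.objects.objects[oid][:] = 1.0
    values = probe_init if probe_init is not None else out.probes.values
    values = np.array(values, dtype=complex, copy=True)
    if n_modes is not None:
        if n_modes > values.shape[3]:
            raise ValueError("cannot request more modes than the model probe has")
        kept = values[:, :, :, :n_modes]
        # keep total energy so flux bookkeeping stays comparable
        e_all = np.sum(np.abs(values) ** 2)
        e_kept = np.sum(np.abs(kept) ** 2)
        values = kept * np.sqrt(e_all / e_kept)
    out.probes = ProbeStack(values)
    out.error_history = []
    return out


# ----------------------------------------------------------------------
# ground-truth scoring
# ----------------------------------------------------------------------

def well_illuminated_mask(
    state: ReconstructionState, oid: int = 1, threshold: float = 0.1
) -> np.ndarray:
    """Pixels whose accumulated illumination exceeds 10% of the peak.

    The accumulated footprint is ``sum_j |P(r - r_j)|^2`` over all
    modes and positions of the scans sharing object ``oid``.
    """
    py, px = state.probes.shape_yx
    shape = state.objects.objects[oid].shape[:2]
    acc = np.zeros(shape)
    corners = state.positions.rounded()
    oy, ox = state.objects.origins[oid]
    for j in range(state.positions.n_positions):
        scan = int(state.positions.scan_id[j])
        if state.share.object_id(scan) != oid:
            continue
        pid = state.share.probe_index(scan)
        y, x = corners[j] - (oy, ox)
        acc[y : y + py, x : x + px] += np.sum(
            np.abs(state.probes.values[:, :, pid, :]) ** 2, axis=2
        )
    return acc > threshold * acc.max()


def _fit_phase_ramp(
    ratio: np.ndarray, weight: np.ndarray
) -> Tuple[float, float, float]:
    """Weighted plane fit (offset, ramp_y, ramp_x) to ``angle(ratio)``.

    Assumes the residual phase is wrap-free over the weighted support;
    callers coarse-align first.
    """
    h, w = ratio.shape
    yy, xx = np.meshgrid(np.arange(h) - h / 2, np.arange(w) - w / 2, indexing="ij")
    phi = np.angle(ratio)
    a = np.column_stack(
        [np.ones(weight.size), yy.ravel(), xx.ravel()]
    ) * np.sqrt(weight.ravel())[:, None]
    b = phi.ravel() * np.sqrt(weight.ravel())
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def align_object(
    reconstructed: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Remove global phase, linear phase ramp and complex scale.

    Coarse ramp alignment via the FFT peak of the weighted ratio
    ``truth * conj(rec)``, refined by two wrap-free weighted plane
    fits, then a global least-squares complex scale.  Returns the
    aligned reconstruction (same shape; only the masked region is
    meaningful).
    """
    h, w = truth.shape
    weight = mask.astype(float) * np.abs(truth)
    ratio = truth * np.conj(reconstructed) * weight
    # coarse: integer-bin spectral peak of the ramp
    spec = np.fft.fftshift(np.fft.fft2(ratio))
    peak = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    ky = (peak[0] - h // 2) / h
    kx = (peak[1] - w // 2) / w
    yy, xx = np.meshgrid(np.arange(h) - h / 2, np.arange(w) - w / 2, indexing="ij")
    aligned = reconstructed * np.exp(2j * np.pi * (ky * yy + kx * xx))
    for _ in range(2):  # fine: wrap-free plane fits
        ratio = truth * np.conj(aligned)
        off, ry, rx = _fit_phase_ramp(np.where(mask, ratio, 1.0), weight**2)
        aligned = aligned * np.exp(1j * (off + ry * yy + rx * xx))
    num = np.sum(np.conj(aligned[mask]) * truth[mask])
    den = np.sum(np.abs(aligned[mask]) ** 2)
    return aligned * (num / den if den > 0 else 1.0)


def phase_rmse(reconstructed: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """RMS phase residual [rad] over the mask, after alignment."""
    aligned = align_object(reconstructed, truth, mask)
    resid = np.angle(aligned[mask] * np.conj(truth[mask]))
    return float(np.sqrt(np.mean(resid**2)))


def snr_db(reconstructed: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """``-10 log10( mean|O_rec - O_true|^2 / mean|O_true|^2 )`` after alignment."""
    aligned = align_object(reconstructed, truth, mask)
    err = np.mean(np.abs(aligned[mask] - truth[mask]) ** 2)
    power = np.mean(np.abs(truth[mask]) ** 2)
    if err == 0:
        return float("inf")
    return float(-10.0 * np.log10(err / power))


def frc_resolution(
    reconstructed: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Fourier ring correlation against ground truth, half-bit threshold.

    Both images are aligned, cropped to the bounding box of the mask,
    and correlated ring by ring (ring width one frequency bin).
    Returns ``(crossing, freqs, frc)`` where ``crossing`` is the lowest
    spatial frequency (cycles/pixel, Nyquist = 0.5) at which the FRC
    first drops below the half-bit threshold — 0.5 if it never does.
    """
    aligned = align_object(reconstructed, truth, mask)
    ys, xs = np.nonzero(mask)
    sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
    a = aligned[sl] * mask[sl]
    b = truth[sl] * mask[sl]
    n = min(a.shape)
    a, b = a[:n, :n], b[:n, :n]
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    yy, xx = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
    rings = np.round(np.sqrt(yy**2 + xx**2)).astype(int)
    n_rings = n // 2
    frc = np.zeros(n_rings)
    thresh = np.zeros(n_rings)
    for r in range(n_rings):
        sel = rings == r
        npx = sel.sum()
        cross = np.abs(np.sum(fa[sel] * np.conj(fb[sel])))
        norm = np.sqrt(np.sum(np.abs(fa[sel]) ** 2) * np.sum(np.abs(fb[sel]) ** 2))
        frc[r] = cross / norm if norm > 0 else 0.0
        thresh[r] = (0.2071 + 1.9102 / np.sqrt(npx)) / (1.2071 + 0.9102 / np.sqrt(npx))
    freqs = np.arange(n_rings) / n
    # ring 0 holds a single pixel, where the half-bit threshold is
    # exactly 1 — start the crossing search at ring 1
    below = np.nonzero(frc[1:] < thresh[1:])[0] + 1
    crossing = float(freqs[below[0]]) if below.size else 0.5
    return crossing, freqs, frc
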