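"""Wavefield propagation operators.

Two propagators cover the regimes the engines need:

* far field — a centered, unitary 2-D Fourier transform.  In the
  far-field regime the Fresnel integral reduces to a Fourier transform
  of the exit wave, so detector-plane fields are just spectra.  The
  unitary normalization makes Parseval exact, which keeps error metrics
  directly comparable to photon flux.
* near field — the angular spectrum method (ASM): multiply the spectrum
  by the exact free-space transfer function
  ``exp(i 2 pi dz sqrt(1/lambda^2 - fy^2 - fx^2))``.  Evanescent
  components (inside the square root < 0) are damped to zero — a hard
  cutoff.  A paraxial (Fresnel) transfer-function variant is available
  behind a flag; both share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Wavefield",
    "propagate_farfield",
    "propagate_farfield_inverse",
    "propagate_asm",
    "fft2c",
    "ifft2c",
]


@dataclass
class Wavefield:
    """A complex 2-D field sampled on a square pixel grid."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("wavefield must be 2-D")


def _require_square(a: np.ndarray) -> None:
    if a.shape[-2] != a.shape[-1]:
        raise ValueError(f"field must be square, got shape {a.shape}")


def fft2c(a: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D FFT over the last two axes.

    Zero frequency sits at the array center on both sides of the
    transform; total energy is conserved exactly (up to rounding).
    """
    _require_square(a)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(a, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (also its adjoint, since it is unitary)."""
    _require_square(a)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(a, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def propagate_farfield(field: Wavefield) -> Wavefield:
    """Propagate to the far field (detector plane)."""
    return Wavefield(fft2c(field.values), field.pixel_size)


def propagate_farfield_inverse(field: Wavefield) -> Wavefield:
    """Back-propagate from the far field; exact inverse of the forward op."""
    return Wavefield(ifft2c(field.values), field.pixel_size)


def asm_transfer(
    n: int, pixel_size: float, dz: float, wavelength: float, paraxial: bool = False
) -> np.ndarray:
    """Angular-spectrum transfer function on a centered ``n x n`` grid.

    With ``paraxial=True`` the Fresnel approximation
    ``exp(i 2 pi dz / lambda) * exp(-i pi lambda dz f^2)`` is used
    instead of the exact square root.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    f = np.fft.fftshift(np.fft.fftfreq(n, d=pixel_size))
    fy, fx = np.meshgrid(f, f, indexing="ij")
    f2 = fy**2 + fx**2
    if paraxial:
        return np.exp(2j * np.pi * dz / wavelength) * np.exp(
            -1j * np.pi * wavelength * dz * f2
        )
    arg = 1.0 / wavelength**2 - f2
    h = np.zeros((n, n), dtype=complex)
    prop = arg > 0  # evanescent components are cut hard to zero
    h[prop] = np.exp(2j * np.pi * dz * np.sqrt(arg[prop]))
    return h


def propagate_asm(
    field: Wavefield, dz: float, wavelength: float, paraxial: bool = False
) -> Wavefield:
    """Near-field propagation by the angular spectrum method.

    ``dz`` may be negative (back-propagation); ``dz = 0`` is the
    identity.  Sampling should satisfy the ASM band limit for the
    given distance; aliasing outside it is the caller's concern.
    """
    if not np.isfinite(dz):
        raise ValueError("dz must be finite")
    v = field.values
    _require_square(v)
    n = v.shape[-1]
    h = asm_transfer(n, field.pixel_size, dz, wavelength, paraxial=paraxial)
    return Wavefield(ifft2c(fft2c(v) * h), field.pixel_size)
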