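"""Variance-stabilized lossy compression of diffraction stacks.

Photon-counting diffraction data are Poisson distributed, so the noise
standard deviation grows with the signal.  The square-root transform
``M = sqrt(N)`` stabilizes it: for Poisson counts the transformed
standard deviation is approximately constant at sigma = 0.5, nearly
independent of the mean.  A uniform quantizer with step QS applied to
M therefore treats every intensity level equally:

    code = clip( round( sqrt(N) / QS ), 0, 2**bits - 1 )

With the default QS = 0.5 (equal to the Poisson sigma) the added
quantization error is well below the counting noise, and an 8-bit code
spans counts up to (2**8 * 0.5)**2 = 16 384; 16-bit codes extend the
range beyond 1e9 counts.  Versus storing moduli as 32-bit floats this
saves 75% (8-bit) or 50% (16-bit) of memory.

Rounding is half-to-even; values beyond the code range saturate and are
counted.  Decompression is ``N_hat = (code * QS)**2``, which bounds the
round-trip error in the M domain by QS/2 for non-saturated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CompressedStack",
    "vst",
    "vst_inverse",
    "compress",
    "decompress",
    "capacity",
    "memory_ratio",
    "qs_quality_sweep",
    "reconstruct_and_score",
]


@dataclass
class CompressedStack:
    """Quantized square-root intensities plus codec parameters."""

    codes: np.ndarray
    quantization_step: float
    bits: int
    valid_mask: Optional[np.ndarray] = None
    n_saturated: int = 0

    def __post_init__(self) -> None:
        if self.quantization_step <= 0:
            raise ValueError("quantization step must be positive")
        if self.bits not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")
        if self.codes.max(initial=0) > 2**self.bits - 1:
            raise ValueError("codes exceed the declared bit depth")


def vst(counts: np.ndarray) -> np.ndarray:
    """Variance-stabilizing square root, ``M = sqrt(N)``."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return np.sqrt(counts)


def vst_inverse(m: np.ndarray) -> np.ndarray:
    return np.asarray(m, dtype=float) ** 2


def compress(
    counts: np.ndarray,
    qs: float = 0.5,
    bits: Optional[int] = None,
    valid_mask: Optional[np.ndarray] = None,
) -> CompressedStack:
    """Quantize intensities into unsigned integer codes.

    ``bits=None`` selects 8 bits, promoted to 16 when the input maximum
    exceeds the nominal 8-bit capacity.  Saturated pixels are clipped
    to the top code and counted in ``n_saturated``.
    """
    if qs <= 0:
        raise ValueError("quantization step must be positive")
    m = vst(counts)
    if bits is None:
        nominal8 = capacity(8, qs)[0]
        bits = 8 if float(np.max(counts, initial=0.0)) <= nominal8 else 16
    if bits not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    top = 2**bits - 1
    raw = np.rint(m / qs)  # ties to even
    n_sat = int(np.count_nonzero(raw > top))
    codes = np.clip(raw, 0, top).astype(np.uint8 if bits == 8 else np.uint16)
    return CompressedStack(codes, float(qs), int(bits), valid_mask, n_sat)


def decompress(cstack: CompressedStack) -> np.ndarray:
    """Reconstruct intensities, ``N_hat = (code * QS)**2``."""
    return (cstack.codes.astype(float) * cstack.quantization_step) ** 2


def capacity(bits: int, qs: float) -> Tuple[float, float]:
    """Dynamic range of the codec at a given bit depth and step.

    Returns ``(nominal, exact)``: the nominal bound ``(2**bits * QS)**2``
    (the figure usually quoted) and the exact largest non-saturating
    count ``((2**bits - 1) * QS)**2``.
    """
    if bits not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    if qs <= 0:
        raise ValueError("quantization step must be positive")
    return (2**bits * qs) ** 2, ((2**bits - 1) * qs) ** 2


def memory_ratio(bits: int) -> float:
    """Percentage of memory saved versus 32-bit float moduli."""
    if bits <= 0 or bits > 32:
        raise ValueError("bits must lie in (0, 32]")
    return 100.0 * (1.0 - bits / 32.0)


# ----------------------------------------------------------------------
# reconstruction-quality sweep
# ----------------------------------------------------------------------

def reconstruct_and_score(
    state,
    truth: Dict[str, np.ndarray],
    dm_iterations: int = 100,
    ml_iterations: int = 0,
) -> Dict[str, float]:
    """Run DM (and optionally ML) from a fresh start and score vs truth."""
    from .engine_dm import DMSettings, dm_iterate
    from .engine_ml import MLSettings, ml_iterate
    from .simulator import frc_resolution, initial_state, snr_db, well_illuminated_mask

    start = initial_state(state)
    rec = dm_iterate(start, DMSettings(n_iterations=dm_iterations))
    if ml_iterations > 0:
        rec = ml_iterate(rec, MLSettings(max_iterations=ml_iterations))
    mask = well_illuminated_mask(rec)
    o_rec = rec.objects.field2d(1)
    o_true = truth["object"]
    crossing, _, _ = frc_resolution(o_rec, o_true, mask)
    return {
        "snr_db": snr_db(o_rec, o_true, mask),
        "frc_crossing": crossing,
        "final_error": rec.error_history[-1][2] if rec.error_history else float("nan"),
    }


def qs_quality_sweep(
    state,
    truth: Dict[str, np.ndarray],
    qs_list: Sequence[float],
    dm_iterations: int = 100,
    ml_iterations: int = 0,
    bits: int = 16,
) -> List[Dict[str, float]]:
    """Reconstruction quality versus quantization step.

    For each QS the measured stack is compressed, decompressed and
    reconstructed from scratch; quality is reported as SNR [dB] against
    the ground-truth object and as the FRC half-bit crossing frequency.
    ``QS = 0`` means no compression (the lossless baseline).  A 16-bit
    code is used by default so capacity never confounds the sweep.
    """
    rows: List[Dict[str, float]] = []
    for qs in qs_list:
        trial = state.copy()
        if qs > 0:
            packed = compress(trial.data.intensities, qs=qs, bits=bits)
            trial.data.intensities = decompress(packed)
        score = reconstruct_and_score(trial, truth, dm_iterations, ml_iterations)
        score["qs"] = float(qs)
        rows.append(score)
    return rows
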