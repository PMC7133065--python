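"""Maximum-likelihood refinement by nonlinear conjugate gradient.

Refines the probe and object jointly by minimizing the amplitude
objective

    L(P, O) = sum_k sum_{l in M} ( sqrt(I_model,k,l) - sqrt(I_meas,k,l) )^2,

the same error surface the difference-map engine reports, so the two
engines can be chained freely.  Search directions follow the
Polak-Ribiere *plus* rule with a Powell restart; step lengths come from
a bracketed line search (geometric expansion, then quadratic and cubic
fits, then geometric bisection) accepted under the Armijo criterion.

Objective values are accumulated with a magnitude-grouped summation
(:func:`grouped_sum`): values are bucketed by binary exponent, buckets
are reduced pairwise, and bucket totals are combined exactly.  This
keeps the loss of significance bounded even when residuals span many
orders of magnitude, which matters because the line search compares
nearly equal objective values.

Gradients are Wirtinger-style: ``grad = 2 * dL/d(conj(z))``, the true
gradient of L viewed as a function of the real and imaginary parts, so
the directional derivative of L along a step ``z + alpha*d`` is the
real inner product ``<grad, d>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .datamodel import ObjectStore, ProbeStack, ReconstructionState
from .engine_dm import dm_error
from .forward import exit_waves, extract_views, iter_blocks
from .propagators import fft2c, ifft2c

__all__ = [
    "MLSettings",
    "SearchState",
    "LineSearchError",
    "grouped_sum",
    "ml_objective",
    "ml_gradient",
    "pr_plus_beta",
    "line_search",
    "ml_iterate",
]


@dataclass
class MLSettings:
    """Conjugate-gradient hyperparameters.

    ``error_target`` is a normalized error value (raw objective divided
    by measured flux over valid pixels); iteration stops once reached.
    """

    max_iterations: int = 50
    error_target: Optional[float] = None
    armijo_c1: float = 1e-4
    powell_threshold: float = 0.2
    bracket_growth: float = 2.0
    max_line_evals: int = 20
    block_size: Optional[int] = None
    optimize_probe: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.armijo_c1 < 1:
            raise ValueError("armijo_c1 must lie in (0, 1)")
        if self.powell_threshold < 0:
            raise ValueError("powell_threshold must be nonnegative")
        if self.bracket_growth <= 1:
            raise ValueError("bracket_growth must exceed 1")
        if self.max_line_evals < 3:
            raise ValueError("max_line_evals must be >= 3")


class LineSearchError(RuntimeError):
    """No Armijo-satisfying step found within the evaluation budget."""


# ----------------------------------------------------------------------
# magnitude-grouped summation
# ----------------------------------------------------------------------

def grouped_sum(values) -> float:
    """Sum reals with values grouped by binary exponent.

    Values sharing a binary exponent are reduced pairwise within their
    bucket (in the input's floating dtype), buckets are walked in
    ascending magnitude, and the bucket totals are combined exactly.
    The result deviates from the exact sum by at most
    ``64 * eps * sum(|values|)``.
    """
    v = np.ravel(np.asarray(values))
    if v.size == 0:
        return 0.0
    if not np.issubdtype(v.dtype, np.floating):
        v = v.astype(float)
    v = v[v != 0]
    if v.size == 0:
        return 0.0
    _, exponents = np.frexp(v)
    order = np.argsort(exponents, kind="stable")
    v = v[order]
    exponents = exponents[order]
    cuts = np.flatnonzero(np.diff(exponents)) + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [v.size]))
    totals = [float(v[s:e].sum()) for s, e in zip(starts, ends)]
    totals.sort(key=abs)
    return math.fsum(totals)


# ----------------------------------------------------------------------
# objective and gradient
# ----------------------------------------------------------------------

def ml_objective(state: ReconstructionState, block_size: Optional[int] = None) -> float:
    """Raw amplitude objective, accumulated with :func:`grouped_sum`."""
    from .forward import model_intensity  # local to keep module top light

    pieces: List[np.ndarray] = []
    probe_shape = state.probes.shape_yx
    for idx in iter_blocks(state.positions.n_positions, block_size):
        patches = extract_views(state.objects, state.positions, state.share, probe_shape, idx)
        views = exit_waves(state.probes, patches, state.share)
        i_model = model_intensity(views)
        for k, j in enumerate(idx):
            mask = state.data.mask_for(int(j))
            diff = np.sqrt(i_model[k][mask]) - np.sqrt(state.data.intensities[j][mask])
            pieces.append(diff**2)
    return grouped_sum(np.concatenate(pieces))


def ml_gradient(
    state: ReconstructionState, block_size: Optional[int] = None
) -> Tuple[np.ndarray, Dict[int, np.ndarray]]:
    """Gradient of the amplitude objective w.r.t. probe and object.

    Returns ``(probe_grad, object_grads)`` where ``probe_grad`` has the
    probe stack's ``(y, x, probe_ID, mode)`` shape and ``object_grads``
    maps object IDs to 2-D arrays.  On valid pixels the detector-plane
    residual factor is ``c = 1 - sqrt(I_meas) / sqrt(A)`` with
    ``A = sum_m |psi_hat_m|^2`` (floored to avoid division by zero);
    invalid pixels contribute nothing.  Accumulation is share-aware:
    every view adds to its scan's probe and object slices.
    """
    probes = state.probes
    share = state.share
    py, px = probes.shape_yx
    probe_grad = np.zeros_like(probes.values)
    object_grads: Dict[int, np.ndarray] = {
        oid: np.zeros(state.objects.objects[oid].shape[:2], dtype=complex)
        for oid in state.objects.ids()
    }
    for idx in iter_blocks(state.positions.n_positions, block_size):
        patches = extract_views(state.objects, state.positions, state.share, (py, px), idx)
        views = exit_waves(probes, patches, share)
        spectra = fft2c(np.moveaxis(views.views, 3, 1))  # (pos, mode, y, x)
        total = np.sum(np.abs(spectra) ** 2, axis=1)
        for k, j in enumerate(idx):
            scan = int(views.scan_ids[k])
            oid = share.object_id(scan)
            pid = share.probe_index(scan)
            mask = state.data.mask_for(int(j))
            a = total[k]
            floor = max(a.max(), 1.0) * 1e-30
            c = np.zeros_like(a)
            c[mask] = 1.0 - np.sqrt(state.data.intensities[j][mask]) / np.sqrt(
                np.maximum(a[mask], floor)
            )
            chi = ifft2c(c[None] * spectra[k])  # (mode, y, x), dL/dPsi* times 1/2
            chi = np.moveaxis(chi, 0, 2)  # (y, x, mode)
            oy, ox = state.objects.origins[oid]
            y, x = views.corners[k] - (oy, ox)
            p = probes.values[:, :, pid, :]
            object_grads[oid][y : y + py, x : x + px] += 2.0 * np.sum(
                np.conj(p) * chi, axis=2
            )
            probe_grad[:, :, pid, :] += 2.0 * np.conj(patches.views[k]) * chi
    return probe_grad, object_grads


@dataclass
class SearchState:
    """Gradient/direction bookkeeping for one CG iteration."""

    gradient: Tuple[np.ndarray, Dict[int, np.ndarray]]
    direction: Tuple[np.ndarray, Dict[int, np.ndarray]]
    objective: float


def _inner(
    a: Tuple[np.ndarray, Dict[int, np.ndarray]],
    b: Tuple[np.ndarray, Dict[int, np.ndarray]],
) -> float:
    """Real inner product over the concatenated probe+object space."""
    total = float(np.sum((np.conj(a[0]) * b[0]).real))
    for oid in a[1]:
        total += float(np.sum((np.conj(a[1][oid]) * b[1][oid]).real))
    return total


def _combine(
    a: Tuple[np.ndarray, Dict[int, np.ndarray]],
    b: Tuple[np.ndarray, Dict[int, np.ndarray]],
    ca: float,
    cb: float,
) -> Tuple[np.ndarray, Dict[int, np.ndarray]]:
    return (
        ca * a[0] + cb * b[0],
        {oid: ca * a[1][oid] + cb * b[1][oid] for oid in a[1]},
    )


def pr_plus_beta(
    g_new: Tuple[np.ndarray, Dict[int, np.ndarray]],
    g_old: Tuple[np.ndarray, Dict[int, np.ndarray]],
    powell_threshold: float = 0.2,
) -> float:
    """Polak-Ribiere *plus* momentum with a Powell restart.

    ``beta = max(0, <g_new, g_new - g_old> / <g_old, g_old>)``, forced
    to zero (restart to steepest descent) when consecutive gradients
    lose conjugacy: ``|<g_new, g_old>| >= powell_threshold * <g_new, g_new>``.
    A threshold of zero therefore restarts every iteration, reducing
    the method to steepest descent.
    """
    denom = _inner(g_old, g_old)
    if denom <= 0:
        raise ValueError("old gradient has zero norm")
    gn2 = _inner(g_new, g_new)
    overlap = _inner(g_new, g_old)
    if abs(overlap) >= powell_threshold * gn2:
        return 0.0
    return max(0.0, (gn2 - overlap) / denom)


# ----------------------------------------------------------------------
# line search
# ----------------------------------------------------------------------

def _cubic_min(f0: float, slope0: float, a0: float, fa0: float, a1: float, fa1: float):
    """Minimizer of the cubic through (0,f0) with slope0 and two points."""
    d0 = fa0 - f0 - slope0 * a0
    d1 = fa1 - f0 - slope0 * a1
    det = a0**2 * a1**2 * (a1 - a0)
    if det == 0:
        return None
    a = (a0**2 * d1 - a1**2 * d0) / det
    b = (-(a0**3) * d1 + a1**3 * d0) / det
    if a == 0:
        if b <= 0:
            return None
        return -slope0 / (2 * b)
    disc = b**2 - 3 * a * slope0
    if disc < 0:
        return None
    return (-b + math.sqrt(disc)) / (3 * a)


def line_search(
    f: Callable[[float], float],
    f0: float,
    slope0: float,
    settings: MLSettings,
    initial: float = 1.0,
) -> Tuple[float, float, int]:
    """Find a step length satisfying the Armijo sufficient-decrease test.

    The search brackets a minimum by geometric expansion (factor
    ``bracket_growth``), probes interior points with a quadratic and
    then a cubic fit, and falls back to geometric bisection of the
    bracket.  Among all evaluated points the best one satisfying
    ``f(a) <= f0 + armijo_c1 * a * slope0`` is returned as
    ``(alpha, f(alpha), n_evals)``; :class:`LineSearchError` is raised
    if no such point exists within ``max_line_evals`` evaluations.
    """
    if not slope0 < 0:
        raise ValueError(f"slope at 0 must be negative, got {slope0}")
    if initial <= 0 or not math.isfinite(initial):
        initial = 1.0
    c1 = settings.armijo_c1
    growth = settings.bracket_growth
    evals: List[Tuple[float, float]] = []

    def ev(a: float) -> float:
        fa = f(a)
        evals.append((a, float(fa)))
        return fa

    def armijo(a: float, fa: float) -> bool:
        return fa <= f0 + c1 * a * slope0

    def best_armijo():
        ok = [(fa, a) for a, fa in evals if math.isfinite(fa) and armijo(a, fa)]
        return min(ok) if ok else None

    budget = settings.max_line_evals

    # --- first trial and quadratic fit ---------------------------------
    t1 = initial
    f1 = ev(t1)
    denom = f1 - f0 - slope0 * t1
    if denom > 0 and math.isfinite(denom):
        aq = -slope0 * t1 * t1 / (2.0 * denom)
        aq = min(max(aq, 1e-2 * t1), growth**2 * t1)
        if abs(aq - t1) > 1e-12 * t1:
            ev(aq)

    # --- bracket expansion while still descending ----------------------
    a_hi, f_hi = max(evals)  # largest alpha tried so far
    a_best, f_best = min(((fa, a) for a, fa in evals))[1], min(fa for _, fa in evals)
    t = a_hi
    ft = f_hi
    while ft <= f_best and len(evals) < max(3, budget // 2):
        t *= growth
        ft = ev(t)
        if ft < f_best:
            a_best, f_best = t, ft

    # --- cubic refinement inside the bracket ---------------------------
    if len(evals) >= 2 and len(evals) < budget:
        (a0, fa0), (a1, fa1) = sorted(evals, key=lambda p: p[1])[:2]
        if a0 != a1:
            ac = _cubic_min(f0, slope0, a0, fa0, a1, fa1)
            hi = max(a for a, _ in evals)
            if ac is not None and math.isfinite(ac) and 0 < ac <= growth * hi:
                near = min(abs(ac - a) for a, _ in evals)
                if near > 1e-9 * max(ac, 1e-300):
                    ev(ac)

    # --- geometric bisection fallback ----------------------------------
    while best_armijo() is None and len(evals) < budget:
        a_small = min(a for a, _ in evals)
        ev(a_small / growth)

    hit = best_armijo()
    if hit is None:
        raise LineSearchError(
            f"no Armijo point within {len(evals)} evaluations "
            f"(f0={f0:.6g}, slope0={slope0:.6g})"
        )
    fa, a = hit
    return a, fa, len(evals)


# ----------------------------------------------------------------------
# CG driver
# ----------------------------------------------------------------------

def _apply_step(
    state: ReconstructionState,
    direction: Tuple[np.ndarray, Dict[int, np.ndarray]],
    alpha: float,
) -> ReconstructionState:
    out = state.copy()
    out.probes = ProbeStack(state.probes.values + alpha * direction[0])
    for oid in out.objects.ids():
        out.objects.set_field2d(
            oid, state.objects.field2d(oid) + alpha * direction[1][oid]
        )
    return out


def ml_iterate(state: ReconstructionState, settings: MLSettings) -> ReconstructionState:
    """Refine probe and object jointly by Armijo-safeguarded CG.

    Stops at ``max_iterations``, when the normalized error drops below
    ``error_target``, when the gradient vanishes, or after two
    consecutive line-search failures.  Every accepted step satisfies
    the Armijo inequality by construction (asserted).  The normalized
    error is appended to the state's error history per iteration.
    """
    state = state.copy()
    flux = 0.0
    for j in range(state.data.n_frames):
        mask = state.data.mask_for(j)
        flux += float(np.sum(state.data.intensities[j][mask]))
    if flux <= 0:
        raise ValueError("measured flux over valid pixels is zero")

    def gradient(s: ReconstructionState):
        g = ml_gradient(s, settings.block_size)
        if not settings.optimize_probe:
            g = (np.zeros_like(g[0]), g[1])
        return g

    f_cur = ml_objective(state, settings.block_size)
    grad = gradient(state)
    gnorm2 = _inner(grad, grad)
    direction = _combine(grad, grad, -1.0, 0.0)
    failures = 0
    prev_alpha = None

    for it in range(settings.max_iterations):
        if settings.error_target is not None and f_cur / flux <= settings.error_target:
            break
        if gnorm2 <= (1e-15 * flux) ** 2:
            break  # stationary: nothing to refine
        slope0 = _inner(grad, direction)
        if slope0 >= 0:  # not a descent direction: restart
            direction = _combine(grad, grad, -1.0, 0.0)
            slope0 = -gnorm2

        def f_line(alpha: float, _d=direction) -> float:
            return ml_objective(_apply_step(state, _d, alpha), settings.block_size)

        initial = prev_alpha if prev_alpha else min(1.0, 2.0 * f_cur / -slope0)
        try:
            alpha, f_new, _ = line_search(f_line, f_cur, slope0, settings, initial)
        except LineSearchError:
            failures += 1
            if failures >= 2:
                state.settings["ml_status"] = "line_search_failed"
                break
            direction = _combine(grad, grad, -1.0, 0.0)
            prev_alpha = None
            continue
        assert f_new <= f_cur + settings.armijo_c1 * alpha * slope0
        failures = 0
        prev_alpha = alpha
        state = _apply_step(state, direction, alpha)
        f_cur = f_new
        state.record_error("ml", it, f_cur / flux)
        g_new = gradient(state)
        beta = pr_plus_beta(g_new, grad, settings.powell_threshold)
        direction = _combine(g_new, direction, -1.0, beta)
        grad = g_new
        gnorm2 = _inner(grad, grad)
    return state
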