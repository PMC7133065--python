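"""Difference-map engine: projections, error metric, full iterations."""

import numpy as np
import pytest

from ptychokit.datamodel import (
    DiffractionStack,
    ExperimentGeometry,
    ObjectStore,
    ProbeStack,
    ReconstructionState,
    ScanPositions,
    ShareMap,
)
from ptychokit.engine_dm import (
    DMSettings,
    dm_error,
    dm_iterate,
    fourier_projection,
    overlap_projection,
)
from ptychokit.forward import exit_waves, extract_views, model_intensity
from ptychokit.propagators import fft2c

from conftest import make_manual_state


def full_views(state):
    patches = extract_views(
        state.objects, state.positions, state.share, state.probes.shape_yx
    )
    return exit_waves(state.probes, patches, state.share)


class TestFourierProjection:
    def test_consistent_model_is_fixed_point(self, manual_state):
        views = full_views(manual_state)
        projected = fourier_projection(views, manual_state.data)
        assert np.max(np.abs(projected.views - views.views)) < 1e-8

    def test_all_invalid_mask_is_identity(self, manual_state):
        state = manual_state.copy()
        state.data.intensities[:] = 1.0  # inconsistent measurement
        state.data.valid_mask = np.zeros_like(state.data.valid_mask)
        state.data.valid_mask[0, 0] = True  # constructor needs a nonempty mask
        views = full_views(state)
        # make even that single pixel consistent so only mask semantics act
        spectra = fft2c(np.moveaxis(views.views, 3, 1))
        state.data.intensities[:, 0, 0] = np.sum(np.abs(spectra) ** 2, axis=1)[:, 0, 0]
        projected = fourier_projection(views, state.data)
        assert np.max(np.abs(projected.views - views.views)) < 1e-10

    def test_single_mode_amplitude_replacement_oracle(self):
        """4x4 frame: the projected spectrum is sqrt(I_meas) * phase(model)."""
        rng = np.random.default_rng(12)
        n = 4
        g = ExperimentGeometry(1e-10, 1.0, 1e-10 / n, n)
        psi = rng.standard_normal((1, n, n, 1)) + 1j * rng.standard_normal((1, n, n, 1))
        meas = np.array(
            [[[4.0, 1.0, 0.25, 9.0], [1.0, 16.0, 2.25, 0.0], [0.04, 1.21, 5.0, 7.0], [3.0, 0.5, 0.9, 2.0]]]
        )
        data = DiffractionStack(meas, np.ones((n, n), bool), g)
        from ptychokit.forward import ViewBlock

        block = ViewBlock(psi, np.zeros((1, 2), int), np.zeros(1, int), np.arange(1))
        out = fourier_projection(block, data)
        spectrum = fft2c(psi[0, :, :, 0])
        expected = np.sqrt(meas[0]) * spectrum / np.abs(spectrum)
        got = fft2c(out.views[0, :, :, 0])
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_idempotence(self, manual_state):
        state = manual_state.copy()
        state.data.intensities *= 1.7  # force a non-trivial projection
        views = full_views(state)
        once = fourier_projection(views, state.data)
        twice = fourier_projection(once, state.data)
        assert np.max(np.abs(twice.views - once.views)) < 1e-8

    def test_projected_views_match_measurement_on_valid_pixels(self, manual_state):
        state = manual_state.copy()
        state.data.intensities *= 2.0
        projected = fourier_projection(full_views(state), state.data)
        intensity = model_intensity(projected)
        mask = state.data.mask_for(0)
        assert np.allclose(intensity[0][mask], state.data.intensities[0][mask], rtol=1e-10)


class TestOverlapProjection:
    def test_consistent_views_are_fixed_point(self):
        state = make_manual_state(n=6, n_positions=4, step=2, seed=13)
        views = full_views(state)
        new_probes, new_objects, refreshed = overlap_projection(state, views)
        mask = np.zeros(state.objects.field2d(1).shape, bool)
        # only pixels covered by at least one view are constrained
        for k in range(views.n_views):
            y, x = views.corners[k]
            mask[y : y + 6, x : x + 6] = True
        assert np.max(np.abs(new_objects.field2d(1)[mask] - state.objects.field2d(1)[mask])) < 1e-6
        assert np.max(np.abs(new_probes.values - state.probes.values)) < 1e-6
        assert np.max(np.abs(refreshed.views - views.views)) < 1e-6

    def test_single_view_object_is_quotient(self):
        state = make_manual_state(n=6, n_positions=1, seed=14)
        views = full_views(state)
        psi = views.views.copy()
        psi *= 1.3  # not consistent anymore
        from ptychokit.forward import ViewBlock

        block = ViewBlock(psi, views.corners, views.scan_ids, views.indices)
        _, new_objects, _ = overlap_projection(state, block, update_probe=False)
        p = state.probes.values[:, :, 0, 0]
        strong = np.abs(p) ** 2 > 0.1 * np.max(np.abs(p) ** 2)
        got = new_objects.field2d(1)[:6, :6][strong]
        expected = (psi[0, :, :, 0] / p)[strong]
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_matches_normal_equations_oracle(self):
        """3 overlapping views: object update solves the dense LSQ system."""
        state = make_manual_state(n=4, n_positions=3, step=2, seed=15)
        views = full_views(state)
        psi = views.views + 0.3 * (
            np.random.default_rng(16).standard_normal(views.views.shape)
        )
        from ptychokit.forward import ViewBlock

        block = ViewBlock(psi, views.corners, views.scan_ids, views.indices)
        _, new_objects, _ = overlap_projection(state, block, update_probe=False)
        # oracle: per-pixel normal equations sum |P|^2 O = sum P* psi
        extent = state.objects.field2d(1).shape
        num = np.zeros(extent, complex)
        den = np.zeros(extent)
        p = state.probes.values[:, :, 0, 0]
        for k in range(3):
            y, x = block.corners[k]
            num[y : y + 4, x : x + 4] += np.conj(p) * psi[k, :, :, 0]
            den[y : y + 4, x : x + 4] += np.abs(p) ** 2
        constrained = den > 1e-3 * den.max()
        expected = num[constrained] / den[constrained]
        got = new_objects.field2d(1)[constrained]
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_empty_view_set_rejected(self, manual_state):
        from ptychokit.forward import ViewBlock

        empty = ViewBlock(
            np.zeros((0, 4, 4, 1), complex),
            np.zeros((0, 2), int),
            np.zeros(0, int),
            np.arange(0),
        )
        with pytest.raises(ValueError):
            overlap_projection(manual_state, empty)


class TestDMError:
    def test_zero_at_consistency(self, manual_state):
        raw, norm = dm_error(manual_state)
        assert raw < 1e-18
        assert norm < 1e-20

    def test_zero_model_gives_flux(self, manual_state):
        state = manual_state.copy()
        state.objects.objects[1][:] = 0.0
        raw, norm = dm_error(state)
        flux = state.data.intensities.sum()
        assert raw == pytest.approx(flux, rel=1e-12)
        assert norm == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_toy(self):
        """2x2 frames: error equals the hand-evaluated amplitude mismatch."""
        n = 2
        g = ExperimentGeometry(1e-10, 1.0, 1e-10 / n, n)
        probe = ProbeStack(np.full((n, n, 1, 1), 0.5 + 0j))
        objects = ObjectStore({1: np.ones((n, n, 1, 1), complex)})
        positions = ScanPositions([[0.0, 0.0]], [0])
        share = ShareMap([1], [1])
        views = exit_waves(probe, extract_views(objects, positions, share, (n, n)), share)
        model = model_intensity(views)  # known: all energy patterns from flat 0.5 field
        meas = model.copy()
        meas[0, 0, 0] = (np.sqrt(model[0, 0, 0]) + 0.1) ** 2
        meas[0, 1, 1] = (np.sqrt(model[0, 1, 1]) + 0.3) ** 2
        state = ReconstructionState(
            geometry=g,
            data=DiffractionStack(meas, np.ones((n, n), bool), g),
            positions=positions,
            probes=probe,
            objects=objects,
            share=share,
        )
        raw, norm = dm_error(state)
        assert raw == pytest.approx(0.1**2 + 0.3**2, rel=1e-10)
        assert norm == pytest.approx(raw / meas.sum(), rel=1e-12)

    def test_abs_variant(self, manual_state):
        state = manual_state.copy()
        state.objects.objects[1][:] = 0.0
        raw_abs, _ = dm_error(state, metric="abs")
        assert raw_abs == pytest.approx(np.sum(np.sqrt(state.data.intensities)), rel=1e-12)


class TestDMIterate:
    def test_exact_solution_is_fixed_point(self, manual_state):
        rec = dm_iterate(manual_state, DMSettings(n_iterations=5))
        errors = [v for _, _, v in rec.error_history]
        assert all(e < 1e-12 for e in errors)

    def test_error_drops_two_orders_noiseless(self, dm200):
        errors = [v for _, _, v in dm200.error_history]
        assert errors[-1] < 1e-2 * errors[0]

    def test_shared_probe_equals_concatenated_scan(self, tiny_sim):
        """Splitting a scan into two probe/object-sharing scans changes nothing."""
        state, _ = tiny_sim
        single = state.copy()
        split = state.copy()
        n = split.positions.n_positions
        scan_id = np.zeros(n, int)
        scan_id[n // 2 :] = 1
        split.positions.scan_id = scan_id
        split.share = ShareMap([1, 1], [1, 1])
        rec_single = dm_iterate(
            single, DMSettings(n_iterations=10, probe_update_start=2)
        )
        rec_split = dm_iterate(split, DMSettings(n_iterations=10, probe_update_start=2))
        assert np.max(
            np.abs(rec_single.objects.field2d(1) - rec_split.objects.field2d(1))
        ) < 1e-12
        assert np.max(np.abs(rec_single.probes.values - rec_split.probes.values)) < 1e-12

    def test_block_partition_invariance(self, tiny_sim):
        state, _ = tiny_sim
        rec_all = dm_iterate(state.copy(), DMSettings(n_iterations=8))
        rec_one = dm_iterate(state.copy(), DMSettings(n_iterations=8, block_size=1))
        assert np.max(
            np.abs(rec_all.objects.field2d(1) - rec_one.objects.field2d(1))
        ) < 1e-10

    def test_probe_frozen_before_start(self, tiny_sim):
        state, _ = tiny_sim
        from ptychokit.simulator import initial_state

        start = initial_state(state)
        rec = dm_iterate(start, DMSettings(n_iterations=2, probe_update_start=5))
        assert np.array_equal(rec.probes.values, start.probes.values)

    def test_divergence_aborts_with_diagnostic(self, manual_state):
        state = manual_state.copy()
        state.probes.values[0, 0, 0, 0] = np.inf  # poisoned iterate
        with pytest.raises(FloatingPointError, match="diverged"):
            dm_iterate(state, DMSettings(n_iterations=3))
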