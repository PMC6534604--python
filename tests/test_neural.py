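"""Neural transfer function and cone-lattice noise."""

import numpy as np
import pytest
import scipy.fft as sfft

from acuitysim import neural as N
from acuitysim.psf import GridSpec, TransferFunction


@pytest.fixture(scope="module")
def grid():
    return GridSpec(n=256, dx_arcsec=5.724)


class TestBuildNTF:
    def test_identical_models_give_unity_filter(self, grid):
        model = lambda f: np.exp(-np.asarray(f) / 10.0) + 0.01
        ntf = N.build_ntf(model, model, grid)
        assert np.allclose(ntf.values, 1.0, atol=1e-9)

    def test_unit_dc_gain(self, grid):
        ntf = N.build_ntf(grid=grid)
        assert ntf.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_edge_enhancement_band_exists(self, grid):
        ntf = N.build_ntf(grid=grid)
        assert ntf.values.real.max() > 1.0

    def test_radial_symmetry(self, grid):
        ntf = sfft.fftshift(N.build_ntf(grid=grid).values.real)
        peak = ntf.max()
        # 90-degree rotation and mirror symmetry of the centered filter
        core = ntf[1:, 1:]  # drop the asymmetric Nyquist row/column
        assert np.abs(core - core.T).max() < 1e-3 * peak
        assert np.abs(core - core[::-1, ::-1]).max() < 1e-3 * peak

    def test_masked_beyond_motf_cutoff(self, grid):
        ntf = N.build_ntf(grid=grid)
        fr = grid.freq_radius_cpd
        cutoff = N.MeanOpticalMTF().cutoff_cpd
        assert np.abs(ntf.values[fr > cutoff * 1.05]).max() < 1e-9


class TestApplyNTF:
    def test_unity_filter_is_identity(self, grid, rng):
        ntf = TransferFunction(np.ones((grid.n, grid.n)), grid)
        ri = rng.random((grid.n, grid.n))
        assert np.allclose(N.apply_ntf(ri, ntf), ri, atol=1e-12)

    def test_uniform_background_unchanged(self, grid):
        ntf = N.build_ntf(grid=grid)
        out = N.apply_ntf(np.ones((grid.n, grid.n)), ntf)
        assert np.abs(out - 1.0).max() < 1e-9

    def test_linearity(self, grid, rng):
        ntf = N.build_ntf(grid=grid)
        r1 = rng.random((grid.n, grid.n))
        r2 = rng.random((grid.n, grid.n))
        lhs = N.apply_ntf(2.0 * r1 + 0.5 * r2, ntf)
        rhs = 2.0 * N.apply_ntf(r1, ntf) + 0.5 * N.apply_ntf(r2, ntf)
        assert np.abs(lhs - rhs).max() < 1e-9


class TestConeLattice:
    def test_mean_cell_pitch_within_tolerance(self):
        g = GridSpec(n=1024, dx_arcsec=5.724)
        lat = N.ConeLattice(g)
        ids = lat.window_ids(0, g.n, 0, g.n)
        n_cells = np.unique(ids).size
        px_per_cell = ids.size / n_cells
        # hexagonal cell area = sqrt(3)/2 * a^2 with a = 1/120 deg
        a_px = (1.0 / 120.0) / g.dx_deg
        expected = np.sqrt(3.0) / 2.0 * a_px ** 2
        assert px_per_cell == pytest.approx(expected, rel=0.02)

    def test_every_pixel_assigned_one_cell(self):
        g = GridSpec(n=256, dx_arcsec=5.724)
        ids = N.ConeLattice(g).window_ids(0, 256, 0, 256)
        assert ids.shape == (256, 256)
        assert np.issubdtype(ids.dtype, np.integer)


class TestConeNoise:
    def test_zero_sigma_is_identity(self, grid):
        pi = np.ones((64, 64))
        lat = N.ConeLattice(grid)
        out = N.add_cone_noise(pi, lat, 0.0, 42)
        assert np.array_equal(out, pi)

    def test_deterministic_given_seed(self, grid):
        pi = np.ones((96, 96))
        lat = N.ConeLattice(grid)
        a = N.add_cone_noise(pi, lat, 0.1, 7)
        b = N.add_cone_noise(pi, lat, 0.1, 7)
        assert np.array_equal(a, b)
        c = N.add_cone_noise(pi, lat, 0.1, 8)
        assert not np.array_equal(a, c)

    def test_within_cell_deviates_constant_across_cells_match_sigma(self):
        g = GridSpec(n=1024, dx_arcsec=5.724)
        lat = N.ConeLattice(g)
        pi = np.zeros((g.n, g.n))
        ni = N.add_cone_noise(pi, lat, 0.1, 3)
        ids = lat.window_ids(0, g.n, 0, g.n)
        uniq, idx = np.unique(ids, return_index=True)
        # constant within cells
        flat = ni.ravel()
        for u in uniq[:50]:
            vals = flat[ids.ravel() == u]
            assert np.ptp(vals) == 0.0
        # sample SD over ~38k cells recovers sigma
        cell_vals = flat[idx]
        se = 0.1 / np.sqrt(2 * (uniq.size - 1))
        assert cell_vals.std(ddof=1) == pytest.approx(0.1, abs=4 * se)
        assert abs(cell_vals.mean()) < 4 * 0.1 / np.sqrt(uniq.size)

    def test_neighbor_cells_uncorrelated(self):
        g = GridSpec(n=1024, dx_arcsec=5.724)
        lat = N.ConeLattice(g)
        ni = N.add_cone_noise(np.zeros((g.n, g.n)), lat, 0.1, 11)
        # one-cell horizontal lag ~ 5.24 px
        a_px = int(round(lat.pitch_px))
        x = ni[::7, :-a_px].ravel()
        y = ni[::7, a_px:].ravel()
        r = np.corrcoef(x, y)[0, 1]
        n_cells = ni.size / (np.sqrt(3) / 2 * lat.pitch_px ** 2)
        # pixels within a cell are identical, so use the cell count for
        # the standard error; same-cell pixel pairs at this lag are rare
        assert abs(r) < 0.15

    def test_expectation_is_noiseless_image(self, grid, rng):
        lat = N.ConeLattice(grid)
        pi = rng.random((64, 64))
        acc = np.zeros_like(pi)
        n_rep = 200
        sigma = 0.1
        for k in range(n_rep):
            acc += N.add_cone_noise(pi, lat, sigma, 1000 + k)
        mean_img = acc / n_rep
        bound = 5 * sigma / np.sqrt(n_rep)
        assert np.abs(mean_img - pi).max() < bound * 1.5  # max over ~150 cells

    def test_negative_sigma_rejected(self, grid):
        with pytest.raises(ValueError):
            N.add_cone_noise(np.ones((8, 8)), N.ConeLattice(grid), -0.1, 0)
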