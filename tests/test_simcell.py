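"""Simulation substrate: diffusion, bleaching, contact kinetics, rendering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from omeflux.simcell import (
    CellGeometry, ContactZone, SimConfig, Species, allele_compat, apply_bleach,
    analytic_profile, field_of_view, init_ensemble, merge_ensembles,
    render_frame, simulate_frap_experiment, step_diffusion, straight_cell,
    transfer_cargo, update_contacts,
)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


class TestGeometry:
    def test_arc_length_and_interpolation(self):
        g = CellGeometry(np.array([[0, 0], [3, 4]]), width=0.5)
        assert g.length == pytest.approx(5.0)
        assert g.point_at(2.5) == pytest.approx([1.5, 2.0])

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CellGeometry(np.array([[0.0, 0.0]]), width=0.5)
        with pytest.raises(ValueError):
            CellGeometry(np.array([[0, 0], [0, 0], [1, 0]]), width=0.5)
        with pytest.raises(ValueError):
            straight_cell(4.0, width=0.0)


# --------------------------------------------------------------------------
# ensemble initialization
# --------------------------------------------------------------------------


class TestInitEnsemble:
    def test_all_mobile_fluorescent(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 1000, immobile_fraction=0.0, seed=0)
        assert ens.n == 1000
        assert ens.fluorescent.all()
        assert not ens.immobile.any()
        assert (ens.s >= 0).all() and (ens.s <= 4.0).all()

    def test_immobile_rounding(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 10, immobile_fraction=0.3, seed=1)
        assert int(ens.immobile.sum()) == 3

    def test_uniformity_chi_square(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 100_000, seed=1)
        counts, _ = np.histogram(ens.s, bins=20, range=(0, geometry.length))
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_validation_errors(self, geometry, reporter):
        with pytest.raises(ValueError):
            init_ensemble(geometry, reporter, -1)
        with pytest.raises(ValueError):
            init_ensemble(geometry, reporter, 10, immobile_fraction=1.5)


# --------------------------------------------------------------------------
# diffusion
# --------------------------------------------------------------------------


class TestDiffusion:
    def test_zero_diffusivity_is_identity(self, geometry):
        frozen = Species("frozen", d_free=0.0)
        ens = init_ensemble(geometry, frozen, 500, seed=2)
        out = step_diffusion(ens, dt=1.0, rng=3)
        np.testing.assert_array_equal(out.s, ens.s)

    def test_displacement_variance_matches_2dt(self):
        # point source in the middle of a long cell: free diffusion regime
        g = straight_cell(100.0, 0.5)
        sp = Species("x", d_free=0.05)
        ens = init_ensemble(g, sp, 100_000, seed=4)
        ens.s[:] = 50.0
        rng = np.random.default_rng(5)
        for _ in range(10):
            ens = step_diffusion(ens, 0.1, rng=rng)
        disp = ens.s - 50.0
        var = disp.var()
        expected = 2 * 0.05 * 1.0
        se = expected * np.sqrt(2 / (len(disp) - 1))
        assert abs(var - expected) < 3 * se

    def test_long_time_equilibrium_uniform(self):
        g = straight_cell(2.0, 0.5)
        sp = Species("x", d_free=0.05)
        ens = init_ensemble(g, sp, 10_000, seed=6)
        ens.s[:] = 1.0
        rng = np.random.default_rng(7)
        for _ in range(20):  # folded steps are exact at any dt
            ens = step_diffusion(ens, 5.0, rng=rng)
        res = stats.kstest(ens.s / 2.0, "uniform")
        assert res.pvalue > 0.01

    @given(d=st.floats(0.0, 1.0), dt=st.floats(0.001, 100.0), seed=st.integers(0, 1000))
    def test_reflecting_boundaries_keep_particles_inside(self, d, dt, seed):
        g = straight_cell(3.0, 0.5)
        ens = init_ensemble(g, Species("x", d_free=d), 200, seed=seed)
        out = step_diffusion(ens, dt, rng=seed + 1)
        assert (out.s >= 0).all() and (out.s <= 3.0).all()

    def test_fluorescence_untouched(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 300, seed=8)
        ens = apply_bleach(ens, (1.0, 2.0), 1.0, 1, seed=9)
        dark_before = int((~ens.fluorescent).sum())
        ens = step_diffusion(ens, 0.5, rng=10)
        assert int((~ens.fluorescent).sum()) == dark_before


# --------------------------------------------------------------------------
# closed-form profile vs independent finite-difference oracle
# --------------------------------------------------------------------------


def fd_oracle(d, t, length, interval, depth, nx=800):
    """Explicit finite-volume solver for 1-D diffusion, reflecting ends.

    Cell-centered grid so that step edges coincide with cell boundaries and
    the initial mass is exact.
    """
    dx = length / nx
    x = (np.arange(nx) + 0.5) * dx
    c = np.ones(nx)
    c[(x >= interval[0]) & (x < interval[1])] = 1 - depth
    if d == 0 or t == 0:
        return x, c
    dt = 0.2 * dx**2 / d
    n_steps = int(np.ceil(t / dt))
    dt = t / n_steps
    lam = d * dt / dx**2
    for _ in range(n_steps):
        lap = np.empty_like(c)
        lap[1:-1] = c[:-2] - 2 * c[1:-1] + c[2:]
        lap[0] = c[1] - c[0]          # zero-flux boundary faces
        lap[-1] = c[-2] - c[-1]
        c = c + lam * lap
    return x, c


class TestAnalyticProfile:
    def test_initial_condition_step(self):
        s, c = analytic_profile(0.02, 0.0, 4.0, (1.5, 2.5), 0.7, n_terms=4000)
        inside = (s > 1.6) & (s < 2.4)      # keep clear of Gibbs ringing
        outside = (s < 1.4) | (s > 2.6)
        assert np.allclose(c[inside], 0.3, atol=5e-3)
        assert np.allclose(c[outside], 1.0, atol=5e-3)

    def test_equilibrium_level(self):
        s, c = analytic_profile(0.02, 1e6, 4.0, (1.5, 2.5), 0.8, n_terms=100)
        assert np.allclose(c, 1 - 0.8 * 1.0 / 4.0, atol=1e-10)

    @pytest.mark.parametrize("t", [0.5, 2.0, 10.0])
    def test_mass_conserved(self, t):
        s, c = analytic_profile(0.02, t, 4.0, (1.0, 2.0), 1.0, n_terms=500)
        mass = np.trapezoid(c, s)
        assert mass == pytest.approx(4.0 - 1.0, rel=1e-6)

    def test_matches_finite_difference_solver(self):
        x, c_fd = fd_oracle(0.02, 5.0, 4.0, (1.5, 2.5), 1.0)
        _, c_an = analytic_profile(0.02, 5.0, 4.0, (1.5, 2.5), 1.0,
                                   n_terms=2000, s=x)
        assert np.max(np.abs(c_an - c_fd)) < 1e-3

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            analytic_profile(0.02, 1.0, 4.0, (3.5, 4.5), 1.0)

    def test_particle_density_matches_analytic(self):
        # bleach everything in [1.5, 2.5), diffuse, compare fluorescent density
        g = straight_cell(4.0, 0.5)
        sp = Species("x", d_free=0.02)
        ens = init_ensemble(g, sp, 200_000, seed=11)
        ens = apply_bleach(ens, (1.5, 2.5), 1.0, 1, seed=12)
        rng = np.random.default_rng(13)
        t = 2.0
        for _ in range(4):
            ens = step_diffusion(ens, t / 4, rng=rng)
        s_f = ens.s[ens.fluorescent]
        counts, edges = np.histogram(s_f, bins=40, range=(0, 4.0))
        centers = (edges[:-1] + edges[1:]) / 2
        _, c = analytic_profile(0.02, t, 4.0, (1.5, 2.5), 1.0, n_terms=2000,
                                s=centers)
        expected = c / c.sum() * len(s_f)
        res = stats.chisquare(counts, expected * counts.sum() / expected.sum())
        assert res.pvalue > 0.001


# --------------------------------------------------------------------------
# photobleaching
# --------------------------------------------------------------------------


class TestBleach:
    def test_certain_bleach(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 2000, seed=14)
        out = apply_bleach(ens, (1.0, 3.0), 1.0, 1, seed=15)
        in_roi = (out.s >= 1.0) & (out.s < 3.0)
        assert not out.fluorescent[in_roi].any()
        assert out.fluorescent[~in_roi].all()

    def test_zero_probability_identity(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 500, seed=16)
        out = apply_bleach(ens, (1.0, 3.0), 0.0, 5, seed=17)
        assert out.fluorescent.all()

    def test_pulse_train_binomial(self):
        g = straight_cell(1.0, 0.5)
        ens = init_ensemble(g, Species("x", 0.01), 10_000, seed=18)
        out = apply_bleach(ens, (0.0, 1.0), 0.5, 3, seed=19)
        p = 1 - 0.5**3
        dark = int((~out.fluorescent).sum())
        se = np.sqrt(10_000 * p * (1 - p))
        assert abs(dark - 10_000 * p) < 3 * se

    def test_positions_unchanged_and_empty_roi_warns(self, geometry, reporter):
        ens = init_ensemble(geometry, reporter, 100, seed=20)
        out = apply_bleach(ens, (1.0, 2.0), 0.8, 2, seed=21)
        np.testing.assert_array_equal(out.s, ens.s)
        with pytest.warns(UserWarning, match="empty bleach ROI"):
            out2 = apply_bleach(ens, (2.0, 2.0), 0.8, 2, seed=22)
        assert out2.fluorescent.all()


# --------------------------------------------------------------------------
# contact zones: binding kinetics
# --------------------------------------------------------------------------


def make_contact_pair(allele_a, allele_b, n=1000, d=0.0, seed=0):
    ga = straight_cell(4.0, 0.5, cell_id="a")
    gb = straight_cell(4.0, 0.5, y=0.55, cell_id="b")
    ea = init_ensemble(ga, Species("ra", d, tra_allele=allele_a), n, seed=seed)
    eb = init_ensemble(gb, Species("rb", d, tra_allele=allele_b), n, seed=seed + 1)
    zone = ContactZone("a", "b", (1.0, 3.0), (1.0, 3.0))
    return merge_ensembles(ea, eb), zone


class TestContacts:
    def test_incompatible_never_binds(self):
        ens, zone = make_contact_pair("DK1622", "Mf")
        cfg = SimConfig(k_on=5.0, k_off=0.0)
        rng = np.random.default_rng(23)
        for _ in range(50):
            ens = update_contacts(ens, [zone], allele_compat, 0.1, cfg, rng=rng)
        assert int(ens.bound.sum()) == 0

    def test_k_on_zero_identity(self):
        ens, zone = make_contact_pair("DK1622", "DK1622")
        cfg = SimConfig(k_on=0.0, k_off=0.1)
        out = update_contacts(ens, [zone], allele_compat, 0.1, cfg, rng=24)
        assert int(out.bound.sum()) == 0

    def test_stationary_bound_fraction_matches_gillespie_oracle(self):
        # static-position variant: all receptors inside the zone, D = 0
        k_on, k_off, dt, t_end = 1.0, 0.1, 0.05, 30.0
        ens, zone = make_contact_pair("DK1622", "DK1622", n=2000, d=0.0, seed=25)
        ens.s[:] = np.random.default_rng(26).uniform(1.0, 3.0, ens.n)
        cfg = SimConfig(k_on=k_on, k_off=k_off)
        rng = np.random.default_rng(27)
        for _ in range(int(t_end / dt)):
            ens = update_contacts(ens, [zone], allele_compat, dt, cfg, rng=rng)
        frac = ens.bound.mean()

        # independent oracle: exact Gillespie simulation of the two-state chain
        grng = np.random.default_rng(28)
        m = 4000
        state = np.zeros(m, dtype=bool)
        t = np.zeros(m)
        alive = np.ones(m, dtype=bool)
        while alive.any():
            rates = np.where(state, k_off, k_on)
            t = t + grng.exponential(1 / rates)
            flip = alive & (t < t_end)
            state[flip] = ~state[flip]
            alive = t < t_end
        frac_oracle = state.mean()
        se = np.sqrt(frac_oracle * (1 - frac_oracle) * (1 / ens.n + 1 / m))
        assert abs(frac - frac_oracle) < 4 * se

    def test_zone_deactivation_releases_all_bonds(self):
        ens, zone = make_contact_pair("DK1622", "DK1622", n=500)
        cfg = SimConfig(k_on=10.0, k_off=0.0)
        rng = np.random.default_rng(29)
        for _ in range(20):
            ens = update_contacts(ens, [zone], allele_compat, 0.1, cfg, rng=rng)
        assert int(ens.bound.sum()) > 0
        zone.active = False
        ens = update_contacts(ens, [zone], allele_compat, 0.1, cfg, rng=rng)
        assert int(ens.bound.sum()) == 0

    def test_unknown_allele_raises(self):
        ens, zone = make_contact_pair("DK1622", "weird")
        cfg = SimConfig(k_on=1.0)
        known = {("DK1622", "DK1622"): True}

        def compat(a, b):
            return known[(a, b)]

        with pytest.raises(ValueError, match="unknown allele"):
            update_contacts(ens, [zone], compat, 0.1, cfg, rng=30)

    def test_self_contact_zone_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            ContactZone("a", "a", (1.0, 2.0), (1.5, 2.5))
        ContactZone("a", "a", (0.5, 1.0), (3.0, 3.5))  # knotted filament: fine


# --------------------------------------------------------------------------
# cargo transfer
# --------------------------------------------------------------------------


def engaged_pair(k_transfer, n_cargo=1000, seed=40):
    """Two cells with pinned bound receptors and static in-zone cargo."""
    ga = straight_cell(4.0, 0.5, cell_id="a")
    gb = straight_cell(4.0, 0.5, y=0.55, cell_id="b")
    rec = Species("rec", 0.0, tra_allele="DK1622")
    ca = Species("gfp", 0.0, transferable=True)
    cb = Species("mch", 0.0, transferable=True)
    rng = np.random.default_rng(seed)
    ea = init_ensemble(ga, rec, 50, seed=seed)
    eb = init_ensemble(gb, rec, 50, seed=seed + 1)
    ga_c = init_ensemble(ga, ca, n_cargo, seed=seed + 2)
    gb_c = init_ensemble(gb, cb, n_cargo, seed=seed + 3)
    ens = merge_ensembles(ea, eb, ga_c, gb_c)
    ens.s[:] = rng.uniform(1.0, 3.0, ens.n)  # everything inside the zone
    zone = ContactZone("a", "b", (1.0, 3.0), (1.0, 3.0))
    cfg = SimConfig(k_on=50.0, k_off=0.0, k_transfer=k_transfer)
    ens = update_contacts(ens, [zone], allele_compat, 1.0, cfg, rng=seed + 4)
    return ens, zone, cfg


class TestTransfer:
    def test_k_transfer_zero_identity(self):
        ens, zone, cfg = engaged_pair(0.0)
        out = transfer_cargo(ens, [zone], 0.1, cfg, rng=41)
        np.testing.assert_array_equal(out.cell, ens.cell)

    def test_no_bound_receptors_no_transfer(self):
        # delta-tra analogue: no receptor engagement -> cargo never crosses
        ga = straight_cell(4.0, 0.5, cell_id="a")
        gb = straight_cell(4.0, 0.5, y=0.55, cell_id="b")
        ca = init_ensemble(ga, Species("gfp", 0.0, transferable=True), 500, seed=42)
        cb = init_ensemble(gb, Species("mch", 0.0, transferable=True), 500, seed=43)
        ens = merge_ensembles(ca, cb)
        ens.s[:] = 2.0
        zone = ContactZone("a", "b", (1.0, 3.0), (1.0, 3.0))
        cfg = SimConfig(k_transfer=10.0)
        out = transfer_cargo(ens, [zone], 1.0, cfg, rng=44)
        np.testing.assert_array_equal(out.cell, ens.cell)

    def test_receptors_never_switch_cells(self):
        ens, zone, cfg = engaged_pair(5.0)
        rec_idx = ens.species == ens.species_index("rec")
        cells_before = ens.cell[rec_idx].copy()
        out = transfer_cargo(ens, [zone], 1.0, cfg, rng=45)
        np.testing.assert_array_equal(out.cell[rec_idx], cells_before)

    def test_symmetric_mixing_matches_urn_oracle(self):
        # closed-form two-urn Markov chain: after m steps with per-step hop
        # probability p, P(still in origin cell) = (1 + (1-2p)^m) / 2
        k_tr, dt, m = 0.2, 0.1, 100
        ens, zone, cfg = engaged_pair(k_tr, n_cargo=2000)
        rng = np.random.default_rng(46)
        for _ in range(m):
            ens = transfer_cargo(ens, [zone], dt, cfg, rng=rng)
        gfp = ens.species == ens.species_index("gfp")
        in_origin = (ens.cell[gfp] == ens.cell_index("a")).mean()
        p = 1 - np.exp(-k_tr * dt)
        expected = (1 + (1 - 2 * p) ** m) / 2
        se = np.sqrt(expected * (1 - expected) / gfp.sum())
        assert abs(in_origin - expected) < 4 * se

    def test_global_count_conserved(self):
        ens, zone, cfg = engaged_pair(2.0)
        before = {sp.name: int((ens.species == i).sum())
                  for i, sp in enumerate(ens.species_table)}
        out = transfer_cargo(ens, [zone], 1.0, cfg, rng=47)
        after = {sp.name: int((out.species == i).sum())
                 for i, sp in enumerate(out.species_table)}
        assert before == after


# --------------------------------------------------------------------------
# conservation invariants across operations
# --------------------------------------------------------------------------


def test_particle_count_conservation_under_all_ops(geometry, reporter):
    ens = init_ensemble(geometry, reporter, 800, seed=50)
    counts0 = ens.counts()
    fl0 = int(ens.fluorescent.sum())
    ens = step_diffusion(ens, 0.5, rng=51)
    assert ens.counts() == counts0
    assert int(ens.fluorescent.sum()) == fl0
    ens = apply_bleach(ens, (1.0, 2.0), 0.7, 3, seed=52)
    assert ens.counts() == counts0
    assert int(ens.fluorescent.sum()) <= fl0


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


class TestRender:
    def test_zero_particles_background_only(self, geometry, config):
        ens = init_ensemble(geometry, Species("x", 0.01), 0, seed=60)
        img = render_frame(ens, config, rng=61)
        assert img.mean() == pytest.approx(config.background,
                                           abs=4 * np.sqrt(config.background / img.size))

    def test_noiseless_sharp_psf_conserves_photons(self, geometry, config):
        ens = init_ensemble(geometry, Species("x", 0.01), 777, seed=62)
        cfg = SimConfig(psf_sigma=1e-9, background=0.0, read_noise_sd=0.0)
        img = render_frame(ens, cfg, noise=False)
        assert img.sum() == pytest.approx(cfg.photons_per_particle * 777, rel=1e-9)

    def test_dark_particles_invisible(self, geometry, config):
        ens = init_ensemble(geometry, Species("x", 0.01), 400, seed=63)
        ens = apply_bleach(ens, (0.0, 4.0), 1.0, 1, seed=64)
        img = render_frame(ens, config, noise=False)
        assert img.sum() == 0

    def test_foci_visible_over_seeds(self, config):
        # bound receptors packed in a 0.3 um zone vs a uniform control
        g = straight_cell(4.0, 0.5)
        wins = 0
        for seed in range(20):
            packed = init_ensemble(g, Species("x", 0.01), 500, seed=seed)
            packed.s[:] = np.random.default_rng(seed).uniform(1.85, 2.15, 500)
            uniform = init_ensemble(g, Species("x", 0.01), 500, seed=seed + 100)
            ratios = []
            for ens in (packed, uniform):
                img = render_frame(ens, config, rng=seed + 200).astype(float)
                img -= config.background
                origin, _ = field_of_view([g], config)
                from omeflux.profiles import extract_profile
                prof = extract_profile(img, g, 0.4, config.pixel_size, origin=origin)
                zone = (prof.s >= 1.85) & (prof.s < 2.15)
                ratios.append(prof.intensity[zone].mean()
                              / prof.intensity[~zone].mean())
            wins += ratios[0] > ratios[1]
        assert wins == 20

    def test_out_of_fov_raises(self, config):
        g = straight_cell(4.0, 0.5)
        ens = init_ensemble(g, Species("x", 0.01), 10, seed=65)
        small_fov = (np.array([0.0, 0.0]), (5, 5))
        with pytest.raises(ValueError, match="field of view"):
            render_frame(ens, config, noise=False, fov=small_fov)


# --------------------------------------------------------------------------
# FRAP experiment driver
# --------------------------------------------------------------------------


class TestSimulateFrap:
    def test_deterministic_given_seed(self, geometry, reporter):
        cfg = SimConfig(dt=1.0, n_steps=5, n_particles=500, rng_seed=99)
        s1, f1, _ = simulate_frap_experiment(cfg, geometry, reporter, (1.7, 2.3))
        cfg2 = SimConfig(dt=1.0, n_steps=5, n_particles=500, rng_seed=99)
        s2, f2, _ = simulate_frap_experiment(cfg2, geometry, reporter, (1.7, 2.3))
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(f1.i_frap, f2.i_frap)
        cfg3 = SimConfig(dt=1.0, n_steps=5, n_particles=500, rng_seed=100)
        s3, _, _ = simulate_frap_experiment(cfg3, geometry, reporter, (1.7, 2.3))
        assert not np.array_equal(s1, s3)

    def test_fully_immobile_no_recovery(self, geometry):
        cfg = SimConfig(dt=5.0, n_steps=10, n_particles=3000,
                        immobile_fraction=1.0, rng_seed=1)
        _, series, _ = simulate_frap_experiment(cfg, geometry,
                                                Species("stuck", 0.02), (1.7, 2.3))
        post = series.i_frap[series.t0_index:]
        assert post.max() <= post[0] + 0.05 * series.i_frap[series.pre_index]

    def test_fast_diffusion_recovers_within_frames(self, geometry):
        cfg = SimConfig(dt=5.0, n_steps=10, n_particles=5000, rng_seed=2)
        _, series, _ = simulate_frap_experiment(cfg, geometry,
                                                Species("fast", 1.0), (1.7, 2.3))
        from omeflux.frap import double_normalize
        i_norm = double_normalize(series)
        assert i_norm[series.t0_index + 2:].mean() > 0.9

    def test_roi_outside_cell_raises(self, geometry, reporter, config):
        with pytest.raises(ValueError, match="ROI"):
            simulate_frap_experiment(config, geometry, reporter, (3.5, 4.5))
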