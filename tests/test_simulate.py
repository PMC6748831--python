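"""Generator contracts: geometry invariants, determinism, statistics."""

import numpy as np
import pytest

from synecto import simulate as sim


class TestScene:
    def test_protein_clusters_lie_inside_their_vesicle(self):
        scene = sim.generate_scene(seed=7)
        by_id = {v.id: v for v in scene.vesicles}
        for c in scene.protein_clusters:
            v = by_id[c.vesicle_id]
            d = np.linalg.norm(np.asarray(c.center_nm) - np.asarray(v.center_nm))
            assert d <= v.diameter_nm / 2.0 + 1e-9
            # molecules too, not just cluster centres
            mol = scene.molecule_positions[c.id]
            dm = np.linalg.norm(mol - np.asarray(v.center_nm), axis=1)
            assert np.all(dm <= v.diameter_nm / 2.0 + 1e-9)

    def test_positivity_class_consistent_with_attached_species(self):
        scene = sim.generate_scene(seed=3)
        for v in scene.vesicles:
            species = {c.species for c in scene.clusters_of(v.id)}
            if v.positivity == "TCR-only":
                assert "TCR" in species and "CD40L" not in species
            elif v.positivity == "partner-only":
                assert "CD40L" in species and "TCR" not in species
            else:
                assert {"TCR", "CD40L"} <= species

    def test_same_seed_bit_identical(self):
        a = sim.generate_scene(seed=11)
        b = sim.generate_scene(seed=11)
        assert [v.diameter_nm for v in a.vesicles] == \
               [v.diameter_nm for v in b.vesicles]
        np.testing.assert_array_equal(a.fiducials, b.fiducials)
        for cid in a.molecule_positions:
            np.testing.assert_array_equal(a.molecule_positions[cid],
                                          b.molecule_positions[cid])

    def test_zero_vesicles_gives_cells_only(self):
        params = sim.SceneParams(vesicles_per_cell_mean=0,
                                 vesicles_per_cell_sd=0)
        scene = sim.generate_scene(params, seed=0)
        assert len(scene.cells) == params.n_cells
        assert scene.vesicles == [] and scene.protein_clusters == []

    def test_diameter_distribution_converges(self):
        # 10,000 vesicles: empirical mean/sd within 3 standard errors
        params = sim.SceneParams(n_cells=50, vesicles_per_cell_mean=200,
                                 vesicles_per_cell_sd=0,
                                 membrane_molecules_per_vesicle=2,
                                 molecules_per_cluster=2)
        scene = sim.generate_scene(params, seed=5)
        d = np.array([v.diameter_nm for v in scene.vesicles])
        assert len(d) == 10_000
        se_mean = params.diameter_sd_nm / np.sqrt(len(d))
        assert abs(d.mean() - 84.0) < 3 * se_mean
        assert abs(d.std(ddof=1) - 5.0) < 3 * params.diameter_sd_nm / np.sqrt(2 * len(d))

    def test_double_positive_fraction_within_binomial_ci(self):
        params = sim.SceneParams(n_cells=10, vesicles_per_cell_mean=50,
                                 vesicles_per_cell_sd=0,
                                 double_positive_fraction=0.545,
                                 membrane_molecules_per_vesicle=2,
                                 molecules_per_cluster=2)
        scene = sim.generate_scene(params, seed=9)
        n = len(scene.vesicles)
        k = sum(v.positivity == "double-positive" for v in scene.vesicles)
        half = 1.96 * np.sqrt(0.545 * 0.455 / n)
        assert abs(k / n - 0.545) < half + 1e-12

    @pytest.mark.parametrize("bad", [
        dict(diameter_mean_nm=-1.0),
        dict(double_positive_fraction=1.5),
        dict(n_cells=0),
    ])
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ValueError):
            sim.generate_scene(sim.SceneParams(**bad), seed=0)


class TestLocalizationSimulation:
    def test_noiseless_single_blink_reproduces_truth(self):
        scene = sim.generate_scene(sim.SceneParams(n_cells=1), seed=1)
        blink = sim.BlinkModel(1.0, 1.0, 4000.0, 0.0, 1.0)
        acq = sim.AcquisitionConfig(n_frames=100,
                                    localization_precision_nm=0.0,
                                    warp_channels=())
        res = sim.simulate_localizations(scene, blink, acq, seed=1)
        truth = scene.molecules_by_species()
        for species, table in res.tables.items():
            got = np.sort(table.xy, axis=0)
            want = np.sort(truth[species], axis=0)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_expected_localization_count(self):
        # Monte-Carlo oracle: with full labeling, run length 1, count =
        # sum of (1 + Poisson(mu - 1)) over molecules
        scene = sim.generate_scene(sim.SceneParams(n_cells=1), seed=2)
        n_molecules = sum(len(p) for p in scene.molecule_positions.values())
        mu = 2.5
        blink = sim.BlinkModel(mu, 1.0, 4000.0, 0.0, 1.0)
        acq = sim.AcquisitionConfig(n_frames=200, warp_channels=())
        counts = []
        for seed in range(100):
            res = sim.simulate_localizations(scene, blink, acq, seed=seed)
            counts.append(sum(len(t) for t in res.tables.values()))
        expected = n_molecules * mu
        var = n_molecules * (mu - 1.0)  # Poisson part only
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(var / 100)

    def test_same_seed_identical_tables(self):
        scene = sim.generate_scene(sim.SceneParams(n_cells=1), seed=3)
        blink, acq = sim.BlinkModel(), sim.AcquisitionConfig(n_frames=100)
        a = sim.simulate_localizations(scene, blink, acq, seed=8)
        b = sim.simulate_localizations(scene, blink, acq, seed=8)
        for ch in a.tables:
            assert a.tables[ch].df.equals(b.tables[ch].df)

    def test_fiducials_in_every_frame_and_channel(self):
        scene = sim.generate_scene(sim.SceneParams(n_cells=1, n_fiducials=4),
                                   seed=4)
        acq = sim.AcquisitionConfig(n_frames=50)
        res = sim.simulate_localizations(scene, sim.BlinkModel(), acq, seed=4)
        for ch, table in res.fiducial_tables.items():
            assert len(table) == 4 * 50
            assert set(table.df["frame"]) == set(range(50))


class TestFrames:
    def test_integrated_signal_equals_photons(self):
        pos = np.array([[16 * 107.0, 16 * 107.0]])
        blink = sim.BlinkModel(1.0, 1.0, 3000.0, 0.0, 1.0)
        acq = sim.AcquisitionConfig(n_frames=1, psf_sigma_nm=150.0)
        fr = sim.simulate_frames(pos, blink, acq, (32, 32), background=0.0,
                                 seed=0, poisson_noise=False)
        assert fr.stack.shape == (1, 32, 32)
        np.testing.assert_allclose(fr.stack[0].sum(), 3000.0, rtol=1e-6)

    def test_centroid_matches_emitter_at_pixel_center(self):
        pos = np.array([[10 * 107.0, 20 * 107.0]])
        blink = sim.BlinkModel(1.0, 1.0, 3000.0, 0.0, 1.0)
        acq = sim.AcquisitionConfig(n_frames=1, psf_sigma_nm=150.0)
        fr = sim.simulate_frames(pos, blink, acq, (32, 32), background=0.0,
                                 seed=0, poisson_noise=False)
        img = fr.stack[0]
        yy, xx = np.mgrid[0:32, 0:32]
        cx = (img * xx).sum() / img.sum() * 107.0
        cy = (img * yy).sum() / img.sum() * 107.0
        np.testing.assert_allclose([cx, cy], pos[0], atol=1e-6)

    def test_field_size_budget(self):
        with pytest.raises(ValueError):
            sim.simulate_frames(np.zeros((1, 2)), sim.BlinkModel(),
                                sim.AcquisitionConfig(n_frames=1), (512, 512))


class TestCytometry:
    def test_zero_noise_ladder_fits_exactly(self):
        from synecto import quantify as qt
        panel = sim.simulate_cytometry(sim.CytometryParams(noise_cv=0.0),
                                       seed=0)
        ladder = qt.MESFLadder(panel.ladder["intensity"], panel.ladder["mesf"],
                               blank_intensity=panel.blank_intensity)
        curve = qt.fit_mesf_curve(ladder)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        back = curve.to_mesf(panel.ladder["intensity"].to_numpy())
        np.testing.assert_allclose(back, panel.ladder["mesf"], rtol=1e-9)

    def test_round_trip_recovers_transfer_fraction(self):
        from synecto import quantify as qt
        params = sim.CytometryParams(transfer_fraction=0.30, noise_cv=0.05)
        panel = sim.simulate_cytometry(params, seed=1)
        curve = qt.fit_mesf_curve(qt.MESFLadder(
            panel.ladder["intensity"], panel.ladder["mesf"],
            panel.blank_intensity))
        mol = qt.molecules_from_panel(panel.events, curve)
        frac = qt.transfer_fraction_from_molecules(mol)
        assert frac == pytest.approx(0.30, abs=0.05)

    def test_determinism(self):
        a = sim.simulate_cytometry(seed=6)
        b = sim.simulate_cytometry(seed=6)
        assert a.events.equals(b.events) and a.ladder.equals(b.ladder)


class TestProteome:
    def test_noiseless_recovery_is_exact(self):
        from synecto import network as net
        params = sim.ProteomeParams(effect_size=4.0, noise_cv=0.0,
                                    missing_rate=0.0)
        prot = sim.simulate_proteome(params, seed=2)
        kept = net.fold_change_filter(prot.table, threshold=3.35)
        assert set(kept) == set(prot.protein_ids[prot.enriched])

    def test_null_keeps_almost_nothing(self):
        from synecto import network as net
        # effect size 1 = no enrichment anywhere; Monte-Carlo false-positive rate
        n_kept = 0
        for seed in range(10):
            prot = sim.simulate_proteome(
                sim.ProteomeParams(effect_size=1.0, fraction_enriched=0.0,
                                   noise_cv=0.3, missing_rate=0.0), seed=seed)
            n_kept += len(net.fold_change_filter(prot.table, threshold=3.35))
        assert n_kept / 10 < 1.0

    def test_determinism(self):
        a = sim.simulate_proteome(seed=3)
        b = sim.simulate_proteome(seed=3)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(a.enriched, b.enriched)
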