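"""CBC, cross-correlation, NND and Pearson image correlation."""

import numpy as np
import pytest
from scipy.stats import kstest

from synecto import colocalization as coloc
from synecto.localization import render
from synecto.tables import make_table
from conftest import sample_disk


def brute_force_cbc(A, B, r_max=50.0, n_steps=5):
    """Independent CBC oracle: plain loops, manual average ranks."""
    radii = r_max / n_steps * np.arange(1, n_steps + 1)

    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        i = 0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0
            i = j + 1
        return ranks

    def spearman(u, v):
        ru, rv = avg_ranks(u), avg_ranks(v)
        ru -= ru.mean()
        rv -= rv.mean()
        denom = np.sqrt((ru**2).sum() * (rv**2).sum())
        return (ru * rv).sum() / denom if denom > 0 else 0.0

    values, excluded = [], 0
    for a in A:
        da_all = np.linalg.norm(A - a, axis=1)
        db_all = np.linalg.norm(B - a, axis=1)
        na = np.array([(da_all <= r).sum() - 1 for r in radii], float)
        nb = np.array([((db_all <= r) & (db_all > 1e-9)).sum()
                       for r in radii], float)
        if na[-1] <= 0:
            excluded += 1
            continue
        da = na / radii**2 * (r_max**2 / na[-1])
        if nb[-1] <= 0:
            values.append(0.0)
            continue
        db = nb / radii**2 * (r_max**2 / nb[-1])
        if np.allclose(da, da[0]) and np.allclose(db, db[0]):
            rho = 1.0 if np.allclose(da, db) else 0.0
        elif np.allclose(da, da[0]) or np.allclose(db, db[0]):
            rho = 0.0
        else:
            rho = spearman(da, db)
        values.append(rho * np.exp(-db_all.min() / r_max))
    return np.array(values), excluded


class TestCBC:
    def test_identical_channels_give_plus_one(self, rng):
        A = rng.normal(0, 25, (60, 2))
        A = np.concatenate([A, A + [400.0, 0.0]])
        res = coloc.cbc(A, A.copy())
        np.testing.assert_allclose(res.values, 1.0, atol=1e-9)

    def test_csr_mean_near_zero(self):
        means = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            A = r.uniform(0, 2000, (1000, 2))
            B = r.uniform(0, 2000, (1000, 2))
            means.append(coloc.cbc(A, B).mean)
        assert abs(np.mean(means)) < 0.1

    def test_disk_vs_annulus_segregation(self, rng):
        disk = sample_disk(rng, 50, 25.0)
        r = rng.uniform(30.0, 50.0, 50)
        th = rng.uniform(0, 2 * np.pi, 50)
        annulus = np.column_stack([r * np.cos(th), r * np.sin(th)])
        res = coloc.cbc(disk, annulus)
        assert res.mean < 0.0

    def test_agrees_with_brute_force_oracle(self, rng):
        disk = sample_disk(rng, 50, 25.0)
        r = rng.uniform(30.0, 50.0, 50)
        th = rng.uniform(0, 2 * np.pi, 50)
        annulus = np.column_stack([r * np.cos(th), r * np.sin(th)])
        res = coloc.cbc(disk, annulus)
        expected, excluded = brute_force_cbc(disk, annulus)
        assert res.n_excluded == excluded
        np.testing.assert_allclose(np.sort(res.values), np.sort(expected),
                                   atol=1e-9)

    def test_values_bounded_and_histogram_conserves_mass(self, rng):
        A = rng.uniform(0, 1000, (200, 2))
        B = rng.uniform(0, 1000, (200, 2))
        res = coloc.cbc(A, B)
        assert np.all(res.values >= -1.0 - 1e-12)
        assert np.all(res.values <= 1.0 + 1e-12)
        assert res.histogram.sum() == len(res.values)
        assert len(res.values) + res.n_excluded == len(A)

    def test_empty_channel_raises(self):
        with pytest.raises(ValueError):
            coloc.cbc(np.empty((0, 2)), np.zeros((3, 2)))


class TestNND:
    def test_three_four_five(self):
        res = coloc.nnd(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        assert res.distances_nm[0] == pytest.approx(5.0)

    def test_superset_gives_zero(self, rng):
        A = rng.uniform(0, 1000, (30, 2))
        B = np.concatenate([A, rng.uniform(0, 1000, (20, 2))])
        np.testing.assert_allclose(coloc.nnd(A, B).distances_nm, 0.0)

    @pytest.mark.parametrize("n", [20, 500])
    def test_matches_brute_force(self, rng, n):
        A = rng.uniform(0, 2000, (n, 2))
        B = rng.uniform(0, 2000, (n, 2))
        res = coloc.nnd(A, B)
        brute = np.min(np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2),
                       axis=1)
        np.testing.assert_array_equal(res.distances_nm, brute)

    def test_per_cell_medians(self, rng):
        A = rng.uniform(0, 1000, (40, 2))
        B = rng.uniform(0, 1000, (40, 2))
        labels = np.repeat([0, 1], 20)
        res = coloc.nnd(A, B, cell_labels=labels)
        assert set(res.per_cell_median_nm) == {0, 1}

    def test_csr_matches_rayleigh_distribution(self):
        # NN distance from independent points to a CSR field of intensity
        # rho has CDF 1 - exp(-rho pi r^2)
        r = np.random.default_rng(123)
        side, n = 10_000.0, 2000
        A = r.uniform(0, side, (n, 2))
        B = r.uniform(0, side, (n, 2))
        rho = n / side**2
        d = coloc.nnd(A, B).distances_nm
        p = kstest(d, lambda x: 1.0 - np.exp(-rho * np.pi * x**2)).pvalue
        assert p > 0.01

    def test_empty_b_raises(self):
        with pytest.raises(ValueError):
            coloc.nnd(np.zeros((2, 2)), np.empty((0, 2)))


class TestCrossCorrelation:
    def test_csr_is_flat_at_one(self):
        r = np.random.default_rng(7)
        A = r.uniform(0, 2000, (1000, 2))
        B = r.uniform(0, 2000, (1000, 2))
        mask = coloc.RectMask(0, 2000, 0, 2000)
        cc = coloc.cross_correlation(A, B, mask, n_random=30, seed=7)
        ok = np.abs(cc.c - 1.0) < 3.0 * cc.uncertainty
        assert np.mean(ok) >= 0.95

    def test_fixed_displacement_peaks_at_150(self):
        r = np.random.default_rng(11)
        A = r.uniform(200, 1800, (400, 2))
        th = r.uniform(0, 2 * np.pi, len(A))
        B = A + 150.0 * np.column_stack([np.cos(th), np.sin(th)])
        mask = coloc.RectMask(0, 2000, 0, 2000)
        cc = coloc.cross_correlation(A, B, mask, n_random=30, seed=11)
        assert abs(cc.peak_r_nm - 150.0) <= cc.r_nm[1] - cc.r_nm[0]

    def test_density_invariance_under_duplication(self):
        r = np.random.default_rng(5)
        A = r.uniform(0, 1500, (300, 2))
        th = r.uniform(0, 2 * np.pi, len(A))
        B = A + 100.0 * np.column_stack([np.cos(th), np.sin(th)])
        mask = coloc.RectMask(-200, 1700, -200, 1700)
        c1 = coloc.cross_correlation(A, B, mask, n_random=30, seed=5)
        c2 = coloc.cross_correlation(np.repeat(A, 2, axis=0),
                                     np.repeat(B, 2, axis=0),
                                     mask, n_random=30, seed=6)
        sel = c1.r_nm < 500
        tol = 3.0 * np.hypot(c1.uncertainty[sel], c2.uncertainty[sel])
        assert np.all(np.abs(c1.c[sel] - c2.c[sel]) <= np.maximum(tol, 0.5))

    def test_symmetry_within_uncertainty(self):
        r = np.random.default_rng(3)
        A = r.uniform(0, 1000, (200, 2))
        B = r.uniform(0, 1000, (200, 2))
        mask = coloc.RectMask(0, 1000, 0, 1000)
        ab = coloc.cross_correlation(A, B, mask, n_random=30, seed=1)
        ba = coloc.cross_correlation(B, A, mask, n_random=30, seed=2)
        tol = 3.0 * np.hypot(ab.uncertainty, ba.uncertainty)
        ok = np.abs(ab.c - ba.c) <= tol
        assert np.mean(ok[np.isfinite(ok.astype(float))]) >= 0.95

    def test_parameter_validation(self):
        A = np.zeros((3, 2))
        mask = coloc.RectMask(0, 1, 0, 1)
        with pytest.raises(ValueError):
            coloc.cross_correlation(A, np.empty((0, 2)), mask)
        with pytest.raises(ValueError):
            coloc.cross_correlation(A, A, mask, n_random=5)


class TestImagePCC:
    def test_identity_and_inversion(self, rng):
        img = rng.uniform(0, 10, (50, 50))
        assert coloc.image_pcc(img, img).value == pytest.approx(1.0)
        assert coloc.image_pcc(img, img.max() - img).value == pytest.approx(-1.0)

    def test_independent_renderings_uncorrelated(self):
        r = np.random.default_rng(9)
        imgs = []
        for _ in range(2):
            pts = r.uniform(0, 5000, (800, 2))
            t = make_table(0, pts[:, 0], pts[:, 1], precision_nm=30.0)
            imgs.append(render(t, 50.0, extent_nm=(0, 5000, 0, 5000)).data)
        res = coloc.image_pcc(imgs[0], imgs[1])
        assert res.n_pixels >= 10_000
        assert abs(res.value) < 0.1

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            coloc.image_pcc(np.ones((5, 5)), np.random.default_rng(0).uniform(size=(5, 5)))
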