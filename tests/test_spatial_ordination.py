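"""Distance matrices, Mantel permutation test, PCA, probe clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

import limnoblot as lb
from limnoblot.spatial_ordination import METERS_PER_DEGREE, _haversine
from conftest import random_score_matrix


def _bm(values, habitats=None, probes=None):
    values = np.asarray(values)
    habitats = habitats or [f"H{i}" for i in range(values.shape[0])]
    probes = probes or [f"P{j}" for j in range(values.shape[1])]
    return lb.BinaryMatrix(pd.DataFrame(values, index=habitats, columns=probes))


def _euclid_dm(rng, n, ids=None):
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return lb.DistanceMatrix(tuple(ids or (f"o{i}" for i in range(n))), d)


def _geo_table(lat, lon):
    ids = [f"H{i}" for i in range(len(lat))]
    return lb.HabitatTable(
        pd.DataFrame({"pH": [7.0] * len(lat), "latitude": lat, "longitude": lon}, index=ids)
    )


class TestCommunitySimilarity:
    def test_identical_rows_similarity_one(self):
        b = _bm([[1, 0, 1], [1, 0, 1]])
        sim, dist = lb.community_similarity(b)
        assert sim.iloc[0, 1] == 1.0
        assert dist.values[0, 1] == 0.0

    def test_complementary_rows_simple_matching_zero(self):
        b = _bm([[1, 1, 1], [0, 0, 0]])
        sim, _ = lb.community_similarity(b, "simple-matching")
        assert sim.iloc[0, 1] == 0.0

    def test_hand_counted_example(self):
        b = _bm([[1, 1, 0, 0], [1, 0, 1, 0]])
        sm, _ = lb.community_similarity(b, "simple-matching")
        jc, _ = lb.community_similarity(b, "jaccard")
        assert sm.iloc[0, 1] == 0.5  # agree on probes 0 and 3
        assert jc.iloc[0, 1] == pytest.approx(1 / 3)

    def test_single_habitat_errors(self):
        with pytest.raises(ValueError):
            lb.community_similarity(_bm([[1, 0]]))


class TestGeoDistance:
    def test_identical_coordinates_zero(self):
        h = _geo_table([48.0, 48.0], [14.0, 14.0])
        for method in ("equator-1d", "great-circle"):
            assert lb.geo_distance(h, method).values[0, 1] == 0.0

    def test_one_degree_latitude_equator_transform(self):
        h = _geo_table([48.0, 49.0], [14.0, 14.0])
        d = lb.geo_distance(h, "equator-1d")
        assert d.values[0, 1] == pytest.approx(METERS_PER_DEGREE)

    def test_equator_transform_is_longitude_blind(self):
        h = _geo_table([48.0, 48.0], [14.0, 15.0])
        assert lb.geo_distance(h, "equator-1d").values[0, 1] == 0.0
        assert lb.geo_distance(h, "great-circle").values[0, 1] > 50_000

    def test_great_circle_matches_haversine_oracle(self, rng):
        lat = rng.uniform(45, 50, 5)
        lon = rng.uniform(10, 17, 5)
        d = lb.geo_distance(_geo_table(lat, lon), "great-circle")
        for i in range(5):
            for j in range(5):
                assert d.values[i, j] == pytest.approx(
                    _haversine(lat[i], lon[i], lat[j], lon[j])
                )

    def test_great_circle_triangle_inequality(self, rng):
        lat = rng.uniform(-60, 60, 12)
        lon = rng.uniform(-170, 170, 12)
        d = lb.geo_distance(_geo_table(lat, lon), "great-circle").values
        for i, j, k in itertools.permutations(range(12), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-6

    def test_missing_coordinates_listed(self):
        h = lb.HabitatTable(pd.DataFrame({"pH": [7.0]}, index=["H0"]))
        with pytest.raises(ValueError, match="latitude"):
            lb.geo_distance(h)


class TestEnvDelta:
    def test_ph_delta_matrix(self):
        h = lb.HabitatTable(pd.DataFrame({"pH": [4.0, 6.5, 9.0]}, index=["a", "b", "c"]))
        d = lb.env_delta(h, "pH")
        assert d.values[0, 2] == pytest.approx(5.0)
        assert d.kind == "environmental-delta"


class TestMantel:
    def test_self_correlation_r_one(self, rng):
        d1 = _euclid_dm(rng, 8)
        res = lb.mantel(d1, d1, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_small_n_matches_enumeration_oracle(self, rng):
        for trial in range(5):
            d1, d2 = _euclid_dm(rng, 4), _euclid_dm(rng, 4)
            res = lb.mantel(d1, d2, exact=True)
            v1 = squareform(d1.values)
            count = 0
            for p in itertools.permutations(range(4)):
                w = squareform(d2.values[np.ix_(p, p)])
                count += abs(np.corrcoef(v1, w)[0, 1]) >= abs(res.r) - 1e-12
            assert res.p == pytest.approx(count / 24)
            assert res.method == "exact" and res.n_permutations == 24

    def test_constant_matrix_errors(self, rng):
        d1 = _euclid_dm(rng, 5)
        flat = lb.DistanceMatrix(d1.ids, np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="variance"):
            lb.mantel(d1, flat)

    def test_seed_reproducibility(self, rng):
        d1, d2 = _euclid_dm(rng, 10), _euclid_dm(rng, 10)
        a = lb.mantel(d1, d2, n_permutations=199, seed=42)
        b = lb.mantel(d1, d2, n_permutations=199, seed=42)
        assert (a.r, a.p) == (b.r, b.p)
        assert a.p >= 1 / 200

    def test_signal_beats_shuffled_noise(self, rng):
        """r(d1, d1+noise) should exceed r(d1, independent d2) on average."""
        wins = 0
        for i in range(20):
            local = np.random.default_rng(100 + i)
            d1 = _euclid_dm(local, 12)
            noisy = d1.values + local.normal(0, 0.05, d1.values.shape)
            noisy = np.abs((noisy + noisy.T) / 2)
            np.fill_diagonal(noisy, 0)
            d_noisy = lb.DistanceMatrix(d1.ids, noisy)
            d_indep = _euclid_dm(local, 12, ids=d1.ids)
            r_sig = lb.mantel(d1, d_noisy, 49, seed=i).r
            r_null = lb.mantel(d1, d_indep, 49, seed=i).r
            wins += r_sig > r_null
        assert wins >= 17

    def test_cross_check_against_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        d1, d2 = _euclid_dm(rng, 15), _euclid_dm(rng, 15)
        ours = lb.mantel(d1, d2, n_permutations=999, seed=3)
        r_sk, p_sk, _ = sk_mantel(
            SkDM(d1.values, ids=d1.ids), SkDM(d2.values, ids=d2.ids),
            method="pearson", permutations=999, alternative="two-sided",
        )
        assert ours.r == pytest.approx(float(r_sk), abs=1e-12)
        assert ours.p == pytest.approx(float(p_sk), abs=0.05)


class TestPca:
    def test_single_varying_column_explains_everything(self):
        b = _bm([[0, 1, 1], [0, 0, 1], [0, 1, 1], [0, 0, 1]])
        res = lb.pca(b)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self, rng):
        for _ in range(20):
            b = lb.binarize(random_score_matrix(rng, 10, 5))
            if b.df.std().sum() == 0:
                continue
            res = lb.pca(b)
            assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_axis_variances_match_eigensolve_oracle(self, rng):
        b = lb.binarize(random_score_matrix(rng, 12, 4))
        res = lb.pca(b)
        x = b.df.to_numpy(float)
        cov = np.cov(x - x.mean(axis=0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        score_var = res.scores.to_numpy().var(axis=0, ddof=1)
        assert np.allclose(score_var, eig[: len(score_var)], atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        b = lb.binarize(random_score_matrix(rng, 15, 6))
        r1, r2 = lb.pca(b), lb.pca(b)
        pd.testing.assert_frame_equal(r1.loadings, r2.loadings)
        for ax in r1.loadings.columns:
            j = r1.loadings[ax].abs().idxmax()
            assert r1.loadings.loc[j, ax] > 0

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError):
            lb.pca(_bm([[1, 1], [1, 1]]))


class TestClusterProbes:
    def test_identical_columns_cocluster(self, rng):
        base = rng.integers(0, 2, 30)
        other = 1 - base
        b = _bm(np.column_stack([base, base, other, other]), probes=list("ABCD"))
        cl = lb.cluster_probes(b, k=2)
        assert cl["A"] == cl["B"] and cl["C"] == cl["D"] and cl["A"] != cl["C"]

    def test_k_equals_probes_gives_singletons(self, rng):
        b = lb.binarize(random_score_matrix(rng, 40, 5))
        detected = [p for p in b.probe_names if b.df[p].sum() > 0]
        cl = lb.cluster_probes(b, k=len(detected))
        assert len(set(cl)) == len(detected)

    def test_planted_archetypes_recovered(self, rng):
        """Four occurrence archetypes, 3 probes each: perfect recovery."""
        n = 120
        ph = np.linspace(3.8, 9.1, n)
        archetypes = [
            (ph < 5.2).astype(int),
            ((ph >= 5.2) & (ph < 6.8)).astype(int),
            ((ph >= 6.8) & (ph < 8.0)).astype(int),
            (ph >= 8.0).astype(int),
        ]
        cols, names, truth = [], [], {}
        for a, arch in enumerate(archetypes):
            for r in range(3):
                noisy = arch.copy()
                flips = rng.choice(n, 3, replace=False)
                noisy[flips] = 1 - noisy[flips]
                name = f"G{a}{r}"
                cols.append(noisy)
                names.append(name)
                truth[name] = a
        b = _bm(np.column_stack(cols), probes=names)
        cl = lb.cluster_probes(b, k=4)
        # partition must match truth exactly (up to label renaming)
        mapping = {}
        for name, lab in cl.items():
            mapping.setdefault(lab, set()).add(truth[name])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 4

    def test_invalid_k_errors(self, rng):
        b = lb.binarize(random_score_matrix(rng, 10, 3))
        with pytest.raises(ValueError):
            lb.cluster_probes(b, k=99)
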