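"""PC-DA model: PCA contracts, canonical direction, Mahalanobis membership,
the F1 back-projection identity and biomarker extraction."""

import numpy as np
import pandas as pd
import pytest

import fishspec as fs
from fishspec.pcda import F1Vector, PCDiscriminantAnalysis, fit_pca
from fishspec.spectra import SpectraSet
from tests.conftest import d0d7_set, make_set

GRID = 900.0 + 2.0 * np.arange(441)


def labelled_set(X, days, grid=GRID):
    meta = pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(len(X))],
        "fish_id": "f1", "day": days, "fibre_id": "fb",
    })
    return SpectraSet(grid, X, meta)


def gaussian_groups(n_per=40, sep=6.0, seed=0, p=441):
    """Two spherical groups separated along a fixed spectral direction."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = rng.normal(0, 1.0, size=(2 * n_per, p))
    X[:n_per] += sep / 2 * direction
    X[n_per:] -= sep / 2 * direction
    return labelled_set(X, [0] * n_per + [7] * n_per), direction


class TestPCA:
    def test_rank_one_direction_recovered(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=441)
        direction /= np.linalg.norm(direction)
        X = 5.0 + np.outer(rng.normal(size=60), direction)
        model = fit_pca(labelled_set(X, [0] * 60), k=1)
        cos = abs(model.loadings[0] @ direction)
        assert cos > 1 - 1e-8

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 30))
        sset = labelled_set(X, [0] * 20, grid=900.0 + 2.0 * np.arange(30))
        model = fit_pca(sset, k=19)
        T = model.transform(X)
        recon = model.mean_spectrum + T @ model.loadings
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal_and_variance_sorted(self, paper_pre):
        model = fit_pca(paper_pre, k=5)
        np.testing.assert_allclose(model.loadings @ model.loadings.T, np.eye(5),
                                   atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        total = np.var(paper_pre.intensities, axis=0, ddof=1).sum()
        assert model.explained_variance.sum() / total > 0.5

    def test_k_out_of_range(self):
        sset = make_set(n_spectra=4)
        with pytest.raises(ValueError):
            fit_pca(sset, k=10)


class TestCanonicalDirection:
    def test_spherical_groups_axis_parallel_to_mean_difference(self):
        """With (near-)identity within-group covariance the canonical axis is
        the group mean difference, in PC space and back-projected."""
        sset, direction = gaussian_groups(n_per=150, sep=10.0)
        res = fs.fit_pcda(sset, (0, 7), k=10, ridge=0.0)
        dm = res.group_means_pc[0] - res.group_means_pc[1]
        w = res.canonical_weights[0]
        cos_pc = abs(w @ dm) / np.linalg.norm(w) / np.linalg.norm(dm)
        assert cos_pc > 0.99
        # back-projection stays aligned with the empirical spectral difference
        f1 = res.f1_vector().scores
        d_emp = sset.intensities[:150].mean(0) - sset.intensities[150:].mean(0)
        cos_sp = abs(f1 @ d_emp) / np.linalg.norm(f1) / np.linalg.norm(d_emp)
        assert cos_sp > 0.99

    def test_identical_means_null(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 441))
        sset = labelled_set(X, [0] * 40 + [7] * 40)
        res = fs.fit_pcda(sset, (0, 7), k=5)
        probs = res.membership()
        # membership hovers around 0.5/0.5: no group exceeds 0.95 on average
        assert abs(probs["D0"].mean() - 0.5) < 0.15

    def test_first_group_mean_score_positive(self):
        sset, _ = gaussian_groups(seed=4)
        res = fs.fit_pcda(sset, (0, 7))
        cs = res.canonical_scores()[:, 0]
        assert cs[sset.labels == 0].mean() > 0 > cs[sset.labels == 7].mean()

    def test_d0_d7_resubstitution_accuracy(self):
        sset, _ = d0d7_set(seed=0)
        counts = sset.meta.groupby("day").size()
        assert counts[0] == 111 and counts[7] == 114
        res = fs.fit_pcda(fs.preprocess(sset), (0, 7))
        assert res.resubstitution_accuracy() > 0.95


class TestMembership:
    def test_observation_at_group_mean(self):
        sset, _ = gaussian_groups(sep=10.0, seed=5)
        res = fs.fit_pcda(sset, (0, 7), k=5)
        mean0 = res.pca.mean_spectrum + res.group_means_pc[0] @ res.pca.loadings
        probe = labelled_set(mean0[None, :], [0])
        assert res.membership(probe)["D0"].iloc[0] > 0.99

    def test_equidistant_point_is_half_half(self):
        sset, _ = gaussian_groups(sep=4.0, seed=6)
        res = fs.fit_pcda(sset, (0, 7), k=5)
        mid = res.pca.mean_spectrum + \
            (0.5 * (res.group_means_pc[0] + res.group_means_pc[1])) @ res.pca.loadings
        probs = res.membership(labelled_set(mid[None, :], [0]))
        assert probs["D0"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_probabilities_sum_to_one(self, paper_pre):
        res = fs.fit_pcda(paper_pre, (0, 7, 15))
        p = res.membership()[["D0", "D7", "D15"]].to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_bruteforce_nearest_mahalanobis(self):
        sset, _ = gaussian_groups(n_per=25, sep=2.0, seed=7)
        res = fs.fit_pcda(sset, (0, 7), k=5)
        pred = res.membership()["predicted"].to_numpy()
        # independent brute force in PC space
        T = res.pca.transform(sset.intensities)
        Winv = np.linalg.inv(res.pooled_cov_pc)
        brute = []
        for t in T:
            d2 = [(t - m) @ Winv @ (t - m) for m in res.group_means_pc]
            brute.append(res.groups[int(np.argmin(d2))])
        assert list(pred) == brute


class TestF1:
    def test_k1_is_scaled_loading(self):
        sset, _ = gaussian_groups(seed=8)
        res = fs.fit_pcda(sset, (0, 7), k=1)
        f1 = res.f1_vector()
        np.testing.assert_allclose(
            f1.scores, res.canonical_weights[0, 0] * res.pca.loadings[0], atol=1e-12)

    def test_backprojection_identity(self):
        """canonical_score(x) == F1 . (x - mean) for every training spectrum."""
        for seed in range(3):
            sset, _ = d0d7_set(seed)
            pre = fs.preprocess(sset)
            res = fs.fit_pcda(pre, (0, 7), k=8)
            cs = res.canonical_scores()[:, 0]
            alt = (pre.intensities - res.pca.mean_spectrum) @ res.f1_vector().scores
            np.testing.assert_allclose(cs, alt, atol=1e-8)

    def test_single_differential_band_localised(self):
        """Groups differing in one band's amplitude put the top |F1| extremum
        at that band's center."""
        rng = np.random.default_rng(9)
        base = 0.5 * np.exp(-((GRID - 1400) / 200.0) ** 2)
        band = np.exp(-4 * np.log(2) * ((GRID - 1176.0) / 10.0) ** 2)
        X = []
        for amp in [0.3] * 40 + [0.15] * 40:
            X.append(base + amp * band + rng.normal(0, 0.002, GRID.size))
        sset = labelled_set(np.array(X), [0] * 40 + [7] * 40)
        res = fs.fit_pcda(sset, (0, 7))
        top = res.f1_vector().extract_biomarkers().iloc[0]
        assert abs(top.wavenumber - 1176.0) <= 2.0
        assert top.associated_group == "D0"

    def test_invariant_to_pc_permutation(self):
        sset, _ = gaussian_groups(seed=10)
        res = fs.fit_pcda(sset, (0, 7), k=6)
        perm = np.array([3, 0, 5, 1, 4, 2])
        pca2 = fs.PCAModel(res.pca.grid, res.pca.mean_spectrum,
                           res.pca.loadings[perm], res.pca.explained_variance[perm])
        model2 = PCDiscriminantAnalysis(sset, (0, 7))
        # refit discriminant on permuted scores by hand
        T = pca2.transform(sset.intensities)
        y = sset.labels
        m = np.vstack([T[y == g].mean(0) for g in (0, 7)])
        W = sum((T[y == g] - T[y == g].mean(0)).T @ (T[y == g] - T[y == g].mean(0))
                for g in (0, 7)) / (len(sset) - 2)
        w2 = np.linalg.solve(W, m[0] - m[1])
        f1_perm = w2 @ pca2.loadings
        f1 = res.f1_vector().scores
        cos = (f1 @ f1_perm) / np.linalg.norm(f1) / np.linalg.norm(f1_perm)
        assert abs(cos) > 1 - 1e-8

    def test_flat_f1_yields_empty_biomarkers(self):
        f1 = F1Vector(GRID, np.zeros(GRID.size))
        assert len(f1.extract_biomarkers()) == 0

    def test_paper_effect_signs(self, paper_pre):
        """Nucleic-acid bands positive (day 0), antiparallel beta-sheet bands
        negative (day 7) in the D0-vs-D7 contribution vector."""
        res = fs.fit_pcda(paper_pre, (0, 7))
        f1 = res.f1_vector()
        def at(wn):
            return f1.scores[np.argmin(np.abs(f1.wavenumbers - wn))]
        assert at(1176) > 0 and at(1247) > 0
        assert at(1490) < 0 and at(1670) < 0


class TestPersistence:
    def test_json_roundtrip_rescoring(self, tmp_path):
        sset, _ = gaussian_groups(seed=11)
        res = fs.fit_pcda(sset, (0, 7), k=4)
        p = tmp_path / "model.json"
        res.to_json(p)
        back = fs.PCDAResults.from_json(p)
        np.testing.assert_allclose(back.canonical_scores(sset),
                                   res.canonical_scores(sset), atol=1e-10)
        np.testing.assert_allclose(back.f1_vector().scores,
                                   res.f1_vector().scores, atol=1e-12)
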