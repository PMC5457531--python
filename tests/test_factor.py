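"""Principal axis factoring, varimax rotation, factor scores, standardization."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from cubescreen import (
    PrincipalAxisFactoring,
    REFERENCE_LOADINGS,
    SENSOR_VARIABLES,
    Standardizer,
    generate_cohort,
    standardize,
    tucker_congruence,
    varimax_rotate,
)
from cubescreen.errors import DegenerateInputError


def best_match(rotated: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Reorder/sign-flip rotated columns to best match target columns."""
    m = target.shape[1]
    out = np.zeros_like(target)
    used = set()
    for j in range(m):
        best, best_c = None, -1.0
        for i in range(m):
            if i in used:
                continue
            c = abs(tucker_congruence(rotated[:, i], target[:, j]))
            if c > best_c:
                best, best_c = i, c
        used.add(best)
        col = rotated[:, best]
        if tucker_congruence(col, target[:, j]) < 0:
            col = -col
        out[:, j] = col
    return out


class TestStandardize:
    def test_basic_column(self):
        z, _ = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_z_scores(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        z1, _ = standardize(x)
        z2, _ = standardize(z1)
        assert np.allclose(z1, z2, atol=1e-12)

    def test_random_matrix_moments(self, rng):
        z, _ = standardize(pd.DataFrame(rng.normal(2.0, 5.0, (100, 5))))
        assert np.all(np.abs(z.mean()) < 1e-10)
        assert np.all(np.abs(z.std(ddof=1) - 1.0) < 1e-10)

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(DegenerateInputError, match="flat"):
            standardize(df)

    def test_transform_reuses_fitted_parameters(self):
        train = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
        s = Standardizer().fit(train)
        out = s.transform(pd.DataFrame({"a": [2.0, 6.0]}))
        assert np.allclose(out["a"], [0.0, 2.0])


class TestPrincipalAxisFactoring:
    def test_rank_one_structure_recovered(self):
        lam = np.array([0.9, 0.8, 0.7])
        r = np.outer(lam, lam)
        np.fill_diagonal(r, 1.0)
        res = PrincipalAxisFactoring(corr=r, n_factors=1).fit(rotation=None)
        got = res.loadings.to_numpy().ravel()
        if got.sum() < 0:
            got = -got
        assert np.allclose(got, lam, atol=1e-3)

    def test_identity_correlation_gives_zero_communalities(self):
        res = PrincipalAxisFactoring(corr=np.eye(6), n_factors=2).fit()
        assert np.all(res.communalities < 1e-8)

    def test_reproduced_correlations_match_input(self):
        lam = np.array([[0.8, 0.1], [0.7, 0.2], [0.1, 0.9], [0.2, 0.6]])
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        res = PrincipalAxisFactoring(corr=r, n_factors=2).fit(rotation=None)
        reproduced = res.loadings.to_numpy() @ res.loadings.to_numpy().T
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs(reproduced[off] - r[off])) <= 0.01

    def test_unrotated_variance_explained_non_increasing(self, rng):
        cohort = generate_cohort(400, seed=2)
        res = PrincipalAxisFactoring(data=cohort.data[SENSOR_VARIABLES], n_factors=3).fit()
        unrot_var = (res.unrotated_loadings.to_numpy() ** 2).sum(axis=0)
        assert np.all(np.diff(unrot_var) <= 1e-10)


class TestVarimax:
    def simple_structure(self):
        lam = np.zeros((9, 3))
        for i in range(9):
            lam[i, i % 3] = [0.85, 0.7, 0.6][i // 3]
        return lam

    def test_simple_structure_is_fixed_point(self):
        lam = self.simple_structure()
        rotated, _ = varimax_rotate(lam)
        assert np.allclose(best_match(rotated, lam), lam, atol=1e-8)

    def test_round_trip_recovery_through_random_rotation(self):
        lam = self.simple_structure()
        q = ortho_group.rvs(3, random_state=7)
        rotated, _ = varimax_rotate(lam @ q)
        assert np.max(np.abs(best_match(rotated, lam) - lam)) < 1e-6

    def test_communalities_invariant_under_rotation(self, rng):
        lam = rng.uniform(-0.8, 0.8, (10, 3)) * 0.6
        rotated, rot = varimax_rotate(lam)
        assert np.allclose((rotated**2).sum(axis=1), (lam**2).sum(axis=1), atol=1e-10)
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-10)

    def test_single_factor_is_identity_rotation(self):
        lam = np.array([[0.9], [0.5], [0.3]])
        rotated, rot = varimax_rotate(lam)
        assert np.array_equal(rotated, lam)
        assert np.array_equal(rot, np.eye(1))


class TestFactorScores:
    def fit_reference_model(self, n=800, seed=13):
        cohort = generate_cohort(n, seed=seed)
        model = PrincipalAxisFactoring(data=cohort.data[SENSOR_VARIABLES], n_factors=3)
        return cohort, model.fit().name_factors()

    def test_child_at_cohort_mean_scores_zero(self):
        cohort, res = self.fit_reference_model()
        mean_child = cohort.data[SENSOR_VARIABLES].mean().to_frame().T
        scores = res.score(mean_child)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_cohort_score_means_are_zero_and_sds_one(self):
        cohort, res = self.fit_reference_model()
        scores = res.score(cohort.data[SENSOR_VARIABLES])
        assert np.all(np.abs(scores.mean()) < 1e-8)
        assert np.allclose(scores.std(ddof=1), 1.0, atol=1e-10)

    def test_scores_recover_latent_factors_when_uniqueness_vanishes(self):
        # near-zero uniqueness: scores are essentially the generating factors
        lam = REFERENCE_LOADINGS.copy()
        comm = (lam**2).sum(axis=1)
        lam = lam.div(np.sqrt(comm), axis=0) * 0.9995
        cohort = generate_cohort(600, loadings=lam, seed=3)
        res = (
            PrincipalAxisFactoring(data=cohort.data[SENSOR_VARIABLES], n_factors=3)
            .fit()
            .name_factors()
        )
        scores = res.score(cohort.data[SENSOR_VARIABLES])
        for name in ("trembling", "speed", "accuracy"):
            assert abs(np.corrcoef(scores[name], cohort.factors[name])[0, 1]) > 0.99

    def test_factor_naming_matches_reference_pattern(self):
        _, res = self.fit_reference_model(n=1500, seed=29)
        assert list(res.loadings.columns) == ["trembling", "speed", "accuracy"]
        # trembling is marked by the mean-time variable, accuracy by lowest maxima
        assert res.loadings.loc["Mean time of movement", "trembling"] > 0.8
        assert res.loadings.loc["Lowest maximum speed", "accuracy"] > 0.5
        assert res.loadings.loc["Mean of maximum speed", "speed"] > 0.8
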