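"""Distance-decay table construction and permutation regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from commdecay.core_io import DistanceMatrix
from commdecay.decay import (
    build_decay_table,
    fit_decay_regression,
    permutation_regression_test,
)
from commdecay.descriptors import component_profiles
from commdecay.distances import (
    geographic_distance_matrix,
    jaccard_similarity,
    p_distance_matrix,
)
from commdecay.exceptions import ConfigError, ConsistencyError, SingularDesignError
from commdecay.synthetic_data import SimulationConfig, generate_dataset


def synthetic_pieces(seed=3, **kw):
    ds = generate_dataset(SimulationConfig(seed=seed, **kw))
    profiles = component_profiles(ds.infections)
    dphylo = p_distance_matrix(ds.alignment)
    dgeo = geographic_distance_matrix(ds.sites, ds.site_of_species)
    return ds, profiles, dphylo, dgeo


def make_pair_table(d_phylo, d_geo, y, species=None):
    n_sp = int((1 + np.sqrt(1 + 8 * len(y))) / 2)
    species = species or [f"S{i}" for i in range(n_sp)]
    pairs = list(itertools.combinations(species, 2))
    return pd.DataFrame(
        {
            "species_a": [a for a, _ in pairs],
            "species_b": [b for _, b in pairs],
            "similarity": np.exp(y),
            "log_similarity": y,
            "d_phylo": d_phylo,
            "d_geo": d_geo,
        }
    )


class TestBuildDecayTable:
    def test_eight_species_give_28_rows(self):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        table = build_decay_table(profiles, "jaccard_presence", dphylo, dgeo, epsilon=0.01)
        assert len(table) == 28
        assert (table["similarity"] >= 0).all() and (table["similarity"] <= 1).all()

    def test_rows_match_elementwise_calls(self):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        table = build_decay_table(profiles, "jaccard_presence", dphylo, dgeo, epsilon=0.01)
        for row in table.itertuples():
            expected = jaccard_similarity(
                profiles[row.species_a].presence.to_numpy(),
                profiles[row.species_b].presence.to_numpy(),
            )
            assert row.similarity == pytest.approx(expected)
            assert row.d_phylo == pytest.approx(dphylo.loc(row.species_a, row.species_b))
            assert row.d_geo == pytest.approx(dgeo.loc(row.species_a, row.species_b))
            assert row.log_similarity == pytest.approx(np.log(expected + 0.01))

    def test_species_set_mismatch_is_consistency_error(self):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        bad = dphylo.submatrix(dphylo.labels[:-1])
        with pytest.raises(ConsistencyError):
            build_decay_table(profiles, "jaccard_presence", bad, dgeo)

    def test_unknown_metric_is_config_error(self):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        with pytest.raises(ConfigError):
            build_decay_table(profiles, "sorensen", dphylo, dgeo)


class TestFitDecayRegression:
    def test_noiseless_plane_recovered_exactly(self):
        rng = np.random.default_rng(0)
        d_ph = rng.uniform(0, 0.2, 28)
        d_geo = rng.uniform(0, 500, 28)
        y = 1.0 - 2.0 * d_ph + 0.0 * d_geo
        fit = fit_decay_regression(make_pair_table(d_ph, d_geo, y))
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope_phylo == pytest.approx(-2.0)
        assert fit.slope_geo == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_geographic_distance_is_singular(self):
        rng = np.random.default_rng(1)
        d_ph = rng.uniform(0, 0.2, 28)
        d_geo = np.zeros(28)  # every species at one site
        y = 1.0 - d_ph
        with pytest.raises(SingularDesignError):
            fit_decay_regression(make_pair_table(d_ph, d_geo, y))

    def test_slope_recovery_within_three_se(self):
        """Known slopes + Gaussian noise: 3-SE coverage >= 95% over 500 fits."""
        rng = np.random.default_rng(2)
        true_ph, true_geo = -3.0, -0.002
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            d_ph = rng.uniform(0, 0.2, 28)
            d_geo = rng.uniform(0, 600, 28)
            y = 0.5 + true_ph * d_ph + true_geo * d_geo + rng.normal(0, 0.1, 28)
            fit = fit_decay_regression(make_pair_table(d_ph, d_geo, y))
            # recompute SEs via the classical formula
            x = np.column_stack([np.ones(28), d_ph, d_geo])
            resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
            sigma2 = resid @ resid / (28 - 3)
            cov = sigma2 * np.linalg.inv(x.T @ x)
            ok_ph = abs(fit.slope_phylo - true_ph) < 3 * np.sqrt(cov[1, 1])
            ok_geo = abs(fit.slope_geo - true_geo) < 3 * np.sqrt(cov[2, 2])
            hits += ok_ph and ok_geo
        assert hits / n_rep >= 0.95

    def test_constant_shift_changes_only_intercept(self):
        rng = np.random.default_rng(3)
        d_ph = rng.uniform(0, 0.2, 28)
        d_geo = rng.uniform(0, 600, 28)
        y = 0.5 - 2 * d_ph - 0.001 * d_geo + rng.normal(0, 0.1, 28)
        a = fit_decay_regression(make_pair_table(d_ph, d_geo, y))
        b = fit_decay_regression(make_pair_table(d_ph, d_geo, y + 5.0))
        assert b.intercept == pytest.approx(a.intercept + 5.0)
        assert b.slope_phylo == pytest.approx(a.slope_phylo)
        assert b.slope_geo == pytest.approx(a.slope_geo)
        assert b.r2 == pytest.approx(a.r2)


class TestPermutationRegression:
    def test_same_seed_identical_p_values(self):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        table = build_decay_table(profiles, "jaccard_presence", dphylo, dgeo, epsilon=0.01)
        a = permutation_regression_test(table, n_perm=99, seed=42)
        b = permutation_regression_test(table, n_perm=99, seed=42)
        assert a.p_perm_phylo == b.p_perm_phylo
        assert a.p_perm_geo == b.p_perm_geo

    @pytest.mark.parametrize("scheme", ["matrix_permute", "row_permute"])
    def test_p_values_respect_floor(self, scheme):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        table = build_decay_table(profiles, "jaccard_presence", dphylo, dgeo, epsilon=0.01)
        fit = permutation_regression_test(table, n_perm=99, seed=0, scheme=scheme)
        assert fit.p_perm_phylo >= 1 / 100
        assert fit.p_perm_geo >= 1 / 100
        assert fit.scheme == scheme

    def test_unknown_scheme_is_config_error(self):
        _, profiles, dphylo, dgeo = synthetic_pieces()
        table = build_decay_table(profiles, "jaccard_presence", dphylo, dgeo, epsilon=0.01)
        with pytest.raises(ConfigError):
            permutation_regression_test(table, n_perm=9, seed=0, scheme="bootstrap")

    def test_null_slope_gives_uniformish_p(self):
        """Exchangeable response: rejection at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(4)
        rej_ph = rej_geo = 0
        n_rep = 200
        for _ in range(n_rep):
            d_ph = rng.uniform(0, 0.2, 28)
            d_geo = rng.uniform(0, 600, 28)
            y = rng.normal(0, 1, 28)
            table = make_pair_table(d_ph, d_geo, y)
            fit = permutation_regression_test(
                table, n_perm=99, seed=int(rng.integers(2**31)), scheme="row_permute"
            )
            rej_ph += fit.p_perm_phylo <= 0.05
            rej_geo += fit.p_perm_geo <= 0.05
        assert rej_ph / n_rep <= 0.08
        assert rej_geo / n_rep <= 0.08

    def test_schemes_agree_under_full_exchangeability(self):
        """With iid responses both schemes give comparable mean p."""
        rng = np.random.default_rng(5)
        means = {"matrix_permute": [], "row_permute": []}
        for _ in range(60):
            d_ph = rng.uniform(0, 0.2, 28)
            d_geo = rng.uniform(0, 600, 28)
            y = rng.normal(0, 1, 28)
            table = make_pair_table(d_ph, d_geo, y)
            for scheme in means:
                fit = permutation_regression_test(
                    table, n_perm=99, seed=int(rng.integers(2**31)), scheme=scheme
                )
                means[scheme].append(fit.p_perm_phylo)
        assert abs(np.mean(means["matrix_permute"]) - np.mean(means["row_permute"])) < 0.12

    def test_strong_decay_detected(self):
        """Injected phylogeny-only decay: negative slope, significant phylo."""
        hits = 0
        n_rep = 20
        seeds = np.random.SeedSequence(99).generate_state(n_rep)
        for s in seeds:
            _, profiles, dphylo, dgeo = synthetic_pieces(
                seed=int(s) % 2**31, n_parasites=100, lambda_phylo=12.0, base_occurrence=0.7
            )
            table = build_decay_table(profiles, "jaccard_presence", dphylo, dgeo, epsilon=0.05)
            fit = permutation_regression_test(table, n_perm=199, seed=int(s) % 2**31)
            hits += fit.slope_phylo < 0 and fit.p_perm_phylo <= 0.01
        assert hits / n_rep >= 0.8
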