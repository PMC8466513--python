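"""REML animal model: design construction, degenerate equivalences,
independent-implementation cross-checks and simulation-based recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import SCENARIO_FACTORS, recovery_config
from pigeonassoc.errors import InputError
from pigeonassoc.mixed_model import (
    ModelSpec,
    build_design,
    contrast,
    fit_reml,
    genotype_contrasts,
    genotype_lsmeans,
    summarize_by_genotype,
)
from pigeonassoc.pedigree_kinship import RelationshipMatrix
from pigeonassoc.synthetic_data import simulate


def _records(
    rng,
    n_birds=20,
    n_records=5,
    mu=30.0,
    s2i=0.0,
    s2e=100.0,
    genotypes=("AG/AG", "AG/TT"),
):
    """Balanced repeated records with only a bird random intercept."""
    rows = []
    bird_effects = rng.normal(0, np.sqrt(s2i), n_birds)
    for b in range(n_birds):
        geno = genotypes[b % len(genotypes)]
        for r in range(n_records):
            rows.append(
                {
                    "pigeon_id": f"b{b:02d}",
                    "genotype": geno,
                    "ap": mu + bird_effects[b] + rng.normal(0, np.sqrt(s2e)),
                }
            )
    return pd.DataFrame(rows)


GENO_ONLY = ModelSpec(factors={"genotype": ("AG/AG", "AG/TT", "TT/TT")})


class TestBuildDesign:
    def test_dimension_bookkeeping_two_birds_two_races(self):
        rng = np.random.default_rng(0)
        records = _records(rng, n_birds=2, n_records=2)
        design = build_design(records, GENO_ONLY)
        assert design.X.shape[1] <= 3
        assert design.Z.shape == (4, 2)
        assert design.y.shape == (4,)

    def test_undeclared_level_is_an_error(self):
        rng = np.random.default_rng(0)
        records = _records(rng, genotypes=("AG/AG", "GG/GG"))
        with pytest.raises(InputError, match="GG/GG"):
            build_design(records, GENO_ONLY)

    def test_single_level_factor_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        records = _records(rng, genotypes=("AG/AG",))
        with pytest.warns(UserWarning, match="genotype"):
            design = build_design(records, GENO_ONLY)
        assert design.xnames == ["intercept"]
        assert "genotype" in design.dropped_factors

    def test_missing_pigeon_in_kinship_is_an_error(self):
        rng = np.random.default_rng(0)
        records = _records(rng, n_birds=3)
        A = RelationshipMatrix(["b00"], np.eye(1))
        with pytest.raises(InputError, match="not in relationship matrix"):
            build_design(records, GENO_ONLY, A=A)


class TestDegenerateEquivalences:
    def test_zero_random_variances_reduce_to_ols(self):
        """With both bird variances pinned at 0, GLS collapses to ordinary
        least squares (normal-equations oracle)."""
        rng = np.random.default_rng(3)
        records = _records(rng, n_birds=12, n_records=3, s2i=40.0)
        design = build_design(records, GENO_ONLY)
        res = fit_reml(design, fix={"individual": 0.0})
        X, y = design.X, design.y
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.fixed["estimate"].to_numpy() == pytest.approx(beta_ols, abs=1e-6)
        rss = float(y @ y - y @ X @ beta_ols)
        assert res.varcomp.sigma2_e == pytest.approx(rss / (len(y) - X.shape[1]), rel=1e-9)

    def test_balanced_layout_matches_closed_form_anova_reml(self):
        """20 unrelated birds x 5 records, intercept-only: REML equals the
        ANOVA estimators (within MS; (between MS - within MS)/m)."""
        rng = np.random.default_rng(11)
        records = _records(rng, n_birds=20, n_records=5, s2i=60.0, s2e=100.0,
                           genotypes=("AG/AG",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            design = build_design(records, GENO_ONLY)
        res = fit_reml(design, tol=1e-10)

        wide = records.assign(obs=records.groupby("pigeon_id").cumcount())
        mat = wide.pivot(index="pigeon_id", columns="obs", values="ap").to_numpy()
        q, m = mat.shape
        bird_means = mat.mean(axis=1)
        msw = ((mat - bird_means[:, None]) ** 2).sum() / (q * (m - 1))
        msb = m * ((bird_means - bird_means.mean()) ** 2).sum() / (q - 1)
        assert res.varcomp.sigma2_e == pytest.approx(msw, abs=1e-4, rel=1e-4)
        assert res.varcomp.sigma2_i == pytest.approx((msb - msw) / m, abs=1e-4, rel=1e-4)

    def test_matches_statsmodels_random_intercept_model(self):
        """Independent generic implementation: statsmodels MixedLM with a
        random intercept per bird, REML, on 10 random unbalanced datasets."""
        statsmodels = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            records = _records(
                rng,
                n_birds=int(rng.integers(15, 30)),
                n_records=int(rng.integers(3, 6)),
                s2i=50.0,
                s2e=80.0,
            )
            records = (
                records.sample(frac=0.9, random_state=seed)
                .sort_values("pigeon_id")  # MixedLM wants contiguous groups
                .reset_index(drop=True)
            )
            design = build_design(records, GENO_ONLY)
            mine = fit_reml(design, tol=1e-10)

            md = statsmodels.MixedLM(
                design.y, design.X, groups=records["pigeon_id"].to_numpy()
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = md.fit(reml=True)
            assert mine.fixed["estimate"].to_numpy() == pytest.approx(
                ref.fe_params, abs=1e-4
            )
            assert mine.varcomp.sigma2_i == pytest.approx(
                float(np.asarray(ref.cov_re)[0, 0]), abs=1e-3, rel=1e-3
            )
            assert mine.varcomp.sigma2_e == pytest.approx(
                float(ref.scale), abs=1e-3, rel=1e-3
            )


class TestFitBehaviour:
    def test_converged_fit_reports_small_gradient(self):
        rng = np.random.default_rng(5)
        records = _records(rng, n_birds=25, n_records=4, s2i=50.0)
        res = fit_reml(build_design(records, GENO_ONLY), tol=1e-8)
        assert res.converged
        assert res.grad_norm < 1e-3

    def test_record_permutation_leaves_estimates_unchanged(self):
        sim = simulate(recovery_config(0))
        spec = ModelSpec(response="latent", factors=SCENARIO_FACTORS)
        base = fit_reml(build_design(sim.truth_records, spec, A=sim.relationship), tol=1e-8)
        shuffled = sim.truth_records.sample(frac=1.0, random_state=9).reset_index(drop=True)
        perm = fit_reml(build_design(shuffled, spec, A=sim.relationship), tol=1e-8)
        assert perm.varcomp.sigma2_a == pytest.approx(base.varcomp.sigma2_a, rel=1e-4)
        assert perm.varcomp.sigma2_i == pytest.approx(base.varcomp.sigma2_i, rel=1e-4)
        for name in base.fixed.index:
            assert perm.fixed.loc[name, "estimate"] == pytest.approx(
                base.fixed.loc[name, "estimate"], rel=1e-5, abs=1e-8
            )

    def test_singular_design_is_an_error(self):
        rng = np.random.default_rng(1)
        records = _records(rng, n_birds=10, n_records=2)
        # duplicate the genotype factor under another name -> aliased columns
        records["sex"] = np.where(records["genotype"] == "AG/AG", "male", "female")
        spec = ModelSpec(
            factors={
                "genotype": ("AG/AG", "AG/TT"),
                "sex": ("male", "female"),
            }
        )
        with pytest.raises(InputError, match="singular"):
            fit_reml(build_design(records, spec))

    def test_single_seed_recovery_within_information_bound(self):
        """One recovery-scenario fit lands within ~2 asymptotic SDs of the
        truth (SDs ~41, 26, 13 for sigma2_a, sigma2_i, sigma2_e)."""
        sim = simulate(recovery_config(1))
        spec = ModelSpec(response="latent", factors=SCENARIO_FACTORS)
        res = fit_reml(build_design(sim.truth_records, spec, A=sim.relationship))
        assert res.converged
        assert abs(res.varcomp.sigma2_a - 100.0) < 85.0
        assert abs(res.varcomp.sigma2_i - 50.0) < 55.0
        assert abs(res.varcomp.sigma2_e - 400.0) < 30.0


@pytest.fixture(scope="module")
def fitted():
    sim = simulate(recovery_config(2))
    spec = ModelSpec(response="latent", factors=SCENARIO_FACTORS)
    res = fit_reml(build_design(sim.truth_records, spec, A=sim.relationship))
    return sim, res


class TestContrastsAndMeans:
    def test_self_contrast_is_null(self, fitted):
        _, res = fitted
        c = contrast(res, "AG/AG", "AG/AG")
        assert c["estimate"] == 0.0 and c["p"] == 1.0

    def test_all_pairs_reported_with_positive_ses(self, fitted):
        _, res = fitted
        table = genotype_contrasts(res)
        levels = res.design.factor_levels["genotype"]
        assert len(table) == len(levels) * (len(levels) - 1) // 2
        assert (table["se"] > 0).all()

    def test_lsmeans_expose_injected_ordering(self, fitted):
        _, res = fitted
        lsm = genotype_lsmeans(res)
        # injected shifts: AG/AG 0, AG/TT +7 -> heterozygote mean higher
        assert lsm.loc["AG/TT", "lsmean"] > lsm.loc["AG/AG", "lsmean"]

    def test_genotype_absent_from_model_is_an_error(self):
        rng = np.random.default_rng(0)
        records = _records(rng, genotypes=("AG/AG",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fit_reml(build_design(records, GENO_ONLY))
        with pytest.raises(InputError):
            genotype_contrasts(res)

    def test_alpha_flags_significance(self, fitted):
        _, res = fitted
        strict = genotype_contrasts(res, alpha=1e-12)
        assert not strict["significant"].any()


class TestSummarizeByGenotype:
    def test_two_record_group_mean_and_se(self):
        records = pd.DataFrame(
            {
                "pigeon_id": ["x", "x"],
                "genotype": ["AG/AG", "AG/AG"],
                "ap": [40.0, 60.0],
                "category": ["short", "short"],
            }
        )
        table = summarize_by_genotype(records)
        row = table.loc[("AG/AG", "all")]
        assert row["mean_ap"] == pytest.approx(50.0)
        assert row["se"] == pytest.approx(10.0)
        assert row["rr"] == 2

    def test_empty_group_is_absent_not_zero(self):
        records = pd.DataFrame(
            {
                "pigeon_id": ["x"],
                "genotype": ["AG/AG"],
                "ap": [40.0],
                "category": ["short"],
            }
        )
        table = summarize_by_genotype(records)
        assert ("AG/AG", "long") not in table.index
        assert ("TT/TT", "all") not in table.index

    def test_ungenotyped_records_excluded_with_warning(self):
        records = pd.DataFrame(
            {
                "pigeon_id": ["x", "y"],
                "ap": [40.0, 60.0],
                "category": ["short", "short"],
            }
        )
        genotypes = pd.DataFrame({"pigeon_id": ["x"], "genotype": ["AG/TT"]})
        with pytest.warns(UserWarning, match="1 record"):
            table = summarize_by_genotype(records, genotypes)
        assert table.loc[("AG/TT", "all"), "rr"] == 1

    def test_group_means_track_simulated_truth(self):
        sim = simulate(recovery_config(3))
        table = summarize_by_genotype(sim.races, sim.genotypes)
        # heterozygote advantage (+7 latent AP) survives the rank->AP transform
        assert (
            table.loc[("AG/TT", "all"), "mean_ap"]
            > table.loc[("AG/AG", "all"), "mean_ap"] - 2 * table.loc[("AG/TT", "all"), "se"]
        )
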