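import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import epiblup as eb
from epiblup.gibbs import effective_sample_size

from conftest import small_simulation


def dense_mme_reference(design, grms, variances, include_pe=True):
    """Independent oracle: assemble and invert Henderson's equations with
    explicit G inverses at the individual level."""
    spec = design.spec
    terms = list(spec.terms)
    idx = design.indiv_index
    N, n = design.n_records, design.n_individuals
    C = design.X if design.f_record is None else np.column_stack(
        [design.X, design.f_record])
    Z = np.zeros((N, n))
    Z[np.arange(N), idx] = 1.0
    var_e = variances["e"]
    blocks = [C] + [Z for _ in terms] + ([Z] if include_pe else [])
    Q = np.hstack(blocks)
    lhs = Q.T @ Q
    p = C.shape[1]
    pos = p
    for t in terms:
        Ginv = np.linalg.inv(grms[t].values)
        lhs[pos:pos + n, pos:pos + n] += Ginv * (var_e / variances[t])
        pos += n
    if include_pe:
        lhs[pos:pos + n, pos:pos + n] += np.eye(n) * (var_e / variances["pe"])
    theta = np.linalg.solve(lhs, Q.T @ design.y)
    out = {"beta": theta[:p]}
    pos = p
    for t in terms:
        out[t] = theta[pos:pos + n]
        pos += n
    if include_pe:
        out["pe"] = theta[pos:pos + n]
    return out


def fitted_design(seed=11, n=40, m=120, terms=("A", "D"), cov=False, records=(2, 3)):
    _, geno, _, truth, rec = small_simulation(seed, n=n, m=m, records=records)
    freqs = eb.allele_frequencies(geno)
    f = eb.genomic_inbreeding(geno)
    grms = eb.build_grms(geno, freqs)
    spec = eb.ModelSpec(terms=terms, inbreeding_covariate=cov)
    design = eb.build_design(rec, spec, f, geno.individual_ids)
    return design, grms


class TestSolveGblup:
    def test_matches_dense_inverse_on_random_problems(self):
        rng = np.random.default_rng(2)
        for k in range(5):
            design, grms = fitted_design(seed=20 + k, n=int(rng.integers(20, 50)),
                                         terms=("A", "D"), cov=(k % 2 == 0))
            variances = {"A": 0.8, "D": 0.3, "pe": 0.5, "e": 5.0}
            sol = eb.solve_gblup(design, grms, variances)
            ref = dense_mme_reference(design, grms, variances)
            np.testing.assert_allclose(sol.g["A"], ref["A"], atol=1e-7)
            np.testing.assert_allclose(sol.g["D"], ref["D"], atol=1e-7)
            np.testing.assert_allclose(sol.pe, ref["pe"], atol=1e-7)
            np.testing.assert_allclose(
                np.concatenate([sol.beta, [] if sol.b is None else [sol.b]]),
                ref["beta"], atol=1e-7)
            assert sol.mme_relative_residual < 1e-8

    def test_identity_grm_equals_ridge(self):
        """With G = I and no fixed part, GBLUP is ridge regression."""
        rng = np.random.default_rng(0)
        n = 5
        y = rng.normal(size=n)
        from epiblup.phenotypes import PhenotypeRecords
        from epiblup.design import DesignSet
        df = pd.DataFrame({"individual_id": range(n), "parity": 1, "group": 1,
                           "period": 1, "y": y})
        design = DesignSet(y=y, X=np.empty((n, 0)), x_names=[], f_record=None,
                           indiv_index=np.arange(n),
                           individual_ids=np.arange(n).astype(object),
                           spec=eb.ModelSpec(terms=("A",), inbreeding_covariate=False),
                           records=PhenotypeRecords(df))
        grm = {"A": eb.RelationshipMatrix(np.eye(n), "A", np.arange(n).astype(object), 1.0)}
        sol = eb.solve_gblup(design, grm, {"A": 2.0, "e": 1.0}, include_pe=False)
        lam = 1.0 / 2.0
        np.testing.assert_allclose(sol.g["A"], y / (1.0 + lam), atol=1e-10)

    def test_zero_variances_shrink_to_gls(self):
        design, grms = fitted_design(seed=30, terms=("A",), cov=False)
        sol = eb.solve_gblup(design, grms, {"A": 0.0, "pe": 0.0, "e": 3.0})
        np.testing.assert_allclose(sol.g["A"], 0.0)
        np.testing.assert_allclose(sol.pe, 0.0)
        beta_ols = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        np.testing.assert_allclose(sol.beta, beta_ols, atol=1e-8)

    def test_deterministic(self):
        design, grms = fitted_design(seed=31, terms=("A",))
        v = {"A": 0.8, "pe": 0.4, "e": 7.0}
        s1 = eb.solve_gblup(design, grms, v)
        s2 = eb.solve_gblup(design, grms, v)
        np.testing.assert_array_equal(s1.g["A"], s2.g["A"])

    def test_duplicated_records_leave_beta_unchanged_without_random_terms(self):
        # balanced replication leaves the least-squares fixed effects alone;
        # with random terms the residual weighting changes, so this holds in
        # the zero-variance (pure fixed-effects) limit
        design, grms = fitted_design(seed=32, terms=("A",), records=(2, 2))
        v = {"A": 0.0, "pe": 0.0, "e": 7.0}
        base = eb.solve_gblup(design, grms, v)
        rec2 = eb.PhenotypeRecords(pd.concat([design.records.df] * 2,
                                             ignore_index=True))
        design2 = eb.build_design(rec2, design.spec,
                                  pd.Series(0.5, index=design.individual_ids),
                                  design.individual_ids)
        dup = eb.solve_gblup(design2, grms, v)
        np.testing.assert_allclose(dup.beta, base.beta, atol=1e-6)

    def test_agrees_with_gibbs_location_means(self):
        """Posterior means of g at fixed variances equal the BLUP solutions."""
        design, grms = fitted_design(seed=33, n=30, terms=("A",))
        v = {"A": 1.5, "pe": 0.5, "e": 4.0}
        sol = eb.solve_gblup(design, grms, v)
        cfg = eb.ChainConfig(n_iter=6000, burn_in=500, thin=1, seed=1)
        # freeze variances with extremely informative priors at the truth
        big = 1e8
        priors = {k: (v[k], big) for k in v}
        chain = eb.gibbs_sample(design, grms, cfg, priors=priors)
        gbar = chain.genetic_means["A"]
        resid_sd = np.std(chain.samples["var_A"])
        assert np.allclose(chain.samples["var_A"].mean(), 1.5, rtol=0.01)
        err = gbar - sol.g["A"]
        # MC error of each posterior mean, bounded via the marginal SD
        assert np.max(np.abs(err)) < 0.2
        assert np.corrcoef(gbar, sol.g["A"])[0, 1] > 0.99


class TestCorrectedAndPredicted:
    def test_corrected_phenotype_arithmetic(self):
        design, grms = fitted_design(seed=34, terms=("A",), cov=True)
        sol = eb.solve_gblup(design, grms, {"A": 0.8, "pe": 0.4, "e": 7.0})
        y_star = eb.corrected_phenotype(design, sol)
        manual = design.y - design.X @ sol.beta - design.f_record * sol.b
        np.testing.assert_allclose(y_star, manual)

    def test_zero_solutions_identity(self):
        design, grms = fitted_design(seed=35, terms=("A",), cov=False)
        sol = eb.solve_gblup(design, grms, {"A": 0.8, "pe": 0.4, "e": 7.0})
        sol.beta = np.zeros_like(sol.beta)
        np.testing.assert_allclose(eb.corrected_phenotype(design, sol), design.y)

    def test_intercept_shift_invariance(self):
        design, grms = fitted_design(seed=36, terms=("A",), cov=False)
        sol = eb.solve_gblup(design, grms, {"A": 0.8, "pe": 0.4, "e": 7.0})
        y1 = eb.corrected_phenotype(design, sol)
        sol.beta = sol.beta.copy()
        sol.beta[0] += 3.0
        design.y = design.y + 3.0
        y2 = eb.corrected_phenotype(design, sol)
        np.testing.assert_allclose(y1, y2, atol=1e-10)

    def test_prediction_sums_declared_terms(self):
        design, grms = fitted_design(seed=37, terms=("A", "D"))
        sol = eb.solve_gblup(design, grms, {"A": 0.8, "D": 0.3, "pe": 0.4, "e": 7.0})
        idx = design.indiv_index[:5]
        yhat = eb.predict_observation(sol, design.spec, idx)
        manual = (sol.g["A"] + sol.g["D"] + sol.pe)[idx]
        np.testing.assert_allclose(yhat, manual)

    def test_candidate_without_records_gets_zero_pe(self):
        _, geno, _, _, rec = small_simulation(38, n=30, m=100)
        # drop every record of one individual -> candidate at prior mean
        drop = geno.individual_ids[0]
        rec = rec.subset(rec.df["individual_id"] != drop)
        freqs = eb.allele_frequencies(geno)
        grms = eb.build_grms(geno, freqs)
        spec = eb.ModelSpec(terms=("A",), inbreeding_covariate=False)
        design = eb.build_design(rec, spec, eb.genomic_inbreeding(geno),
                                 geno.individual_ids)
        sol = eb.solve_gblup(design, grms, {"A": 0.8, "pe": 0.4, "e": 7.0})
        assert sol.pe[0] == pytest.approx(0.0, abs=1e-10)

    def test_missing_term_rejected(self):
        design, grms = fitted_design(seed=39, terms=("A",))
        sol = eb.solve_gblup(design, grms, {"A": 0.8, "pe": 0.4, "e": 7.0})
        with pytest.raises(ValueError, match="missing"):
            eb.predict_observation(sol, eb.ModelSpec(terms=("A", "D")),
                                   design.indiv_index)
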