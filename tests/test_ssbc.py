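"""Single-step BayesC: imputation algebra, sampler correctness, diagnostics."""

import numpy as np
import pytest
from scipy import linalg

from goatbv import (
    GenotypeSet,
    Pedigree,
    breed_composition,
    build_J,
    build_ssbc_model,
    compute_A,
    fit_pblup,
    gbv,
    geweke,
    gibbs_chain,
    impute_marker_covariates,
    partition_A,
    per_locus_prior_scale,
    RunConfig,
)
from goatbv.config import TraitVariances
from goatbv.ssbc import (
    expected_locus_variance,
    genetic_part_draws,
    load_run,
    mc_standard_error,
    save_run,
)

from conftest import random_pedigree
from test_pblup import make_records


# ---------------------------------------------------------------------------
# Imputation and J covariates
# ---------------------------------------------------------------------------

class TestImputation:
    def test_offspring_of_two_genotyped_parents_is_parent_mean(self):
        ped = Pedigree(records=[("S", "", "", 0), ("D", "", "", 1),
                                ("O", "S", "D", 2)])
        part = partition_A(compute_A(ped), {"S", "D"})
        Mg = np.array([[1.0, -0.5], [0.0, 1.5]])
        Mn = impute_marker_covariates(Mg, part.Ang, part.Agg)
        assert Mn[0] == pytest.approx(0.5 * (Mg[0] + Mg[1]))

    def test_unrelated_animal_gets_zero(self):
        ped = Pedigree(records=[("G", "", "", 0), ("U", "", "", 1)])
        part = partition_A(compute_A(ped), {"G"})
        Mn = impute_marker_covariates(np.array([[2.0, -1.0]]), part.Ang, part.Agg)
        assert Mn == pytest.approx(np.zeros((1, 2)))

    def test_matches_dense_inverse_oracle(self, rng):
        ped = random_pedigree(rng, 12, p_missing=0.1)
        rel = compute_A(ped)
        geno = set(rng.choice(ped.ids, size=5, replace=False))
        part = partition_A(rel, geno)
        Mg = rng.normal(size=(5, 7))
        Mn = impute_marker_covariates(Mg, part.Ang, part.Agg)
        oracle = part.Ang @ linalg.inv(part.Agg) @ Mg
        assert np.abs(Mn - oracle).max() < 1e-9

    def test_projection_of_genotyped_rows_is_identity(self, rng):
        """Passing the genotyped block itself through the projection
        reproduces the original covariates (Agg Agg^-1 = I)."""
        ped = random_pedigree(rng, 10)
        rel = compute_A(ped)
        geno = set(ped.ids[:4])
        part = partition_A(rel, geno)
        Mg = rng.normal(size=(4, 3))
        back = impute_marker_covariates(Mg, part.Agg, part.Agg)
        assert np.abs(back - Mg).max() < 1e-9


class TestBuildJ:
    def test_genotyped_purebred_saanen_row(self, trio):
        ped = Pedigree(records=[("S", "", "", 0), ("O", "S", "", 1)],
                       founder_breeds={"S": "saanen"})
        comp = breed_composition(ped)
        part = partition_A(compute_A(ped), {"S"})
        Jg, Jn = build_J(comp, ["S"], ["O"], part.Ang, part.Agg)
        assert Jg[0] == pytest.approx([1.0, 0.0, 0.0])

    def test_nongenotyped_offspring_is_parent_mean(self):
        ped = Pedigree(
            records=[("P1", "", "", 0), ("P2", "", "", 1), ("O", "P1", "P2", 2)],
            founder_breeds={"P1": "saanen", "P2": "anto"},
        )
        comp = breed_composition(ped)
        part = partition_A(compute_A(ped), {"P1", "P2"})
        Jg, Jn = build_J(comp, part.genotyped, part.nongenotyped, part.Ang, part.Agg)
        assert Jn[0] == pytest.approx(0.5 * (Jg[0] + Jg[1]))

    def test_all_genotyped_drops_J(self, trio):
        comp = breed_composition(trio)
        part = partition_A(compute_A(trio), set(trio.ids))
        Jg, Jn = build_J(comp, part.genotyped, part.nongenotyped, part.Ang, part.Agg)
        assert Jn.shape == (0, 3)


class TestPriorScale:
    def test_single_marker_identity(self):
        ev = expected_locus_variance(100.0, np.array([0.5]), pi=0.0)
        assert ev == pytest.approx(100.0 / 0.5)

    def test_doubling_markers_halves_scale(self):
        one = per_locus_prior_scale(50.0, np.array([0.3]), pi=0.9)
        two = per_locus_prior_scale(50.0, np.array([0.3, 0.3]), pi=0.9)
        assert two == pytest.approx(one / 2)

    def test_allocation_plugs_back(self, rng):
        freqs = rng.uniform(0.05, 0.95, size=40)
        pi, nu = 0.98, 4.0
        s2 = per_locus_prior_scale(123.4, freqs, pi, nu)
        e_locus = nu * s2 / (nu - 2.0)
        total = (1 - pi) * np.sum(2 * freqs * (1 - freqs)) * e_locus
        assert total == pytest.approx(123.4, abs=1e-10)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            per_locus_prior_scale(1.0, np.array([0.0, 1.0]), pi=0.5)


# ---------------------------------------------------------------------------
# Sampler fixtures
# ---------------------------------------------------------------------------

def genotyped_herd(rng, n_founders=20, n_off=60, p=40, geno_frac=0.6,
                   p_missing=0.15):
    """A two-generation herd with genotypes on a subset.

    Some offspring have unrecorded parents — without them the J covariates
    are exactly confounded with the intercept and breed design.
    """
    records, breeds = [], {}
    for i in range(n_founders):
        a = f"F{i:02d}"
        records.append((a, "", "", i))
        u = rng.random()
        if u < 0.5:
            breeds[a] = "saanen"
        elif u < 0.85:
            breeds[a] = "anto"
    for i in range(n_off):
        s = f"F{rng.integers(0, n_founders // 2):02d}"
        d = f"F{rng.integers(n_founders // 2, n_founders):02d}"
        if rng.random() < p_missing:
            s = ""
        if rng.random() < p_missing:
            d = ""
        records.append((f"O{i:02d}", s, d, n_founders + i))
    ped = Pedigree(records=records, founder_breeds=breeds)
    freq = rng.uniform(0.1, 0.9, p)
    pos = {a: i for i, a in enumerate(ped.ids)}
    dos = np.empty((ped.n, p))
    for i, (a, s, d, _bo) in enumerate(ped.records):
        a1 = (rng.random(p) < dos[pos[s]] / 2.0) if s else (rng.random(p) < freq)
        a2 = (rng.random(p) < dos[pos[d]] / 2.0) if d else (rng.random(p) < freq)
        dos[i] = a1.astype(float) + a2.astype(float)
    geno_ids = [a for a in ped.ids if rng.random() < geno_frac]
    gi = [pos[a] for a in geno_ids]
    genos = GenotypeSet(animal_ids=geno_ids, marker_ids=[f"m{j}" for j in range(p)],
                        dosages=dos[gi])
    return ped, genos


def exact_gaussian_posterior(model):
    """Dense exact posterior of the genetic part for pi=0, fixed variances."""
    base = model.base
    y = base.y
    nr = y.size
    idx = {a: i for i, a in enumerate(base.animal_order)}
    N = len(base.animal_order)
    blocks = [base.X, base.D_rec]
    rec_rows = np.array([idx[a] for a in base.record_animals])
    if model.include_J:
        blocks.append(model.J_full[rec_rows])
    F = np.column_stack(blocks)
    nong = model.nongenotyped
    eidx = {a: i for i, a in enumerate(nong)}
    nn = len(nong)
    Ze = np.zeros((nr, nn))
    for r, a in enumerate(base.record_animals):
        if a in eidx:
            Ze[r, eidx[a]] = 1.0
    Mp = model.M_full[rec_rows]
    p = Mp.shape[1]
    W = np.hstack([F, base.Z, Ze, Mp])
    nf = F.shape[1]
    se2, sg2, w = model.sigma_e2, model.sigma_g2_total, model.w
    C = W.T @ W / se2
    C[nf:nf + N, nf:nf + N] += model.Ainv.toarray() / (w * sg2)
    if nn:
        C[nf + N:nf + N + nn, nf + N:nf + N + nn] += model.Q.toarray() / ((1 - w) * sg2)
    if p:
        C[nf + N + nn:, nf + N + nn:] += np.eye(p) / model.sigma_a2
    Cinv = linalg.inv(C)
    theta = Cinv @ (W.T @ y / se2)
    L = np.zeros((N, C.shape[0]))
    L[:, nf:nf + N] = np.eye(N)
    for a, i in eidx.items():
        L[idx[a], nf + N + i] = 1.0
    L[:, nf + N + nn:] = model.M_full
    return L @ theta, np.einsum("ij,jk,ik->i", L, Cinv, L)


# ---------------------------------------------------------------------------
# Sampler correctness
# ---------------------------------------------------------------------------

class TestGibbs:
    def test_matches_exact_gaussian_posterior(self, rng):
        """With pi=0 and fixed variances the model is jointly Gaussian; the
        chain must reproduce the exact posterior mean and variance of the
        genetic part."""
        ped, genos = genotyped_herd(rng)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var, pi=0.0)
        mean_ex, var_ex = exact_gaussian_posterior(model)
        run = gibbs_chain(model, chain_length=8000, burn_in=1000, thin=10, seed=4)
        sd = np.sqrt(var_ex.mean())
        assert np.abs(run.gen_mean - mean_ex).max() < 0.25 * sd
        assert abs(run.gen_var.mean() - var_ex.mean()) < 0.02 * var_ex.mean()
        assert np.corrcoef(run.gen_var, var_ex)[0, 1] > 0.9

    def test_null_phenotypes_give_null_marker_effects(self, rng):
        ped, genos = genotyped_herd(rng, p=30)
        comp = breed_composition(ped)
        recs = make_records(ped, rng, trait_sd=0.0)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var)
        run = gibbs_chain(model, chain_length=4000, burn_in=500, thin=5, seed=8)
        post = run.alpha.mean(axis=0)
        se = np.maximum(mc_standard_error(run.alpha), 1e-6)
        assert np.abs(post / se).max() < 5.0

    def test_null_inclusion_rate_matches_prior(self, rng):
        """Under uninformative data the marginal inclusion frequency
        averaged over loci stays near 1 - pi."""
        ped, genos = genotyped_herd(rng, p=60)
        comp = breed_composition(ped)
        recs = make_records(ped, rng, trait_sd=0.0)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var, pi=0.98)
        run = gibbs_chain(model, chain_length=6000, burn_in=1000, thin=5, seed=9)
        mean_incl = run.inclusion_freq().mean()
        # binomial-ish error over 60 loci x effective draws
        assert abs(mean_incl - 0.02) < 0.015

    def test_no_marker_limit_equals_pblup(self, rng):
        """With markers removed and w=1 the posterior means of breed plus
        polygenic effects converge to the PBLUP breeding values."""
        ped, genos = genotyped_herd(rng)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        cfg = RunConfig(trait="milk")
        ebv = fit_pblup(recs, ped, cfg, comp)
        model = build_ssbc_model(recs, ped, comp, genos, "milk", cfg.variances,
                                 pi=0.0, w=1.0, include_markers=False)
        run = gibbs_chain(model, chain_length=12000, burn_in=2000, thin=10, seed=2)
        res = gbv(run, model)
        spread = ebv.bv.std()
        assert np.corrcoef(res.bv, ebv.bv)[0, 1] > 0.999
        assert np.abs(res.bv - ebv.bv).max() < 0.15 * spread
        assert abs(res.pev.mean() - ebv.pev.mean()) < 0.02 * ebv.pev.mean()

    def test_retained_draw_count_and_indicator_consistency(self, rng):
        ped, genos = genotyped_herd(rng, n_founders=12, n_off=30, p=15, p_missing=0.3)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var)
        run = gibbs_chain(model, chain_length=600, burn_in=100, thin=10, seed=3)
        assert run.n_retained == (600 - 100) // 10
        assert set(np.unique(run.delta)) <= {0, 1}
        assert np.all(run.alpha[run.delta == 0] == 0.0)

    def test_bit_reproducible(self, rng):
        ped, genos = genotyped_herd(rng, n_founders=12, n_off=30, p=15, p_missing=0.3)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var)
        r1 = gibbs_chain(model, chain_length=400, burn_in=100, thin=5, seed=11)
        r2 = gibbs_chain(model, chain_length=400, burn_in=100, thin=5, seed=11)
        assert np.array_equal(r1.beta, r2.beta)
        assert np.array_equal(r1.alpha, r2.alpha)
        assert np.array_equal(r1.gen_var, r2.gen_var)

    def test_burn_in_validation(self, rng):
        ped, genos = genotyped_herd(rng, n_founders=10, n_off=20, p=10)
        model = build_ssbc_model(make_records(ped, rng), ped,
                                 breed_composition(ped), genos, "milk",
                                 TraitVariances.for_trait("milk"))
        with pytest.raises(ValueError, match="burn_in"):
            gibbs_chain(model, chain_length=100, burn_in=100)


class TestGbv:
    def test_genetic_part_excludes_eps_for_genotyped(self, rng):
        ped, genos = genotyped_herd(rng, n_founders=10, n_off=20, p=12)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var)
        run = gibbs_chain(model, chain_length=500, burn_in=100, thin=5, seed=6)
        G = genetic_part_draws(run, model)
        idx = {a: i for i, a in enumerate(model.animal_order)}
        gcols = [idx[a] for a in model.genotyped]
        manual = run.u[:, gcols] + run.alpha @ model.M_full[gcols].T
        assert np.abs(G[:, gcols] - manual).max() < 1e-12

    def test_posterior_summary_matches_stored_draws_at_thin_one(self, rng):
        """With thin=1 the streaming moments must equal statistics of the
        stored draws exactly."""
        ped, genos = genotyped_herd(rng, n_founders=10, n_off=20, p=12)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var)
        run = gibbs_chain(model, chain_length=300, burn_in=50, thin=1, seed=6)
        G = genetic_part_draws(run, model)
        assert np.abs(run.gen_mean - G.mean(axis=0)).max() < 1e-9
        assert np.abs(run.gen_var - G.var(axis=0)).max() < 1e-9

    def test_degenerate_constant_chain(self, rng):
        ped, genos = genotyped_herd(rng, n_founders=10, n_off=20, p=12)
        comp = breed_composition(ped)
        recs = make_records(ped, rng)
        var = TraitVariances.for_trait("milk")
        model = build_ssbc_model(recs, ped, comp, genos, "milk", var)
        run = gibbs_chain(model, chain_length=300, burn_in=50, thin=1, seed=6)
        run.gen_var[:] = 0.0  # collapse to a constant chain
        res = gbv(run, model)
        assert np.all(res.pev == 0.0)
        assert np.all(res.accuracy == 1.0)

    def test_save_load_round_trip(self, rng, tmp_path):
        ped, genos = genotyped_herd(rng, n_founders=10, n_off=20, p=12)
        model = build_ssbc_model(make_records(ped, rng), ped,
                                 breed_composition(ped), genos, "milk",
                                 TraitVariances.for_trait("milk"))
        run = gibbs_chain(model, chain_length=300, burn_in=50, thin=5, seed=6)
        save_run(run, tmp_path / "run.h5")
        back = load_run(tmp_path / "run.h5")
        assert np.array_equal(back.alpha, run.alpha)
        assert np.array_equal(back.gen_var, run.gen_var)
        assert back.col_names == run.col_names
        assert back.d_cols == run.d_cols


class TestGeweke:
    def test_constant_chain_is_zero(self):
        assert geweke(np.full(1000, 10109.6)) == 0.0

    def test_null_calibration(self):
        """For i.i.d. N(0,1) chains the z-score is standard normal."""
        rng = np.random.default_rng(1)
        inside = sum(
            abs(geweke(rng.standard_normal(10_000))) < 1.96 for _ in range(500)
        )
        assert inside >= 0.93 * 500

    def test_planted_mean_step_detected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.zeros(5000), np.ones(5000)])
        x = x + rng.standard_normal(10_000) * 0.3
        assert abs(geweke(x)) > 3.0

    def test_short_chain_raises(self):
        with pytest.raises(ValueError):
            geweke(np.arange(50.0))
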