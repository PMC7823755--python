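"""Synthetic herd generator: pedigree shape, genotype distributions,
trait architecture and ground truth."""

import numpy as np
import pytest
from scipy import stats

from goatbv import (
    RunConfig,
    SimulationConfig,
    breed_composition,
    fit_pblup,
    fit_ssbc,
    hwe_test,
    read_dosage_csv,
    read_pedigree_csv,
    read_phenotype_csv,
    read_plink,
    realized_h2,
    simulate_genotypes,
    simulate_herd,
    simulate_pedigree,
    write_dosage_csv,
    write_pedigree_csv,
    write_phenotype_csv,
    write_plink,
)
from goatbv.config import ChainConfig
from goatbv.simulate import doe_ids

from conftest import small_sim_config


class TestPedigreeGeneration:
    def test_trio_case(self):
        cfg = SimulationConfig(
            n_does=1, n_sires=1, n_founder_dams=1, n_generations=1,
            generation_weights=(1.0,), missing_sire_fraction=0.0,
            missing_dam_fraction=0.0, n_markers=10, n_qtl=2, seed=1,
        )
        ped = simulate_pedigree(cfg)
        assert ped.n == 3
        doe = doe_ids(ped)[0]
        assert "" not in ped.parents(doe)

    def test_no_missing_parents_means_no_scenario_d(self):
        cfg = small_sim_config(missing_sire_fraction=0.0, missing_dam_fraction=0.0)
        ped = simulate_pedigree(cfg)
        for a in doe_ids(ped):
            s, d = ped.parents(a)
            assert s != "" and d != ""

    def test_default_structure_matches_planted_ranges(self):
        cfg = SimulationConfig(seed=7)
        ped = simulate_pedigree(cfg)
        does = doe_ids(ped)
        assert len(does) == 839
        sires = {ped.parents(a)[0] for a in does} - {""}
        assert len(sires) <= 46
        progeny = len(does) / max(len(sires), 1)
        assert 10 <= progeny <= 40
        # dams are mostly base females without lactation records
        doe_set = set(does)
        doe_dams = sum(ped.parents(a)[1] in doe_set for a in does)
        assert doe_dams / len(does) < 0.1


class TestGenotypeGeneration:
    def test_mendelian_consistency(self):
        cfg = small_sim_config(seed=5)
        ped = simulate_pedigree(cfg)
        full, _obs, _geno = simulate_genotypes(ped, cfg)
        idx = {a: i for i, a in enumerate(full.animal_ids)}
        dos = full.dosages
        checked = 0
        for a, s, d, _bo in ped.records:
            if s == "" or d == "":
                continue
            both = dos[idx[s]] + dos[idx[d]]
            child = dos[idx[a]]
            # homozygous x homozygous opposite -> heterozygous offspring
            opp = (dos[idx[s]] == 0) & (dos[idx[d]] == 2)
            opp |= (dos[idx[s]] == 2) & (dos[idx[d]] == 0)
            assert np.all(child[opp] == 1)
            checked += opp.sum()
        assert checked > 100

    def test_zero_fst_founders_in_hwe(self):
        cfg = small_sim_config(seed=9, fst=0.0, n_markers=400, n_founder_dams=300)
        ped = simulate_pedigree(cfg)
        full, _obs, _geno = simulate_genotypes(ped, cfg)
        founders = [i for i, a in enumerate(full.animal_ids)
                    if ped.parents(a) == ("", "")]
        dos = full.dosages[founders]
        passing = 0
        for j in range(dos.shape[1]):
            counts = ((dos[:, j] == 0).sum(), (dos[:, j] == 1).sum(),
                      (dos[:, j] == 2).sum())
            passing += hwe_test(counts) >= 1e-3
        assert passing / dos.shape[1] >= 0.99

    def test_fst_recovered_by_hudson_estimator(self):
        cfg = SimulationConfig(n_does=50, n_sires=30, n_founder_dams=470,
                               n_markers=2000, n_qtl=5, fst=0.10,
                               saanen_founder_fraction=0.5, seed=13)
        ped = simulate_pedigree(cfg)
        full, _obs, _geno = simulate_genotypes(ped, cfg)
        idx = {a: i for i, a in enumerate(full.animal_ids)}
        groups = {}
        for a, lab in ped.founder_breeds.items():
            groups.setdefault(lab, []).append(idx[a])
        p1 = full.dosages[groups["saanen"]].mean(axis=0) / 2
        p2 = full.dosages[groups["anto"]].mean(axis=0) / 2
        n1, n2 = len(groups["saanen"]), len(groups["anto"])
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = num.sum() / den.sum()
        assert abs(fst_hat - 0.10) < 0.03

    def test_genotyping_fraction_and_bias(self):
        herd = simulate_herd(small_sim_config(seed=3))
        frac = len(herd.genotyped_ids) / len(herd.records)
        assert abs(frac - herd.config.genotyping_fraction) < 0.02
        # genotyped does skew towards recent birth orders
        orders = {a: herd.pedigree.birth_order(a) for a in doe_ids(herd.pedigree)}
        geno = set(herd.genotyped_ids)
        g_mean = np.mean([orders[a] for a in geno])
        all_mean = np.mean(list(orders.values()))
        assert g_mean > all_mean


class TestPhenotypeArchitecture:
    def test_residual_only_when_architecture_off(self):
        from goatbv.config import TraitVariances

        cfg = small_sim_config(
            seed=21,
            n_does=600, n_founder_dams=350,
            variances=TraitVariances(polygenic=1e-6, snp=1e-6, residual=30345.0),
            breed_effects=(0.0, 0.0, 0.0), heterosis_effect=0.0,
            parity_effects=(0.0,) * 5, dmkd_range=(0.0, 0.0),
            dim_range=(245.0, 245.0),
        )
        herd = simulate_herd(cfg)
        y = np.array([r.milk_yield for r in herd.records])
        assert np.var(y) == pytest.approx(30345.0, rel=0.15)

    def test_realized_h2_matches_parametric(self):
        cfg = SimulationConfig(n_does=2000, n_sires=60, n_founder_dams=900,
                               n_markers=400, n_qtl=16, seed=5)
        herd = simulate_herd(cfg)
        h2 = realized_h2(herd.records, herd.truth, "milk")
        assert abs(h2 - cfg.variances.h2) < 0.04

    def test_bv_phenotype_correlation_is_sqrt_h2(self):
        cfg = SimulationConfig(n_does=2000, n_sires=60, n_founder_dams=900,
                               n_markers=300, n_qtl=12, seed=6,
                               breed_effects=(0.0, 0.0, 0.0),
                               heterosis_effect=0.0, parity_effects=(0.0,) * 5,
                               dmkd_range=(0.0, 0.0), dim_range=(245.0, 245.0))
        herd = simulate_herd(cfg)
        y = np.array([r.milk_yield for r in herd.records])
        bv = np.array([herd.truth.true_bv[r.animal_id] for r in herd.records])
        h = np.sqrt(cfg.variances.h2)
        assert abs(np.corrcoef(y, bv)[0, 1] - h) < 0.05

    def test_founder_additive_variance_near_parametric(self):
        cfg = SimulationConfig(n_does=800, n_sires=46, n_founder_dams=550,
                               n_markers=500, n_qtl=20, seed=17)
        herd = simulate_herd(cfg)
        bv = np.array(list(herd.truth.true_bv.values()))
        assert abs(bv.var() - cfg.variances.total_genetic) \
            < 0.15 * cfg.variances.total_genetic

    def test_scc_tests_flow_through_scs(self):
        herd = simulate_herd(small_sim_config(seed=2))
        scs = np.array([r.scs for r in herd.records])
        # log2 of counts around 300k: scores in a plausible band
        assert 12 < scs.mean() < 24
        assert scs.std() > 0.05


class TestReproducibilityAndIO:
    def test_bit_reproducible(self):
        h1 = simulate_herd(small_sim_config(seed=42))
        h2 = simulate_herd(small_sim_config(seed=42))
        assert h1.pedigree.records == h2.pedigree.records
        assert np.array_equal(h1.genotypes.dosages, h2.genotypes.dosages)
        assert [r.milk_yield for r in h1.records] == [r.milk_yield for r in h2.records]

    def test_writers_round_trip(self, tmp_path):
        herd = simulate_herd(small_sim_config(seed=8, n_does=60, n_founder_dams=40,
                                              n_markers=30))
        write_pedigree_csv(herd.pedigree, tmp_path / "ped.csv")
        write_phenotype_csv(herd.records, tmp_path / "phe.csv")
        write_dosage_csv(herd.genotypes, tmp_path / "dos.csv")
        write_plink(herd.genotypes, tmp_path / "g.ped", tmp_path / "g.map")
        ped = read_pedigree_csv(tmp_path / "ped.csv")
        assert ped.records == herd.pedigree.records
        recs = read_phenotype_csv(tmp_path / "phe.csv")
        assert [r.animal_id for r in recs] == [r.animal_id for r in herd.records]
        assert recs[0].milk_yield == pytest.approx(herd.records[0].milk_yield)
        dos = read_dosage_csv(tmp_path / "dos.csv")
        assert np.array_equal(dos.dosages, herd.genotypes.dosages, equal_nan=True)
        plink = read_plink(tmp_path / "g.ped", tmp_path / "g.map")
        assert np.array_equal(plink.dosages, herd.genotypes.dosages, equal_nan=True)


class TestMarkerFreeLimit:
    def test_no_genomic_gain_when_markers_carry_nothing(self):
        """With the marker-linked fraction at zero the two models' mean
        validation accuracies are statistically indistinguishable."""
        diffs = []
        for seed in range(6):
            cfg = small_sim_config(seed=300 + seed, w=1.0, n_qtl=0)
            herd = simulate_herd(cfg)
            rc = RunConfig(trait="milk",
                           chain=ChainConfig(length=3000, burn_in=500, thin=10,
                                             seed=seed))
            from goatbv import age_split

            pairs = [(r.animal_id, herd.pedigree.birth_order(r.animal_id))
                     for r in herd.records]
            design = age_split(pairs, 0.7)
            train = [r for r in herd.records
                     if r.animal_id in set(design.training_ids)]
            ebv = fit_pblup(train, herd.pedigree, rc, herd.composition)
            res, _run, _model = fit_ssbc(train, herd.pedigree, herd.genotypes,
                                         rc, herd.composition)
            acc_e = dict(zip(ebv.animal_ids, ebv.accuracy))
            acc_g = dict(zip(res.animal_ids, res.accuracy))
            val = design.validation_ids
            diffs.append(np.mean([acc_g[a] for a in val])
                         - np.mean([acc_e[a] for a in val]))
        _t, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01
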