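"""Association scans, Bonferroni thresholding and the random haplotype model."""

import math

import numpy as np
import pandas as pd
import pytest

from lethalscan import association_scan as scans
from lethalscan import io_formats as io
from lethalscan.mixed_models import RelationshipMatrix, build_A
from lethalscan.simulate import (SimulationConfig, call_genotypes,
                                 simulate_population,
                                 simulate_records_and_drp)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 8_938_927, 8.25),   # genome-wide sequence-variant correction
        (0.05, 1, 1.30),
        (1.0, 1, 0.0),
    ])
    def test_values(self, alpha, n, expected):
        assert round(scans.bonferroni_threshold(alpha, n), 2) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            scans.bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            scans.bonferroni_threshold(0.05, 0)


def _tag_span(pop):
    pos = pop.markers.set_index("id").loc[pop.tag_window_ids, "pos"]
    return int(pos.min()), int(pos.max())


class TestSireScan:
    def test_monomorphic_marker_skipped(self, scan_data):
        g = scan_data["g_qc"]
        mono = g.dosages.copy()
        mono[:, 0] = 1  # constant dosage
        g_mono = io.GenotypeData(markers=g.markers.drop(columns="maf").copy(),
                                 samples=list(g.samples), dosages=mono)
        res = scans.scan_sire_model(g_mono, scan_data["pheno"], scan_data["ped"])
        assert res["note"].iloc[0] == "monomorphic"
        assert np.isnan(res["p"].iloc[0])

    def test_peak_localises_to_tag_window_with_negative_effect(self, scan_data):
        res = scans.scan_sire_model(scan_data["g_qc"], scan_data["pheno"],
                                    scan_data["ped"])
        peak = res.loc[res["p"].idxmin()]
        lo, hi = _tag_span(scan_data["pop"])
        assert lo <= peak["pos"] <= hi
        # the deletion allele raises stillbirth, i.e. lowers the survival DRP
        assert peak["beta"] < 0

    def test_missing_sire_raises(self, scan_data):
        ped = scan_data["ped"].copy()
        ped.loc[ped["generation"] > 0, "sire"] = ""
        with pytest.raises(ValueError, match="no sire"):
            scans.scan_sire_model(scan_data["g_qc"], scan_data["pheno"], ped)

    def test_null_scans_respect_familywise_error(self):
        """Without any QTL, a whole-panel scan crosses the Bonferroni line
        only at the nominal familywise rate."""
        crossings = 0
        for seed in (101, 102, 103):
            cfg = SimulationConfig(n_founders=240, n_generations=1,
                                   n_sires_per_gen=20, progeny_per_sire=20,
                                   n_markers=250, causative_allele_freq=0.0,
                                   seed=seed)
            pop = simulate_population(cfg)
            g = call_genotypes(pop)
            _, drp = simulate_records_and_drp(pop)
            pheno = io.prepare_phenotypes(drp)
            res = scans.scan_sire_model(g, pheno, pop.pedigree())
            line = scans.bonferroni_threshold(0.05, int(res["p"].notna().sum()))
            if (res["mlog10p"] > line).any():
                crossings += 1
        assert crossings <= 1

    def test_fast_mode_close_to_exact(self, scan_data):
        exact = scans.scan_sire_model(scan_data["g_qc"], scan_data["pheno"],
                                      scan_data["ped"])
        fast = scans.scan_sire_model(scan_data["g_qc"], scan_data["pheno"],
                                     scan_data["ped"], fast=True)
        assert fast.attrs["mode"] == "fast"
        ok = exact["p"].notna()
        np.testing.assert_allclose(fast.loc[ok, "beta"], exact.loc[ok, "beta"],
                                   rtol=0.1, atol=0.02)


class TestAnimalScan:
    def test_identity_a_equals_weighted_regression(self):
        """With A = I and unit weights the animal model collapses to ordinary
        weighted regression: one iid random effect is absorbed into the
        residual, so estimates and SEs match a plain WLS fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(33)
        n, m = 120, 5
        ids = [f"S{i}" for i in range(n)]
        dosages = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        markers = pd.DataFrame({"id": [f"m{j}" for j in range(m)],
                                "chrom": "1", "pos": 100 * np.arange(1, m + 1),
                                "ref": "A", "alt": "G"})
        g = io.GenotypeData(markers=markers, samples=ids, dosages=dosages)
        y = 1.0 + 0.5 * dosages[:, 2] + rng.normal(0, 1.0, n)
        pheno = pd.DataFrame({"id": ids, "y": y, "r2": 0.5, "w": 1.0})
        A = RelationshipMatrix(ids=ids, A=np.eye(n))
        res = scans.scan_animal_model(g, pheno, A)
        for j in range(m):
            X = sm.add_constant(dosages[:, j].astype(float))
            ols = sm.OLS(y, X).fit()
            assert res["beta"].iloc[j] == pytest.approx(ols.params[1], rel=1e-5)
            assert res["se"].iloc[j] == pytest.approx(ols.bse[1], rel=1e-3)

    def test_planted_effect_recovered_and_peak_agrees_with_sire_model(
            self, scan_data):
        res_a = scans.scan_animal_model(scan_data["g_qc"], scan_data["pheno"],
                                        scan_data["A"])
        res_s = scans.scan_sire_model(scan_data["g_qc"], scan_data["pheno"],
                                      scan_data["ped"])
        lo, hi = _tag_span(scan_data["pop"])
        peak_a = res_a.loc[res_a["p"].idxmin()]
        assert lo <= peak_a["pos"] <= hi
        # both models place their minimum inside the same tag window
        peak_s = res_s.loc[res_s["p"].idxmin()]
        assert lo <= peak_s["pos"] <= hi

    def test_marker_reordering_invariance(self, scan_data):
        g = scan_data["g_qc"]
        res = scans.scan_animal_model(g, scan_data["pheno"], scan_data["A"])
        # positions must stay sorted, so reverse-and-resort is the available
        # reordering; instead check the scan is a pure per-marker map by
        # rerunning on a marker subset
        mask = np.zeros(g.n_markers, dtype=bool)
        mask[::3] = True
        res_sub = scans.scan_animal_model(g.subset_markers(mask),
                                          scan_data["pheno"], scan_data["A"])
        merged = res.set_index("marker").loc[res_sub["marker"]]
        np.testing.assert_allclose(res_sub["beta"], merged["beta"], rtol=1e-8)
        np.testing.assert_allclose(res_sub["mlog10p"], merged["mlog10p"],
                                   rtol=1e-6)

    def test_allele_flip_negates_beta_keeps_p(self, scan_data):
        g = scan_data["g_qc"]
        flipped = io.GenotypeData(
            markers=g.markers.drop(columns="maf").rename(
                columns={"ref": "alt", "alt": "ref"})[
                ["id", "chrom", "pos", "ref", "alt"]].copy(),
            samples=list(g.samples),
            dosages=np.where(g.dosages == io.MISSING, io.MISSING,
                             2 - g.dosages).astype(np.int8))
        res = scans.scan_animal_model(g, scan_data["pheno"], scan_data["A"])
        res_f = scans.scan_animal_model(flipped, scan_data["pheno"],
                                        scan_data["A"])
        ok = res["p"].notna().to_numpy() & res_f["p"].notna().to_numpy()
        np.testing.assert_allclose(res_f.loc[ok, "beta"],
                                   -res.loc[ok, "beta"], rtol=1e-6)
        np.testing.assert_allclose(res_f.loc[ok, "mlog10p"],
                                   res.loc[ok, "mlog10p"], rtol=1e-6)


class TestCofactorScan:
    def test_zero_cofactor_matches_animal_model(self, scan_data):
        pheno = scan_data["pheno"]
        base = scans.scan_animal_model(scan_data["g_qc"], pheno, scan_data["A"])
        cof = scans.cofactor_scan(scan_data["g_qc"], pheno, scan_data["A"],
                                  np.zeros(len(pheno)))
        # an all-zero cofactor is dropped from nothing -- it is collinear with
        # nothing and estimates are unchanged
        ok = base["p"].notna()
        np.testing.assert_allclose(cof.loc[ok, "beta"], base.loc[ok, "beta"],
                                   rtol=1e-5)

    def test_true_tag_cofactor_removes_all_significance(self, scan_data):
        pop = scan_data["pop"]
        pheno = scan_data["pheno"]
        truth_copies = pop.individuals.set_index("id").loc[
            pheno["id"], "deletion_copies"].to_numpy(dtype=float)
        res = scans.cofactor_scan(scan_data["g_qc"], pheno, scan_data["A"],
                                  truth_copies)
        line = scans.bonferroni_threshold(0.05, int(res["p"].notna().sum()))
        assert (res["mlog10p"].dropna() <= line).all()

    def test_collinear_marker_flagged(self):
        rng = np.random.default_rng(8)
        n = 80
        ids = [f"S{i}" for i in range(n)]
        x = rng.binomial(2, 0.4, n).astype(np.int8)
        markers = pd.DataFrame({"id": ["m0", "m1"], "chrom": "1",
                                "pos": [100, 200], "ref": "A", "alt": "G"})
        g = io.GenotypeData(markers=markers, samples=ids,
                            dosages=np.column_stack([x, rng.binomial(2, 0.4, n)
                                                     ]).astype(np.int8))
        pheno = pd.DataFrame({"id": ids, "y": rng.normal(size=n),
                              "r2": 0.5, "w": 1.0})
        A = RelationshipMatrix(ids=ids, A=np.eye(n))
        res = scans.cofactor_scan(g, pheno, A, x.astype(float))
        assert res["note"].iloc[0] == "collinear_with_cofactor"
        assert res["note"].iloc[1] == ""


class TestTopSnpSelection:
    def test_rank_by_p_then_position(self):
        scan = pd.DataFrame({
            "marker": ["a", "b", "c", "d"], "pos": [400, 100, 300, 200],
            "p": [0.5, 0.01, 0.01, np.nan],
        })
        assert scans.select_top_snps(scan, 2) == ["b", "c"]
        assert scans.select_top_snps(scan, 10) == ["b", "c", "a"]


class TestRhm:
    def test_window_allele_space_is_2_to_k(self, rhm_result):
        assert rhm_result.n_possible == 2 ** 10 == 1024
        assert len(rhm_result.haplotypes) <= 1024

    def test_designates_the_simulated_tag_haplotype(self, scan_data, rhm_result):
        assert rhm_result.hap_qtl == scan_data["pop"].tag_haplotype
        assert rhm_result.lrt_p < 1e-10
        i = rhm_result.haplotypes.index(rhm_result.hap_qtl)
        assert rhm_result.effects[i] < 0

    def test_discovered_cofactor_attenuates_the_peak(self, scan_data,
                                                     rhm_result):
        """The full discovery path: counting copies of the RHM-designated
        allele and re-scanning with it as a cofactor collapses the peak.
        A few true recombinants (haplotype without deletion or vice versa)
        leave a residual trace, so attenuation, not elimination, is the
        check here; elimination is asserted for the exact carrier count."""
        from lethalscan.association_scan import _align
        from lethalscan.lethal_scan import make_window

        g = scan_data["g"]
        win = make_window(g, scan_data["pop"].tag_window_ids)
        copies = pd.Series(win.copy_count(rhm_result.hap_qtl),
                           index=win.samples)
        ph, _ = _align(scan_data["g_qc"], scan_data["pheno"])
        base = scans.scan_animal_model(scan_data["g_qc"], scan_data["pheno"],
                                       scan_data["A"])
        res = scans.cofactor_scan(scan_data["g_qc"], scan_data["pheno"],
                                  scan_data["A"],
                                  copies.loc[ph["id"]].to_numpy(dtype=float))
        assert res["mlog10p"].max() < base["mlog10p"].max() / 3.0

    def test_unphased_window_raises(self, scan_data):
        g = scan_data["g_qc"]
        g_unphased = io.GenotypeData(
            markers=g.markers.drop(columns="maf").copy(),
            samples=list(g.samples), dosages=g.dosages.copy())
        with pytest.raises(ValueError, match="phased"):
            scans.fit_rhm(g_unphased, scan_data["pheno"], scan_data["A"],
                          g.markers["id"].head(4).tolist())
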