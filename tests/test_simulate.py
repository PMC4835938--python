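"""Gene-drop simulator: Mendelian transmission, lethality, observables."""

import numpy as np
import pandas as pd
import pytest

from lethalscan.io_formats import MISSING
from lethalscan.simulate import (ConfigError, SimulationConfig, call_genotypes,
                                 simulate_depth, simulate_intensity,
                                 simulate_population,
                                 simulate_records_and_drp)


@pytest.mark.parametrize("field,value,match", [
    ("causative_allele_freq", 0.6, "causative_allele_freq"),
    ("penetrance", 1.5, "penetrance"),
    ("deletion_end_bp", 30_000_000, "deletion"),
    ("n_founders", 0, "n_founders"),
    ("intensity_sd", -0.1, "intensity_sd"),
])
def test_invalid_config_names_the_field(field, value, match):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(ConfigError, match=match):
        cfg.validate()


def test_full_penetrance_leaves_no_live_homozygotes(pop_scan, pop_lethal10k):
    for pop in (pop_scan, pop_lethal10k):
        assert ((pop.deletion_copies == 2) & pop.alive).sum() == 0


def test_zero_frequency_gives_no_carriers_and_baseline_stillbirth():
    cfg = SimulationConfig(n_founders=300, n_generations=2, n_sires_per_gen=20,
                           progeny_per_sire=30, n_markers=60,
                           causative_allele_freq=0.0,
                           baseline_stillbirth=0.05, seed=13)
    pop = simulate_population(cfg)
    assert (pop.deletion_copies == 0).all()
    born = pop.individuals[pop.individuals["generation"] > 0]
    rate = 1.0 - born["alive"].mean()
    se = np.sqrt(0.05 * 0.95 / len(born))
    assert abs(rate - 0.05) < 3 * se


def test_mendelian_transmission_of_the_deletion(pop_lethal10k):
    """Each carrier parent transmits its deleted chromosome to half its
    gametes (0.5 within 3 binomial SE over >= 10^4 informative meioses)."""
    pop = pop_lethal10k
    ind = pop.individuals
    idx = {i: k for k, i in enumerate(ind["id"])}
    carrier = pop.deletion_copies == 1
    n_meioses = 0
    n_transmitted = 0
    for row in ind[ind["generation"] > 0].itertuples(index=False):
        for parent in (row.sire, row.dam):
            if carrier[idx[parent]]:
                n_meioses += 1
    # transmitted copies among offspring of carrier x noncarrier pairs equal
    # total offspring deletion copies minus double-carrier contributions;
    # count directly from inherited flags instead
    child_gen = ind["generation"].to_numpy() > 0
    sires = ind["sire"].map(idx).to_numpy()[child_gen].astype(int)
    dams = ind["dam"].map(idx).to_numpy()[child_gen].astype(int)
    del_flags = pop.del_flags[child_gen]
    informative = 0
    transmitted = 0
    for strand, parent in ((0, sires), (1, dams)):
        mask = carrier[parent]
        informative += int(mask.sum())
        transmitted += int(del_flags[mask, strand].sum())
    assert informative >= 100
    se = np.sqrt(0.25 / informative)
    assert abs(transmitted / informative - 0.5) < 3 * se


def test_tag_haplotype_frequency_near_p_among_founders(pop_scan):
    pop = pop_scan
    founders = (pop.individuals["generation"] == 0).to_numpy()
    n_del = pop.del_flags[founders].sum()
    freq = n_del / (2 * founders.sum())
    assert freq == pytest.approx(0.08, abs=0.002)  # exact-count assignment
    # complete LD at generation 0: every deleted founder chromosome carries
    # the tag string and no intact one does
    from lethalscan.lethal_scan import make_window

    g = call_genotypes(pop)
    win = make_window(g, pop.tag_window_ids)
    assert pop.tag_haplotype in win.frequencies.index


def test_same_seed_bit_identical_outputs(pop_small):
    cfg = pop_small.config
    pop2 = simulate_population(cfg)
    assert pop_small.individuals.equals(pop2.individuals)
    np.testing.assert_array_equal(pop_small.haplotypes, pop2.haplotypes)
    np.testing.assert_array_equal(pop_small.del_flags, pop2.del_flags)
    for fn in (call_genotypes, simulate_intensity):
        a, b = fn(pop_small), fn(pop2)
        va = a.dosages if hasattr(a, "dosages") else a.values
        vb = b.dosages if hasattr(b, "dosages") else b.values
        np.testing.assert_array_equal(va, vb)
    d1 = simulate_depth(pop_small, samples=pop_small.live_ids[:10])
    d2 = simulate_depth(pop2, samples=pop2.live_ids[:10])
    pd.testing.assert_frame_equal(d1, d2)
    c1, r1 = simulate_records_and_drp(pop_small)
    c2, r2 = simulate_records_and_drp(pop2)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(r1, r2)


class TestCallGenotypes:
    def test_hemizygote_called_homozygous_for_present_allele(self):
        cfg = SimulationConfig(n_founders=200, n_generations=1,
                               n_sires_per_gen=10, progeny_per_sire=10,
                               n_markers=200, genotype_error=0.0,
                               causative_allele_freq=0.1, seed=3)
        pop = simulate_population(cfg)
        g = call_genotypes(pop)
        in_del = pop.in_deletion_mask()
        live_rows = np.flatnonzero(pop.alive)
        sample_of = {s: i for i, s in enumerate(g.samples)}
        for i in live_rows:
            ident = pop.individuals["id"].iloc[i]
            row = g.dosages[sample_of[ident]]
            copies = pop.deletion_copies[i]
            if copies == 1:
                present = pop.haplotypes[i, int(pop.del_flags[i, 0]), :]
                np.testing.assert_array_equal(row[in_del],
                                              2 * present[in_del])
            elif copies == 0:
                np.testing.assert_array_equal(
                    row, pop.haplotypes[i].sum(axis=0))

    def test_error_rate_controls_in_deletion_homozygosity(self):
        """With per-call error e, a carrier is called homozygous at a
        fraction ~(1-e) of in-deletion markers (the 97 % rule's rationale)."""
        cfg = SimulationConfig(n_founders=600, n_generations=1,
                               n_sires_per_gen=10, progeny_per_sire=5,
                               n_markers=5600, genotype_error=0.03,
                               causative_allele_freq=0.15, seed=4)
        pop = simulate_population(cfg)
        g = call_genotypes(pop)
        in_del = pop.in_deletion_mask()
        truth = pop.carrier_truth(g.samples).to_numpy()
        d = g.dosages[truth][:, in_del]
        hom_frac = ((d == 0) | (d == 2)).mean()
        n_calls = d.size
        se = np.sqrt(0.03 * 0.97 / n_calls)
        assert abs(hom_frac - 0.97) < 4 * se


class TestIntensity:
    def test_zero_sd_is_exact(self):
        cfg = SimulationConfig(n_founders=100, n_generations=1,
                               n_sires_per_gen=5, progeny_per_sire=5,
                               n_markers=400, intensity_sd=0.0,
                               causative_allele_freq=0.1, seed=8)
        pop = simulate_population(cfg)
        inten = simulate_intensity(pop)
        in_del = pop.in_deletion_mask()
        truth = pop.carrier_truth(inten.samples).to_numpy()
        carrier_vals = inten.values[np.ix_(in_del, truth)]
        noncarrier_vals = inten.values[:, ~truth]
        assert np.all(carrier_vals == cfg.intensity_mean_carrier)
        assert np.all(noncarrier_vals == 0.0)
        out_del_carrier = inten.values[np.ix_(~in_del, truth)]
        assert np.all(out_del_carrier == 0.0)

    def test_carrier_mean_in_deletion_negative_at_defaults(self, hd_panel):
        pop, g = hd_panel["pop"], hd_panel["g"]
        inten = simulate_intensity(pop)
        in_del = pop.in_deletion_mask()
        truth = pop.carrier_truth(inten.samples).to_numpy()
        means = inten.values[in_del][:, truth].mean(axis=0)
        assert (means < 0).mean() > 0.99


class TestDepth:
    def test_ratio_targets_and_poisson_moments(self, pop_scan):
        live = pop_scan.individuals[pop_scan.alive]
        carriers = live.loc[live["deletion_copies"] == 1, "id"].head(10).tolist()
        noncarr = live.loc[live["deletion_copies"] == 0, "id"].head(10).tolist()
        depth = simulate_depth(pop_scan, samples=carriers + noncarr)
        cfg = pop_scan.config
        per_bp = depth.assign(
            rate=depth["reads"] / (depth["window_end"] - depth["window_start"] + 1))
        inside = ((per_bp["window_start"] >= cfg.deletion_start_bp)
                  & (per_bp["window_end"] <= cfg.deletion_end_bp))
        outside = ((per_bp["window_end"] < cfg.deletion_start_bp)
                   | (per_bp["window_start"] > cfg.deletion_end_bp))
        for ids, target in ((carriers, 0.5), (noncarr, 1.0)):
            sub = per_bp[per_bp["sample"].isin(ids)]
            ratio = (sub.loc[inside.reindex(sub.index, fill_value=False), "rate"].mean()
                     / sub.loc[outside.reindex(sub.index, fill_value=False), "rate"].mean())
            assert ratio == pytest.approx(target, abs=0.02)
        # Poisson: variance ~ mean for off-region windows of one noncarrier
        one = per_bp[(per_bp["sample"] == noncarr[0])
                     & outside.reindex(per_bp.index, fill_value=False)]
        reads = one["reads"].to_numpy(dtype=float)
        assert one["reads"].var() / one["reads"].mean() == pytest.approx(
            1.0, abs=0.35)


class TestRecordsAndDrp:
    def test_dead_calves_recorded_but_not_genotyped(self, pop_scan):
        calving, _ = simulate_records_and_drp(pop_scan)
        g = call_genotypes(pop_scan)
        dead = set(pop_scan.individuals.loc[~pop_scan.alive, "id"])
        assert dead & set(calving["calf"])        # recorded
        assert not dead & set(g.samples)          # not genotyped
        n_offspring = (pop_scan.individuals["generation"] > 0).sum()
        assert len(calving) == n_offspring

    def test_p_zero_gives_identical_drp_distributions(self):
        cfg = SimulationConfig(n_founders=600, n_generations=2,
                               n_sires_per_gen=40, progeny_per_sire=40,
                               n_markers=60, causative_allele_freq=0.0, seed=19)
        pop = simulate_population(cfg)
        _, drp = simulate_records_and_drp(pop)
        # no carriers exist, so no group shift is even definable; the DRPs
        # must be centred on the polygenic mean (0) with unit-scale spread
        z = drp["drp"].mean() / (drp["drp"].std() / np.sqrt(len(drp)))
        assert abs(z) < 4

    def test_carrier_bulls_have_depressed_drp(self, pop_scan):
        _, drp = simulate_records_and_drp(pop_scan)
        truth = pop_scan.carrier_truth(drp["id"]).to_numpy()
        gap = drp.loc[~truth, "drp"].mean() - drp.loc[truth, "drp"].mean()
        assert gap > 0.5  # carriers depressed by ~1.9 additive SD at p=0.08
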