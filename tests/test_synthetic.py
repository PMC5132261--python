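import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coenrich.psm_filter import accept_proteins, assign_decoy_status, filter_psms
from coenrich.sequence_db import map_peptides, mapping_index
from coenrich.spectral_quant import count_spectra, compute_dnsaf, distribute_counts
from coenrich.synthetic import (
    ALL_RUNS,
    BAIT_RUNS,
    CONTROL_RUNS,
    ImageSimConfig,
    SimulationConfig,
    simulate_experiment,
    simulate_image_set,
    simulate_proteome,
    simulate_run,
)


class TestProteome:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_target_proteins=50, n_complex_members=5, seed=1)
        sim1 = simulate_experiment(cfg)
        sim2 = simulate_experiment(cfg)
        assert [r.sequence for r in sim1.targets] == [r.sequence for r in sim2.targets]
        assert sim1.truth.complex_members == sim2.truth.complex_members
        for run in ALL_RUNS:
            pd.testing.assert_frame_equal(sim1.psm_tables[run], sim2.psm_tables[run])

    def test_different_seeds_differ(self):
        a = simulate_experiment(SimulationConfig(n_target_proteins=30, run_depth=300, seed=1))
        b = simulate_experiment(SimulationConfig(n_target_proteins=30, run_depth=300, seed=2))
        assert [r.sequence for r in a.targets] != [r.sequence for r in b.targets]

    def test_members_absent_from_f210_and_controls(self):
        _, truth = simulate_proteome(SimulationConfig(seed=5))
        members = sorted(truth.complex_members)
        assert (truth.abundance.loc[members, "F210"] == 0).all()
        for run in CONTROL_RUNS:
            assert (truth.abundance.loc[members, run] == 0).all()
        assert (truth.abundance.loc[members, "F290"] > 0).all()
        for run in BAIT_RUNS:
            assert (truth.abundance.loc[members, run] > 0).all()

    def test_member_fold_gap_at_least_configured_minimum(self):
        cfg = SimulationConfig(seed=9)
        _, truth = simulate_proteome(cfg)
        members = sorted(truth.complex_members)
        ratio = (
            truth.abundance.loc[members, "F290"] / truth.abundance.loc[members, "F350"]
        )
        assert (ratio >= cfg.fold_gap_range[0] - 1e-9).all()

    def test_background_abundance_matches_lognormal_quantiles(self):
        # distribution-shape check against closed-form log-normal quantiles
        cfg = SimulationConfig(
            n_target_proteins=10_000,
            n_complex_members=0,
            protein_length_range=(40, 50),
            n_shared_segments=0,
            seed=2,
        )
        _, truth = simulate_proteome(cfg)
        sample = truth.abundance["F210"].to_numpy()
        mu, sigma = cfg.background_abundance
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            expected = stats.lognorm.ppf(q, s=sigma, scale=np.exp(mu))
            assert np.quantile(sample, q) == pytest.approx(expected, rel=0.1)

    def test_kr_frequency_near_target(self):
        cfg = SimulationConfig(n_target_proteins=50, n_shared_segments=0, seed=3)
        records, _ = simulate_proteome(cfg)
        residues = "".join(r.sequence for r in records)
        kr = sum(residues.count(a) for a in "KR") / len(residues)
        assert kr == pytest.approx(cfg.kr_frequency, abs=0.01)


class TestRuns:
    def test_decoy_psm_fraction_binomial(self):
        cfg = SimulationConfig(
            n_target_proteins=40, run_depth=1000, decoy_match_rate=0.05, seed=7
        )
        sim = simulate_experiment(cfg)
        frac = 1.0 - sim.psm_tables["F290"]["correct"].mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) <= 3 * se

    def test_all_abundance_on_one_protein(self):
        cfg = SimulationConfig(n_target_proteins=10, run_depth=200, decoy_match_rate=0.0, seed=4)
        sim = simulate_experiment(cfg)
        abundance = {r.accession: 0.0 for r in sim.targets}
        abundance["PROT0000"] = 5.0
        rng = np.random.default_rng(0)
        table = simulate_run(sim.database, abundance, cfg, "solo", rng)
        assert (table["source"] == "PROT0000").all()

    def test_zero_abundance_condition_gives_empty_table(self):
        cfg = SimulationConfig(n_target_proteins=10, run_depth=100, seed=4)
        sim = simulate_experiment(cfg)
        table = simulate_run(
            sim.database,
            {r.accession: 0.0 for r in sim.targets},
            cfg,
            "void",
            np.random.default_rng(0),
        )
        assert table.empty

    def test_dnsaf_tracks_planted_abundance(self):
        # rank correlation between recovered dNSAF and planted abundance
        cfg = SimulationConfig(
            n_target_proteins=50,
            n_complex_members=0,
            run_depth=10_000,
            decoy_match_rate=0.0,
            seed=6,
        )
        sim = simulate_experiment(cfg)
        psms = sim.psms(["F290"])
        mapping = mapping_index(map_peptides({p.peptide for p in psms}, sim.database))
        assign_decoy_status(psms, mapping)
        accepted = filter_psms(psms, mapping).accepted
        proteins = {
            a for a in accept_proteins(accepted, mapping) if not a.startswith("DECOY_")
        }
        spc, u = count_spectra(accepted, mapping, proteins)
        d = distribute_counts(spc, mapping, u)
        dnsaf = compute_dnsaf(d, {r.accession: r.length for r in sim.targets})
        planted = sim.truth.abundance["F290"]
        accs = sorted(proteins)
        rho = stats.spearmanr(
            [dnsaf[a] for a in accs], [planted[a] for a in accs]
        ).statistic
        assert rho >= 0.9

    def test_shared_segments_create_shared_peptides(self):
        cfg = SimulationConfig(n_target_proteins=30, n_shared_segments=15, seed=8)
        records, _ = simulate_proteome(cfg)
        from coenrich.sequence_db import digest

        peps = set()
        shared = False
        for rec in records:
            mine = {dp.sequence for dp in digest(rec, 0) if len(dp.sequence) >= 7}
            if peps & mine:
                shared = True
                break
            peps |= mine
        assert shared


class TestImages:
    def test_planted_extremes(self):
        for p, expect in ((1.0, True), (0.0, False)):
            cfg = ImageSimConfig(n_images=2, n_puncta=50, p_refpos=p, p_refneg=p, seed=1)
            _, truth = simulate_image_set(cfg)
            assert (truth["third_positive"] == expect).all()

    def test_planted_fraction_binomial(self):
        cfg = ImageSimConfig(n_images=1, n_puncta=200, ref_fraction=1.0, p_refpos=0.75, seed=3)
        _, truth = simulate_image_set(cfg)
        realized = truth["third_positive"].mean()
        se = np.sqrt(0.75 * 0.25 / 200)
        assert abs(realized - 0.75) <= 3 * se

    def test_deterministic(self):
        cfg = ImageSimConfig(n_images=1, n_puncta=20, seed=5)
        im1, t1 = simulate_image_set(cfg)
        im2, t2 = simulate_image_set(cfg)
        assert np.array_equal(im1[0]["marker"], im2[0]["marker"])
        pd.testing.assert_frame_equal(t1, t2)

    def test_channels_share_centers(self):
        cfg = ImageSimConfig(n_images=1, n_puncta=30, ref_fraction=1.0, p_refpos=1.0, seed=2)
        images, truth = simulate_image_set(cfg)
        # every marker punctum has reference and third signal at its center
        for _, row in truth.iterrows():
            y, x = int(round(row.y)), int(round(row.x))
            assert images[0]["marker"][y, x] > 1000
            assert images[0]["reference"][y, x] > 1000
            assert images[0]["third"][y, x] > 1000


class TestConfigValidation:
    def test_bad_charge_probabilities(self):
        with pytest.raises(ValueError):
            SimulationConfig(charge_probabilities={1: 0.5, 2: 0.2})

    def test_too_many_members(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_target_proteins=3, n_complex_members=5)
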