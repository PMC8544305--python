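"""The synthetic-study generator: determinism, planted truth, null behaviour."""

import numpy as np
import pytest

from methylaging.simulate import (
    DEFAULT_AGE_GROUPS,
    ReadPatternSet,
    SimulationConfig,
    _latent_fraction,
    simulate_aging_cohort,
    simulate_genome,
    simulate_ir_cohort,
    simulate_read_patterns,
)


class TestConfigValidation:
    def test_zero_samples_rejected(self):
        cfg = SimulationConfig(age_groups=[(61, 0), (122, 6)])
        with pytest.raises(ValueError, match="zero samples"):
            cfg.validate()

    def test_pdr_outside_range_rejected(self):
        cfg = SimulationConfig(pdr_intercept=95.0, pdr_slope=3.0)
        with pytest.raises(ValueError, match="PDR"):
            cfg.validate()

    def test_ir_bins_required_with_effect(self):
        cfg = SimulationConfig(ir_target_bins=[], ir_effect_size=30.0)
        with pytest.raises(ValueError, match="ir_target_bins"):
            cfg.validate()

    @pytest.mark.parametrize("field,value", [("frac_age_sites", 1.5), ("effect_scale", 150.0)])
    def test_fraction_bounds(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestLatentTrajectory:
    def test_configured_slope_arithmetic(self):
        # +0.15 %/day early over the 122 days between the first two ages
        baseline = np.array([10.0])
        change = _latent_fraction(
            baseline, np.array([0.15]), np.array([0.075]), 61, 183, np.array([61.0, 183.0])
        )
        assert 100 * (change[0, 1] - change[0, 0]) == pytest.approx(18.3)

    def test_null_sites_constant(self):
        cfg = SimulationConfig(seed=0, n_sites=50, frac_age_sites=0.0)
        _, truth = simulate_aging_cohort(cfg)
        assert (truth.df["direction"] == 0).all()
        assert (truth.df["slope_early"] == 0).all()
        q = _latent_fraction(
            truth.df["baseline"].to_numpy(),
            truth.df["slope_early"].to_numpy(),
            truth.df["slope_late"].to_numpy(),
            61,
            183,
            np.array([61.0, 426.0]),
        )
        np.testing.assert_allclose(q[:, 0], q[:, 1])

    def test_early_late_ratio_of_slopes(self):
        cfg = SimulationConfig(seed=1, n_sites=500, frac_age_sites=0.1, early_late_rate_ratio=2.0)
        _, truth = simulate_aging_cohort(cfg)
        planted = truth.df[truth.df["direction"] != 0]
        np.testing.assert_allclose(
            planted["slope_early"], 2.0 * planted["slope_late"], rtol=1e-12
        )


class TestAgingCohort:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, n_sites=300)
        d1, t1 = simulate_aging_cohort(cfg)
        d2, t2 = simulate_aging_cohort(cfg)
        np.testing.assert_array_equal(d1.meth, d2.meth)
        np.testing.assert_array_equal(d1.unmeth, d2.unmeth)
        assert t1.df.equals(t2.df)

    def test_study_design_shape(self):
        ds, _ = simulate_aging_cohort(SimulationConfig(seed=0, n_sites=100))
        assert ds.n_samples == sum(n for _, n in DEFAULT_AGE_GROUPS) == 47
        assert ds.samples["batch"].nunique() == 2

    def test_planted_fraction_recovered_by_downstream_correlation(self):
        """Sites with sample Spearman rho > 0.5 match the planted fraction
        within +/-50% (downstream age_association as oracle)."""
        from methylaging.association import site_age_correlation
        from methylaging.preprocess import preprocess_chain

        cfg = SimulationConfig(seed=42, n_sites=8000)
        ds, _ = simulate_aging_cohort(cfg)
        tab = site_age_correlation(preprocess_chain(ds))
        frac = tab["age_associated"].mean()
        assert 0.5 * cfg.frac_age_sites <= frac <= 1.5 * cfg.frac_age_sites

    def test_truth_table_one_record_per_site(self):
        ds, truth = simulate_aging_cohort(SimulationConfig(seed=2, n_sites=250))
        assert len(truth) == ds.n_sites
        assert set(truth.df["direction"].unique()) <= {-1, 0, 1}

    def test_truth_json_roundtrip(self, tmp_path):
        from methylaging.simulate import TruthTable

        _, truth = simulate_aging_cohort(SimulationConfig(seed=3, n_sites=50))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthTable.from_json(path)
        assert list(back.df["direction"]) == list(truth.df["direction"])


class TestIrCohort:
    def test_null_effect_gives_near_zero_dmcs(self):
        from methylaging.ir import call_ir_dmcs

        cfg = SimulationConfig(seed=6, n_sites=2000, ir_effect_size=0.0)
        _, truth = simulate_aging_cohort(cfg)
        ir_ds, truth2 = simulate_ir_cohort(cfg, truth)
        assert not truth2.df["ir_affected"].any()
        dmcs = call_ir_dmcs(ir_ds)
        # q <= 0.01 with a 25% floor: false positives should be essentially absent
        assert len(dmcs["union"]) <= 0.001 * cfg.n_sites

    def test_planted_shift_visible_in_group_means(self):
        cfg = SimulationConfig(
            seed=7, n_sites=1500, ir_effect_size=30.0, frac_ir_sites=0.02
        )
        _, truth = simulate_aging_cohort(cfg)
        ir_ds, truth2 = simulate_ir_cohort(cfg, truth)
        groups = ir_ds.groups()
        pct = ir_ds.percent
        aff = truth2.df["ir_affected"].to_numpy()
        assert aff.sum() >= 10
        control = np.nanmean(pct[aff][:, groups == "control"], axis=1)
        high = np.nanmean(pct[aff][:, groups == "500mGy"], axis=1)
        signs = truth2.df.loc[aff, "ir_dir_500"].to_numpy()
        shift = (high - control) * signs
        assert np.median(shift) > 15  # planted 30-point shift, attenuated by clipping

    def test_affected_sites_come_from_target_bins(self):
        cfg = SimulationConfig(seed=8, n_sites=1500, frac_ir_sites=0.02)
        _, truth = simulate_aging_cohort(cfg)
        _, truth2 = simulate_ir_cohort(cfg, truth)
        hit_bins = set(truth2.df.loc[truth2.df["ir_affected"], "bin"])
        assert hit_bins <= set(cfg.ir_target_bins)

    def test_arm_sizes(self):
        cfg = SimulationConfig(seed=9, n_sites=100)
        _, truth = simulate_aging_cohort(cfg)
        ir_ds, _ = simulate_ir_cohort(cfg, truth)
        assert ir_ds.n_samples == 24
        assert sorted(ir_ds.samples["group"].unique()) == [
            "500mGy",
            "50mGy",
            "5mGy",
            "control",
        ]


class TestReadPatterns:
    def test_flat_model_recovers_intercept(self):
        from methylaging.pdr import pdr_table

        cfg = SimulationConfig(
            seed=10, pdr_slope=0.0, pdr_intercept=20.0, pdr_batch_sd=0.0,
            reads_per_sample=2000,
        )
        pats = simulate_read_patterns(cfg)
        table = pdr_table(pats)
        # binomial error on 2000 reads ~ 0.9 percentage points; allow 4 sd
        assert np.all(np.abs(table["pdr"] - 20.0) < 4.0)

    def test_fully_methylated_reads_have_zero_pdr(self):
        import pandas as pd

        from methylaging.pdr import compute_pdr

        df = pd.DataFrame(
            {"sample_id": "s", "chrom": "chr1", "start": [1, 2, 3], "calls": ["11", "111", "11"]}
        )
        assert compute_pdr(ReadPatternSet(df), "s").pdr == 0.0

    def test_min_one_cpg_per_read(self):
        cfg = SimulationConfig(seed=11, reads_per_sample=500)
        pats = simulate_read_patterns(cfg)
        assert (pats.df["calls"].str.len() >= 1).all()

    def test_tsv_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=12, reads_per_sample=50)
        pats = simulate_read_patterns(cfg)
        path = tmp_path / "patterns.tsv"
        pats.write_tsv(path)
        back = ReadPatternSet.read_tsv(path)
        assert back.df["calls"].tolist() == pats.df["calls"].tolist()


@pytest.fixture(scope="module")
def genome():
    return simulate_genome(SimulationConfig(seed=13, n_sites=1500))


class TestGenome:

    def test_planted_islands_detected(self, genome):
        from methylaging.context import detect_cgi_genome

        detected = detect_cgi_genome(genome.sequences)
        for _, isl in genome.islands.iterrows():
            overlap = detected[
                (detected["chrom"] == isl["chrom"])
                & (detected["end"] > isl["start"])
                & (detected["start"] < isl["end"])
            ]
            assert len(overlap) >= 1

    def test_planted_motifs_present_in_sequence(self, genome):
        from methylaging.simulate import DEFAULT_MOTIFS

        for _, row in genome.motif_instances.iterrows():
            seq = genome.sequences[row["chrom"]][row["start"] : row["end"]]
            assert seq == DEFAULT_MOTIFS[row["motif"]]

    def test_far_from_island_site_is_open_sea(self, genome):
        from methylaging._utils import interval_distance

        for chrom in genome.sequences:
            isl = genome.islands[genome.islands["chrom"] == chrom]
            sub = genome.sites[genome.sites["chrom"] == chrom]
            d = interval_distance(
                sub["pos"].to_numpy() - 1,
                isl["start"].to_numpy(),
                isl["end"].to_numpy(),
            )
            far = d > 4000
            assert (sub.loc[far, "cgi_context"] == "open_sea").all()

    def test_fasta_writable_and_readable(self, genome, tmp_path):
        from Bio import SeqIO

        path = tmp_path / "genome.fa"
        genome.write_fasta(path)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert records == genome.sequences
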