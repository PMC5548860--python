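"""Synthetic-data generator: determinism, truth consistency, and recovery."""

import numpy as np
import pytest

from cfbackground.filtering import FilterConfig, build_pileup, filter_reads
from cfbackground.panel import PanelDefinition
from cfbackground.simulate import (
    SimulationConfig,
    simulate_pair,
    simulate_reads,
    simulate_reference_and_panel,
    simulate_replicates,
    simulate_spikein_series,
    simulate_trio,
)
from cfbackground.sensitivity import DilutionDesign
from cfbackground.panel import HotspotSite


class TestReferenceAndPanel:
    def test_default_cardinalities(self):
        reference, panel = simulate_reference_and_panel(seed=5)
        assert panel.n_genes == 50
        assert panel.n_amplicons == 207
        assert panel.total_bp == 22027
        assert len(panel.hotspots) == 2800

    def test_two_even_amplicons(self):
        reference, panel = simulate_reference_and_panel(
            seed=5, n_genes=2, n_amplicons=2, total_bp=200, n_hotspots=4
        )
        assert [a.length for a in panel.amplicons] == [100, 100]

    def test_same_seed_identical(self):
        ref_a, panel_a = simulate_reference_and_panel(seed=9)
        ref_b, panel_b = simulate_reference_and_panel(seed=9)
        assert ref_a == ref_b
        assert panel_a.amplicons == panel_b.amplicons
        assert panel_a.hotspots == panel_b.hotspots

    def test_different_seed_differs(self):
        ref_a, _ = simulate_reference_and_panel(seed=1)
        ref_b, _ = simulate_reference_and_panel(seed=2)
        assert ref_a != ref_b

    def test_infeasible_partition_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference_and_panel(seed=1, n_genes=2, n_amplicons=10, total_bp=5)

    def test_hotspots_inside_amplicons_with_true_ref(self):
        reference, panel = simulate_reference_and_panel(seed=5)
        for site in panel.hotspots[:100]:
            assert reference[site.contig][site.position] == site.ref_base


@pytest.fixture(scope="module")
def small_world():
    reference, panel = simulate_reference_and_panel(
        seed=13, n_genes=5, n_amplicons=10, total_bp=2000, n_hotspots=100
    )
    return reference, panel


class TestSimulatePair:
    def test_same_seed_identical_profiles(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, mean_depth=5000)
        wbc_a, cf_a, _ = simulate_pair(config, 0, panel, reference)
        wbc_b, cf_b, _ = simulate_pair(config, 0, panel, reference)
        assert wbc_a.positions == wbc_b.positions
        assert cf_a.positions == cf_b.positions

    def test_covers_every_panel_position(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, mean_depth=1000)
        wbc, cf, truth = simulate_pair(config, 0, panel, reference)
        assert len(wbc) == panel.total_bp
        assert len(truth.for_sample(wbc.sample_id)) == panel.total_bp

    def test_shared_weight_one_truths_identical(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, shared_weight=1.0, germline_het_density=0.0)
        wbc, cf, truth = simulate_pair(config, 0, panel, reference)
        t_wbc = truth.for_sample(wbc.sample_id)["true_freq"].to_numpy()
        t_cf = truth.for_sample(cf.sample_id)["true_freq"].to_numpy()
        np.testing.assert_allclose(t_cf, t_wbc)

    def test_shared_weight_zero_truths_uncorrelated(self):
        reference, panel = simulate_reference_and_panel(
            seed=13, n_genes=10, n_amplicons=40, total_bp=20000, n_hotspots=200
        )
        config = SimulationConfig(seed=4, shared_weight=0.0, germline_het_density=0.0)
        wbc, cf, truth = simulate_pair(config, 0, panel, reference)
        t_wbc = truth.for_sample(wbc.sample_id)["true_freq"].to_numpy()
        t_cf = truth.for_sample(cf.sample_id)["true_freq"].to_numpy()
        assert abs(np.corrcoef(t_wbc, t_cf)[0, 1]) < 0.1

    def test_germline_positions_near_half_in_both(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, germline_het_density=0.05, mean_depth=5000)
        wbc, cf, truth = simulate_pair(config, 0, panel, reference)
        germ = truth.for_sample(wbc.sample_id)
        germ = germ[germ["germline"]]
        assert len(germ) > 0
        index = wbc.index()
        for row in germ.itertuples():
            observed = index[(row.contig, row.position)].maf
            assert abs(observed - 0.5) < 0.1

    def test_parameter_recovery_within_three_binomial_se(self, small_world):
        """Estimated MAF sits within 3 binomial SEs of truth for >=99% of
        positions (sequencing error inflates slightly; tolerance covers it)."""
        reference, panel = simulate_reference_and_panel(
            seed=13, n_genes=10, n_amplicons=40, total_bp=20000, n_hotspots=200
        )
        config = SimulationConfig(seed=4, mean_depth=40000)
        wbc, _, truth = simulate_pair(config, 0, panel, reference)
        t = truth.for_sample(wbc.sample_id)
        f = t["true_freq"].to_numpy()
        observed = np.array([p.maf for p in wbc.positions])
        depth = np.array([p.depth for p in wbc.positions])
        # total non-ref truth includes the error inflow
        f_total = f + (1 - f) * config.base_error_rate
        se = np.sqrt(np.maximum(f_total * (1 - f_total), 1e-12) / depth)
        within = np.abs(observed - f_total) <= 3 * se
        assert within.mean() >= 0.99


class TestSimulateReplicates:
    def test_same_truth_different_draws(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, mean_depth=5000)
        rep1, rep2, truth = simulate_replicates(config, panel, reference)
        assert len(truth.entries) == panel.total_bp
        assert rep1.positions != rep2.positions  # independent count draws

    def test_same_seed_identical_first_replicate(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, mean_depth=5000)
        a1, _, _ = simulate_replicates(config, panel, reference)
        b1, _, _ = simulate_replicates(config, panel, reference)
        assert a1.positions == b1.positions

    def test_infinite_depth_limit_approaches_truth(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4, base_error_rate=0.0)
        rep1, _, truth = simulate_replicates(
            config, panel, reference, mean_depth=10**6, base_error_rate=0.0
        )
        f = truth.entries["true_freq"].to_numpy()
        observed = np.array([p.maf for p in rep1.positions])
        assert np.max(np.abs(observed - f)) < 1e-3


class TestSimulateTrio:
    def test_truncal_design_by_construction(self, replica_panel, replica_reference):
        config = SimulationConfig(seed=4, base_error_rate=0.0, mean_depth=100000)
        wbc, cf, s1, s2, truth = simulate_trio(config, replica_panel, replica_reference)
        t = truth.for_sample("trio_tumor1")
        assert (t["origin"].isin(["truncal", "truncal_cf_leak"])).sum() == 6
        assert (t["origin"] == "private1").sum() == 5

    def test_zero_truncal_design(self, replica_panel, replica_reference):
        config = SimulationConfig(seed=4, base_error_rate=0.0, mean_depth=50000)
        *_, truth = simulate_trio(
            config, replica_panel, replica_reference, n_truncal=0, n_cf_detectable=0
        )
        assert (truth.entries["origin"] == "truncal").sum() == 0

    def test_design_larger_than_hotspot_set_rejected(self, small_world):
        reference, panel = small_world
        config = SimulationConfig(seed=4)
        with pytest.raises(ValueError, match="hotspots"):
            simulate_trio(config, panel, reference, n_truncal=200)


class TestSpikeinSeries:
    def _design(self):
        return DilutionDesign(
            variants=(HotspotSite("c", 0, "A", "C"), HotspotSite("c", 1, "A", "G")),
            levels=(0.001, 0.01),
            replicates=5,
            depth=30000,
        )

    def test_same_seed_identical(self):
        config = SimulationConfig(seed=7)
        a = simulate_spikein_series(self._design(), config)
        b = simulate_spikein_series(self._design(), config)
        assert [(m.level, m.replicate, dict(m.column.counts)) for m in a] == [
            (m.level, m.replicate, dict(m.column.counts)) for m in b
        ]

    def test_mean_vaf_near_nominal(self):
        config = SimulationConfig(seed=7)
        measurements = simulate_spikein_series(self._design(), config)
        for level in (0.001, 0.01):
            vafs = [
                m.column.counts.get(m.variant.alt_base, 0) / m.column.depth
                for m in measurements
                if m.level == level
            ]
            se = np.sqrt(level * (1 - level) / 30000 / len(vafs))
            # error inflow adds ~ e/3 to the alternate
            assert abs(np.mean(vafs) - level) <= 3 * se + config.base_error_rate / 3


class TestReadLevelSimulation:
    def test_reads_parse_and_recover_spiked_fraction(self, small_world):
        reference, panel = small_world
        amp = panel.amplicons[0]
        pos = amp.start + 5
        ref_base = reference[amp.contig][pos]
        alt = "A" if ref_base != "A" else "C"
        truth = {(amp.contig, pos): (alt, 0.3)}
        reads = simulate_reads(
            seed=3, panel=panel, reference=reference, truth=truth,
            mean_depth=400, base_error_rate=0.0,
        )
        columns = build_pileup(
            filter_reads(reads, FilterConfig(min_base_quality=0)), panel, reference
        )
        by_key = {(c.contig, c.position): c for c in columns}
        column = by_key[(amp.contig, pos)]
        frac = column.counts.get(alt, 0) / column.depth
        assert abs(frac - 0.3) < 0.1

    def test_sam_roundtrip_through_panel_io(self, small_world, tmp_path):
        from cfbackground.alignments import read_alignments, write_sam

        reference, panel = small_world
        reads = simulate_reads(seed=3, panel=panel, reference=reference, mean_depth=20)
        path = tmp_path / "sim.sam"
        write_sam(reads, reference, path)
        back = list(read_alignments(path, panel, reference))
        assert len(back) == len(reads)
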