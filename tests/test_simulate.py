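"""Gene-drop generator: pedigree construction, transmission, phenotypes,
controls, determinism."""

import numpy as np
import pytest

from founderscan.pedigree import PedigreeError
from founderscan.pipeline import simulate_dataset
from founderscan.simulate import (
    PlantedSpec,
    SimulationConfig,
    add_planted_variant_markers,
    array_subset_indices,
    assign_phenotypes,
    draw_founder_haplotypes,
    gene_drop,
    make_controls,
    make_marker_map,
    plant_risk_haplotype,
    simulate_pedigree,
)


class TestSimulatePedigree:
    def test_default_design_counts(self, dataset_p1):
        ped = dataset_p1.pedigree
        assert len(ped.sampled_ids) == 19
        assert sum(dataset_p1.affected.values()) == len(
            dataset_p1.truth.carrier_set(
                dataset_p1.truth.planted[0], ped.sampled_ids, 0.5
            )
        )

    def test_default_scenario_reaches_seventeen_affected(self):
        cfg = SimulationConfig()  # penetrance 0.8, phenocopy 0.1, matched counts
        ds = simulate_dataset(cfg, seed=1)
        assert ds.phased_panel.n_samples == 19
        assert sum(ds.affected.values()) == 17

    def test_degenerate_generation_count_is_an_error(self):
        with pytest.raises(PedigreeError, match="n_generations"):
            simulate_pedigree(SimulationConfig(n_generations=1), np.random.default_rng(0))

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig()
        p1 = simulate_pedigree(cfg, np.random.default_rng(5))
        p2 = simulate_pedigree(cfg, np.random.default_rng(5))
        assert set(p1.individuals) == set(p2.individuals)
        for ind_id in p1.individuals:
            assert p1.individuals[ind_id] == p2.individuals[ind_id]

    def test_structural_constraints(self):
        cfg = SimulationConfig()
        ped = simulate_pedigree(cfg, np.random.default_rng(3))
        sampled = ped.sampled_ids
        gens = [ped.individuals[s].generation for s in sampled]
        assert all(g >= cfg.n_generations - 1 for g in gens)
        for s in sampled:
            assert ped.founder_ancestry(s)
        for i, a in enumerate(sampled):
            for b in sampled[i + 1 :]:
                assert ped.meiotic_distance(a, b) >= cfg.min_meiotic_distance


def _small_setup(seed, **cfg_kwargs):
    cfg = SimulationConfig(
        chrom_lengths_bp=cfg_kwargs.pop("chrom_lengths_bp", {"1": 20_000_000}),
        **cfg_kwargs,
    )
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(cfg, rng)
    markers, freqs = make_marker_map(cfg, rng)
    founders = draw_founder_haplotypes(ped, markers, freqs, rng)
    return cfg, rng, ped, markers, freqs, founders


class TestGeneDrop:
    def test_no_crossover_no_error_transmits_parental_haplotype_verbatim(self):
        cfg, rng, ped, markers, freqs, founders = _small_setup(
            2, recomb_rate_cm_per_mb=0.0, allele_error_rate=0.0
        )
        panel, truth = gene_drop(ped, founders, markers, cfg, rng)
        hap_lookup = {}
        for fid, (h0, h1) in founders.items():
            hap_lookup[f"{fid}.0"] = h0
            hap_lookup[f"{fid}.1"] = h1
        for si, sample in enumerate(panel.samples):
            for copy in (0, 1):
                mosaic = truth.mosaics[sample][copy]["1"]
                assert len(mosaic) == 1  # zero recombination: single origin
                origin = mosaic[0][2]
                assert (panel.haplotypes[si, copy] == hap_lookup[origin]).all()

    def test_mean_crossovers_match_poisson_expectation(self):
        """100 cM map: mean crossover count over 2,000 meioses ~ 1.0."""
        cfg = SimulationConfig(chrom_lengths_bp={"1": 100_000_000})
        rng = np.random.default_rng(8)
        from founderscan.simulate import _meiosis

        parent = (
            {"1": [(1, 100_000_001, "f.0")]},
            {"1": [(1, 100_000_001, "f.1")]},
        )
        counts = []
        for _ in range(2000):
            mosaic = _meiosis(parent, "1", 100_000_000, cfg, rng)
            counts.append(len(mosaic) - 1)  # breakpoints between alternating origins
        assert np.mean(counts) == pytest.approx(1.0, abs=0.07)

    def test_truth_mosaics_tile_each_chromosome(self, dataset_p1):
        truth = dataset_p1.truth
        for ind, copies in truth.mosaics.items():
            for copy in copies:
                for chrom, segs in copy.items():
                    assert segs[0][0] == 1
                    assert segs[-1][1] == truth.chrom_lengths_bp[chrom] + 1
                    for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
                        assert e1 == s2
                        assert e2 > s2

    def test_dosage_derivable_from_recorded_mosaic(self):
        """Truth-consistency: rebuilding alleles from the mosaic + founder
        haplotypes reproduces the panel exactly when the error rate is 0."""
        cfg, rng, ped, markers, freqs, founders = _small_setup(4, allele_error_rate=0.0)
        panel, truth = gene_drop(ped, founders, markers, cfg, rng)
        hap_lookup = {}
        for fid, (h0, h1) in founders.items():
            hap_lookup[f"{fid}.0"] = h0
            hap_lookup[f"{fid}.1"] = h1
        pos = markers.pos_bp
        for si, sample in enumerate(panel.samples):
            for copy in (0, 1):
                rebuilt = np.zeros(len(markers), dtype=np.int8)
                for s, e, origin in truth.mosaics[sample][copy]["1"]:
                    sel = (pos >= s) & (pos < e)
                    rebuilt[sel] = hap_lookup[origin][sel]
                assert (rebuilt == panel.haplotypes[si, copy]).all()

    def test_byte_identical_repeat_under_same_seed(self):
        def build():
            cfg, rng, ped, markers, freqs, founders = _small_setup(9)
            return gene_drop(ped, founders, markers, cfg, rng)

        p1, t1 = build()
        p2, t2 = build()
        assert (p1.haplotypes == p2.haplotypes).all()
        assert t1.mosaics == t2.mosaics

    def test_empty_marker_map_rejected(self):
        cfg, rng, ped, markers, freqs, founders = _small_setup(1)
        empty = markers.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            gene_drop(ped, founders, empty, cfg, rng)


class TestPlanting:
    def test_planted_length_matches_spec(self, dataset_p1):
        ph = dataset_p1.truth.planted[0]
        assert ph.length_mb == pytest.approx(3.527903)

    def test_backbone_only_plant_yields_no_variants(self):
        cfg, rng, ped, markers, freqs, founders = _small_setup(3)
        spec = PlantedSpec(
            founder_pair="B", chrom="1", start_bp=5_000_000, end_bp=9_000_000, variants=[]
        )
        markers2, freqs2 = add_planted_variant_markers(markers, freqs, [spec])
        ph = plant_risk_haplotype(founders, spec, markers2, freqs2, ped, rng)
        assert ph.variants == {}
        assert len(markers2) == len(markers)

    def test_planted_alt_alleles_exclusive_to_planted_copy(self, dataset_p1):
        """Embedded rare alleles appear on no other founder haplotype and in
        no control genotype."""
        ph = dataset_p1.truth.planted[0]
        markers = dataset_p1.wgs_genotypes.markers
        for mid in ph.variants:
            j = int(np.flatnonzero(markers.ids == mid)[0])
            assert dataset_p1.background_freqs[j] == 0.0
        for ctrl in dataset_p1.controls:
            rv_cols = [
                k
                for k, m in enumerate(ctrl.markers.ids)
                if str(m).startswith("rv_")
            ]
            if rv_cols:
                assert (ctrl.genotypes[:, rv_cols] == 0).all()

    def test_interval_outside_chromosome_rejected(self):
        cfg, rng, ped, markers, freqs, founders = _small_setup(5)
        spec = PlantedSpec(founder_pair="B", chrom="1", start_bp=50_000_000, end_bp=90_000_000)
        with pytest.raises(ValueError, match="outside"):
            plant_risk_haplotype(founders, spec, markers, freqs, ped, rng)


class TestAssignPhenotypes:
    def test_full_penetrance_no_phenocopy_affected_equals_carriers(self, dataset_p1):
        carriers = dataset_p1.truth.carrier_set(
            dataset_p1.truth.planted[0], dataset_p1.pedigree.sampled_ids, 0.5
        )
        affected = {s for s, a in dataset_p1.affected.items() if a}
        assert affected == set(carriers)

    def test_penetrance_calibration_binomial(self):
        """200 replicate assignments of ~10 carriers: affected carrier
        fraction within +-0.08 of the 0.8 penetrance."""
        cfg, rng, ped, markers, freqs, founders = _small_setup(6)
        spec = PlantedSpec(
            founder_pair="B", chrom="1", start_bp=5_000_000, end_bp=9_000_000, variants=[]
        )
        ph = plant_risk_haplotype(founders, spec, markers, freqs, ped, rng)
        from founderscan.simulate import lineage_forced_transmissions

        targets = [s for s in ped.sampled_ids if "B" in ped.founder_ancestry(s)]
        forced = lineage_forced_transmissions(ped, ph, targets)
        panel, truth = gene_drop(
            ped, founders, markers, cfg, rng, forced_transmissions=forced, planted=[ph]
        )
        carriers = truth.carrier_set(ph, ped.sampled_ids, 0.5)
        cfg_pen = SimulationConfig(penetrance=0.8, phenocopy_rate=0.0, match_design_counts=False)
        frac = []
        for rep in range(200):
            affected = assign_phenotypes(ped, truth, cfg_pen, np.random.default_rng(rep))
            frac.append(np.mean([affected[c] for c in carriers]))
        assert np.mean(frac) == pytest.approx(0.8, abs=0.08)

    def test_phenotype_vector_deterministic(self, dataset_p1):
        cfg = SimulationConfig(penetrance=1.0, phenocopy_rate=0.0)
        a1 = assign_phenotypes(
            dataset_p1.pedigree, dataset_p1.truth, cfg, np.random.default_rng(77)
        )
        a2 = assign_phenotypes(
            dataset_p1.pedigree, dataset_p1.truth, cfg, np.random.default_rng(77)
        )
        assert a1 == a2


class TestControls:
    def test_default_cohort_sizes_sum_to_91(self, dataset_p1):
        sizes = [c.n_samples for c in dataset_p1.controls]
        assert sizes == [49, 42]
        assert sum(sizes) == 91

    def test_zero_controls_gives_empty_panel(self):
        cfg, rng, ped, markers, freqs, founders = _small_setup(7)
        arr = array_subset_indices(markers, cfg, freqs)
        panels = make_controls(markers, arr, freqs, (0,), rng)
        assert panels[0].n_samples == 0

    def test_empty_array_subset_rejected(self):
        cfg, rng, ped, markers, freqs, founders = _small_setup(7)
        with pytest.raises(ValueError, match="empty"):
            make_controls(markers, np.array([], dtype=int), freqs, (5,), rng)

    def test_array_subset_density(self, dataset_p1):
        cfg = dataset_p1.config
        per_mb = len(dataset_p1.array_indices) / (
            sum(cfg.chrom_lengths_bp.values()) / 1e6
        )
        assert per_mb == pytest.approx(cfg.array_markers_per_mb, rel=0.15)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(penetrance=0.9, chrom_lengths_bp={"7": 12_000_000})
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == cfg

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(penetrance=1.5)
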