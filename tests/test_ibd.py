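"""IBD detection: LOD scoring, seed-and-extend recovery, relatedness."""

import math

import numpy as np
import pandas as pd
import pytest

from founderscan.ibd import (
    IBDParams,
    IBDSegment,
    ibd_copy_number,
    lod_score,
    pairwise_ibd,
    relatedness_degree,
)
from founderscan.markers import MarkerMap
from founderscan.panels import PhasedPanel
from founderscan.pedigree import Individual, Pedigree
from founderscan.simulate import SimulationConfig, draw_founder_haplotypes, gene_drop, make_marker_map


def direct_site_lod(a: int, b: int, f: float, eps: float) -> float:
    """Oracle: evaluate the per-site likelihood ratio from its definition."""
    freqs = {1: f, 0: 1 - f}

    def q(x, c):
        return 1 - eps if x == c else eps

    p_ibd = sum(freqs[c] * q(a, c) * q(b, c) for c in (0, 1))
    p_null = freqs[a] * freqs[b]
    return math.log10(p_ibd / p_null)


class TestLodScore:
    def test_shared_rare_allele_closed_form(self):
        # both alt, f = 0.1, eps -> 0: ratio = f / f^2 = 1/f, log10 = 1
        a = np.array([1], dtype=np.int8)
        b = np.array([1], dtype=np.int8)
        got = lod_score(a, b, np.array([0.1]), epsilon=1e-12)
        assert got == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("a,b,f", [(0, 1, 0.3), (1, 0, 0.1), (1, 1, 0.4), (0, 0, 0.25)])
    def test_matches_direct_evaluation(self, a, b, f):
        eps = 0.0025
        got = lod_score(np.array([a], dtype=np.int8), np.array([b], dtype=np.int8), np.array([f]), eps)
        assert got == pytest.approx(direct_site_lod(a, b, f, eps), abs=1e-12)

    def test_additive_over_sites(self, rng):
        n = 50
        a = rng.integers(0, 2, n).astype(np.int8)
        b = rng.integers(0, 2, n).astype(np.int8)
        f = rng.uniform(0.05, 0.95, n)
        total = lod_score(a, b, f, 0.0025)
        singles = sum(
            lod_score(a[i : i + 1], b[i : i + 1], f[i : i + 1], 0.0025) for i in range(n)
        )
        assert total == pytest.approx(singles, abs=1e-9)

    def test_mismatch_decreases_score(self):
        a = np.ones(10, dtype=np.int8)
        b = np.ones(10, dtype=np.int8)
        f = np.full(10, 0.2)
        base = lod_score(a, b, f, 0.0025)
        b2 = b.copy()
        b2[5] = 0
        assert lod_score(a, b2, f, 0.0025) < base

    def test_degenerate_frequency_site_skipped_with_warning(self):
        a = np.array([1, 1], dtype=np.int8)
        b = np.array([1, 1], dtype=np.int8)
        f = np.array([0.0, 0.2])
        with pytest.warns(UserWarning, match="frequency"):
            got = lod_score(a, b, f, 0.0025)
        assert got == pytest.approx(direct_site_lod(1, 1, 0.2, 0.0025))

    def test_interval_bounds_checked(self):
        a = np.ones(5, dtype=np.int8)
        with pytest.raises(IndexError):
            lod_score(a, a, np.full(5, 0.3), 0.0025, interval=(0, 9))


class TestSegmentInvariants:
    def test_segment_validation(self):
        with pytest.raises(ValueError):
            IBDSegment("a", 0, "b", 0, "1", 100, 100, 5, 4.0)
        with pytest.raises(ValueError):
            IBDSegment("a", 0, "b", 0, "1", 100, 200, 1, 4.0)
        with pytest.raises(ValueError):
            IBDSegment("a", 0, "b", 0, "1", 100, 200, 5, float("inf"))

    def test_unphased_like_input_rejected(self):
        m = MarkerMap(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos_bp": [1, 2],
                    "pos_cm": [1e-6, 2e-6],
                    "ref": "A",
                    "alt": "G",
                    "id": ["a", "b"],
                }
            )
        )
        panel = PhasedPanel(m, ["s"], np.zeros((1, 2, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="two individuals"):
            pairwise_ibd(panel)


def _sib_dataset(seed, allele_error=0.0):
    """Two full sibs below one couple, one 50 Mb chromosome."""
    cfg = SimulationConfig(
        chrom_lengths_bp={"1": 50_000_000},
        allele_error_rate=allele_error,
        n_sampled=2,
        n_affected=0,
    )
    ped = Pedigree(
        [
            Individual("f", sex="male"),
            Individual("m", sex="female"),
            Individual("s1", "f", "m", "male", 1, sampled=True),
            Individual("s2", "f", "m", "female", 1, sampled=True),
        ],
        {"A": ("f", "m")},
    )
    rng = np.random.default_rng(seed)
    markers, freqs = make_marker_map(cfg, rng)
    founders = draw_founder_haplotypes(ped, markers, freqs, rng)
    panel, truth = gene_drop(ped, founders, markers, cfg, rng)
    return panel, truth


def true_shared_intervals(truth, id_a, id_b, chrom):
    """Oracle: same-founder-origin overlap of two individuals' mosaics."""
    out = []
    for ha in (0, 1):
        for hb in (0, 1):
            for s1, e1, o1 in truth.mosaics[id_a][ha][chrom]:
                for s2, e2, o2 in truth.mosaics[id_b][hb][chrom]:
                    if o1 == o2 and min(e1, e2) > max(s1, s2):
                        out.append((ha, hb, max(s1, s2), min(e1, e2)))
    return out


class TestPairwiseIbdRecovery:
    def test_sib_blocks_recovered_error_free(self):
        """Each true shared block > 2 Mb is covered >= 95% by one segment."""
        panel, truth = _sib_dataset(seed=3)
        segments = pairwise_ibd(panel)
        for ha, hb, s, e in true_shared_intervals(truth, "s1", "s2", "1"):
            if e - s < 2_000_000:
                continue
            covering = [
                seg
                for seg in segments
                if seg.hap_a == ha and seg.hap_b == hb
                and min(seg.end_bp, e) - max(seg.start_bp, s) >= 0.95 * (e - s)
            ]
            assert len(covering) == 1, (s, e)

    def test_short_true_segments_filtered_by_length(self):
        panel, _ = _sib_dataset(seed=5)
        params = IBDParams(min_length_bp=10**9)  # nothing is this long
        assert pairwise_ibd(panel, params) == []

    def test_emitted_segments_respect_thresholds(self):
        panel, _ = _sib_dataset(seed=9, allele_error=0.001)
        params = IBDParams()
        for seg in pairwise_ibd(panel, params):
            assert seg.length_bp > params.min_length_bp
            assert seg.lod > params.min_lod
            assert seg.n_markers >= 2

    def test_no_false_positives_on_unrelated_haplotypes(self):
        """i.i.d. haplotypes at 2,000 markers: no segments in >= 95% of seeds."""
        m = MarkerMap(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos_bp": np.arange(1, 2001) * 10_000,
                    "pos_cm": np.arange(1, 2001) * 0.01,
                    "ref": "A",
                    "alt": "G",
                    "id": [f"m{i}" for i in range(2000)],
                }
            )
        )
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            f = r.uniform(0.05, 0.5, 2000)
            h = (r.random((4, 2, 2000)) < f).astype(np.int8)
            panel = PhasedPanel(m, [f"s{i}" for i in range(4)], h)
            if not pairwise_ibd(panel):
                clean += 1
        assert clean >= 0.95 * n_seeds


class TestCopyNumber:
    def test_no_overlap_is_zero(self):
        assert ibd_copy_number("x", {("a", 0), ("b", 1), ("c", 0)}) == 0

    def test_both_copies_is_two(self):
        assert ibd_copy_number("a", {("a", 0), ("a", 1), ("b", 0)}) == 2

    def test_single_copy_is_one(self):
        assert ibd_copy_number("a", {("a", 1), ("b", 0), ("c", 0)}) == 1


def _cousin_pedigree(degree_meioses=8):
    """Two individuals separated by `degree_meioses` meioses via one couple."""
    half = degree_meioses // 2
    inds = [Individual("F", sex="male"), Individual("M", sex="female")]
    sampled = []
    for branch in ("L", "R"):
        prev = ("F", "M")
        for g in range(1, half + 1):
            ind_id = f"{branch}{g}"
            spouse = f"{branch}{g}x"
            inds.append(Individual(ind_id, prev[0], prev[1], "male", g, sampled=(g == half)))
            if g < half:
                inds.append(Individual(spouse, sex="female"))
                prev = (ind_id, spouse)
        sampled.append(f"{branch}{half}")
    return Pedigree(inds, {"A": ("F", "M")}), sampled


class TestRelatednessDegree:
    def test_no_segments_is_unrelated(self):
        kin, label = relatedness_degree([], 3_000_000_000)
        assert kin == 0.0 and label == "unrelated"

    def test_full_genome_ibd2_is_duplicate(self):
        g = 100_000_000
        segs = [
            IBDSegment("a", 0, "b", 0, "1", 1, g, 100, 50.0),
            IBDSegment("a", 1, "b", 1, "1", 1, g, 100, 50.0),
        ]
        kin, label = relatedness_degree(segs, g)
        assert kin == pytest.approx(0.5)
        assert label == "duplicate/MZ"

    def test_half_genome_ibd1_is_first_degree(self):
        g = 100_000_000
        segs = [IBDSegment("a", 0, "b", 0, "1", 1, g, 100, 50.0)]
        kin, label = relatedness_degree(segs, g)
        assert kin == pytest.approx(0.25)
        assert label == "1st degree"

    def test_simulated_third_cousins_within_one_degree(self):
        """20 gene-drop replicates over a 3 Gb genome; truth is degree 7
        (kinship 2^-8 through the shared couple)."""
        cfg = SimulationConfig(
            chrom_lengths_bp={str(c): 100_000_000 for c in range(1, 31)},
            wgs_markers_per_mb=0.2,
            n_sampled=2,
            n_affected=0,
        )
        genome = sum(cfg.chrom_lengths_bp.values())
        degrees = []
        for seed in range(20):
            ped, (a, b) = _cousin_pedigree(8)
            r = np.random.default_rng(500 + seed)
            markers, freqs = make_marker_map(cfg, r)
            founders = draw_founder_haplotypes(ped, markers, freqs, r)
            _panel, truth = gene_drop(ped, founders, markers, cfg, r)
            segs = []
            for chrom in cfg.chrom_lengths_bp:
                for ha, hb, s, e in true_shared_intervals(truth, a, b, chrom):
                    if e - s > 1000:
                        segs.append(IBDSegment(a, ha, b, hb, chrom, s, e, 2, 9.9))
            kin, _ = relatedness_degree(segs, genome)
            degrees.append(99 if kin == 0 else round(-math.log2(kin) - 1))
        assert abs(float(np.median(degrees)) - 7) <= 1

    def test_mixed_pairs_rejected(self):
        segs = [
            IBDSegment("a", 0, "b", 0, "1", 1, 10**7, 10, 9.0),
            IBDSegment("a", 0, "c", 0, "1", 1, 10**7, 10, 9.0),
        ]
        with pytest.raises(ValueError, match="pair"):
            relatedness_degree(segs, 10**8)
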