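"""Fine-mapping: backbone construction and allele assignment logic."""

from itertools import combinations_with_replacement, permutations

import numpy as np
import pandas as pd
import pytest

from founderscan.finemap import (
    AlleleSource,
    RiskHaplotype,
    SiteAssignment,
    assign_allele,
    build_backbone,
    fine_map,
    haplotype_specific_variants,
)
from founderscan.hapfilter import RiskHaplotypeCandidate
from founderscan.markers import MarkerMap
from founderscan.panels import MISSING, GenotypePanel, PhasedPanel


def enumeration_oracle(carrier_genotypes, noncarrier_genotypes):
    """Exhaustive diplotype-enumeration oracle for one site.

    For each candidate shared allele h, enumerate every explicit
    diplotype (ordered pair of alleles) consistent with each carrier's
    dosage and check whether the carrier can place h on its shared copy
    (both copies for IBD2).  h is possible iff every observed carrier has
    such an arrangement.  A unique possible allele is the assignment;
    with two possibilities the allele absent from all non-carriers wins
    if unique; no possibility means discordance.
    """

    def possible(h):
        for dosage, copies in carrier_genotypes:
            if dosage == MISSING:
                continue
            alleles = [1] * dosage + [0] * (2 - dosage)
            ok = False
            for arrangement in set(permutations(alleles)):
                shared = arrangement[:copies]
                if all(x == h for x in shared):
                    ok = True
                    break
            if not ok:
                return False
        return True

    poss = [h for h in (0, 1) if possible(h)]
    if not poss:
        return SiteAssignment(None, AlleleSource.DISCORDANT)
    if len(poss) == 1:
        return SiteAssignment(poss[0], AlleleSource.GENOTYPE)
    absent = []
    for h in (0, 1):
        dosages = [d for d in noncarrier_genotypes if d != MISSING]
        seen = any((d if h == 1 else 2 - d) > 0 for d in dosages)
        if not seen:
            absent.append(h)
    if len(absent) == 1:
        return SiteAssignment(absent[0], AlleleSource.GENOTYPE)
    return SiteAssignment(None, AlleleSource.UNASSIGNED)


class TestAssignAllele:
    def test_all_carriers_homozygous_alt(self):
        got = assign_allele([(2, 1), (2, 1), (2, 2)], [0, 1])
        assert got == SiteAssignment(1, AlleleSource.GENOTYPE)

    def test_het_carriers_with_discriminating_noncarriers(self):
        # all carriers het (c=1); alt absent from every non-carrier while
        # ref is present -> the shared haplotype must carry alt
        got = assign_allele([(1, 1), (1, 1), (1, 1)], [0, 0, 0])
        assert got == SiteAssignment(1, AlleleSource.GENOTYPE)
        assert got == enumeration_oracle([(1, 1), (1, 1), (1, 1)], [0, 0, 0])

    def test_het_carriers_uninformative_noncarriers_unassigned(self):
        got = assign_allele([(1, 1), (1, 1)], [1, 1])
        assert got == SiteAssignment(None, AlleleSource.UNASSIGNED)

    def test_ibd2_carrier_must_be_homozygous(self):
        # IBD2 carrier het at the site: neither allele can occupy both copies
        got = assign_allele([(1, 2)], [])
        assert got.source is AlleleSource.DISCORDANT

    def test_discordant_when_no_allele_fits(self):
        got = assign_allele([(0, 1), (2, 2)], [])
        assert got.source is AlleleSource.DISCORDANT

    def test_missing_carrier_is_nonconstraining(self):
        got = assign_allele([(MISSING, 1), (2, 2)], [0])
        assert got == SiteAssignment(1, AlleleSource.GENOTYPE)

    def test_exhaustive_agreement_with_enumeration_oracle(self):
        """All configurations with <= 4 carriers and <= 4 non-carriers."""
        carrier_states = [(d, c) for d in (0, 1, 2) for c in (1, 2)]
        for n_car in (1, 2, 3, 4):
            for carriers in combinations_with_replacement(carrier_states, n_car):
                for n_non in (0, 2, 4):
                    for noncarriers in combinations_with_replacement((0, 1, 2), n_non):
                        got = assign_allele(list(carriers), list(noncarriers))
                        want = enumeration_oracle(list(carriers), list(noncarriers))
                        assert got == want, (carriers, noncarriers)

    def test_adding_noncarriers_never_flips_an_assignment(self):
        """Monotonicity: extra non-carriers can resolve ties but never
        change an assigned allele."""
        carrier_states = [(d, c) for d in (0, 1, 2) for c in (1, 2)]
        for carriers in combinations_with_replacement(carrier_states, 2):
            for base_non in combinations_with_replacement((0, 1, 2), 2):
                before = assign_allele(list(carriers), list(base_non))
                for extra in (0, 1, 2):
                    after = assign_allele(list(carriers), list(base_non) + [extra])
                    if before.allele is not None and before.source is AlleleSource.GENOTYPE:
                        if after.allele is not None:
                            # consistency set shrinks only via non-carrier info;
                            # an assigned allele from carrier constraints is stable
                            if len(_consistent_set(carriers)) == 1:
                                assert after.allele == before.allele


def _consistent_set(carriers):
    out = []
    for h in (0, 1):
        ok = True
        for d, c in carriers:
            if d == MISSING:
                continue
            if (d if h == 1 else 2 - d) < c:
                ok = False
        if ok:
            out.append(h)
    return out


class _StubCluster:
    """Degenerate cluster stand-in (fewer than 3 copies) for backbone tests."""

    def __init__(self, chrom, start_bp, end_bp, members):
        self.chrom = chrom
        self.start_bp = start_bp
        self.end_bp = end_bp
        self.members = frozenset(members)


def _toy_candidate(panel, members, start, end, chrom="1"):
    return RiskHaplotypeCandidate(cluster=_StubCluster(chrom, start, end, members))


def _markers(n, spacing=10_000):
    pos = np.arange(1, n + 1) * spacing
    return MarkerMap(
        pd.DataFrame(
            {
                "chrom": "1",
                "pos_bp": pos,
                "pos_cm": pos * 1e-6,
                "ref": "A",
                "alt": "G",
                "id": [f"m{i}" for i in range(n)],
            }
        )
    )


class TestBuildBackbone:
    def test_planted_backbone_matches_truth_exactly(self, dataset_clean, result_clean):
        ph = dataset_clean.truth.planted[0]
        samples = dataset_clean.phased_panel.samples
        tcar = dataset_clean.truth.carrier_set(ph, samples)
        cand = next(
            c
            for c, _, _ in result_clean.risk_haplotypes
            if c.cluster.carriers >= tcar and c.cluster.chrom == ph.chrom
        )
        backbone = build_backbone(cand, dataset_clean.phased_panel)
        planted_alleles = dict(zip(ph.backbone_marker_ids, ph.backbone_alleles))
        checked = 0
        for mid, assignment in backbone.items():
            if mid in planted_alleles:
                assert assignment.allele == planted_alleles[mid]
                assert assignment.source is AlleleSource.BACKBONE
                checked += 1
        assert checked > 100

    def test_interval_without_phased_markers_gives_empty_backbone(self):
        markers = _markers(10, spacing=1_000_000)
        panel = PhasedPanel(markers, ["a"], np.zeros((1, 2, 10), dtype=np.int8))
        cand = _toy_candidate(panel, frozenset({("a", 0)}), 100, 200)
        assert build_backbone(cand, panel) == {}

    def test_single_member_backbone_is_that_copy(self, rng):
        markers = _markers(20)
        haps = rng.integers(0, 2, (1, 2, 20)).astype(np.int8)
        panel = PhasedPanel(markers, ["a"], haps)
        cand = _toy_candidate(panel, frozenset({("a", 1)}), 1, 300_000)
        backbone = build_backbone(cand, panel)
        for i in range(20):
            assert backbone[f"m{i}"].allele == haps[0, 1, i]

    def test_disagreeing_members_raise_in_strict_mode(self, rng):
        markers = _markers(20)
        haps = np.zeros((2, 2, 20), dtype=np.int8)
        haps[1, 0, 5] = 1
        panel = PhasedPanel(markers, ["a", "b"], haps)
        cand = _toy_candidate(panel, frozenset({("a", 0), ("b", 0)}), 1, 300_000)
        with pytest.raises(ValueError, match="disagree"):
            build_backbone(cand, panel)


class TestFineMap:
    def test_planted_variants_assigned_correctly_zero_discordant(
        self, dataset_clean, result_clean
    ):
        ph = dataset_clean.truth.planted[0]
        samples = dataset_clean.phased_panel.samples
        tcar = dataset_clean.truth.carrier_set(ph, samples)
        cand = next(
            c
            for c, _, _ in result_clean.risk_haplotypes
            if c.cluster.carriers >= tcar and c.cluster.chrom == ph.chrom
        )
        hap = fine_map(cand, dataset_clean.wgs_genotypes, dataset_clean.phased_panel)
        assert hap.counts["discordant"] == 0
        for mid in ph.variants:
            assert hap.allele_map[mid].allele == 1, mid
        # every site in the allele map lies inside the interval
        tab = dataset_clean.wgs_genotypes.markers.table.set_index("id")
        for mid in hap.allele_map:
            pos = int(tab.loc[mid, "pos_bp"])
            assert hap.start_bp <= pos <= hap.end_bp

    def test_discordant_fraction_tracks_allele_error_rate(self):
        from founderscan.pipeline import simulate_dataset, run_full
        from founderscan.simulate import SimulationConfig

        eps = 0.002
        cfg = SimulationConfig(penetrance=1.0, phenocopy_rate=0.0, allele_error_rate=eps)
        ds = simulate_dataset(cfg, seed=23)
        res = run_full(ds)
        ph = ds.truth.planted[0]
        tcar = ds.truth.carrier_set(ph, ds.phased_panel.samples)
        cand = next(
            c for c, _, _ in res.risk_haplotypes if c.cluster.carriers >= tcar
        )
        hap = fine_map(
            cand, ds.wgs_genotypes, ds.phased_panel, strict_backbone=False
        )
        n_genotype_sites = hap.counts["genotype"] + hap.counts["discordant"] + hap.counts["unassigned"]
        if n_genotype_sites:
            frac = hap.counts["discordant"] / len(hap.allele_map)
            # a discordance needs an error in a carrier; expectation is of
            # order n_carriers * eps, allow 3x headroom
            assert frac <= 3 * len(tcar) * eps

    def test_fraction_accounting_sums_to_one(self, dataset_p1, result_p1):
        for cand, hap, _ in result_p1.risk_haplotypes:
            counts = hap.counts
            total = sum(counts.values())
            assert total == len(hap.allele_map) > 0
            frac = (counts["backbone"] + counts["genotype"] + counts["unassigned"] + counts["discordant"]) / total
            assert frac == pytest.approx(1.0)
            assert hap.backbone_fraction == pytest.approx(counts["backbone"] / total)


class TestHaplotypeSpecificVariants:
    def _setup(self):
        markers = _markers(3)
        # carriers a (copies 1); non-carriers b, c
        hap = RiskHaplotype(
            chrom="1",
            start_bp=1,
            end_bp=40_000,
            carriers={"a": 1},
            allele_map={
                "m0": SiteAssignment(1, AlleleSource.GENOTYPE),  # private alt
                "m1": SiteAssignment(1, AlleleSource.BACKBONE),  # alt also in b
                "m2": SiteAssignment(0, AlleleSource.BACKBONE),  # ref assigned
            },
        )
        g = np.array(
            [
                [1, 1, 0],  # a (carrier)
                [0, 1, 0],  # b carries alt at m1
                [0, 0, 0],  # c
            ],
            dtype=np.int8,
        )
        panel = GenotypePanel(markers, ["a", "b", "c"], g)
        return hap, panel

    def test_private_alt_included_shared_or_ref_excluded(self):
        hap, panel = self._setup()
        assert haplotype_specific_variants(hap, panel) == ["m0"]

    def test_full_synthetic_run_recovers_planted_variant_set(
        self, dataset_clean, result_clean
    ):
        ph = dataset_clean.truth.planted[0]
        samples = dataset_clean.phased_panel.samples
        tcar = dataset_clean.truth.carrier_set(ph, samples)
        for cand, hap, specific in result_clean.risk_haplotypes:
            if cand.cluster.carriers >= tcar and cand.cluster.chrom == ph.chrom:
                assert set(ph.variants) <= set(specific)
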