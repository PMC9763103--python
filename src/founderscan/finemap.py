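"""Fine-mapping: full allele sequence of a risk haplotype.

The backbone comes from the phased data: over the refined interval the
member haplotype copies are mutually identical, so each phased marker
directly contributes its allele.  Sites present only in the dense WGS
genotype data are then assigned by contrasting carrier genotypes
(respecting each carrier's copy number — an IBD2 carrier must be
homozygous for the haplotype allele) against the genotypes of pedigree
individuals who do not carry the haplotype.  Where the genotype
configurations do not pin down a unique allele the site is left
explicitly unassigned — never guessed — and sites no allele can explain
are flagged discordant (likely genotyping error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .hapfilter import RiskHaplotypeCandidate
from .panels import MISSING, GenotypePanel, PhasedPanel


class AlleleSource(str, Enum):
    BACKBONE = "backbone"
    GENOTYPE = "genotype"
    UNASSIGNED = "unassigned"
    DISCORDANT = "discordant"


@dataclass(frozen=True)
class SiteAssignment:
    allele: int | None  # 0 ref, 1 alt, None when unassigned/discordant
    source: AlleleSource


@dataclass
class RiskHaplotype:
    """A fine-mapped risk haplotype.

    ``allele_map`` maps marker id -> :class:`SiteAssignment` for every
    marker in the interval on the WGS marker set.
    """

    chrom: str
    start_bp: int
    end_bp: int
    carriers: dict  # individual id -> copy number (1 = IBD1, 2 = IBD2)
    allele_map: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        c = {s: 0 for s in AlleleSource}
        for a in self.allele_map.values():
            c[a.source] += 1
        return {s.value: n for s, n in c.items()}

    @property
    def backbone_fraction(self) -> float:
        n = len(self.allele_map)
        return self.counts["backbone"] / n if n else 0.0


def build_backbone(
    candidate: RiskHaplotypeCandidate, phased_panel: PhasedPanel, strict: bool = True
) -> dict:
    """Allele map contributions from the phased backbone markers.

    Every interval marker present in the phased panel gets the allele
    carried by the member haplotype copies.  A disagreement among
    non-missing members means the refinement contract was violated:
    ``strict`` raises, otherwise (data with residual phasing/genotyping
    error) the majority allele is taken and exact ties are left to the
    genotype-assignment stage.
    """
    start, end = candidate.interval
    idx = phased_panel.markers.interval_indices(candidate.cluster.chrom, start, end)
    rows = np.stack(
        [phased_panel.haplotype(ind, h)[idx] for ind, h in sorted(candidate.cluster.members)]
    )
    nonmissing = rows != MISSING
    lo = np.where(nonmissing, rows, 2).min(axis=0)
    hi = np.where(nonmissing, rows, -1).max(axis=0)
    observed = nonmissing.any(axis=0)
    disagree = observed & (lo != hi)
    if disagree.any() and strict:
        bad = phased_panel.markers.ids[idx[np.flatnonzero(disagree)[:5]]]
        raise ValueError(
            f"member haplotypes disagree at backbone marker(s) {list(bad)}; "
            "refine boundaries before building the backbone"
        )
    n_alt = np.where(nonmissing, rows, 0).sum(axis=0)
    n_obs = nonmissing.sum(axis=0)
    out = {}
    ids = phased_panel.markers.ids[idx]
    for k, marker_id in enumerate(ids):
        if not observed[k]:
            continue
        if not disagree[k]:
            out[marker_id] = SiteAssignment(int(hi[k]), AlleleSource.BACKBONE)
        elif 2 * n_alt[k] != n_obs[k]:  # majority consensus, ties skipped
            out[marker_id] = SiteAssignment(int(2 * n_alt[k] > n_obs[k]), AlleleSource.BACKBONE)
    return out


def assign_allele(
    carrier_genotypes: list[tuple[int, int]],
    noncarrier_genotypes: list[int],
) -> SiteAssignment:
    """Assign the haplotype allele at one biallelic site from genotypes.

    ``carrier_genotypes`` is a list of (alt dosage, copy number) pairs,
    copy number in {1, 2}; ``noncarrier_genotypes`` a list of alt
    dosages.  Missing dosages (-1) make that individual
    non-constraining.

    An allele x is consistent iff every observed carrier has
    dosage(x) >= its copy number.  A unique consistent allele is
    assigned; if both are consistent, the allele absent from every
    non-carrier is assigned when exactly one such allele exists;
    otherwise the site is unassigned.  No consistent allele means a
    discordant site.
    """
    consistent = []
    for allele in (0, 1):
        ok = True
        for dosage, copies in carrier_genotypes:
            if dosage == MISSING:
                continue
            if copies not in (1, 2):
                raise ValueError(f"carrier copy number must be 1 or 2, got {copies}")
            d = dosage if allele == 1 else 2 - dosage
            if d < copies:
                ok = False
                break
        if ok:
            consistent.append(allele)
    if not consistent:
        return SiteAssignment(None, AlleleSource.DISCORDANT)
    if len(consistent) == 1:
        return SiteAssignment(consistent[0], AlleleSource.GENOTYPE)
    absent = []
    for allele in (0, 1):
        seen = any(
            (d if allele == 1 else 2 - d) > 0
            for d in noncarrier_genotypes
            if d != MISSING
        )
        if not seen:
            absent.append(allele)
    if len(absent) == 1:
        return SiteAssignment(absent[0], AlleleSource.GENOTYPE)
    return SiteAssignment(None, AlleleSource.UNASSIGNED)


def fine_map(
    candidate: RiskHaplotypeCandidate,
    wgs_genotypes: GenotypePanel,
    phased_panel: PhasedPanel,
    copy_numbers: dict | None = None,
    strict_backbone: bool = True,
) -> RiskHaplotype:
    """Fine-map a candidate: phased backbone first, then genotype contrast.

    ``copy_numbers`` optionally overrides the per-carrier copy number
    derived from the cluster membership (IBD2 carriers contribute both
    haplotype copies).
    """
    start, end = candidate.interval
    chrom = candidate.cluster.chrom
    idx = wgs_genotypes.markers.interval_indices(chrom, start, end)
    if idx.size == 0:
        raise ValueError("candidate interval contains no WGS markers")
    if copy_numbers is None:
        copy_numbers = {}
        for ind, _h in candidate.cluster.members:
            copy_numbers[ind] = copy_numbers.get(ind, 0) + 1
    carriers = sorted(copy_numbers)
    noncarriers = [s for s in wgs_genotypes.samples if s not in copy_numbers]

    allele_map = build_backbone(candidate, phased_panel, strict=strict_backbone)
    hap = RiskHaplotype(
        chrom=chrom, start_bp=start, end_bp=end, carriers=dict(copy_numbers)
    )
    carrier_rows = [wgs_genotypes.sample_index(s) for s in carriers]
    noncarrier_rows = [wgs_genotypes.sample_index(s) for s in noncarriers]
    ids = wgs_genotypes.markers.ids[idx]
    for k, marker_id in zip(idx, ids):
        if marker_id in allele_map:
            hap.allele_map[marker_id] = allele_map[marker_id]
            continue
        cg = [(int(wgs_genotypes.genotypes[r, k]), copy_numbers[s]) for r, s in zip(carrier_rows, carriers)]
        ng = [int(wgs_genotypes.genotypes[r, k]) for r in noncarrier_rows]
        hap.allele_map[marker_id] = assign_allele(cg, ng)
    return hap


def haplotype_specific_variants(
    risk_haplotype: RiskHaplotype,
    pedigree_genotypes: GenotypePanel,
) -> list[str]:
    """Markers whose assigned haplotype allele is alt and private.

    Private: the alt allele has dosage 0 in every sampled pedigree
    individual outside the carrier set.  Returns marker ids.
    """
    carrier_set = set(risk_haplotype.carriers)
    outside_rows = [
        pedigree_genotypes.sample_index(s)
        for s in pedigree_genotypes.samples
        if s not in carrier_set
    ]
    lookup = {m: k for k, m in enumerate(pedigree_genotypes.markers.ids)}
    out = []
    for marker_id, assignment in risk_haplotype.allele_map.items():
        if assignment.allele != 1:
            continue
        k = lookup.get(marker_id)
        if k is None:
            continue
        dosages = pedigree_genotypes.genotypes[outside_rows, k]
        if (dosages[dosages != MISSING] == 0).all():
            out.append(marker_id)
    return out


def risk_haplotype_to_frame(
    risk_haplotype: RiskHaplotype, markers
) -> pd.DataFrame:
    """Per-site table (chrom, pos, ref, alt, assigned allele, source)."""
    tab = markers.table.set_index("id")
    rows = []
    for marker_id, a in risk_haplotype.allele_map.items():
        m = tab.loc[marker_id]
        assigned = "NA"
        if a.allele is not None:
            assigned = m.alt if a.allele == 1 else m.ref
        rows.append(
            {
                "chrom": m.chrom,
                "pos_bp": int(m.pos_bp),
                "id": marker_id,
                "ref": m.ref,
                "alt": m.alt,
                "assigned_allele": assigned,
                "source": a.source.value,
            }
        )
    return pd.DataFrame(rows).sort_values("pos_bp").reset_index(drop=True)
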