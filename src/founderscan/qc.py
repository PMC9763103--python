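"""Marker and sample quality control ahead of IBD analysis.

The filters mirror standard pre-IBD practice on pedigree WGS data:
per-individual missingness, per-marker missingness, an exact
Hardy-Weinberg test (asymptotic tests are invalid at pedigree sample
sizes), a minor-allele-frequency floor, Mendelian-consistency screening
over genotyped parent-offspring pairs, and sliding-window LD pruning.
Filter order is fixed: individuals -> genotype missingness -> HWE ->
MAF -> Mendelian -> LD prune; the report telescopes (counts removed per
stage sum to input minus output).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from .panels import MISSING, GenotypePanel
from .pedigree import Pedigree


@dataclass
class QCThresholds:
    """Defaults reproduce a standard PLINK-style pre-IBD filter set."""

    max_genotype_missing: float = 0.01
    max_individual_missing: float = 0.05
    min_hwe_p: float = 0.001
    min_maf: float = 0.05
    ld_window_bp: int = 500_000
    ld_step: int = 50
    max_r2: float = 0.6
    drop_mendelian_errors: bool = True

    def __post_init__(self) -> None:
        for name in ("max_genotype_missing", "max_individual_missing", "min_hwe_p", "min_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ld_window_bp <= 0 or self.ld_step <= 0:
            raise ValueError("LD window and step must be positive")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all
    heterozygote counts of the correct parity, the probabilities of
    outcomes no more likely than the observed one (two-sided by
    probability mass).  Monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0
    # log P(het = h | allele counts), h over the parity class of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    keep = common_homs >= 0
    hets, rare_homs, common_homs = hets[keep], rare_homs[keep], common_homs[keep]
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_homs + 1)
        - gammaln(common_homs + 1)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete observations; undefined (zero
    variance, or fewer than two complete pairs) is returned as 0.0 so a
    monomorphic marker never triggers pruning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("dosage vectors must be equal-length 1-D with >= 2 entries")
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    vx = x - x.mean()
    vy = y - y.mean()
    denom = (vx @ vx) * (vy @ vy)
    if denom == 0:
        return 0.0
    return float(min(1.0, (vx @ vy) ** 2 / denom))


def ld_prune(panel: GenotypePanel, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Sliding-window LD pruning; returns retained marker indices.

    Windows span ``ld_window_bp`` base pairs and advance by ``ld_step``
    markers.  Within a window, while any retained pair exceeds
    ``max_r2``, the lower-MAF member of the worst offending pair is
    removed (ties: the later marker).  The result is idempotent and
    depends only on positions, dosages and MAFs, never on marker ids.
    """
    thresholds = thresholds or QCThresholds()
    removed = np.zeros(len(panel.markers), dtype=bool)
    maf = np.nan_to_num(panel.maf)
    for chrom in panel.markers.chromosomes:
        cidx = panel.markers.chrom_indices(chrom)
        pos = panel.markers.pos_bp[cidx]
        start = 0
        while start < len(cidx):
            in_win = np.flatnonzero(pos[start:] - pos[start] <= thresholds.ld_window_bp) + start
            window = [int(cidx[k]) for k in in_win if not removed[cidx[k]]]
            if len(window) > 1:
                r2 = _r2_matrix(panel.genotypes[:, window])
                alive = np.ones(len(window), dtype=bool)
                while True:
                    m = r2 * np.outer(alive, alive)
                    u, v = np.unravel_index(np.argmax(m), m.shape)
                    if m[u, v] <= thresholds.max_r2:
                        break
                    i, j = window[u], window[v]
                    # drop lower MAF; ties -> later position (j > i in window order)
                    drop_local = v if maf[j] <= maf[i] else u
                    alive[drop_local] = False
                    removed[window[drop_local]] = True
            start += thresholds.ld_step
        # completeness sweep: the stepped windows can miss pairs that are
        # within the bp window yet never share an examined window; scan
        # every remaining within-window pair and prune by the same rule
        # until no offending pair is left (this also makes the result
        # idempotent by construction)
        kept_local = np.array([int(i) for i in cidx if not removed[i]], dtype=int)
        offenders = _offending_pairs(panel, kept_local, thresholds)
        while offenders:
            offenders.sort(key=lambda t: (-t[0], t[1], t[2]))
            _, i, j = offenders[0]
            drop = j if maf[j] <= maf[i] else i
            removed[drop] = True
            offenders = [o for o in offenders if drop not in o[1:]]
    return np.flatnonzero(~removed)


def _offending_pairs(panel: GenotypePanel, kept: np.ndarray, thresholds: QCThresholds) -> list:
    """All (r2, i, j) with r2 > max_r2 among kept markers within the bp
    window, computed blockwise."""
    if kept.size < 2:
        return []
    pos = panel.markers.pos_bp[kept]
    out = []
    block = 256
    k = kept.size
    for a in range(0, k, block):
        b = min(a + block, k)
        # furthest column any marker in [a, b) can pair with
        hi = int(np.searchsorted(pos, pos[b - 1] + thresholds.ld_window_bp, side="right"))
        cols = kept[a:hi]
        r2 = _r2_matrix(panel.genotypes[:, cols])[: b - a, :]
        posd = pos[a:hi][None, :] - pos[a:b][:, None]
        idxd = np.arange(a, hi)[None, :] - np.arange(a, b)[:, None]
        mask = (idxd > 0) & (posd <= thresholds.ld_window_bp) & (r2 > thresholds.max_r2)
        for u, v in np.argwhere(mask):
            out.append((float(r2[u, v]), int(kept[a + u]), int(kept[a + v])))
    return out


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """All-pairs r^2 over the columns of a (samples x markers) block.

    Uses a single correlation computation when there are no missing
    calls, falling back to pairwise-complete :func:`pairwise_r2`
    otherwise.  Undefined entries (zero variance) are set to 0 and the
    diagonal is zeroed.
    """
    k = dosages.shape[1]
    if not (dosages == MISSING).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(dosages.astype(float), rowvar=False)
        r2 = np.nan_to_num(np.asarray(c) ** 2)
    else:
        r2 = np.zeros((k, k))
        for u in range(k):
            for v in range(u + 1, k):
                r2[u, v] = r2[v, u] = pairwise_r2(dosages[:, u], dosages[:, v])
    np.fill_diagonal(r2, 0.0)
    return np.minimum(r2, 1.0)


def mendelian_error_markers(panel: GenotypePanel, pedigree: Pedigree) -> np.ndarray:
    """Boolean mask of markers with a dosage impossible under Mendelian
    transmission in any genotyped parent-offspring pair.

    For a biallelic dosage pair (parent p, child c) the impossible
    combinations are p=0,c=2 / p=2,c=0 and vice versa: the child must
    receive one allele from that parent.
    """
    bad = np.zeros(len(panel.markers), dtype=bool)
    sample_set = set(panel.samples)
    for ind in pedigree.individuals.values():
        if ind.id not in sample_set:
            continue
        c = panel.genotypes[panel.sample_index(ind.id)]
        for pid in (ind.father_id, ind.mother_id):
            if pid is None or pid not in sample_set:
                continue
            p = panel.genotypes[panel.sample_index(pid)]
            ok = (c != MISSING) & (p != MISSING)
            bad |= ok & (((p == 0) & (c == 2)) | ((p == 2) & (c == 0)))
    return bad


@dataclass
class QCReport:
    """Telescoping per-stage removal counts (schema version 1)."""

    schema_version: int = 1
    n_individuals_in: int = 0
    n_markers_in: int = 0
    individuals_removed_missingness: int = 0
    markers_removed_missingness: int = 0
    markers_removed_hwe: int = 0
    markers_removed_maf: int = 0
    markers_removed_mendelian: int = 0
    markers_removed_ld: int = 0
    n_individuals_out: int = 0
    n_markers_out: int = 0
    removed_individuals: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def apply_qc(
    panel: GenotypePanel,
    pedigree: Pedigree | None = None,
    thresholds: QCThresholds | None = None,
    hwe_sample_ids: list[str] | None = None,
    run_ld_prune: bool = True,
) -> tuple[GenotypePanel, np.ndarray, QCReport]:
    """Run the full QC cascade on a genotype panel.

    ``hwe_sample_ids`` restricts the HWE test to a founder-independent
    subset; the default (all samples) matches common practice on small
    pedigree panels but inflates heterozygote correlations, so a
    restricted subset is available for larger designs.

    Returns the filtered panel, the retained marker indices relative to
    the input panel, and a :class:`QCReport`.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(n_individuals_in=panel.n_samples, n_markers_in=len(panel.markers))

    # 1. individuals above missingness
    miss = (panel.genotypes == MISSING).mean(axis=1)
    keep_samples = [s for s, m in zip(panel.samples, miss) if m <= thresholds.max_individual_missing]
    report.removed_individuals = [s for s in panel.samples if s not in keep_samples]
    report.individuals_removed_missingness = len(report.removed_individuals)
    if not keep_samples:
        raise ValueError("QC removed every individual (missingness)")
    panel = panel.subset_samples(keep_samples)

    keep = np.ones(len(panel.markers), dtype=bool)

    # 2. marker missingness
    gmiss = (panel.genotypes == MISSING).mean(axis=0)
    drop = keep & (gmiss > thresholds.max_genotype_missing)
    report.markers_removed_missingness = int(drop.sum())
    keep &= ~drop

    # 3. HWE
    hwe_panel = panel if hwe_sample_ids is None else panel.subset_samples(hwe_sample_ids)
    hwe_drop = np.zeros(len(panel.markers), dtype=bool)
    for j in np.flatnonzero(keep):
        g = hwe_panel.genotypes[:, j]
        g = g[g != MISSING]
        if g.size == 0:
            continue
        p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        hwe_drop[j] = p < thresholds.min_hwe_p
    report.markers_removed_hwe = int(hwe_drop.sum())
    keep &= ~hwe_drop

    # 4. MAF
    maf = panel.maf
    drop = keep & ~(np.nan_to_num(maf) > thresholds.min_maf)
    report.markers_removed_maf = int(drop.sum())
    keep &= ~drop

    # 5. Mendelian errors
    if thresholds.drop_mendelian_errors and pedigree is not None:
        bad = mendelian_error_markers(panel, pedigree)
        drop = keep & bad
        report.markers_removed_mendelian = int(drop.sum())
        keep &= ~drop

    if not keep.any():
        raise ValueError("QC removed every marker before LD pruning")
    retained = np.flatnonzero(keep)
    panel = panel.subset_markers(retained)

    # 6. LD prune
    if run_ld_prune:
        kept_local = ld_prune(panel, thresholds)
        report.markers_removed_ld = len(panel.markers) - len(kept_local)
        panel = panel.subset_markers(kept_local)
        retained = retained[kept_local]

    if len(panel.markers) == 0:
        raise ValueError("QC removed every marker")
    report.n_individuals_out = panel.n_samples
    report.n_markers_out = len(panel.markers)
    return panel, retained, report
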