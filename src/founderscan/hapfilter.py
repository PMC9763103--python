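"""Risk-haplotype filter cascade.

Multi-IBD clusters are reduced to putative risk haplotypes in a fixed
order: length (> 1 Mb), founder-pair clustering (>= 3 carriers sharing
one founder pair), absence from population control cohorts, affected
phenotype in every carrier, and finally boundary refinement on the full
(unpruned) phased data.  A :class:`FilterTrace` records the fate of
every cluster and telescoping per-stage counts, mirroring the way such
cascades are reported (n in -> n out per arrow).

Control screening works on unphased array genotypes: a control "carries"
the candidate haplotype if its genotype at every shared marker is
consistent with at least one copy of the backbone allele.  This is
deliberately conservative — a common haplotype will find a compatible
control by chance and be discarded, which is the designed behaviour.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .cluster import MultiIBDCluster
from .panels import MISSING, GenotypePanel, PhasedPanel
from .pedigree import Pedigree

STAGES = ("length", "founder_pair", "controls", "phenotype", "refine")


@dataclass
class FilterTrace:
    """Per-stage in/out counts and per-cluster outcomes."""

    stage_counts: dict = field(default_factory=dict)  # stage -> (n_in, n_out)
    outcomes: dict = field(default_factory=dict)  # cluster key -> "kept" | "removed:<stage>"

    def record_stage(self, stage: str, n_in: int, n_out: int) -> None:
        self.stage_counts[stage] = (n_in, n_out)

    def mark_removed(self, key, stage: str) -> None:
        self.outcomes[key] = f"removed:{stage}"

    def mark_kept(self, key) -> None:
        self.outcomes[key] = "kept"

    def telescopes(self) -> bool:
        stages = [s for s in STAGES if s in self.stage_counts]
        return all(
            self.stage_counts[a][1] == self.stage_counts[b][0]
            for a, b in zip(stages[:-1], stages[1:])
        )

    def to_dict(self) -> dict:
        return {
            "stage_counts": {k: list(v) for k, v in self.stage_counts.items()},
            "outcomes": {str(k): v for k, v in self.outcomes.items()},
        }


@dataclass
class RiskHaplotypeCandidate:
    """A cluster annotated with founder-pair and phenotype context."""

    cluster: MultiIBDCluster
    main_fp: frozenset[str] = frozenset()
    n_main_fp_carriers: int = 0
    carrier_fp: dict = field(default_factory=dict)
    carrier_diagnoses: dict = field(default_factory=dict)
    refined_start_bp: int | None = None
    refined_end_bp: int | None = None

    @property
    def interval(self) -> tuple[int, int]:
        if self.refined_start_bp is not None:
            return (self.refined_start_bp, self.refined_end_bp)
        return (self.cluster.start_bp, self.cluster.end_bp)


def cluster_key(cluster: MultiIBDCluster) -> tuple:
    return (cluster.chrom, cluster.start_bp, cluster.end_bp, tuple(sorted(cluster.members)))


def filter_by_length(
    clusters: list[MultiIBDCluster],
    min_bp: int = 1_000_000,
    trace: FilterTrace | None = None,
) -> list[MultiIBDCluster]:
    """Keep clusters strictly longer than ``min_bp`` (end - start)."""
    kept = []
    for c in clusters:
        if c.length_bp > min_bp:
            kept.append(c)
        elif trace is not None:
            trace.mark_removed(cluster_key(c), "length")
    if trace is not None:
        trace.record_stage("length", len(clusters), len(kept))
    return kept


def filter_by_founder_pair(
    clusters: list[MultiIBDCluster],
    pedigree: Pedigree,
    min_same_fp: int = 3,
    trace: FilterTrace | None = None,
) -> list[RiskHaplotypeCandidate]:
    """Keep clusters with >= ``min_same_fp`` carriers sharing a founder pair.

    The main founder pair(s) are the label(s) attaining the maximal
    carrier count; ties are kept as a set.
    """
    out = []
    for c in clusters:
        carrier_fp = {}
        for ind in c.carriers:
            fp = pedigree.founder_ancestry(ind)
            if not fp:
                raise ValueError(
                    f"carrier {ind!r} descends from no founder pair; pedigree inconsistent"
                )
            carrier_fp[ind] = fp
        counts = Counter(label for fp in carrier_fp.values() for label in fp)
        best = max(counts.values())
        if best >= min_same_fp:
            main = frozenset(label for label, n in counts.items() if n == best)
            out.append(
                RiskHaplotypeCandidate(
                    cluster=c,
                    main_fp=main,
                    n_main_fp_carriers=best,
                    carrier_fp=carrier_fp,
                )
            )
        elif trace is not None:
            trace.mark_removed(cluster_key(c), "founder_pair")
    if trace is not None:
        trace.record_stage("founder_pair", len(clusters), len(out))
    return out


def candidate_backbone(
    candidate: RiskHaplotypeCandidate, phased_panel: PhasedPanel
) -> tuple[np.ndarray, np.ndarray]:
    """(marker indices, backbone alleles) over the candidate interval.

    The backbone allele at each marker is the consensus of the member
    haplotype copies (majority over non-missing; members are mutually
    identical over the cluster interval up to genotyping error).
    """
    start, end = candidate.interval
    idx = phased_panel.markers.interval_indices(candidate.cluster.chrom, start, end)
    rows = np.stack(
        [phased_panel.haplotype(ind, h)[idx] for ind, h in sorted(candidate.cluster.members)]
    )
    masked = np.ma.masked_equal(rows, MISSING)
    backbone = np.where(masked.mean(axis=0).filled(0.5) >= 0.5, 1, 0).astype(np.int8)
    all_missing = (rows == MISSING).all(axis=0)
    backbone = np.where(all_missing, MISSING, backbone).astype(np.int8)
    return idx, backbone


def screen_controls(
    candidate: RiskHaplotypeCandidate,
    phased_panel: PhasedPanel,
    control_panels: list[GenotypePanel],
    max_mismatch_frac: float = 0.0,
    min_shared_markers: int = 20,
) -> dict:
    """Check the candidate haplotype against unphased control cohorts.

    A control carries the haplotype if, at every marker shared between
    the candidate backbone and the control array, its genotype contains
    at least one copy of the backbone allele, allowing at most
    ``max_mismatch_frac`` inconsistent markers.  Returns a dict with
    ``status`` ("absent" or "present_in") and, when present, the index
    of the offending panel and control id.
    """
    idx, backbone = candidate_backbone(candidate, phased_panel)
    informative = backbone != MISSING
    ids = phased_panel.markers.ids[idx][informative]
    backbone = backbone[informative]
    for p, panel in enumerate(control_panels):
        if panel.n_samples == 0:
            continue
        lookup = {m: k for k, m in enumerate(panel.markers.ids)}
        shared = [(a, lookup[m]) for a, m in enumerate(ids) if m in lookup]
        if len(shared) < min_shared_markers:
            raise ValueError(
                f"only {len(shared)} markers shared with control panel {p}; "
                f"need >= {min_shared_markers} to evaluate the screen"
            )
        cand_cols = np.array([a for a, _ in shared])
        ctrl_cols = np.array([k for _, k in shared])
        alleles = backbone[cand_cols]
        dosages = panel.genotypes[:, ctrl_cols]
        # dosage of the backbone allele: alt allele -> dosage, ref -> 2 - dosage
        carry_dosage = np.where(alleles == 1, dosages, 2 - dosages)
        consistent = (carry_dosage >= 1) | (dosages == MISSING)
        mismatch_frac = 1 - consistent.mean(axis=1)
        hits = np.flatnonzero(mismatch_frac <= max_mismatch_frac)
        if hits.size:
            return {
                "status": "present_in",
                "panel": p,
                "control": panel.samples[int(hits[0])],
            }
    return {"status": "absent"}


def filter_by_controls(
    candidates: list[RiskHaplotypeCandidate],
    phased_panel: PhasedPanel,
    control_panels: list[GenotypePanel],
    max_mismatch_frac: float = 0.0,
    trace: FilterTrace | None = None,
) -> list[RiskHaplotypeCandidate]:
    kept = []
    for cand in candidates:
        res = screen_controls(cand, phased_panel, control_panels, max_mismatch_frac)
        if res["status"] == "absent":
            kept.append(cand)
        elif trace is not None:
            trace.mark_removed(cluster_key(cand.cluster), "controls")
    if trace is not None:
        trace.record_stage("controls", len(candidates), len(kept))
    return kept


def filter_by_phenotype(
    candidates: list[RiskHaplotypeCandidate],
    pedigree: Pedigree,
    confirmed_only: bool = False,
    trace: FilterTrace | None = None,
) -> list[RiskHaplotypeCandidate]:
    """Keep candidates whose every carrier is affected.

    Affected means a confirmed or probable TS/CMVT diagnosis; with
    ``confirmed_only`` probable diagnoses no longer qualify.
    """
    kept = []
    for cand in candidates:
        diag = {ind: pedigree.individuals[ind].diagnosis for ind in cand.cluster.carriers}
        cand.carrier_diagnoses = diag
        if confirmed_only:
            ok = all(d & {"TS", "CMVT"} for d in diag.values())
        else:
            ok = all(pedigree.individuals[ind].affected for ind in diag)
        if ok:
            kept.append(cand)
        elif trace is not None:
            trace.mark_removed(cluster_key(cand.cluster), "phenotype")
    if trace is not None:
        trace.record_stage("phenotype", len(candidates), len(kept))
    return kept


def refine_boundaries(
    candidate: RiskHaplotypeCandidate,
    full_phased_panel: PhasedPanel,
    max_mismatches: int = 0,
    mismatch_stop_window: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Re-define the candidate interval on the full phased marker set.

    Finds the largest run of markers inside the original (pruned-data)
    interval where all member copies agree, then extends each flank
    outward while agreement holds, tolerating up to ``max_mismatches``
    disagreeing markers per flank.  ``mismatch_stop_window = (m, w)``
    additionally stops a flank once ``m`` of the last ``w`` markers
    disagree: isolated disagreements are the signature of haplotype
    allele errors inside a real shared segment, whereas the true segment
    end shows up as locally dense disagreement.  Returns the refined
    (start_bp, end_bp).
    """
    chrom = candidate.cluster.chrom
    cidx = full_phased_panel.markers.chrom_indices(chrom)
    pos = full_phased_panel.markers.pos_bp[cidx]
    rows = np.stack(
        [
            full_phased_panel.haplotype(ind, h)[cidx]
            for ind, h in sorted(candidate.cluster.members)
        ]
    )
    nonmissing = rows != MISSING
    any_obs = nonmissing.any(axis=0)
    lo = np.where(nonmissing, rows, 2).min(axis=0)
    hi = np.where(nonmissing, rows, -2).max(axis=0)
    consistent = ~any_obs | (lo == hi)  # all observed members agree

    start_bp, end_bp = candidate.cluster.start_bp, candidate.cluster.end_bp
    inside = np.flatnonzero((pos >= start_bp) & (pos <= end_bp))
    if inside.size == 0:
        raise ValueError("candidate interval contains no markers on the full panel")
    frac_bad = 1 - consistent[inside].mean()
    if frac_bad > 0.5:
        raise ValueError(
            f"members disagree across {frac_bad:.0%} of the original interval; "
            "cluster looks spurious"
        )
    # largest consistent core inside the original interval
    best_len = best_s = -1
    s = None
    for k in list(inside) + [None]:
        if k is not None and consistent[k]:
            if s is None:
                s = k
            if k - s > best_len:
                best_len, best_s = k - s, s
        else:
            s = None
    if best_s < 0:
        raise ValueError("no consistent core inside the candidate interval")
    L = best_s
    R = best_s + best_len
    # extend flanks on the full marker set
    # change-point scoring for the flank edge: inside a shared segment
    # disagreements are rare allele errors (log-ratio strongly negative),
    # outside they occur at the chance-disagreement rate, so the edge is
    # the argmax of the cumulative inside/outside log-likelihood ratio.
    _W_CONSISTENT = 0.45  # ~log(0.996 / 0.64)
    _W_MISMATCH = -4.5  # ~log(0.004 / 0.36)

    def _extend_flank(start: int, step: int, limit: int) -> int:
        edge = start - step
        budget = max_mismatches
        recent: list[bool] = []
        cum = best = 0.0
        k = start
        while k != limit:
            ok = bool(consistent[k])
            if ok:
                cum += _W_CONSISTENT
                if cum > best:
                    best, edge = cum, k
            else:
                cum += _W_MISMATCH
                budget -= 1
                if budget < 0:
                    break
            if mismatch_stop_window is not None:
                m, w = mismatch_stop_window
                recent.append(ok)
                if len(recent) > w:
                    recent.pop(0)
                if sum(not r for r in recent) >= m:
                    break
            k += step
        return edge

    left_edge = _extend_flank(L - 1, -1, -1)
    if 0 <= left_edge < L:
        L = left_edge
    right_edge = _extend_flank(R + 1, +1, len(cidx))
    if right_edge > R:
        R = right_edge
    candidate.refined_start_bp = int(pos[L])
    candidate.refined_end_bp = int(pos[R])
    return candidate.refined_start_bp, candidate.refined_end_bp


def run_cascade(
    clusters: list[MultiIBDCluster],
    pedigree: Pedigree,
    phased_panel: PhasedPanel,
    full_phased_panel: PhasedPanel,
    control_panels: list[GenotypePanel],
    min_length_bp: int = 1_000_000,
    min_same_fp: int = 3,
    max_mismatch_frac: float = 0.0,
    confirmed_only: bool = False,
    refine_max_mismatches: int = 0,
    refine_stop_window: tuple[int, int] | None = None,
) -> tuple[list[RiskHaplotypeCandidate], FilterTrace]:
    """Run the full fixed-order cascade; returns survivors and the trace."""
    trace = FilterTrace()
    step1 = filter_by_length(clusters, min_length_bp, trace)
    step2 = filter_by_founder_pair(step1, pedigree, min_same_fp, trace)
    step3 = filter_by_controls(step2, phased_panel, control_panels, max_mismatch_frac, trace)
    step4 = filter_by_phenotype(step3, pedigree, confirmed_only, trace)
    kept = []
    for cand in step4:
        try:
            refine_boundaries(
                cand, full_phased_panel, refine_max_mismatches, refine_stop_window
            )
        except ValueError:
            trace.mark_removed(cluster_key(cand.cluster), "refine")
            continue
        trace.mark_kept(cluster_key(cand.cluster))
        kept.append(cand)
    trace.record_stage("refine", len(step4), len(kept))
    return kept, trace
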