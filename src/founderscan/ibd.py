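"""Pairwise IBD segment detection on phased haplotypes.

Detection is a transparent seed-and-extend scan: maximal runs of
identical alleles seed candidate segments, which are extended outward
under a log10 likelihood-ratio (LOD) score and trimmed to the
LOD-maximising interval.  Per site, the likelihood of the observed
allele pair under IBD marginalises over the shared ancestral allele with
a symmetric allele-error rate epsilon; under non-IBD the two alleles are
independent draws from the population frequency.  Segments are kept when
they exceed a physical length floor (1 Mb) and LOD > 3, the thresholds
standard for high-confidence IBD calls.

Total detected sharing also yields a genome-wide kinship estimate and a
relatedness-degree label for each pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import MISSING, PhasedPanel


@dataclass(frozen=True)
class IBDSegment:
    """A shared interval between one haplotype copy of each of two people."""

    id_a: str
    hap_a: int
    id_b: str
    hap_b: int
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    lod: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("IBD segment must have end_bp > start_bp")
        if self.n_markers < 2:
            raise ValueError("IBD segment must span at least two markers")
        if not math.isfinite(self.lod):
            raise ValueError("IBD segment LOD must be finite")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def covers(self, start_bp: int, end_bp: int) -> bool:
        return self.start_bp <= start_bp and self.end_bp >= end_bp

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class IBDParams:
    min_length_bp: int = 1_000_000
    min_lod: float = 3.0
    allele_error: float = 0.0025
    seed_length: int = 64
    lod_backoff: float = 2.5
    merge_gap_bp: int = 100_000  # heal breaks from isolated allele errors

    def __post_init__(self) -> None:
        if not 0 < self.allele_error < 0.5:
            raise ValueError("allele_error must be in (0, 0.5)")
        if self.min_lod < 0:
            raise ValueError("min_lod must be >= 0")


def site_lod_contributions(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    freqs: np.ndarray,
    epsilon: float,
    warn_degenerate: bool = True,
) -> np.ndarray:
    """Per-site log10 likelihood-ratio contributions (vectorised).

    Sites where either allele is missing, or where the alt frequency is
    degenerate (0, 1 or undefined), contribute 0; degenerate frequencies
    trigger a warning because the non-IBD likelihood is ill-defined
    there.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    f = np.asarray(freqs, dtype=float)
    valid = (a != MISSING) & (b != MISSING)
    degenerate = ~np.isfinite(f) | (f <= 0.0) | (f >= 1.0)
    if warn_degenerate and (degenerate & valid).any():
        warnings.warn(
            f"{int((degenerate & valid).sum())} site(s) with allele frequency 0 or 1 "
            "skipped in LOD computation",
            stacklevel=2,
        )
    use = valid & ~degenerate
    fs = np.where(degenerate, 0.5, f)  # placeholder freq at skipped sites
    e = epsilon
    f_shared = np.where(a == 1, fs, 1 - fs)  # freq of the shared allele when a == b
    p_ibd_match = f_shared * (1 - e) ** 2 + (1 - f_shared) * e**2
    p_null_match = f_shared**2
    p_ibd_mismatch = e * (1 - e)  # sum over ancestral allele: (f0 + f1) e(1-e)
    p_null_mismatch = fs * (1 - fs)
    match = a == b
    num = np.where(match, p_ibd_match, p_ibd_mismatch)
    den = np.where(match, p_null_match, p_null_mismatch)
    out = np.zeros(a.shape, dtype=float)
    out[use] = np.log10(num[use] / den[use])
    return out


def lod_score(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    freqs: np.ndarray,
    epsilon: float = 0.0025,
    interval: tuple[int, int] | None = None,
) -> float:
    """LOD (log10 likelihood ratio, IBD vs non-IBD) over marker indices.

    ``interval`` is an inclusive (start_index, end_index) pair into the
    marker arrays; ``None`` scores all sites.  Additive over disjoint
    intervals.
    """
    contrib = site_lod_contributions(hap_a, hap_b, freqs, epsilon)
    if interval is not None:
        s, e = interval
        if not (0 <= s <= e < len(contrib)):
            raise IndexError(f"interval {interval} outside marker range")
        contrib = contrib[s : e + 1]
    return float(contrib.sum())


def _seed_runs(a: np.ndarray, b: np.ndarray, seed_length: int) -> list[tuple[int, int]]:
    """Maximal runs of agreement with >= seed_length informative sites.

    A run may span missing calls (uninformative, not counted toward the
    seed length) but breaks at any observed mismatch.
    """
    valid = (a != MISSING) & (b != MISSING)
    ok = (a == b) | ~valid
    if not ok.any():
        return []
    edges = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    informative = np.concatenate(([0], np.cumsum(valid)))
    runs = []
    for s, e in zip(starts, ends):
        if informative[e + 1] - informative[s] >= seed_length:
            runs.append((int(s), int(e)))
    return runs


def _extend(contrib: np.ndarray, s: int, e: int, backoff: float) -> tuple[int, int, float]:
    """Extend [s, e] outward under the LOD score with a fixed backoff.

    Walk outward accumulating per-site contributions; stop once the
    running sum drops more than ``backoff`` below its running maximum,
    and trim each flank to its argmax.  Returns the trimmed interval and
    its total LOD.
    """
    base = contrib[s : e + 1].sum()
    best_left, best_right = s, e
    # left flank
    cum = 0.0
    best = 0.0
    for k in range(s - 1, -1, -1):
        cum += contrib[k]
        if cum > best:
            best, best_left = cum, k
        elif cum < best - backoff:
            break
    left_gain = best
    # right flank
    cum = 0.0
    best = 0.0
    for k in range(e + 1, len(contrib)):
        cum += contrib[k]
        if cum > best:
            best, best_right = cum, k
        elif cum < best - backoff:
            break
    right_gain = best
    return best_left, best_right, float(base + left_gain + right_gain)


def pairwise_ibd(panel: PhasedPanel, params: IBDParams | None = None) -> list[IBDSegment]:
    """Detect IBD segments between every haplotype pair of distinct individuals.

    Per chromosome and ordered haplotype pair: seed on long identical
    runs, extend/trim under the LOD score, merge overlapping candidate
    intervals from the same haplotype pair, and emit segments passing
    the length (> ``min_length_bp``) and LOD (> ``min_lod``) filters.
    """
    params = params or IBDParams()
    if panel.n_samples < 2:
        raise ValueError("pairwise IBD needs at least two individuals")
    segments: list[IBDSegment] = []
    freqs_all = panel.allele_freq
    for chrom in panel.markers.chromosomes:
        cidx = panel.markers.chrom_indices(chrom)
        pos = panel.markers.pos_bp[cidx]
        freqs = freqs_all[cidx]
        haps = panel.haplotypes[:, :, cidx]
        degenerate_warned = False
        for i in range(panel.n_samples):
            for j in range(i + 1, panel.n_samples):
                for hi in (0, 1):
                    for hj in (0, 1):
                        a, b = haps[i, hi], haps[j, hj]
                        runs = _seed_runs(a, b, params.seed_length)
                        if not runs:
                            continue
                        with warnings.catch_warnings():
                            if degenerate_warned:
                                warnings.simplefilter("ignore")
                            contrib = site_lod_contributions(
                                a, b, freqs, params.allele_error
                            )
                        degenerate_warned = True
                        intervals = []
                        for s, e in runs:
                            L, R, lod = _extend(contrib, s, e, params.lod_backoff)
                            intervals.append((L, R))
                        # merge overlapping or nearly-adjacent intervals from
                        # this haplotype pair (small gaps arise from isolated
                        # allele errors splitting one true segment)
                        intervals.sort()
                        merged: list[list[int]] = []
                        for L, R in intervals:
                            if merged and (
                                L <= merged[-1][1] + 1
                                or pos[L] - pos[merged[-1][1]] <= params.merge_gap_bp
                            ):
                                merged[-1][1] = max(merged[-1][1], R)
                            else:
                                merged.append([L, R])
                        for L, R in merged:
                            lod = float(contrib[L : R + 1].sum())
                            start_bp, end_bp = int(pos[L]), int(pos[R])
                            if (
                                end_bp - start_bp > params.min_length_bp
                                and lod > params.min_lod
                                and R - L + 1 >= 2
                            ):
                                segments.append(
                                    IBDSegment(
                                        id_a=panel.samples[i],
                                        hap_a=hi,
                                        id_b=panel.samples[j],
                                        hap_b=hj,
                                        chrom=chrom,
                                        start_bp=start_bp,
                                        end_bp=end_bp,
                                        n_markers=int(R - L + 1),
                                        lod=lod,
                                    )
                                )
    return segments


def ibd_copy_number(individual_id: str, cluster_members, segments=None) -> int:
    """How many haplotype copies (0, 1 or 2) an individual contributes.

    ``cluster_members`` is a collection of (individual_id, haplotype
    index) pairs — the membership of a multi-IBD cluster.  IBD1 means
    one chromosome copy carries the shared haplotype, IBD2 both.
    """
    copies = {h for (ind, h) in cluster_members if ind == individual_id}
    return min(len(copies), 2)


_DEGREE_LABELS = {0: "duplicate/MZ", 1: "1st degree", 2: "2nd degree", 3: "3rd degree"}


def relatedness_degree(
    segments_for_pair: list[IBDSegment],
    genome_length_bp: int,
    max_degree: int = 9,
) -> tuple[float, str]:
    """Kinship estimate and degree label from a pair's IBD segments.

    Kinship phi = (sum IBD1 lengths / 2 + sum IBD2 lengths) / (2 * genome
    length); a region is IBD2 where both chromosome copies of each
    individual participate in (distinct) shared segments.  The degree is
    the nearest integer d with midpoint kinship 2^-(d+1) (d = 0 is a
    duplicate/MZ pair, 1 first-degree, 3 ~ first cousins); pairs beyond
    ``max_degree`` are labelled unrelated.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    if segments_for_pair:
        pairs = {tuple(sorted(s.pair)) for s in segments_for_pair}
        if len(pairs) > 1:
            raise ValueError("segments span more than one individual pair")
    ibd1 = ibd2 = 0
    by_chrom: dict[str, list[IBDSegment]] = {}
    for s in segments_for_pair:
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        bounds = sorted({x for s in segs for x in (s.start_bp, s.end_bp)})
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            active = [s for s in segs if s.start_bp <= lo and s.end_bp >= hi]
            if not active:
                continue
            first = min(active[0].id_a, active[0].id_b)
            n_a = len({s.hap_a if s.id_a == first else s.hap_b for s in active})
            n_b = len({s.hap_b if s.id_a == first else s.hap_a for s in active})
            if min(n_a, n_b) >= 2:
                ibd2 += hi - lo
            else:
                ibd1 += hi - lo
    kinship = (ibd1 / 2 + ibd2) / (2 * genome_length_bp)
    if kinship <= 0:
        return 0.0, "unrelated"
    degree = max(0, round(-math.log2(kinship) - 1))
    if degree > max_degree:
        return kinship, "unrelated"
    label = _DEGREE_LABELS.get(degree, f"{degree}th degree")
    return kinship, label


def segments_to_frame(segments: list[IBDSegment]) -> pd.DataFrame:
    cols = ["id_a", "hap_a", "id_b", "hap_b", "chrom", "start_bp", "end_bp", "n_markers", "lod"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in segments], columns=cols)


def write_segments_tsv(segments: list[IBDSegment], path) -> None:
    """Tab-separated segment table (1-based inclusive coordinates)."""
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: list[IBDSegment], path) -> None:
    """BED export: converts to 0-based half-open (start-1, end)."""
    df = segments_to_frame(segments)
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start_bp"] - 1,
            "end": df["end_bp"],
            "name": df["id_a"] + "." + df["hap_a"].astype(str) + "__" + df["id_b"] + "." + df["hap_b"].astype(str),
            "score": df["lod"].round(2),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
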