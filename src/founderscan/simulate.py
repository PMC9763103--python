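"""Gene-drop synthetic-data generator.

Emulates, at desk scale, the study design of a deep founder pedigree:
six labelled founder couples at generation 0, a configurable number of
generations below them, and ~19 sampled individuals in the last two
generations whose ancestry-pattern mix mirrors the published carrier
matrix.  Founder haplotypes are dropped down the pedigree with a
Poisson/uniform crossover model (no interference), recording the exact
founder-haplotype mosaic of every transmitted chromosome as ground
truth.  One or more multi-megabase "risk" haplotypes, carrying embedded
rare annotated variants, are planted on a founder chromosome and
transmitted to a chosen set of sampled carriers by conditional gene
drop (meioses along the carrier lineages are resampled until they
transmit the planted interval — the standard way to condition a drop on
segregation without changing the crossover model elsewhere).

Phenotypes follow a penetrance/phenocopy Bernoulli model tied to planted
-haplotype carriage, and two array-genotyped control cohorts are drawn
from the background allele-frequency spectrum, never carrying the
planted haplotypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .markers import MarkerMap
from .panels import GenotypePanel, PhasedPanel
from .pedigree import Individual, Pedigree, PedigreeError
from .prioritize import VariantAnnotation

#: Founder-pair ancestry mix of the emulated design: the 17 affected
#: individuals' sets from the published carrier matrix plus two controls.
STUDY_FOUNDER_SETS: tuple[tuple[str, frozenset[str]], ...] = (
    ("1", frozenset("CD")),
    ("2", frozenset("DF")),
    ("3", frozenset("D")),
    ("4", frozenset("D")),
    ("5", frozenset("CE")),
    ("6", frozenset("ABCD")),
    ("7", frozenset("AB")),
    ("8", frozenset("ABC")),
    ("9", frozenset("ABC")),
    ("10", frozenset("B")),
    ("11", frozenset("B")),
    ("12", frozenset("B")),
    ("13", frozenset("B")),
    ("15", frozenset("C")),
    ("17", frozenset("E")),
    ("19", frozenset("ABC")),
    ("20", frozenset("F")),
    ("16", frozenset("CD")),
    ("18", frozenset("E")),
)

PAIR_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults are desk-scale: 2 chromosomes of 50 Mb at 100 WGS-like
    markers/Mb (array subset 20/Mb), 6 generations standing in for the
    11-generation design, 19 sampled individuals of whom 17 are
    affected, penetrance 0.8 and phenocopy rate 0.1.
    """

    n_generations: int = 6
    n_founder_pairs: int = 6
    n_sampled: int = 19
    n_affected: int = 17
    chrom_lengths_bp: dict = field(default_factory=lambda: {"1": 50_000_000, "2": 50_000_000})
    wgs_markers_per_mb: float = 100.0
    array_markers_per_mb: float = 20.0
    recomb_rate_cm_per_mb: float = 1.0
    common_af_range: tuple = (0.05, 0.5)
    allele_error_rate: float = 0.001
    unphased_fraction: float = 0.032
    penetrance: float = 0.8
    phenocopy_rate: float = 0.1
    min_meiotic_distance: int = 6
    control_sizes: tuple = (49, 42)
    match_design_counts: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("allele_error_rate", "penetrance", "phenocopy_rate", "unphased_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.wgs_markers_per_mb <= 0 or self.array_markers_per_mb <= 0:
            raise ValueError("marker densities must be positive")
        if not 0 <= self.common_af_range[0] < self.common_af_range[1] <= 1:
            raise ValueError("common_af_range must be an increasing pair in [0, 1]")
        if self.n_affected > self.n_sampled:
            raise ValueError("n_affected cannot exceed n_sampled")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["control_sizes"] = list(self.control_sizes)
        d["common_af_range"] = list(self.common_af_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["control_sizes"] = tuple(d.get("control_sizes", (49, 42)))
        d["common_af_range"] = tuple(d.get("common_af_range", (0.05, 0.5)))
        return cls(**d)

    def bp_to_cm(self, bp) -> np.ndarray:
        return np.asarray(bp, dtype=float) * self.recomb_rate_cm_per_mb / 1e6

    def cm_to_bp(self, cm) -> np.ndarray:
        return np.asarray(cm, dtype=float) * 1e6 / self.recomb_rate_cm_per_mb


@dataclass
class PlantedVariantSpec:
    """One rare variant embedded on a planted haplotype."""

    offset_bp: int  # position relative to the haplotype start
    annotation_template: dict  # kwargs for VariantAnnotation minus coordinates


@dataclass
class PlantedSpec:
    founder_pair: str = "B"
    chrom: str = "1"
    start_bp: int = 20_000_000
    end_bp: int = 23_527_903  # emulates the scale of the study's chr1 haplotype
    n_carriers: int = 4
    variants: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class PlantedHaplotype:
    """A planted founder haplotype and its embedded variants (truth record)."""

    hap_id: str  # founder haplotype id, e.g. "FPB.f.0"
    founder_pair: str
    chrom: str
    start_bp: int
    end_bp: int
    backbone_marker_ids: tuple
    backbone_alleles: np.ndarray
    variants: dict  # marker id -> VariantAnnotation

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class TransmissionTruth:
    """Exact founder-haplotype mosaics for every pedigree member.

    ``mosaics[ind_id][copy][chrom]`` is a list of (start_bp, end_bp,
    founder_hap_id) tuples tiling the chromosome; copy 0 is paternal.
    """

    mosaics: dict
    chrom_lengths_bp: dict
    planted: list = field(default_factory=list)

    def carrier_intervals(
        self, planted: PlantedHaplotype, sample_ids, min_frac: float = 0.9
    ) -> dict:
        """Per-sample carried sub-intervals of a planted haplotype.

        Returns {individual id: {"copies": n, "intervals": [(s, e), ...]}}
        for individuals with at least one chromosome copy covering
        >= ``min_frac`` of the planted interval with the planted origin.
        """
        out = {}
        for ind in sample_ids:
            copies = 0
            intervals = []
            for copy in (0, 1):
                segs = [
                    (s, e)
                    for s, e, origin in self.mosaics[ind][copy][planted.chrom]
                    if origin == planted.hap_id and e > planted.start_bp and s < planted.end_bp
                ]
                covered = sum(
                    min(e, planted.end_bp) - max(s, planted.start_bp) for s, e in segs
                )
                if covered >= min_frac * planted.length_bp:
                    copies += 1
                    # unclipped: the carried founder segment extends beyond the
                    # planted interval by whatever flank survived recombination
                    intervals.append((min(s for s, _ in segs), max(e for _, e in segs)))
            if copies:
                out[ind] = {"copies": copies, "intervals": intervals}
        return out

    def carrier_set(self, planted: PlantedHaplotype, sample_ids, min_frac: float = 0.9):
        return frozenset(self.carrier_intervals(planted, sample_ids, min_frac))

    def shared_interval(
        self, planted: PlantedHaplotype, sample_ids, min_frac: float = 0.9
    ) -> tuple[int, int]:
        """Intersection of all carriers' carried intervals (the expected
        recoverable region)."""
        carriers = self.carrier_intervals(planted, sample_ids, min_frac)
        if not carriers:
            raise ValueError("planted haplotype has no carriers at this threshold")
        start = max(iv[0] for c in carriers.values() for iv in c["intervals"])
        end = min(iv[1] for c in carriers.values() for iv in c["intervals"])
        return int(start), int(end)


# ---------------------------------------------------------------------------
# marker map and founder haplotypes


def make_marker_map(config: SimulationConfig, rng: np.random.Generator) -> tuple[MarkerMap, np.ndarray]:
    """Random WGS-like marker map plus background alt frequencies.

    Positions are uniform within each chromosome; frequencies uniform on
    the configured common range.
    """
    rows = []
    freqs = []
    lo, hi = config.common_af_range
    # zero recombination still needs a valid (strictly increasing) genetic
    # map; use a vanishing pseudo-rate for map coordinates only
    cm_rate = config.recomb_rate_cm_per_mb or 1e-9
    for chrom, length in config.chrom_lengths_bp.items():
        n = int(round(config.wgs_markers_per_mb * length / 1e6))
        pos = np.unique(rng.integers(1, length + 1, size=2 * n + 16))
        while pos.size < n:  # vanishingly unlikely at these densities
            pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        f = rng.uniform(lo, hi, size=n)
        ra = rng.choice(list("ACGT"), size=n)
        alt_offset = rng.integers(1, 4, size=n)
        bases = np.array(list("ACGT"))
        base_idx = {b: i for i, b in enumerate("ACGT")}
        aa = bases[[(base_idx[r] + o) % 4 for r, o in zip(ra, alt_offset)]]
        for k in range(n):
            rows.append(
                {
                    "chrom": chrom,
                    "pos_bp": int(pos[k]),
                    "pos_cm": float(pos[k] * cm_rate / 1e6),
                    "ref": ra[k],
                    "alt": aa[k],
                    "id": f"snv_{chrom}_{pos[k]}",
                }
            )
        freqs.append(f)
    return MarkerMap(pd.DataFrame(rows)), np.concatenate(freqs)


def array_subset_indices(markers: MarkerMap, config: SimulationConfig, background_freqs: np.ndarray) -> np.ndarray:
    """Indices of an array-like marker subset (every k-th common marker)."""
    step = max(1, int(round(config.wgs_markers_per_mb / config.array_markers_per_mb)))
    common = background_freqs > 0
    idx = np.flatnonzero(common)[::step]
    return idx


def draw_founder_haplotypes(
    pedigree: Pedigree,
    markers: MarkerMap,
    background_freqs: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Two independent Bernoulli(f) haplotypes per founder."""
    out = {}
    for fid in sorted(pedigree.founder_ids):
        out[fid] = (
            (rng.random(len(markers)) < background_freqs).astype(np.int8),
            (rng.random(len(markers)) < background_freqs).astype(np.int8),
        )
    return out


# ---------------------------------------------------------------------------
# pedigree construction


def default_founder_sets(config: SimulationConfig) -> list[tuple[str, frozenset[str]]]:
    if config.n_sampled == 19 and config.n_founder_pairs == 6:
        return list(STUDY_FOUNDER_SETS)
    labels = PAIR_LABELS[: config.n_founder_pairs]
    sets = []
    for i in range(config.n_sampled):
        sets.append((f"s{i + 1}", frozenset({labels[i % len(labels)]})))
    return sets


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Build the synthetic pedigree skeleton.

    Founder pairs sit at generation 0; each sampled individual gets a
    private descent chain attaching directly to its founder pairs, so
    sampled individuals are related only through the founder couples and
    pairwise meiotic distances stay large.  Sampled individuals land in
    the last two generations.
    """
    if config.n_generations < 3:
        raise PedigreeError(
            f"n_generations={config.n_generations} leaves no room for sampled "
            "descendants; increase n_generations (>= 3)"
        )
    founder_sets = default_founder_sets(config)
    max_set = max(len(s) for _, s in founder_sets)
    min_depth = 1 + (max_set - 1).bit_length() + 1
    if config.n_generations < min_depth:
        raise PedigreeError(
            f"n_generations={config.n_generations} cannot realise founder sets of "
            f"size {max_set}; increase n_generations to >= {min_depth}"
        )
    individuals: dict[str, Individual] = {}
    counter = [0]

    def add(ind: Individual) -> str:
        individuals[ind.id] = ind
        return ind.id

    founder_pairs = {}
    for label in PAIR_LABELS[: config.n_founder_pairs]:
        fid = add(Individual(id=f"FP{label}.f", sex="male"))
        mid = add(Individual(id=f"FP{label}.m", sex="female"))
        founder_pairs[label] = (fid, mid)

    def married_in(sex: str) -> str:
        counter[0] += 1
        return add(Individual(id=f"ext{counter[0]}", sex=sex))

    def line(owner: str, labels: tuple, generation: int, sex: str) -> str:
        counter[0] += 1
        node_id = f"{owner}.a{counter[0]}"
        if len(labels) == 1:
            if generation == 1:
                father, mother = founder_pairs[labels[0]]
            else:
                father = line(owner, labels, generation - 1, "male")
                mother = married_in("female")
        else:
            half = (len(labels) + 1) // 2
            father = line(owner, labels[:half], generation - 1, "male")
            mother = line(owner, labels[half:], generation - 1, "female")
        return add(
            Individual(id=node_id, father_id=father, mother_id=mother, sex=sex, generation=generation)
        )

    for ind_id, labels in founder_sets:
        depth = int(config.n_generations - rng.integers(0, 2))
        depth = max(depth, min_depth)
        father = line(ind_id, tuple(sorted(labels)), depth - 1, "male")
        mother = married_in("female")
        sex = "male" if rng.random() < 0.5 else "female"
        add(
            Individual(
                id=ind_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                generation=depth,
                sampled=True,
            )
        )
    ped = Pedigree(individuals, founder_pairs)
    # construction guarantees: check the distance constraint holds
    sampled = ped.sampled_ids
    for i, a in enumerate(sampled):
        for b in sampled[i + 1 :]:
            d = ped.meiotic_distance(a, b)
            if d < config.min_meiotic_distance:
                raise PedigreeError(
                    f"sampled pair ({a}, {b}) at meiotic distance {d} < "
                    f"{config.min_meiotic_distance}; increase n_generations"
                )
    shared = max(
        sum(1 for _, s in founder_sets if label in s)
        for label in PAIR_LABELS[: config.n_founder_pairs]
    )
    if shared < 3:
        raise PedigreeError("no founder pair is shared by >= 3 sampled individuals")
    return ped


# ---------------------------------------------------------------------------
# planting


def plant_risk_haplotype(
    founder_haplotypes: dict,
    spec: PlantedSpec,
    markers: MarkerMap,
    background_freqs: np.ndarray,
    pedigree: Pedigree,
    rng: np.random.Generator,
) -> PlantedHaplotype:
    """Embed rare variants on one founder chromosome copy.

    The planted backbone is the founder's own haplotype over the
    interval (a multi-megabase random haplotype is effectively unique in
    the population).  Embedded rare-variant markers are appended to the
    marker map by the caller (see :func:`add_planted_variant_markers`);
    here their alt alleles are set on the planted copy only, so they are
    absent from every other founder haplotype by construction.
    """
    chrom_len = int(markers.pos_bp[markers.chrom_indices(spec.chrom)].max())
    if spec.start_bp < 1 or spec.end_bp > chrom_len + 1_000_000 or spec.end_bp <= spec.start_bp:
        raise ValueError(f"planted interval outside chromosome {spec.chrom}")
    founder_id = pedigree.founder_pairs[spec.founder_pair][0]  # the pair's father
    hap = founder_haplotypes[founder_id][0]
    variants = {}
    for v in spec.variants:
        pos = spec.start_bp + v.offset_bp
        marker_id = f"rv_{spec.chrom}_{pos}"
        j = np.flatnonzero(markers.ids == marker_id)
        if j.size != 1:
            raise ValueError(
                f"rare-variant marker {marker_id} missing from the map; call "
                "add_planted_variant_markers first"
            )
        j = int(j[0])
        hap[j] = 1
        row = markers.table.iloc[j]
        variants[marker_id] = VariantAnnotation(
            id=marker_id,
            chrom=spec.chrom,
            pos_bp=int(row.pos_bp),
            ref=row.ref,
            alt=row.alt,
            **v.annotation_template,
        )
    idx = markers.interval_indices(spec.chrom, spec.start_bp, spec.end_bp)
    return PlantedHaplotype(
        hap_id=f"{founder_id}.0",
        founder_pair=spec.founder_pair,
        chrom=spec.chrom,
        start_bp=spec.start_bp,
        end_bp=spec.end_bp,
        backbone_marker_ids=tuple(markers.ids[idx]),
        backbone_alleles=hap[idx].copy(),
        variants=variants,
    )


def add_planted_variant_markers(
    markers: MarkerMap, background_freqs: np.ndarray, specs: list
) -> tuple[MarkerMap, np.ndarray]:
    """Insert rare-variant marker rows (background frequency 0).

    Background frequency 0 means no founder or control haplotype carries
    the alt allele unless a planting sets it.
    """
    tab = markers.table.copy()
    rows = list(tab.itertuples(index=False))
    extra = []
    rate = None
    for spec in specs:
        for v in spec.variants:
            pos = spec.start_bp + v.offset_bp
            cidx = markers.chrom_indices(spec.chrom)
            if rate is None:
                p = markers.pos_bp[cidx]
                c = markers.pos_cm[cidx]
                rate = (c[-1] - c[0]) / (p[-1] - p[0])
            extra.append(
                {
                    "chrom": spec.chrom,
                    "pos_bp": pos,
                    "pos_cm": float(markers.pos_cm[cidx][0] + rate * (pos - markers.pos_bp[cidx][0])),
                    "ref": "G",
                    "alt": "A",
                    "id": f"rv_{spec.chrom}_{pos}",
                }
            )
    if not extra:
        return markers, background_freqs
    new_tab = pd.concat([tab, pd.DataFrame(extra)], ignore_index=True)
    # preserve the original chromosome ordering rather than lexicographic
    chrom_rank = {c: i for i, c in enumerate(markers.chromosomes)}
    order = sorted(range(len(new_tab)), key=lambda i: (chrom_rank[new_tab["chrom"][i]], new_tab["pos_bp"][i]))
    freqs = np.concatenate([background_freqs, np.zeros(len(extra))])
    return MarkerMap(new_tab.iloc[order].reset_index(drop=True)), freqs[np.asarray(order)]


# ---------------------------------------------------------------------------
# gene drop


def _meiosis(
    parent_mosaics: tuple,
    chrom: str,
    chrom_len: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list:
    """One meiosis on one chromosome: Poisson crossovers, uniform in cM."""
    length_cm = float(config.bp_to_cm(chrom_len))
    n_x = rng.poisson(length_cm / 100.0)
    cuts_bp = np.sort(config.cm_to_bp(rng.uniform(0, length_cm, size=n_x))).astype(np.int64)
    cuts = [c for c in cuts_bp.tolist() if 1 < c < chrom_len]
    phase = int(rng.integers(0, 2))
    out = []
    bounds = [1] + cuts + [chrom_len + 1]
    for k in range(len(bounds) - 1):
        seg_start, seg_end = bounds[k], bounds[k + 1]
        if seg_end <= seg_start:
            continue
        src = parent_mosaics[(phase + k) % 2][chrom]
        for s, e, origin in src:
            lo, hi = max(s, seg_start), min(e, seg_end)
            if hi > lo:
                out.append((lo, hi, origin))
    merged = [out[0]]
    for s, e, origin in out[1:]:
        if origin == merged[-1][2] and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e, origin)
        else:
            merged.append((s, e, origin))
    return merged


def _mosaic_covers(mosaic: list, start: int, end: int, origin: str) -> bool:
    covered = sum(
        min(e, end) - max(s, start)
        for s, e, o in mosaic
        if o == origin and min(e, end) > max(s, start)
    )
    return covered >= end - start


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: dict,
    markers: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    forced_transmissions: dict | None = None,
    planted: list | None = None,
) -> tuple[PhasedPanel, TransmissionTruth]:
    """Drop founder haplotypes down the pedigree.

    ``forced_transmissions`` maps (child_id, parent_role) — role
    "father" or "mother" — to a list of (chrom, start_bp, end_bp,
    origin_hap_id) constraints; the corresponding meioses are resampled
    until the transmitted chromosome carries each interval from the
    required origin (conditional gene drop).

    Returns the phased panel of sampled individuals (with allele errors
    at ``allele_error_rate``) and the full transmission truth.
    """
    if len(markers) == 0:
        raise ValueError("marker map is empty")
    forced_transmissions = forced_transmissions or {}
    chrom_lens = {c: int(length) for c, length in config.chrom_lengths_bp.items()}
    mosaics: dict = {}
    for fid in pedigree.founder_ids:
        mosaics[fid] = (
            {c: [(1, L + 1, f"{fid}.0")] for c, L in chrom_lens.items()},
            {c: [(1, L + 1, f"{fid}.1")] for c, L in chrom_lens.items()},
        )
    order = sorted(
        (i for i in pedigree.individuals.values() if not i.is_founder),
        key=lambda i: (i.generation, i.id),
    )
    for ind in order:
        copies = []
        for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
            constraints = forced_transmissions.get((ind.id, role), [])
            child_chrom = {}
            for chrom, L in chrom_lens.items():
                chrom_constraints = [c for c in constraints if c[0] == chrom]
                for attempt in range(1000):
                    m = _meiosis(mosaics[pid], chrom, L, config, rng)
                    if all(
                        _mosaic_covers(m, s, e, origin)
                        for _, s, e, origin in chrom_constraints
                    ):
                        break
                else:
                    raise RuntimeError(
                        f"could not satisfy forced transmission to {ind.id} on {chrom}"
                    )
                child_chrom[chrom] = m
            copies.append(child_chrom)
        mosaics[ind.id] = tuple(copies)

    truth = TransmissionTruth(
        mosaics=mosaics, chrom_lengths_bp=dict(chrom_lens), planted=list(planted or [])
    )

    sample_ids = sorted(pedigree.sampled_ids, key=_natural_key)
    n_m = len(markers)
    haps = np.zeros((len(sample_ids), 2, n_m), dtype=np.int8)
    founder_hap_lookup = {}
    for fid, (h0, h1) in founder_haplotypes.items():
        founder_hap_lookup[f"{fid}.0"] = h0
        founder_hap_lookup[f"{fid}.1"] = h1
    pos_by_chrom = {c: markers.pos_bp[markers.chrom_indices(c)] for c in markers.chromosomes}
    idx_by_chrom = {c: markers.chrom_indices(c) for c in markers.chromosomes}
    for si, ind_id in enumerate(sample_ids):
        for copy in (0, 1):
            for chrom in markers.chromosomes:
                pos = pos_by_chrom[chrom]
                gidx = idx_by_chrom[chrom]
                for s, e, origin in mosaics[ind_id][copy][chrom]:
                    sel = (pos >= s) & (pos < e)
                    haps[si, copy, gidx[sel]] = founder_hap_lookup[origin][gidx[sel]]
    if config.allele_error_rate > 0:
        flips = rng.random(haps.shape) < config.allele_error_rate
        haps[flips] = 1 - haps[flips]
    panel = PhasedPanel(markers, sample_ids, haps)
    return panel, truth


def _natural_key(s: str):
    return (0, int(s)) if s.isdigit() else (1, s)


def lineage_forced_transmissions(
    pedigree: Pedigree, planted: PlantedHaplotype, targets
) -> dict:
    """Forced-transmission constraints carrying a planted haplotype to targets.

    For each target, walks from the target up to the planted founder and
    requires every meiosis on the path to transmit the planted interval
    from the planted origin.
    """
    founder_id = planted.hap_id.rsplit(".", 1)[0]
    constraint = (planted.chrom, planted.start_bp, planted.end_bp, planted.hap_id)
    forced: dict = {}
    for target in targets:
        path = _path_to_ancestor(pedigree, target, founder_id)
        for child, role in path:
            forced.setdefault((child, role), []).append(constraint)
    return forced


def _path_to_ancestor(pedigree: Pedigree, target: str, ancestor: str) -> list:
    """(child, parent_role) steps from *ancestor* down to *target*."""
    steps = []
    cur = target
    while cur != ancestor:
        ind = pedigree.individuals[cur]
        chosen = None
        for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
            if pid is None:
                continue
            if pid == ancestor or ancestor in pedigree.ancestors(pid):
                chosen = (cur, role, pid)
                break
        if chosen is None:
            raise PedigreeError(f"{target!r} does not descend from {ancestor!r}")
        steps.append((chosen[0], chosen[1]))
        cur = chosen[2]
    return list(reversed(steps))


# ---------------------------------------------------------------------------
# phenotypes and controls


def assign_phenotypes(
    pedigree: Pedigree,
    truth: TransmissionTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    carrier_min_frac: float = 0.5,
) -> dict:
    """Penetrance/phenocopy phenotype assignment; updates the pedigree.

    Sampled carriers of any planted haplotype are affected with
    probability ``penetrance``; other sampled individuals with
    probability ``phenocopy_rate``.  When ``match_design_counts`` is set
    and phenocopies are possible, the number of affected non-carriers is
    resampled so that exactly ``n_affected`` sampled individuals are
    affected (ascertainment emulation); with a zero phenocopy rate the
    penetrance model is left untouched.
    """
    sample_ids = pedigree.sampled_ids
    carriers: set[str] = set()
    for planted in truth.planted:
        carriers |= set(truth.carrier_intervals(planted, sample_ids, carrier_min_frac))
    affected = {}
    for ind in sample_ids:
        p = config.penetrance if ind in carriers else config.phenocopy_rate
        affected[ind] = bool(rng.random() < p)
    if config.match_design_counts and config.phenocopy_rate > 0:
        noncarriers = [s for s in sample_ids if s not in carriers]
        target_nc = config.n_affected - sum(affected[c] for c in carriers)
        target_nc = max(0, min(target_nc, len(noncarriers)))
        chosen = set(rng.choice(noncarriers, size=target_nc, replace=False)) if target_nc else set()
        for s in noncarriers:
            affected[s] = s in chosen
    for ind, is_affected in affected.items():
        pedigree.relabel_diagnosis(ind, {"TS"} if is_affected else {"unaffected"})
    return affected


def make_controls(
    markers: MarkerMap,
    array_indices: np.ndarray,
    background_freqs: np.ndarray,
    sizes: tuple,
    rng: np.random.Generator,
    contaminate_haplotype: np.ndarray | None = None,
    contaminate_chrom: str | None = None,
    n_contaminated: int = 0,
) -> list:
    """Array-genotyped control cohorts from the background frequency pool.

    Controls are unphased dosage panels over the array marker subset.
    Planted rare-variant sites have background frequency 0, so controls
    never carry them.  ``contaminate_haplotype`` (a full-length allele
    vector over all WGS markers) puts one copy of that haplotype, over
    ``contaminate_chrom``, into the first ``n_contaminated`` controls of
    each panel — emulating a founder chromosome that is common in the
    population, the negative control the screen must reject.
    """
    array_indices = np.asarray(array_indices)
    if array_indices.size == 0:
        raise ValueError("array marker subset is empty")
    sub_markers = markers.subset(array_indices)
    f = background_freqs[array_indices]
    panels = []
    cols = alleles = None
    if contaminate_haplotype is not None:
        chroms = sub_markers.table["chrom"].to_numpy()
        cols = np.flatnonzero(chroms == contaminate_chrom)
        alleles = contaminate_haplotype[array_indices[cols]].astype(np.int8)
    for p, n in enumerate(sizes):
        h = (rng.random((n, 2, array_indices.size)) < f).astype(np.int8)
        if cols is not None and n_contaminated:
            h[: min(n_contaminated, n), 0, cols[None, :]] = alleles
        dosage = h.sum(axis=1).astype(np.int8)
        panels.append(
            GenotypePanel(sub_markers, [f"ctrl{p + 1}_{k + 1}" for k in range(n)], dosage)
        )
    return panels
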