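"""End-to-end orchestration: simulate -> QC -> IBD -> cluster -> filter ->
fine-map -> prioritize.

The pipeline consumes a :class:`SimulatedDataset` (or files in the
package's formats) and produces the three result tables of a
risk-haplotype study — the risk-haplotype summary, the prioritized
variant report and the carrier matrix — together with a filter trace
whose per-stage counts telescope.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vcfio
from .cluster import MultiIBDCluster, clusters_to_frame, multi_ibd_clusters
from .hapfilter import FilterTrace, RiskHaplotypeCandidate, run_cascade
from .finemap import fine_map, haplotype_specific_variants
from .ibd import IBDParams, pairwise_ibd, segments_to_frame
from .panels import GenotypePanel, PhasedPanel
from .pedigree import Pedigree
from .prioritize import (
    PrioritizationThresholds,
    VariantAnnotation,
    prioritize,
    write_annotation_tsv,
)
from .qc import QCThresholds, apply_qc
from .simulate import (
    PlantedSpec,
    PlantedVariantSpec,
    SimulationConfig,
    add_planted_variant_markers,
    array_subset_indices,
    assign_phenotypes,
    default_founder_sets,
    draw_founder_haplotypes,
    gene_drop,
    lineage_forced_transmissions,
    make_controls,
    make_marker_map,
    plant_risk_haplotype,
    simulate_pedigree,
)

log = logging.getLogger("founderscan")


def default_planted_spec() -> PlantedSpec:
    """A 3.53 Mb founder-pair-B haplotype with two embedded rare variants.

    One qualifying deleterious missense variant (rare AF, damaging SIFT/
    PolyPhen, CADD > 20) and one non-qualifying intronic decoy (low CADD
    and ncER), so a prioritization run should surface exactly one
    variant.
    """
    return PlantedSpec(
        founder_pair="B",
        chrom="1",
        start_bp=20_000_000,
        end_bp=23_527_903,
        n_carriers=4,
        variants=[
            PlantedVariantSpec(
                offset_bp=1_000_000,
                annotation_template=dict(
                    af_by_population={"AMR": 0.001976, "NFE": 0.0001},
                    consequence="missense",
                    gene="GENE1",
                    aa_substitution="S/L",
                    sift="deleterious_low_confidence",
                    sift_score=0.0,
                    polyphen="probably_damaging",
                    polyphen_score=0.999,
                    cadd_phred=23.8,
                    pli=1.0,
                    missense_z=3.13,
                ),
            ),
            PlantedVariantSpec(
                offset_bp=2_000_000,
                annotation_template=dict(
                    af_by_population={"AMR": 0.000661},
                    consequence="intronic",
                    gene="GENE2",
                    cadd_phred=6.5,
                    ncer_percentile=80.0,
                ),
            ),
        ],
    )


def contaminated_planted_spec() -> PlantedSpec:
    """A second planted haplotype, also given to controls (common-haplotype
    negative control: it must be removed at the control-screen stage)."""
    spec = default_planted_spec()
    spec.founder_pair = "C"
    spec.chrom = "2"
    spec.start_bp = 10_000_000
    spec.end_bp = 13_000_000
    spec.variants = []
    return spec


@dataclass
class SimulatedDataset:
    """Everything one synthetic replicate produces."""

    config: SimulationConfig
    pedigree: Pedigree
    phased_panel: PhasedPanel  # phased markers only (QC + IBD input)
    wgs_genotypes: GenotypePanel  # all WGS markers, incl. unphased sites
    truth: object
    controls: list
    annotations: dict
    array_indices: np.ndarray
    background_freqs: np.ndarray
    affected: dict


def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    planted_specs: list | None = None,
    contaminate_controls: bool = False,
    n_contaminated: int = 5,
) -> SimulatedDataset:
    """Generate one synthetic replicate of the study design.

    Planted haplotypes are transmitted to ``n_carriers`` sampled
    descendants of their founder pair by conditional gene drop.  With
    ``contaminate_controls`` an extra haplotype is planted both in the
    pedigree and in control genotypes, emulating a common haplotype that
    entered the pedigree more than once.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if planted_specs is None:
        planted_specs = [default_planted_spec()]
        if contaminate_controls:
            planted_specs.append(contaminated_planted_spec())

    pedigree = simulate_pedigree(config, rng)
    markers, bg_freqs = make_marker_map(config, rng)
    markers, bg_freqs = add_planted_variant_markers(markers, bg_freqs, planted_specs)
    founder_haps = draw_founder_haplotypes(pedigree, markers, bg_freqs, rng)

    founder_sets = dict(default_founder_sets(config))
    planted = []
    forced = {}
    for spec in planted_specs:
        ph = plant_risk_haplotype(founder_haps, spec, markers, bg_freqs, pedigree, rng)
        eligible = sorted(
            s for s, fps in founder_sets.items() if spec.founder_pair in fps
        )
        if len(eligible) < spec.n_carriers:
            raise ValueError(
                f"only {len(eligible)} sampled individuals descend from founder pair "
                f"{spec.founder_pair}; cannot plant {spec.n_carriers} carriers"
            )
        targets = rng.choice(eligible, size=spec.n_carriers, replace=False)
        for key, cons in lineage_forced_transmissions(pedigree, ph, targets).items():
            forced.setdefault(key, []).extend(cons)
        planted.append(ph)

    full_panel, truth = gene_drop(
        pedigree, founder_haps, markers, config, rng, forced_transmissions=forced, planted=planted
    )
    affected = assign_phenotypes(pedigree, truth, config, rng)

    # phased subset: rare planted variants are always genotype-only (they
    # would be absent from a phasing reference panel); a further random
    # fraction of background markers is unphased.
    is_rare = np.char.startswith(markers.ids.astype(str), "rv_")
    unphased = is_rare | (rng.random(len(markers)) < config.unphased_fraction)
    phased_panel = full_panel.subset_markers(np.flatnonzero(~unphased))
    wgs_genotypes = full_panel.to_genotypes()

    array_idx = array_subset_indices(markers, config, bg_freqs)
    contaminate_hap = contaminate_chrom = None
    if contaminate_controls:
        # give controls the contaminant founder's whole array chromosome: a
        # founder haplotype that is common in the population matches the
        # carriers over any extent the pipeline refines to
        contaminant = planted[-1]
        founder_id = contaminant.hap_id.rsplit(".", 1)[0]
        contaminate_hap = founder_haps[founder_id][int(contaminant.hap_id.rsplit(".", 1)[1])]
        contaminate_chrom = contaminant.chrom
    controls = make_controls(
        markers,
        array_idx,
        bg_freqs,
        config.control_sizes,
        rng,
        contaminate_haplotype=contaminate_hap,
        contaminate_chrom=contaminate_chrom,
        n_contaminated=n_contaminated if contaminate_controls else 0,
    )
    annotations = build_annotations(markers, bg_freqs, planted)
    return SimulatedDataset(
        config=config,
        pedigree=pedigree,
        phased_panel=phased_panel,
        wgs_genotypes=wgs_genotypes,
        truth=truth,
        controls=controls,
        annotations=annotations,
        array_indices=array_idx,
        background_freqs=bg_freqs,
        affected=affected,
    )


def build_annotations(markers, background_freqs, planted) -> dict:
    """Annotation rows for every marker.

    Background markers are common intergenic variants with their true
    simulated population frequency; planted rare variants carry the
    annotations they were planted with.
    """
    out = {}
    overrides = {}
    for ph in planted:
        overrides.update(ph.variants)
    tab = markers.table
    for j in range(len(markers)):
        mid = tab["id"].iloc[j]
        if mid in overrides:
            out[mid] = overrides[mid]
            continue
        out[mid] = VariantAnnotation(
            id=mid,
            chrom=tab["chrom"].iloc[j],
            pos_bp=int(tab["pos_bp"].iloc[j]),
            ref=tab["ref"].iloc[j],
            alt=tab["alt"].iloc[j],
            af_by_population={"AMR": float(background_freqs[j])},
            consequence="intergenic",
            cadd_phred=1.0,
        )
    return out


@dataclass
class PipelineParams:
    qc: QCThresholds = field(default_factory=QCThresholds)
    ibd: IBDParams = field(default_factory=IBDParams)
    min_copies: int = 3
    window_bp: int = 250_000
    min_length_bp: int = 1_000_000
    min_same_fp: int = 3
    max_mismatch_frac: float = 0.0
    confirmed_only: bool = False
    refine_max_mismatches: int = 50  # total per flank; sporadic allele errors
    refine_stop_window: tuple = (3, 10)  # dense disagreement = true segment end
    prioritize: PrioritizationThresholds = field(default_factory=PrioritizationThresholds)


@dataclass
class PipelineResult:
    qc_report: object
    segments: list
    clusters: list
    candidates: list
    trace: FilterTrace
    risk_haplotypes: list  # (candidate, RiskHaplotype, [variant ids]) triples
    risk_table: pd.DataFrame
    variant_report: pd.DataFrame
    carrier_matrix: pd.DataFrame
    stage_log: list


def run_full(dataset: SimulatedDataset, params: PipelineParams | None = None) -> PipelineResult:
    """Execute the whole analysis on one dataset."""
    params = params or PipelineParams()
    stage_log = []

    def _stage(name, n_in, n_out, t0):
        entry = {"stage": name, "n_in": n_in, "n_out": n_out, "seconds": round(time.time() - t0, 3)}
        stage_log.append(entry)
        log.info("stage %-12s in=%-6s out=%-6s %.2fs", name, n_in, n_out, entry["seconds"])

    t0 = time.time()
    geno = dataset.phased_panel.to_genotypes()
    if len(geno.markers) == 0 or geno.n_samples == 0:
        raise ValueError("qc stage received an empty panel")
    qc_panel, retained, qc_report = apply_qc(geno, dataset.pedigree, params.qc)
    _stage("qc", qc_report.n_markers_in, qc_report.n_markers_out, t0)

    t0 = time.time()
    pruned_phased = dataset.phased_panel.subset_markers(retained)
    segments = pairwise_ibd(pruned_phased, params.ibd)
    _stage("ibd", len(pruned_phased.markers), len(segments), t0)

    t0 = time.time()
    clusters: list[MultiIBDCluster] = []
    for chrom in pruned_phased.markers.chromosomes:
        chrom_segments = [s for s in segments if s.chrom == chrom]
        clusters.extend(
            multi_ibd_clusters(
                chrom_segments, pruned_phased.markers, params.min_copies, params.window_bp
            )
        )
    _stage("cluster", len(segments), len(clusters), t0)

    t0 = time.time()
    candidates, trace = run_cascade(
        clusters,
        dataset.pedigree,
        pruned_phased,
        dataset.phased_panel,
        dataset.controls,
        min_length_bp=params.min_length_bp,
        min_same_fp=params.min_same_fp,
        max_mismatch_frac=params.max_mismatch_frac,
        confirmed_only=params.confirmed_only,
        refine_max_mismatches=params.refine_max_mismatches,
        refine_stop_window=params.refine_stop_window,
    )
    _stage("filter", len(clusters), len(candidates), t0)

    t0 = time.time()
    risk_haplotypes = []
    all_variant_reports = []
    for cand in candidates:
        hap = fine_map(
            cand, dataset.wgs_genotypes, dataset.phased_panel, strict_backbone=False
        )
        specific = haplotype_specific_variants(hap, dataset.wgs_genotypes)
        risk_haplotypes.append((cand, hap, specific))
        if specific:
            report = prioritize(specific, dataset.annotations, params.prioritize)
            report.insert(0, "hap", _hap_label(cand))
            all_variant_reports.append(report)
    variant_report = (
        pd.concat(all_variant_reports, ignore_index=True)
        if all_variant_reports
        else pd.DataFrame(columns=["hap", "id", "passed"])
    )
    _stage("finemap+prioritize", len(candidates), int(variant_report.get("passed", pd.Series(dtype=bool)).sum()), t0)

    risk_table = _risk_table(dataset, risk_haplotypes)
    carrier_matrix = _carrier_matrix(dataset, risk_haplotypes)
    return PipelineResult(
        qc_report=qc_report,
        segments=segments,
        clusters=clusters,
        candidates=candidates,
        trace=trace,
        risk_haplotypes=risk_haplotypes,
        risk_table=risk_table,
        variant_report=variant_report,
        carrier_matrix=carrier_matrix,
        stage_log=stage_log,
    )


def _hap_label(cand: RiskHaplotypeCandidate) -> str:
    s, e = cand.interval
    return f"{cand.cluster.chrom}:{s}-{e}"


def _risk_table(dataset, risk_haplotypes) -> pd.DataFrame:
    rows = []
    for cand, hap, _specific in risk_haplotypes:
        s, e = cand.interval
        carriers = sorted(cand.cluster.carriers)
        rows.append(
            {
                "hap": _hap_label(cand),
                "chrom": cand.cluster.chrom,
                "start_bp": s,
                "end_bp": e,
                "length_mb": round((e - s) / 1e6, 2),
                "carriers": ",".join(carriers),
                "carrier_fp_sets": "|".join(
                    "/".join(sorted(cand.carrier_fp[c])) for c in carriers
                ),
                "main_fp": "/".join(sorted(cand.main_fp)),
                "n_main_fp_carriers": cand.n_main_fp_carriers,
                "diagnoses": "|".join(
                    ",".join(sorted(dataset.pedigree.individuals[c].diagnosis)) or "."
                    for c in carriers
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hap",
            "chrom",
            "start_bp",
            "end_bp",
            "length_mb",
            "carriers",
            "carrier_fp_sets",
            "main_fp",
            "n_main_fp_carriers",
            "diagnoses",
        ],
    )


def _carrier_matrix(dataset, risk_haplotypes) -> pd.DataFrame:
    affected_ids = [
        s for s in dataset.phased_panel.samples if dataset.pedigree.individuals[s].affected
    ]
    rows = []
    for ind in affected_ids:
        row = {
            "id": ind,
            "founder_pairs": "/".join(sorted(dataset.pedigree.founder_ancestry(ind))),
        }
        for cand, hap, _ in risk_haplotypes:
            row[f"hap_{_hap_label(cand)}"] = int(ind in cand.cluster.carriers)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk IO


def run_simulation(config: SimulationConfig, outdir, seed: int | None = None, **kwargs) -> dict:
    """Simulate one dataset and write it to ``outdir``; returns the manifest.

    Files: phased pedigree VCF, two control VCFs, FAM + founder-pair/
    diagnosis side-car, truth JSON, annotation TSV and the config YAML.
    Reruns with the same seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.chrom_lengths_bp:
        raise ValueError("config must specify at least one chromosome")
    ds = simulate_dataset(config, seed=seed, **kwargs)
    paths = {
        "config": outdir / "config.yaml",
        "pedigree_vcf": outdir / "pedigree_phased.vcf",
        "wgs_vcf": outdir / "pedigree_wgs.vcf",
        "controls1_vcf": outdir / "controls_cohort1.vcf",
        "controls2_vcf": outdir / "controls_cohort2.vcf",
        "fam": outdir / "pedigree.fam",
        "sidecar": outdir / "pedigree_meta.tsv",
        "truth": outdir / "truth.json",
        "annotations": outdir / "annotations.tsv",
    }
    config.to_yaml(paths["config"])
    vcfio.write_phased_vcf(ds.phased_panel, paths["pedigree_vcf"])
    vcfio.write_genotype_vcf(ds.wgs_genotypes, paths["wgs_vcf"])
    vcfio.write_genotype_vcf(ds.controls[0], paths["controls1_vcf"])
    vcfio.write_genotype_vcf(ds.controls[1], paths["controls2_vcf"])
    ds.pedigree.to_fam(paths["fam"], paths["sidecar"])
    with open(paths["truth"], "w") as fh:
        json.dump(_truth_to_json(ds.truth), fh, indent=1, sort_keys=True)
    write_annotation_tsv(ds.annotations, paths["annotations"])
    manifest = {
        "files": {
            name: {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for name, p in paths.items()
        }
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _truth_to_json(truth) -> dict:
    return {
        "chrom_lengths_bp": truth.chrom_lengths_bp,
        "mosaics": {
            ind: [
                {c: [list(seg) for seg in segs] for c, segs in copy.items()}
                for copy in copies
            ]
            for ind, copies in truth.mosaics.items()
        },
        "planted": [
            {
                "hap_id": p.hap_id,
                "founder_pair": p.founder_pair,
                "chrom": p.chrom,
                "start_bp": p.start_bp,
                "end_bp": p.end_bp,
                "variants": sorted(p.variants),
            }
            for p in truth.planted
        ],
    }


def write_results(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    segments_to_frame(result.segments).to_csv(outdir / "ibd_segments.tsv", sep="\t", index=False)
    clusters_to_frame(result.clusters).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    result.risk_table.to_csv(outdir / "risk_haplotypes.tsv", sep="\t", index=False)
    result.variant_report.to_csv(outdir / "prioritized_variants.tsv", sep="\t", index=False)
    result.carrier_matrix.to_csv(outdir / "carrier_matrix.tsv", sep="\t", index=False)
    with open(outdir / "filter_trace.json", "w") as fh:
        json.dump(result.trace.to_dict(), fh, indent=1, sort_keys=True)
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(result.qc_report.to_dict(), fh, indent=1, sort_keys=True)
    with open(outdir / "stage_log.json", "w") as fh:
        json.dump(result.stage_log, fh, indent=1)
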