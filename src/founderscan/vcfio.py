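"""VCF 4.2 reading and writing for phased and unphased panels.

Writers emit plain-text VCF with one contig line per chromosome and a
``CM`` INFO field carrying the genetic-map position, so a panel written
here round-trips through the readers without an external genetic map.
Reading uses cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .markers import MarkerMap
from .panels import MISSING, GenotypePanel, PhasedPanel

_HEADER = """\
##fileformat=VCFv4.2
##source=founderscan
##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position in centimorgans">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _contig_lines(markers: MarkerMap) -> str:
    lines = []
    for chrom in markers.chromosomes:
        idx = markers.chrom_indices(chrom)
        length = int(markers.pos_bp[idx].max()) + 1
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    return "".join(lines)


def _write(path, markers: MarkerMap, samples: list[str], gt_strings: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(_contig_lines(markers))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        tab = markers.table
        for j in range(len(markers)):
            row = tab.iloc[j]
            fields = [
                str(row.chrom),
                str(row.pos_bp),
                str(row.id),
                row.ref,
                row.alt,
                ".",
                "PASS",
                f"CM={row.pos_cm:.6f}",
                "GT",
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(gt_strings[:, j]) + "\n")


def write_phased_vcf(panel: PhasedPanel, path) -> None:
    """Write a panel as VCF with phased GT (``0|1`` style, ``.`` missing)."""
    h = panel.haplotypes
    a = np.where(h[:, 0] == MISSING, ".", h[:, 0].astype(str))
    b = np.where(h[:, 1] == MISSING, ".", h[:, 1].astype(str))
    gt = np.char.add(np.char.add(a.astype("U4"), "|"), b.astype("U4"))
    _write(path, panel.markers, panel.samples, gt)


def write_genotype_vcf(panel: GenotypePanel, path) -> None:
    """Write an unphased dosage panel as VCF (``0/1`` style GT)."""
    g = panel.genotypes
    gt = np.empty(g.shape, dtype="U3")
    gt[g == 0] = "0/0"
    gt[g == 1] = "0/1"
    gt[g == 2] = "1/1"
    gt[g == MISSING] = "./."
    _write(path, panel.markers, panel.samples, gt)


def _read_markers_and_gts(path):
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    gts = []
    phased = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"non-biallelic-SNV record at {var.CHROM}:{var.POS}")
        cm = var.INFO.get("CM")
        rows.append(
            {
                "chrom": var.CHROM,
                "pos_bp": var.POS,
                "pos_cm": float(cm) if cm is not None else float(var.POS) * 1e-6,
                "ref": var.REF,
                "alt": var.ALT[0],
                "id": var.ID or f"{var.CHROM}:{var.POS}",
            }
        )
        gt = var.genotype.array()  # (N, ploidy+1); last column is phase flag
        gts.append(gt[:, :2].copy())
        phased.append(gt[:, 2].copy())
    vcf.close()
    markers = MarkerMap(pd.DataFrame(rows))
    alleles = np.stack(gts, axis=2) if gts else np.zeros((len(samples), 2, 0))
    phase = np.stack(phased, axis=1) if phased else np.ones((len(samples), 0))
    return markers, samples, alleles.astype(np.int8), phase.astype(bool)


def read_phased_vcf(path) -> PhasedPanel:
    """Read a VCF with phased GT into a :class:`PhasedPanel`.

    Raises if any non-missing genotype is unphased — statistical phasing
    is out of scope here, so unphased input must be phased upstream (or
    generated phased by the simulator).
    """
    markers, samples, alleles, phase = _read_markers_and_gts(path)
    nonmissing = (alleles != MISSING).all(axis=1)
    if (~phase & nonmissing).any():
        raise ValueError(
            "VCF contains unphased genotypes; phase the data (or use the "
            "simulator, which emits phased haplotypes) before IBD analysis"
        )
    return PhasedPanel(markers, samples, alleles)


def read_genotype_vcf(path) -> GenotypePanel:
    """Read a VCF (phased or not) into an unphased :class:`GenotypePanel`."""
    markers, samples, alleles, _ = _read_markers_and_gts(path)
    dosage = alleles.sum(axis=1)
    dosage[(alleles == MISSING).any(axis=1)] = MISSING
    return GenotypePanel(markers, samples, dosage.astype(np.int8))
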