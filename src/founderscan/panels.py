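"""Phased haplotype and unphased genotype panels.

A :class:`PhasedPanel` holds, for every sampled individual, two allele
sequences over the marker map (index 0 = paternally derived copy,
1 = maternally derived).  Alleles are coded 0 (ref), 1 (alt) and -1
(missing).  A :class:`GenotypePanel` holds unphased dosages 0/1/2 with
-1 for missing — the natural representation for array-genotyped control
cohorts where phase is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import MarkerMap

MISSING = -1


def allele_frequencies(alleles: np.ndarray, *, ploidy_axis: bool = True) -> np.ndarray:
    """Per-marker alt-allele frequency over non-missing calls.

    ``alleles`` is an integer array whose last axis indexes markers;
    missing entries are coded -1 and excluded from the denominator.
    Markers where every call is missing get ``nan`` (undefined).
    """
    a = np.asarray(alleles)
    flat = a.reshape(-1, a.shape[-1])
    valid = flat != MISSING
    denom = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(valid, flat, 0).sum(axis=0) / np.where(denom == 0, np.nan, denom)
    return freq


@dataclass
class PhasedPanel:
    """Phased biallelic haplotypes for a set of individuals.

    Attributes
    ----------
    markers
        The marker map (length M).
    samples
        Individual ids, length N.
    haplotypes
        int8 array of shape (N, 2, M); values in {0, 1, -1}.
    """

    markers: MarkerMap
    samples: list[str]
    haplotypes: np.ndarray
    _freq: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.samples), 2, len(self.markers)):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"({len(self.samples)}, 2, {len(self.markers)})"
            )
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype alleles must be 0, 1 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker (column mean of non-missing)."""
        if self._freq is None:
            self._freq = allele_frequencies(self.haplotypes)
        return self._freq

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def haplotype(self, sample_id: str, copy: int) -> np.ndarray:
        return self.haplotypes[self.sample_index(sample_id), copy]

    def subset_markers(self, indices) -> "PhasedPanel":
        indices = np.asarray(indices)
        return PhasedPanel(
            self.markers.subset(indices),
            list(self.samples),
            self.haplotypes[:, :, indices],
        )

    def subset_samples(self, sample_ids) -> "PhasedPanel":
        idx = [self.sample_index(s) for s in sample_ids]
        return PhasedPanel(self.markers, list(sample_ids), self.haplotypes[idx])

    def to_genotypes(self) -> "GenotypePanel":
        """Collapse phase: dosage = sum of the two copies (missing if either is)."""
        h = self.haplotypes
        dosage = h.sum(axis=1)
        dosage[(h == MISSING).any(axis=1)] = MISSING
        return GenotypePanel(self.markers, list(self.samples), dosage)


@dataclass
class GenotypePanel:
    """Unphased dosage matrix (N individuals x M markers, values 0/1/2/-1)."""

    markers: MarkerMap
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        if not np.isin(self.genotypes, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def allele_freq(self) -> np.ndarray:
        g = self.genotypes.astype(float)
        valid = self.genotypes != MISSING
        denom = 2 * valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(valid, g, 0).sum(axis=0) / np.where(denom == 0, np.nan, denom)

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1 - f)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_markers(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        return GenotypePanel(
            self.markers.subset(indices), list(self.samples), self.genotypes[:, indices]
        )

    def subset_samples(self, sample_ids) -> "GenotypePanel":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypePanel(self.markers, list(sample_ids), self.genotypes[idx])
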