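"""Published summary tables of a deep Tourette-syndrome founder-pedigree study.

The protected WGS data behind the study cannot be redistributed, but its
three printed result tables can: the eleven putative risk haplotypes
(coordinates, carriers, founder-pair ancestry, diagnoses), the five
prioritized deleterious variants with their full annotations, and the
17-affected-individual carrier/ancestry matrix.  These serve as ground
truth for the fixture-level logic tests and as realistic templates for
the synthetic-data generator.

Transcription notes are carried as flag columns rather than silently
"fixed":

* ``length_discrepant`` — two rows' printed Mb lengths (haplotypes 4.1
  and 20.1) do not equal ``end - start`` at the printed coordinates; the
  printed values are stored verbatim and flagged.
* ``carriers_ambiguous`` — the carrier-id column of haplotype 9.1 is not
  cleanly recoverable from the published table; the stored ids are the
  only assignment consistent with the carriers' printed founder-pair
  sets and the study's statement that the eleven haplotypes cover
  fourteen of the seventeen affected individuals.
* ``fp_conflict`` — where a carrier's founder-pair set printed in the
  haplotype table disagrees with the carrier matrix (ids 9 and 19), the
  carrier matrix is followed and the conflicting value recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..pedigree import Pedigree, pedigree_from_founder_sets

__all__ = [
    "FixtureTables",
    "load_fixture_tables",
    "table3_pedigree",
]


def _read(name: str) -> pd.DataFrame:
    path = resources.files(__package__) / "data" / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def _fp_set(text: str) -> frozenset[str]:
    return frozenset(text.split("/"))


@dataclass(frozen=True)
class FixtureTables:
    """The three published tables, lightly typed.

    ``haplotypes`` — one row per putative risk haplotype with integer
    coordinates, parsed carrier lists (``carrier_ids``), per-carrier
    founder-pair sets and diagnosis sets, and the transcription flags.
    ``variants`` — the five prioritized variants with numeric scores.
    ``carrier_matrix`` — 17 affected individuals x 4 variant-bearing
    haplotypes, plus each individual's founder-pair set.
    """

    haplotypes: pd.DataFrame
    variants: pd.DataFrame
    carrier_matrix: pd.DataFrame

    def haplotype(self, hap_id: str) -> pd.Series:
        sub = self.haplotypes[self.haplotypes["hap_id"] == hap_id]
        if sub.empty:
            raise KeyError(f"unknown haplotype id {hap_id!r}")
        return sub.iloc[0]

    def variant(self, rsid: str) -> pd.Series:
        sub = self.variants[self.variants["id"] == rsid]
        if sub.empty:
            raise KeyError(f"unknown variant id {rsid!r}")
        return sub.iloc[0]

    def carriers_of(self, hap_id: str) -> frozenset[str]:
        """Carrier ids of one of the four variant-bearing haplotypes."""
        col = f"hap_{hap_id}"
        if col not in self.carrier_matrix.columns:
            raise KeyError(f"haplotype {hap_id!r} not in the carrier matrix")
        m = self.carrier_matrix
        return frozenset(m.loc[m[col] == 1, "id"])


def load_fixture_tables() -> FixtureTables:
    """Load the transcribed study tables.

    Returns a :class:`FixtureTables` with 11 haplotype records, 5 variant
    records and the 17 x 4 carrier matrix.
    """
    t1 = _read("table1_haplotypes.tsv")
    for col in ("start_bp", "end_bp", "n_main_fp_carriers"):
        t1[col] = t1[col].astype(int)
    t1["length_printed_mb"] = t1["length_printed_mb"].astype(float)
    t1["length_computed_mb"] = (t1["end_bp"] - t1["start_bp"]) / 1e6
    for col in ("length_discrepant", "carriers_ambiguous"):
        t1[col] = t1[col].astype(int).astype(bool)
    t1["carrier_ids"] = t1["carriers"].map(lambda s: tuple(s.split(",")))
    t1["carrier_fp"] = t1["carrier_fp_sets"].map(
        lambda s: tuple(_fp_set(x) for x in s.split("|"))
    )
    t1["main_fp_set"] = t1["main_fp"].map(_fp_set)
    t1["carrier_diagnosis_sets"] = t1["carrier_diagnoses"].map(
        lambda s: tuple(frozenset(x.split(",")) for x in s.split("|"))
    )

    t2 = _read("table2_variants.tsv")
    t2["pos_bp"] = t2["pos_bp"].astype(int)
    for col in ("af_amr", "max_af", "cadd_phred"):
        t2[col] = t2[col].astype(float)
    for col in ("sift_score", "polyphen_score", "ncer_percentile", "pli", "missense_z"):
        t2[col] = pd.to_numeric(t2[col].replace(".", None))
    t2 = t2.replace({".": None})

    t3 = _read("table3_carriers.tsv")
    for col in t3.columns:
        if col.startswith("hap_"):
            t3[col] = t3[col].astype(int)
    t3["fp_set"] = t3["founder_pairs"].map(_fp_set)
    return FixtureTables(t1, t2, t3)


def table3_pedigree(tables: FixtureTables | None = None) -> Pedigree:
    """Synthetic pedigree realising the carrier matrix's ancestry sets.

    The true 11-generation pedigree is protected, so this builds a
    minimal synthetic stand-in in which every one of the 17 affected
    individuals descends from exactly the founder pairs the carrier
    matrix records, with private descent lines so that any two sampled
    individuals are related only through the founder couples.  Diagnoses
    come from the haplotype table where printed, defaulting to confirmed
    TS (the matrix covers TS-affected individuals only).
    """
    tables = tables or load_fixture_tables()
    founder_sets = {row["id"]: row["fp_set"] for _, row in tables.carrier_matrix.iterrows()}
    diagnoses: dict[str, set[str]] = {}
    for _, hap in tables.haplotypes.iterrows():
        if hap["carriers_ambiguous"]:
            continue
        for cid, diag in zip(hap["carrier_ids"], hap["carrier_diagnosis_sets"]):
            diagnoses.setdefault(cid, set()).update(diag)
    for ind_id in founder_sets:
        diagnoses.setdefault(ind_id, {"TS"})
    return pedigree_from_founder_sets(founder_sets, diagnoses)
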