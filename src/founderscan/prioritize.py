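"""Rare-variant prioritization of haplotype-specific variants.

Variants private to a risk haplotype's carriers are classified by
reference-population frequency (rare < 0.01, ultra-rare < 0.001) and
routed by consequence to one of two deleteriousness branches:

* coding (frameshift, nonsense, splice-site, missense): SIFT
  deleterious (including low-confidence), PolyPhen probably- or
  possibly-damaging, and CADD phred > 20;
* non-coding (everything else): CADD phred > 10 and ncER percentile
  > 95 (ncER is precomputed on hg19; positions whose GRCh38->hg19
  conversion is unstable carry a null ncER and fail with reason
  "unliftable").

All threshold inequalities are strict.  The optional ``strict_polyphen``
flag narrows PolyPhen to probably-damaging only, and
``cadd_or_predictors`` relaxes the coding branch to CADD OR the
SIFT/PolyPhen pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CODING_CONSEQUENCES = frozenset({"frameshift", "nonsense", "splice_site", "missense"})
SIFT_DELETERIOUS = frozenset({"deleterious", "deleterious_low_confidence"})
POLYPHEN_DAMAGING = frozenset({"probably_damaging", "possibly_damaging"})


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-variant annotation row (frequencies plus deleteriousness scores)."""

    id: str
    chrom: str
    pos_bp: int
    ref: str
    alt: str
    af_by_population: dict
    consequence: str
    gene: str | None = None
    aa_substitution: str | None = None
    sift: str | None = None
    sift_score: float | None = None
    polyphen: str | None = None
    polyphen_score: float | None = None
    cadd_phred: float = 0.0
    ncer_percentile: float | None = None
    pli: float | None = None
    missense_z: float | None = None

    def __post_init__(self) -> None:
        for pop, af in self.af_by_population.items():
            if af is not None and not 0 <= af <= 1:
                raise ValueError(f"AF for {pop} out of [0, 1]: {af}")
        if self.cadd_phred < 0:
            raise ValueError("CADD phred must be >= 0")
        if self.ncer_percentile is not None and not 0 <= self.ncer_percentile <= 100:
            raise ValueError("ncER percentile must be in [0, 100]")

    @property
    def is_coding(self) -> bool:
        return self.consequence in CODING_CONSEQUENCES


@dataclass
class PrioritizationThresholds:
    rare_max_af: float = 0.01
    ultra_rare_max_af: float = 0.001
    coding_min_cadd: float = 20.0
    noncoding_min_cadd: float = 10.0
    min_ncer: float = 95.0
    reference_population: str = "AMR"
    strict_polyphen: bool = False
    cadd_or_predictors: bool = False

    def __post_init__(self) -> None:
        if self.ultra_rare_max_af > self.rare_max_af:
            raise ValueError("ultra_rare_max_af must be <= rare_max_af")
        for name in ("coding_min_cadd", "noncoding_min_cadd", "min_ncer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def classify_rarity(
    af: float | None, thresholds: PrioritizationThresholds | None = None
) -> tuple[str, bool]:
    """(rarity class, missing-AF flag).

    ultra_rare iff af < 0.001; rare iff 0.001 <= af < 0.01; common
    otherwise (boundaries excluded).  A missing AF means absence from
    the reference database and is treated as the rarest class, flagged.
    """
    t = thresholds or PrioritizationThresholds()
    if af is None or (isinstance(af, float) and np.isnan(af)):
        return "ultra_rare", True
    if not 0 <= af <= 1:
        raise ValueError(f"allele frequency out of [0, 1]: {af}")
    if af < t.ultra_rare_max_af:
        return "ultra_rare", False
    if af < t.rare_max_af:
        return "rare", False
    return "common", False


def coding_filter(
    annotation: VariantAnnotation, thresholds: PrioritizationThresholds | None = None
) -> tuple[bool, list[str]]:
    """Coding-branch deleteriousness filter; returns (pass, fail reasons)."""
    t = thresholds or PrioritizationThresholds()
    reasons = []
    if annotation.consequence not in CODING_CONSEQUENCES:
        reasons.append("consequence")
    if annotation.sift not in SIFT_DELETERIOUS:
        reasons.append("sift")
    accepted_polyphen = {"probably_damaging"} if t.strict_polyphen else POLYPHEN_DAMAGING
    if annotation.polyphen not in accepted_polyphen:
        reasons.append("polyphen")
    cadd_ok = annotation.cadd_phred > t.coding_min_cadd
    if not cadd_ok:
        reasons.append("cadd")
    if t.cadd_or_predictors:
        predictors_ok = "sift" not in reasons and "polyphen" not in reasons
        if "consequence" not in reasons and (cadd_ok or predictors_ok):
            return True, []
        return False, reasons
    return (not reasons), reasons


def noncoding_filter(
    annotation: VariantAnnotation, thresholds: PrioritizationThresholds | None = None
) -> tuple[bool, list[str]]:
    """Non-coding-branch filter; returns (pass, fail reasons)."""
    t = thresholds or PrioritizationThresholds()
    reasons = []
    if annotation.is_coding:
        reasons.append("consequence")
    if not annotation.cadd_phred > t.noncoding_min_cadd:
        reasons.append("cadd")
    if annotation.ncer_percentile is None:
        reasons.append("unliftable")
    elif not annotation.ncer_percentile > t.min_ncer:
        reasons.append("ncer")
    return (not reasons), reasons


def max_population_af(annotation: VariantAnnotation) -> tuple[str, float, bool]:
    """(population, AF) attaining the maximum AF; ties flagged.

    Ties resolve to the lexicographically first population, with the
    third element True when a tie occurred.
    """
    items = {p: af for p, af in annotation.af_by_population.items() if af is not None}
    if not items:
        raise ValueError(f"variant {annotation.id!r} has no population AFs")
    best = max(items.values())
    winners = sorted(p for p, af in items.items() if af == best)
    return winners[0], best, len(winners) > 1


def prioritize(
    variant_ids: list[str],
    annotations: dict,
    thresholds: PrioritizationThresholds | None = None,
) -> pd.DataFrame:
    """Filter haplotype-specific variants; returns a Table-2-shaped report.

    ``annotations`` maps variant id -> :class:`VariantAnnotation`.  One
    row per input variant; column ``passed`` marks survivors, ``branch``
    the routing (coding / noncoding), ``fail_reasons`` the audit for the
    rest.  Common variants are dropped before branch routing.
    """
    t = thresholds or PrioritizationThresholds()
    missing = [v for v in variant_ids if v not in annotations]
    if missing:
        raise KeyError(f"variants without annotation rows: {missing}")
    rows = []
    for vid in variant_ids:
        ann = annotations[vid]
        af = ann.af_by_population.get(t.reference_population)
        rarity, af_missing = classify_rarity(af, t)
        branch = "coding" if ann.is_coding else "noncoding"
        if rarity == "common":
            passed, reasons = False, ["common"]
        elif branch == "coding":
            passed, reasons = coding_filter(ann, t)
        else:
            passed, reasons = noncoding_filter(ann, t)
        pop, max_af, tie = max_population_af(ann)
        rows.append(
            {
                "id": vid,
                "chrom": ann.chrom,
                "pos_bp": ann.pos_bp,
                "ref": ann.ref,
                "alt": ann.alt,
                "gene": ann.gene,
                "consequence": ann.consequence,
                "branch": branch,
                "rarity": rarity,
                "af_missing": af_missing,
                f"af_{t.reference_population.lower()}": af,
                "max_af": max_af,
                "max_af_population": pop,
                "max_af_tie": tie,
                "aa_substitution": ann.aa_substitution,
                "sift": ann.sift,
                "sift_score": ann.sift_score,
                "polyphen": ann.polyphen,
                "polyphen_score": ann.polyphen_score,
                "cadd_phred": ann.cadd_phred,
                "ncer_percentile": ann.ncer_percentile,
                "pli": ann.pli,
                "missense_z": ann.missense_z,
                "passed": passed,
                "fail_reasons": ",".join(reasons) or ".",
            }
        )
    return pd.DataFrame(rows)


def read_annotation_tsv(path) -> dict:
    """Read a variant-annotation TSV into {id: VariantAnnotation}.

    Expected columns: id, chrom, pos_bp, ref, alt, consequence, plus
    ``af_<POP>`` frequency columns (AMR required) and optional gene,
    aa_substitution, sift, sift_score, polyphen, polyphen_score,
    cadd_phred, ncer_percentile, pli, missense_z.  Empty fields and
    ``.`` are null.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).replace({".": None})
    af_cols = [c for c in df.columns if c.startswith("af_")]
    if not any(c.lower() == "af_amr" for c in af_cols):
        raise ValueError("annotation table must include an af_AMR column")
    out = {}
    for _, r in df.iterrows():
        afs = {
            c[3:].upper(): (float(r[c]) if r[c] is not None else None) for c in af_cols
        }

        def fnum(col):
            v = r.get(col)
            return float(v) if v is not None and v == v else None

        out[r["id"]] = VariantAnnotation(
            id=r["id"],
            chrom=str(r["chrom"]),
            pos_bp=int(r["pos_bp"]),
            ref=r["ref"],
            alt=r["alt"],
            af_by_population=afs,
            consequence=r["consequence"],
            gene=r.get("gene"),
            aa_substitution=r.get("aa_substitution"),
            sift=r.get("sift"),
            sift_score=fnum("sift_score"),
            polyphen=r.get("polyphen"),
            polyphen_score=fnum("polyphen_score"),
            cadd_phred=fnum("cadd_phred") or 0.0,
            ncer_percentile=fnum("ncer_percentile"),
            pli=fnum("pli"),
            missense_z=fnum("missense_z"),
        )
    return out


def write_annotation_tsv(annotations: dict, path) -> None:
    pops = sorted({p for a in annotations.values() for p in a.af_by_population})
    rows = []
    for a in annotations.values():
        row = {
            "id": a.id,
            "chrom": a.chrom,
            "pos_bp": a.pos_bp,
            "ref": a.ref,
            "alt": a.alt,
            "consequence": a.consequence,
            "gene": a.gene,
            "aa_substitution": a.aa_substitution,
            "sift": a.sift,
            "sift_score": a.sift_score,
            "polyphen": a.polyphen,
            "polyphen_score": a.polyphen_score,
            "cadd_phred": a.cadd_phred,
            "ncer_percentile": a.ncer_percentile,
            "pli": a.pli,
            "missense_z": a.missense_z,
        }
        for p in pops:
            row[f"af_{p}"] = a.af_by_population.get(p)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=".")
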