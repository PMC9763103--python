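"""Pedigree structure for a multi-founder-pair kindred.

A deep founder pedigree is modelled as a directed ancestry graph of
:class:`Individual` records, with a small number of labelled founder
couples ("founder pairs", labels ``A``..``F``) at generation 0.  Queries
needed by the IBD pipeline — from which founder pairs an individual
descends, and how many meioses separate two individuals — are graph
reachability / shortest-path computations on that structure.

Diagnoses are stored as sets because pedigree members routinely carry
co-morbid labels (e.g. a confirmed tic disorder plus probable ADHD).
"Affected" for the haplotype filters means a confirmed or probable
primary tic diagnosis (TS or chronic motor/vocal tic disorder);
OCD-only or unaffected individuals count as pedigree controls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

#: Diagnosis labels understood by the package.
DIAGNOSES = frozenset(
    {
        "TS",
        "TS_probable",
        "CMVT",
        "OCD",
        "OCD_probable",
        "ADHD",
        "ADHD_probable",
        "unaffected",
    }
)

#: Diagnoses that define "affected" status for the haplotype filters.
AFFECTED_DIAGNOSES = frozenset({"TS", "TS_probable", "CMVT"})


class PedigreeError(ValueError):
    """Raised for malformed pedigrees or unknown individual ids."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Parameters
    ----------
    id
        Unique identifier (string).
    father_id, mother_id
        Parent ids, or ``None`` for founders / married-in individuals.
    sex
        ``"male"``, ``"female"`` or ``"unknown"``.
    generation
        0 for founders (both parents unknown); otherwise strictly greater
        than both parents' generations.
    diagnosis
        Set of diagnosis labels (see :data:`DIAGNOSES`).
    sampled
        Whether genotype data exist for this individual.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    generation: int = 0
    diagnosis: frozenset[str] = field(default_factory=frozenset)
    sampled: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id!r}")
        unknown = set(self.diagnosis) - DIAGNOSES
        if unknown:
            raise PedigreeError(f"unknown diagnosis labels {sorted(unknown)} for {self.id!r}")
        object.__setattr__(self, "diagnosis", frozenset(self.diagnosis))

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def affected(self) -> bool:
        """Confirmed or probable TS/CMVT diagnosis."""
        return bool(self.diagnosis & AFFECTED_DIAGNOSES)


class Pedigree:
    """Directed ancestry graph with labelled founder pairs.

    Parameters
    ----------
    individuals
        Iterable of :class:`Individual`.
    founder_pairs
        Mapping of pair label (e.g. ``"A"``) to ``(father_id, mother_id)``;
        both must be founders.
    """

    def __init__(
        self,
        individuals: "list[Individual] | dict[str, Individual]",
        founder_pairs: dict[str, tuple[str, str]],
    ) -> None:
        if isinstance(individuals, dict):
            individuals = list(individuals.values())
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.founder_pairs = dict(founder_pairs)
        self._validate()
        self._fp_cache: dict[str, frozenset[str]] = {}

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    raise PedigreeError(f"individual {ind.id!r} references missing parent {pid!r}")
            if ind.is_founder:
                if ind.generation != 0:
                    raise PedigreeError(f"founder {ind.id!r} must have generation 0")
            else:
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None and ind.generation <= self.individuals[pid].generation:
                        raise PedigreeError(
                            f"{ind.id!r} generation {ind.generation} does not exceed "
                            f"parent {pid!r} generation"
                        )
        for label, (fid, mid) in self.founder_pairs.items():
            for pid in (fid, mid):
                if pid not in self.individuals:
                    raise PedigreeError(f"founder pair {label!r} names missing individual {pid!r}")
                if not self.individuals[pid].is_founder:
                    raise PedigreeError(f"founder pair {label!r} member {pid!r} is not a founder")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.individuals:
            if start in state:
                continue
            stack = [(start, iter(self._parents(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise PedigreeError("ancestry graph contains a cycle")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    # -- basic queries ----------------------------------------------------
    def _parents(self, ind_id: str) -> list[str]:
        ind = self.individuals[ind_id]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    def _require(self, ind_id: str) -> Individual:
        try:
            return self.individuals[ind_id]
        except KeyError:
            raise PedigreeError(f"unknown individual id {ind_id!r}") from None

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    @property
    def sampled_ids(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.sampled]

    @property
    def founder_ids(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.is_founder]

    def ancestors(self, ind_id: str) -> set[str]:
        """All strict ancestors of *ind_id* (breadth-first walk)."""
        self._require(ind_id)
        seen: set[str] = set()
        frontier = self._parents(ind_id)
        while frontier:
            nxt: list[str] = []
            for p in frontier:
                if p not in seen:
                    seen.add(p)
                    nxt.extend(self._parents(p))
            frontier = nxt
        return seen

    def founder_ancestry(self, ind_id: str) -> frozenset[str]:
        """Founder-pair labels from which *ind_id* descends.

        A founder-pair member is considered its own descendant, so a
        founder of pair ``B`` has ancestry ``{"B"}``.
        """
        self._require(ind_id)
        cached = self._fp_cache.get(ind_id)
        if cached is not None:
            return cached
        reachable = self.ancestors(ind_id) | {ind_id}
        labels = frozenset(
            label
            for label, (fid, mid) in self.founder_pairs.items()
            if fid in reachable or mid in reachable
        )
        self._fp_cache[ind_id] = labels
        return labels

    def meiotic_distance(self, id1: str, id2: str) -> float:
        """Minimum number of meioses separating two individuals.

        Minimises, over common ancestors ``c`` (including the endpoints
        themselves), ``up_steps(id1, c) + up_steps(id2, c)``.  Returns
        ``math.inf`` when the two share no common ancestor.
        """
        self._require(id1)
        self._require(id2)
        d1 = self._up_distances(id1)
        d2 = self._up_distances(id2)
        common = d1.keys() & d2.keys()
        if not common:
            return float("inf")
        return min(d1[c] + d2[c] for c in common)

    def _up_distances(self, ind_id: str) -> dict[str, int]:
        dist = {ind_id: 0}
        frontier = [ind_id]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for node in frontier:
                for p in self._parents(node):
                    if p not in dist:
                        dist[p] = depth
                        nxt.append(p)
            frontier = nxt
        return dist

    def relabel_diagnosis(self, ind_id: str, diagnosis: set[str]) -> None:
        """Replace the diagnosis set of one individual in place."""
        ind = self._require(ind_id)
        self.individuals[ind_id] = replace(ind, diagnosis=frozenset(diagnosis))

    # -- IO ---------------------------------------------------------------
    _SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}
    _FAM_TO_SEX = {"1": "male", "2": "female"}

    def to_fam(self, fam_path, sidecar_path=None, family_id: str = "FAM1") -> None:
        """Write a 6-column FAM/PED file plus an optional side-car TSV.

        FAM columns: family, id, father (0 = unknown), mother, sex
        (1/2/0), phenotype (2 = affected, 1 = unaffected, -9 = missing).
        The side-car carries what FAM cannot: generation, sampled flag,
        diagnosis set and founder-pair labels.
        """
        order = sorted(self.individuals.values(), key=lambda i: (i.generation, i.id))
        rows = []
        for ind in order:
            pheno = "2" if ind.affected else ("1" if ind.diagnosis else "-9")
            rows.append(
                (
                    family_id,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    self._SEX_TO_FAM[ind.sex],
                    pheno,
                )
            )
        pd.DataFrame(rows).to_csv(fam_path, sep="\t", header=False, index=False)
        if sidecar_path is not None:
            fp_of = {}
            for label, (fid, mid) in sorted(self.founder_pairs.items()):
                fp_of[fid] = fp_of[mid] = label
            side = pd.DataFrame(
                {
                    "id": [i.id for i in order],
                    "generation": [i.generation for i in order],
                    "sampled": [int(i.sampled) for i in order],
                    "diagnosis": [",".join(sorted(i.diagnosis)) or "." for i in order],
                    "founder_pair": [fp_of.get(i.id, ".") for i in order],
                    "founder_pair_role": [
                        (
                            "father"
                            if i.id in fp_of and self.founder_pairs[fp_of[i.id]][0] == i.id
                            else ("mother" if i.id in fp_of else ".")
                        )
                        for i in order
                    ],
                }
            )
            side.to_csv(sidecar_path, sep="\t", index=False)

    @classmethod
    def from_fam(cls, fam_path, sidecar_path=None) -> "Pedigree":
        """Read a pedigree written by :meth:`to_fam` (round-trips)."""
        fam = pd.read_csv(
            fam_path,
            sep=r"\s+",
            header=None,
            names=["family", "id", "father", "mother", "sex", "phenotype"],
            dtype=str,
        )
        side = None
        if sidecar_path is not None:
            side = pd.read_csv(sidecar_path, sep="\t", dtype=str).set_index("id")
        individuals = []
        founder_pairs: dict[str, dict[str, str]] = {}
        # generations: recompute if no sidecar
        parents = {
            r.id: [p for p in (r.father, r.mother) if p != "0"] for r in fam.itertuples()
        }
        gen_cache: dict[str, int] = {}

        def gen_of(ind_id: str) -> int:
            if ind_id in gen_cache:
                return gen_cache[ind_id]
            ps = parents.get(ind_id, [])
            g = 0 if not ps else 1 + max(gen_of(p) for p in ps)
            gen_cache[ind_id] = g
            return g

        for r in fam.itertuples():
            diagnosis: set[str] = set()
            sampled = False
            generation = gen_of(r.id)
            if side is not None and r.id in side.index:
                srow = side.loc[r.id]
                generation = int(srow["generation"])
                sampled = bool(int(srow["sampled"]))
                if srow["diagnosis"] != ".":
                    diagnosis = set(srow["diagnosis"].split(","))
                if srow["founder_pair"] != ".":
                    founder_pairs.setdefault(srow["founder_pair"], {})[
                        srow["founder_pair_role"]
                    ] = r.id
            elif r.phenotype == "2":
                diagnosis = {"TS"}
            elif r.phenotype == "1":
                diagnosis = {"unaffected"}
            individuals.append(
                Individual(
                    id=r.id,
                    father_id=None if r.father == "0" else r.father,
                    mother_id=None if r.mother == "0" else r.mother,
                    sex=cls._FAM_TO_SEX.get(r.sex, "unknown"),
                    generation=generation,
                    diagnosis=frozenset(diagnosis),
                    sampled=sampled,
                )
            )
        pairs = {
            label: (members["father"], members["mother"])
            for label, members in founder_pairs.items()
        }
        return cls(individuals, pairs)


# -- module-level functional aliases -------------------------------------

def founder_ancestry(pedigree: Pedigree, individual_id: str) -> frozenset[str]:
    """Founder-pair labels from which *individual_id* descends."""
    return pedigree.founder_ancestry(individual_id)


def meiotic_distance(pedigree: Pedigree, id1: str, id2: str) -> float:
    """Minimum meioses separating two individuals (inf if unrelated)."""
    return pedigree.meiotic_distance(id1, id2)


def pedigree_from_founder_sets(
    founder_sets: dict[str, frozenset[str] | set[str]],
    diagnoses: dict[str, set[str]] | None = None,
    pair_labels: tuple[str, ...] = ("A", "B", "C", "D", "E", "F"),
    chain_length: int = 4,
) -> Pedigree:
    """Build a synthetic pedigree realising given founder-pair ancestries.

    Each requested individual gets a private lineage of ``chain_length``
    generations that merges ancestor lines covering exactly the founder
    pairs in its set, so ``founder_ancestry`` reproduces the requested
    sets and any two requested individuals are related only through the
    founder couples themselves.  Useful for turning a carrier/ancestry
    table into an analysable pedigree when the true pedigree is
    protected.
    """
    diagnoses = diagnoses or {}
    individuals: dict[str, Individual] = {}
    counter = itertools.count()

    def add(ind: Individual) -> str:
        individuals[ind.id] = ind
        return ind.id

    founder_pairs: dict[str, tuple[str, str]] = {}
    for label in pair_labels:
        fid = add(Individual(id=f"FP{label}.f", sex="male"))
        mid = add(Individual(id=f"FP{label}.m", sex="female"))
        founder_pairs[label] = (fid, mid)

    def married_in(sex: str) -> str:
        return add(Individual(id=f"ext{next(counter)}", sex=sex))

    def line(owner: str, labels: tuple[str, ...], generation: int, sex: str) -> str:
        """An ancestor of *owner* at *generation* descending from *labels*."""
        node_id = f"{owner}.anc{next(counter)}"
        if len(labels) == 1:
            label = labels[0]
            if generation == 1:
                father, mother = founder_pairs[label]
            else:
                father = line(owner, labels, generation - 1, "male")
                mother = married_in("female")
        else:
            half = (len(labels) + 1) // 2
            father = line(owner, labels[:half], generation - 1, "male")
            mother = line(owner, labels[half:], generation - 1, "female")
        return add(
            Individual(
                id=node_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                generation=generation,
            )
        )

    for ind_id, labels in founder_sets.items():
        labels = tuple(sorted(labels))
        if not labels:
            raise PedigreeError(f"empty founder set for {ind_id!r}")
        depth = max(chain_length, 1 + (len(labels) - 1).bit_length() + 1)
        father = line(ind_id, labels, depth - 1, "male")
        mother = married_in("female")
        add(
            Individual(
                id=ind_id,
                father_id=father,
                mother_id=mother,
                sex="unknown",
                generation=depth,
                diagnosis=frozenset(diagnoses.get(ind_id, set())),
                sampled=True,
            )
        )
    return Pedigree(individuals, founder_pairs)
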