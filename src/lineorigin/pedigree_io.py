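"""Pedigree, genotype and result containers with their text formats.

The unit of analysis is a three-generation F2 intercross between two
outbred lines: line-labelled founders (grandparents of the mapping
generation), F1 parents each with one line-1 and one line-2 founder parent,
and F2 offspring of two F1s.  ``Pedigree`` validates that structure on
construction.  Genotypes are biallelic SNPs stored as allele-dosage codes
(0, 1, 2, or -1 for missing); genotypes are unordered (0/1 and 1/0 are the
same observation).

All file formats are plain tab-separated text with headers, and all writers
are byte-deterministic for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GenotypeError, PedigreeError
from .genetic_map import GeneticMap

__all__ = [
    "Individual",
    "Pedigree",
    "GenotypeMatrix",
    "PosteriorGrid",
    "MISSING",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_posteriors",
    "write_posteriors",
    "write_switches",
    "read_switches",
]

MISSING = -1  # genotype code for a missing observation

FOUNDER, F1, F2 = "founder", "F1", "F2"
_NONE = "."


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "U"  # 'M', 'F' or 'U'
    line: int | None = None  # founder line label (1 or 2); None for non-founders
    generation: str | None = None  # filled in by Pedigree

    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Validated three-generation intercross pedigree.

    Generations are inferred from parent links: individuals without parents
    are founders, children of two founders are F1, children of two F1s are
    F2.  Construction fails with :class:`PedigreeError` (naming the
    offending individuals) on missing parent records, cycles, pedigrees
    deeper than three generations, F1s without exactly one founder parent
    from each line, or F2s whose parents are the same F1.
    """

    def __init__(self, individuals: Iterable[Individual]):
        inds = list(individuals)
        ids = [i.id for i in inds]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual ids: {dup}")
        self._by_id: dict[str, Individual] = {}
        # check parent references before anything else
        idset = set(ids)
        for ind in inds:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in idset:
                    raise PedigreeError(f"individual {ind.id}: parent {parent} has no record")
            if (ind.sire is None) != (ind.dam is None):
                raise PedigreeError(f"individual {ind.id}: must have both parents or neither")
        generation = self._infer_generations(inds)
        for ind in inds:
            gen = generation[ind.id]
            if gen == FOUNDER:
                if ind.line not in (1, 2):
                    raise PedigreeError(f"founder {ind.id}: line must be 1 or 2, got {ind.line}")
            elif ind.line is not None:
                raise PedigreeError(f"non-founder {ind.id} must not carry a line label")
            self._by_id[ind.id] = Individual(
                ind.id, ind.sire, ind.dam, ind.sex, ind.line, gen
            )
        self._validate_structure()
        self._order = tuple(i.id for i in inds)

    @staticmethod
    def _infer_generations(inds: Sequence[Individual]) -> dict[str, str]:
        by_id = {i.id: i for i in inds}
        depth: dict[str, int] = {}

        def walk(iid: str, stack: tuple[str, ...]) -> int:
            if iid in stack:
                cycle = " -> ".join(stack + (iid,))
                raise PedigreeError(f"pedigree contains a cycle: {cycle}")
            if iid in depth:
                return depth[iid]
            ind = by_id[iid]
            if ind.is_founder():
                d = 0
            else:
                d = 1 + max(walk(ind.sire, stack + (iid,)), walk(ind.dam, stack + (iid,)))
            depth[iid] = d
            return d

        for ind in inds:
            walk(ind.id, ())
        names = {0: FOUNDER, 1: F1, 2: F2}
        out = {}
        for iid, d in depth.items():
            if d > 2:
                raise PedigreeError(f"individual {iid} is {d} generations deep; only founder/F1/F2 supported")
            out[iid] = names[d]
        return out

    def _validate_structure(self) -> None:
        for ind in self._by_id.values():
            if ind.generation == F1:
                sire = self._by_id[ind.sire]
                dam = self._by_id[ind.dam]
                if sire.generation != FOUNDER or dam.generation != FOUNDER:
                    raise PedigreeError(f"F1 {ind.id}: both parents must be founders")
                lines = sorted((sire.line, dam.line))
                if lines != [1, 2]:
                    raise PedigreeError(
                        f"F1 {ind.id}: needs one line-1 and one line-2 founder parent, "
                        f"got lines {sire.line} ({sire.id}) and {dam.line} ({dam.id})"
                    )
            elif ind.generation == F2:
                sire = self._by_id[ind.sire]
                dam = self._by_id[ind.dam]
                if sire.generation != F1 or dam.generation != F1:
                    raise PedigreeError(f"F2 {ind.id}: both parents must be F1 individuals")
                if sire.id == dam.id:
                    raise PedigreeError(f"F2 {ind.id}: selfed F1 parent {sire.id} not allowed")
                if sire.sex == "F" or dam.sex == "M":
                    raise PedigreeError(f"F2 {ind.id}: sire must be male and dam female")

    # -- accessors ---------------------------------------------------------
    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return (self._by_id[i] for i in self._order)

    def ids(self) -> tuple[str, ...]:
        return self._order

    def founders(self) -> list[Individual]:
        return [i for i in self if i.generation == FOUNDER]

    def f1(self) -> list[Individual]:
        return [i for i in self if i.generation == F1]

    def f2(self) -> list[Individual]:
        return [i for i in self if i.generation == F2]

    def grandparents_by_line(self, f1_id: str) -> tuple[Individual, Individual]:
        """The founder parents of an F1, ordered (line-1 parent, line-2 parent)."""
        f1 = self._by_id[f1_id]
        if f1.generation != F1:
            raise PedigreeError(f"{f1_id} is not an F1 individual")
        sire, dam = self._by_id[f1.sire], self._by_id[f1.dam]
        return (sire, dam) if sire.line == 1 else (dam, sire)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": i.id,
                "sire": i.sire or _NONE,
                "dam": i.dam or _NONE,
                "sex": i.sex,
                "line": i.line if i.line is not None else _NONE,
            }
            for i in self
        ]
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "line"])


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV: columns ``id  sire  dam  sex  line`` (``.`` = none)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "sex", "line"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file {path} must have columns {sorted(required)}")
    inds = []
    for row in df.itertuples(index=False):
        line = None if row.line in (_NONE, "") else int(row.line)
        sex = row.sex.upper() if row.sex not in (_NONE, "") else "U"
        if sex not in ("M", "F", "U"):
            raise PedigreeError(f"individual {row.id}: sex must be M/F/U, got {row.sex}")
        inds.append(
            Individual(
                id=str(row.id),
                sire=None if row.sire in (_NONE, "") else str(row.sire),
                dam=None if row.dam in (_NONE, "") else str(row.dam),
                sex=sex,
                line=line,
            )
        )
    return Pedigree(inds)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


class GenotypeMatrix:
    """Biallelic genotypes for a set of individuals over the map's markers.

    Stored as an int8 array of allele-1 dosages: 0 (=0/0), 1 (=0/1),
    2 (=1/1), -1 missing.  Genotypes are unordered pairs.
    """

    def __init__(self, individual_ids: Sequence[str], marker_ids: Sequence[str], codes: np.ndarray):
        self.individual_ids = tuple(str(i) for i in individual_ids)
        self.marker_ids = tuple(str(m) for m in marker_ids)
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise GenotypeError(
                f"genotype codes shape {codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if not np.isin(codes, (-1, 0, 1, 2)).all():
            raise GenotypeError("genotype codes must be in {-1, 0, 1, 2}")
        self.codes = codes
        self._row_index = {iid: k for k, iid in enumerate(self.individual_ids)}

    def row(self, individual_id: str) -> np.ndarray:
        """Dosage codes for one individual over all markers (all -1 if absent)."""
        k = self._row_index.get(individual_id)
        if k is None:
            return np.full(len(self.marker_ids), MISSING, dtype=np.int8)
        return self.codes[k]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._row_index

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def to_frame(self) -> pd.DataFrame:
        strings = np.array(["0/0", "0/1", "1/1"], dtype=object)
        body = np.where(self.codes >= 0, strings[np.clip(self.codes, 0, 2)], "NA")
        df = pd.DataFrame(body, columns=list(self.marker_ids))
        df.insert(0, "id", list(self.individual_ids))
        return df


def write_genotypes(gm: GenotypeMatrix, path, missing: str = "NA") -> None:
    df = gm.to_frame()
    if missing != "NA":
        df = df.replace("NA", missing)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, gmap: GeneticMap, pedigree: Pedigree, missing: str = "NA") -> GenotypeMatrix:
    """Read a genotype TSV (rows = individuals, columns = markers).

    Entries are allele pairs like ``0/1`` (unordered) or the missing
    sentinel.  Alleles are recoded to 0/1 per marker; a marker showing more
    than two allele symbols, or an individual absent from the pedigree, is
    an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise GenotypeError(f"genotype file {path} must have an 'id' column")
    absent = [m for m in gmap.marker_ids if m not in df.columns]
    if absent:
        raise GenotypeError(f"genotype file {path} lacks columns for map markers: {absent[:5]} ...")
    unknown = [i for i in df["id"] if i not in pedigree]
    if unknown:
        raise GenotypeError(f"genotype file {path}: individuals not in pedigree: {unknown[:5]}")
    n_ind, n_mark = len(df), gmap.n_markers
    codes = np.full((n_ind, n_mark), MISSING, dtype=np.int8)
    for j, marker in enumerate(gmap.marker_ids):
        col = df[marker].to_numpy(dtype=object)
        obs = col != missing
        if not obs.any():
            continue
        pairs = [entry.split("/") for entry in col[obs]]
        bad = [p for p in pairs if len(p) != 2]
        if bad:
            raise GenotypeError(f"marker {marker}: malformed genotype {'/'.join(bad[0])!r}")
        alleles = sorted({a for p in pairs for a in p})
        if len(alleles) > 2:
            raise GenotypeError(f"marker {marker}: more than two alleles observed: {alleles}")
        if set(alleles) <= {"0", "1"}:
            recode = {"0": 0, "1": 1}
        else:
            recode = {a: k for k, a in enumerate(alleles)}
        codes[obs, j] = [recode[a] + recode[b] for a, b in pairs]
    return GenotypeMatrix(df["id"].tolist(), gmap.marker_ids, codes)


# -- posterior container ---------------------------------------------------

# State order convention used throughout: (maternal origin, paternal origin)
# = (1,1), (1,2), (2,1), (2,2).
STATE_COLUMNS = ("p11", "p12", "p21", "p22")


@dataclass
class PosteriorGrid:
    """Line-origin posteriors for a set of F2 individuals at test positions.

    ``probs[k, p, s]`` is the posterior probability that individual ``k``
    has line-origin state ``s`` at test position ``p``, in the fixed order
    (1,1), (1,2), (2,1), (2,2) where the first index is the maternal
    haplotype's line of origin.  The per-haplotype line-1 probabilities are
    the marginal sums p1_maternal = P(1,1)+P(1,2) and
    p1_paternal = P(1,1)+P(2,1).
    """

    individuals: tuple[str, ...]
    positions_cM: np.ndarray
    probs: np.ndarray  # (n_individuals, n_positions, 4)

    def __post_init__(self):
        self.individuals = tuple(self.individuals)
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (len(self.individuals), self.positions_cM.size, 4)
        if self.probs.shape != expected:
            raise ValueError(f"probs shape {self.probs.shape} != {expected}")
        sums = self.probs.sum(axis=2)
        if self.probs.size and not np.allclose(sums, 1.0, atol=1e-9, rtol=0):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(f"posteriors must sum to 1 at every point (max deviation {worst:g})")
        self._index = {iid: k for k, iid in enumerate(self.individuals)}

    @property
    def p1_maternal(self) -> np.ndarray:
        return self.probs[:, :, 0] + self.probs[:, :, 1]

    @property
    def p1_paternal(self) -> np.ndarray:
        return self.probs[:, :, 0] + self.probs[:, :, 2]

    def for_individual(self, iid: str) -> np.ndarray:
        return self.probs[self._index[iid]]

    def p1(self, iid: str, haplotype: str) -> np.ndarray:
        """Line-1 probability series for one haplotype of one individual."""
        k = self._index[iid]
        if haplotype == "maternal":
            return self.probs[k, :, 0] + self.probs[k, :, 1]
        if haplotype == "paternal":
            return self.probs[k, :, 0] + self.probs[k, :, 2]
        raise KeyError(f"haplotype must be 'maternal' or 'paternal', got {haplotype!r}")

    def to_frame(self) -> pd.DataFrame:
        columns = ["individual", "position_cM", *STATE_COLUMNS, "p1_maternal", "p1_paternal"]
        if not self.individuals:
            return pd.DataFrame(columns=columns)
        order = np.argsort(np.array(self.individuals, dtype=object), kind="stable")
        frames = []
        for k in order:
            df = pd.DataFrame(self.probs[k], columns=list(STATE_COLUMNS))
            df.insert(0, "position_cM", self.positions_cM)
            df.insert(0, "individual", self.individuals[k])
            df["p1_maternal"] = df["p11"] + df["p12"]
            df["p1_paternal"] = df["p11"] + df["p21"]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def write_posteriors(grid: PosteriorGrid, path) -> None:
    """Write a posterior TSV, rows sorted by (individual, position)."""
    grid.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_posteriors(path) -> PosteriorGrid:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str})
    required = {"individual", "position_cM", *STATE_COLUMNS}
    if not required.issubset(df.columns):
        raise GenotypeError(f"posterior file {path} must have columns {sorted(required)}")
    individuals = list(dict.fromkeys(df["individual"]))
    positions = np.sort(df["position_cM"].unique())
    probs = np.empty((len(individuals), positions.size, 4))
    for k, iid in enumerate(individuals):
        sub = df[df["individual"] == iid].sort_values("position_cM")
        if sub.shape[0] != positions.size:
            raise GenotypeError(f"posterior file {path}: ragged grid for individual {iid}")
        probs[k] = sub[list(STATE_COLUMNS)].to_numpy()
    return PosteriorGrid(individuals, positions, probs)


_SWITCH_COLUMNS = [
    "individual",
    "haplotype",
    "direction",
    "start_cM",
    "end_cM",
    "cross_cM",
    "imprecision_cM",
    "matched_truth_cM",
    "inaccuracy_cM",
]


def write_switches(switches, path) -> None:
    """Write switch records (see :mod:`lineorigin.evaluate`) as a TSV."""
    rows = [
        {
            "individual": s.individual,
            "haplotype": s.haplotype,
            "direction": s.direction,
            "start_cM": s.start_cM,
            "end_cM": s.end_cM,
            "cross_cM": s.cross_cM,
            "imprecision_cM": s.imprecision_cM,
            "matched_truth_cM": "" if s.matched_truth_cM is None else s.matched_truth_cM,
            "inaccuracy_cM": "" if s.inaccuracy_cM is None else s.inaccuracy_cM,
        }
        for s in switches
    ]
    df = pd.DataFrame(rows, columns=_SWITCH_COLUMNS)
    df = df.sort_values(["individual", "haplotype", "cross_cM"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_switches(path):
    from .evaluate import SwitchRecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"individual": str})
    out = []
    for row in df.itertuples(index=False):
        matched = None if pd.isna(row.matched_truth_cM) else float(row.matched_truth_cM)
        inacc = None if pd.isna(row.inaccuracy_cM) else float(row.inaccuracy_cM)
        out.append(
            SwitchRecord(
                individual=row.individual,
                haplotype=row.haplotype,
                direction=row.direction,
                start_cM=float(row.start_cM),
                end_cM=float(row.end_cM),
                cross_cM=float(row.cross_cM),
                matched_truth_cM=matched,
                inaccuracy_cM=inacc,
            )
        )
    return out
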