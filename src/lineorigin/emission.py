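"""Compatibility-based emission probabilities for the four line-origin states.

For an F2 individual at one marker, the hidden state is the pair
(maternal origin, paternal origin) with each origin in {line 1, line 2}.
The emission probability of the observed genotype under a state is driven
by Mendelian compatibility with the F1 parents' and the founders'
genotypes: for each F1 parent we work out, per line, which alleles it could
transmit on a haplotype of that line origin (its *transmissible allele
sets*), and a state is compatible when the F2 genotype can be composed
from one maternal and one paternal allele drawn from the corresponding
sets.  Compatible states emit 1; incompatible states emit a small floor
``error_floor`` so that genotyping errors never zero out the likelihood.
Missing F2 genotypes emit 1 in every state.

An optional frequency-weighted variant replaces the flat 1 by the
probability of the observed genotype when transmitted alleles are drawn
uniformly from the transmissible sets; it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pedigree_io import MISSING, GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "STATE_LABELS",
    "EmissionConfig",
    "EmissionTable",
    "transmissible_alleles",
    "emission",
    "build_emission_table",
]

# Fixed state order: (maternal origin, paternal origin).
STATES = ((1, 1), (1, 2), (2, 1), (2, 2))
STATE_LABELS = ("1,1", "1,2", "2,1", "2,2")


@dataclass(frozen=True)
class EmissionConfig:
    """Emission model parameters.

    error_floor
        Probability assigned to Mendelian-incompatible states, in (0, 0.5).
        Keeps the likelihood positive in the presence of genotyping errors.
    frequency_weighted
        If True, compatible states emit the probability of the observed
        genotype under uniform draws from the transmissible allele sets
        instead of a flat 1.
    """

    error_floor: float = 0.01
    frequency_weighted: bool = False

    def __post_init__(self):
        if not (0.0 < self.error_floor < 0.5):
            raise ValueError(f"error_floor must be in (0, 0.5), got {self.error_floor}")


def _alleles(code: int) -> tuple[int, ...]:
    """Unordered allele pair of a dosage code; empty tuple when missing."""
    return {MISSING: (), 0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(code)]


def _gp_allows(gp_code: int, allele: int) -> bool:
    return gp_code == MISSING or allele in _alleles(gp_code)


def transmissible_alleles(parent_code: int, gp_line1_code: int, gp_line2_code: int):
    """Alleles an F1 parent can transmit on its line-1 and line-2 haplotypes.

    Enumerates the two assignments of the parent's allele pair to (from
    line-1 founder, from line-2 founder); an assignment is Mendelian-
    consistent if each side's allele occurs in the corresponding founder's
    genotype (a missing founder genotype imposes no constraint).  Returns
    ``(line1_set, line2_set)`` as frozensets.  If neither assignment is
    consistent the constraint from the founders is dropped (both sets fall
    back to the parent's own alleles — or {0,1} if the parent is
    ungenotyped) and a warning is logged: the error floor downstream is
    what absorbs such likely genotyping errors.
    """
    if parent_code == MISSING:
        s1 = frozenset(a for a in (0, 1) if _gp_allows(gp_line1_code, a))
        s2 = frozenset(a for a in (0, 1) if _gp_allows(gp_line2_code, a))
        return s1 or frozenset((0, 1)), s2 or frozenset((0, 1))
    pa, pb = _alleles(parent_code)
    orderings = {(pa, pb), (pb, pa)}
    s1, s2 = set(), set()
    for to_line1, to_line2 in orderings:
        if _gp_allows(gp_line1_code, to_line1) and _gp_allows(gp_line2_code, to_line2):
            s1.add(to_line1)
            s2.add(to_line2)
    if not s1:
        fallback = frozenset(_alleles(parent_code))
        logger.warning(
            "Mendelian inconsistency: parent genotype %s cannot derive from founder "
            "genotypes (%s, %s); relaxing constraint at this marker",
            parent_code, gp_line1_code, gp_line2_code,
        )
        return fallback, fallback
    return frozenset(s1), frozenset(s2)


def emission(
    f2_code: int,
    mother_sets: tuple[frozenset, frozenset],
    father_sets: tuple[frozenset, frozenset],
    state: tuple[int, int],
    config: EmissionConfig = EmissionConfig(),
) -> float:
    """Emission value of one F2 genotype under one line-origin state."""
    if f2_code == MISSING:
        return 1.0
    x, y = _alleles(f2_code)
    m = mother_sets[state[0] - 1]
    p = father_sets[state[1] - 1]
    compatible = (x in m and y in p) or (y in m and x in p)
    if not compatible:
        return config.error_floor
    if config.frequency_weighted:
        hits = sum(1 for a in m for b in p if tuple(sorted((a, b))) == (x, y))
        return max(hits / (len(m) * len(p)), config.error_floor)
    return 1.0


class EmissionTable:
    """Per-F2, per-marker, per-state emission values.

    ``values[k, j, s]`` is the emission for F2 individual ``k`` (order
    ``f2_ids``) at marker ``j`` under state ``s`` (order :data:`STATES`).
    """

    def __init__(self, f2_ids, marker_ids, values: np.ndarray):
        self.f2_ids = tuple(f2_ids)
        self.marker_ids = tuple(marker_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.f2_ids), len(self.marker_ids), 4):
            raise ValueError("emission values shape mismatch")
        self._index = {iid: k for k, iid in enumerate(self.f2_ids)}

    def for_individual(self, iid: str) -> np.ndarray:
        return self.values[self._index[iid]]


def _parent_set_array(
    parent_row: np.ndarray,
    gp1_row: np.ndarray,
    gp2_row: np.ndarray,
    phase: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised transmissible sets for one F1 parent over all markers.

    Returns a boolean array of shape (n_markers, 2 lines, 2 alleles) where
    ``out[j, i, a]`` means allele ``a`` can ride on the line-(i+1)
    haplotype at marker ``j``.  ``phase``, if given, is an (n_markers, 2)
    int array of known (line-1 allele, line-2 allele) with -1 = unresolved;
    resolved markers collapse to singleton sets.
    """
    n = parent_row.size
    out = np.zeros((n, 2, 2), dtype=bool)

    def allows(gp_row, allele):
        if allele == 0:
            present = (gp_row == 0) | (gp_row == 1)
        else:
            present = (gp_row == 2) | (gp_row == 1)
        return (gp_row == MISSING) | present

    g1a0, g1a1 = allows(gp1_row, 0), allows(gp1_row, 1)
    g2a0, g2a1 = allows(gp2_row, 0), allows(gp2_row, 1)

    p_missing = parent_row == MISSING
    out[p_missing, 0, 0] = g1a0[p_missing]
    out[p_missing, 0, 1] = g1a1[p_missing]
    out[p_missing, 1, 0] = g2a0[p_missing]
    out[p_missing, 1, 1] = g2a1[p_missing]
    # an ungenotyped parent with an impossible founder pair: no constraint
    empty = p_missing & ~out[:, 0].any(axis=1)
    out[empty, 0] = True
    empty = p_missing & ~out[:, 1].any(axis=1)
    out[empty, 1] = True

    for code, allele in ((0, 0), (2, 1)):
        hom = parent_row == code
        out[hom, 0, allele] = True
        out[hom, 1, allele] = True

    het = parent_row == 1
    ord1 = g1a0 & g2a1  # allele 0 from the line-1 founder, 1 from the line-2 founder
    ord2 = g1a1 & g2a0
    out[het, 0, 0] = ord1[het]
    out[het, 0, 1] = ord2[het]
    out[het, 1, 0] = ord2[het]
    out[het, 1, 1] = ord1[het]
    inconsistent = het & ~(ord1 | ord2)
    if inconsistent.any():
        logger.warning(
            "%d marker(s) Mendelian-inconsistent between a heterozygous parent and "
            "its founders; constraints relaxed there", int(inconsistent.sum())
        )
        out[inconsistent, :, :] = True

    if phase is not None:
        for line in (0, 1):
            known = phase[:, line] >= 0
            refined = np.zeros((n, 2), dtype=bool)
            refined[np.arange(n), np.clip(phase[:, line], 0, 1)] = True
            out[known, line, :] &= refined[known]
            # a phase contradicting the sets would empty them; keep the phase
            empty = known & ~out[:, line].any(axis=1)
            out[empty, line, :] = refined[empty]
    return out


def build_emission_table(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: EmissionConfig = EmissionConfig(),
    parental_phase: dict[str, np.ndarray] | None = None,
) -> EmissionTable:
    """Assemble the emission table for every F2 individual and marker.

    ``parental_phase`` optionally maps F1 ids to (n_markers, 2) int arrays
    of known (line-1 allele, line-2 allele), -1 where unresolved — e.g.
    simulator truth or the output of
    :func:`lineorigin.simulate.phase_parent`.
    """
    marker_ids = genotypes.marker_ids
    n_mark = len(marker_ids)
    f2 = pedigree.f2()
    f2_ids = [i.id for i in f2]

    parent_sets: dict[str, np.ndarray] = {}
    for parent in pedigree.f1():
        gp1, gp2 = pedigree.grandparents_by_line(parent.id)
        phase = None
        if parental_phase is not None and parent.id in parental_phase:
            phase = np.asarray(parental_phase[parent.id], dtype=int)
            if phase.shape != (n_mark, 2):
                raise ValueError(f"parental_phase[{parent.id}] must have shape ({n_mark}, 2)")
        parent_sets[parent.id] = _parent_set_array(
            genotypes.row(parent.id), genotypes.row(gp1.id), genotypes.row(gp2.id), phase
        )

    if f2_ids:
        mother = np.stack([parent_sets[i.dam] for i in f2])  # (n_f2, n_mark, 2, 2)
        father = np.stack([parent_sets[i.sire] for i in f2])
        g = np.stack([genotypes.row(i.id) for i in f2])  # (n_f2, n_mark)
    else:
        mother = father = np.zeros((0, n_mark, 2, 2), dtype=bool)
        g = np.zeros((0, n_mark), dtype=np.int8)

    values = np.empty((len(f2_ids), n_mark, 4), dtype=float)
    for s, (mi, pj) in enumerate(STATES):
        m0, m1 = mother[:, :, mi - 1, 0], mother[:, :, mi - 1, 1]
        p0, p1 = father[:, :, pj - 1, 0], father[:, :, pj - 1, 1]
        if config.frequency_weighted:
            den = (m0.astype(float) + m1) * (p0.astype(float) + p1)
            num = np.select(
                [g == 0, g == 1, g == 2],
                [m0 & p0, (m0 & p1) | (m1 & p0), m1 & p1],
                default=False,
            ).astype(float)
            # count both het compositions when both exist
            num = np.where(g == 1, (m0 & p1).astype(float) + (m1 & p0), num)
            with np.errstate(divide="ignore", invalid="ignore"):
                prob = np.where(den > 0, num / np.maximum(den, 1), 0.0)
            values[:, :, s] = np.where(g == MISSING, 1.0, np.maximum(prob, config.error_floor))
        else:
            compat = np.select(
                [g == MISSING, g == 0, g == 1, g == 2],
                [True, m0 & p0, (m0 & p1) | (m1 & p0), m1 & p1],
                default=False,
            )
            values[:, :, s] = np.where(compat, 1.0, config.error_floor)
    return EmissionTable(f2_ids, marker_ids, values)
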