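"""Synthetic three-generation intercross with known line-origin truth.

The generator reproduces the study design the inference engine is meant
for: two outbred lines crossed to make F1 hybrids which are inter-mated to
give a large F2 mapping generation, genotyped at a dense SNP map of mixed
informativeness.  Defaults emulate a chicken-style intercross: 1508
markers evenly spaced on a 451 cM chromosome (mean spacing ~0.3 cM), one
line-1 grandsire and three line-2 granddams shared across families, 4 F1
sires, 37 F1 dams and 773 F2 individuals.

Founder haplotypes are drawn from per-marker, per-line allele frequencies
that are themselves uniform on (0, 1) — so many markers share alleles
between the lines and are only partially informative, while some are fully
informative.  Meiosis is gamete dropping under no interference: the number
of crossovers per gamete is Poisson with mean the chromosome length in
Morgans, crossover positions are i.i.d. uniform along the chromosome, and
the starting haplotype is a fair coin; alleles are copied from the current
haplotype, switching at every crossover.

Because an F1's two haplotypes descend wholly from its line-1 and line-2
founder parents, the line origin of every F2 haplotype is piecewise
constant and flips exactly at the crossovers of the F1 meiosis that
produced it — that truth track is the ground truth for
:mod:`lineorigin.evaluate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emission import transmissible_alleles
from .errors import InputError
from .genetic_map import GeneticMap
from .pedigree_io import MISSING, GenotypeMatrix, Individual, Pedigree

__all__ = [
    "SimConfig",
    "SimResult",
    "HaplotypeTruth",
    "TruthTrack",
    "GameteDrop",
    "ParentPhase",
    "default_marker_map",
    "default_pedigree",
    "simulate_founders",
    "drop_gamete",
    "simulate_cross",
    "phase_parent",
    "write_truth",
    "read_truth",
    "write_phase",
]

HAPLOTYPES = ("maternal", "paternal")


def default_marker_map(n_markers: int = 1508, length_cM: float = 451.0) -> GeneticMap:
    """The default dense map: evenly spaced markers over [0, length]."""
    return GeneticMap.evenly_spaced(n_markers, length_cM)


def default_pedigree(
    n_f2: int = 773,
    n_f1_sires: int = 4,
    n_f1_dams: int = 37,
    n_line1_founders: int = 1,
    n_line2_founders: int = 3,
) -> Pedigree:
    """Three-generation template with founders shared across F1 families.

    Line-1 founders are male, line-2 founders female (as in a single-
    grandsire design); every F1 takes its sire from line 1 and its dam from
    line 2, cycling through the founders; F2 matings cycle through all
    sire x dam pairs.
    """
    inds: list[Individual] = []
    sires1 = [f"L1_GS{i + 1}" for i in range(n_line1_founders)]
    dams2 = [f"L2_GD{i + 1}" for i in range(n_line2_founders)]
    inds += [Individual(s, sex="M", line=1) for s in sires1]
    inds += [Individual(d, sex="F", line=2) for d in dams2]
    f1_sires = [f"F1_S{i + 1}" for i in range(n_f1_sires)]
    f1_dams = [f"F1_D{i + 1}" for i in range(n_f1_dams)]
    for k, fid in enumerate(f1_sires + f1_dams):
        sex = "M" if k < n_f1_sires else "F"
        inds.append(
            Individual(fid, sire=sires1[k % len(sires1)], dam=dams2[k % len(dams2)], sex=sex)
        )
    width = len(str(n_f2))
    for k in range(n_f2):
        inds.append(
            Individual(
                f"F2_{k + 1:0{width}d}",
                sire=f1_sires[k % n_f1_sires],
                dam=f1_dams[k % n_f1_dams],
                sex="M" if k % 2 == 0 else "F",
            )
        )
    return Pedigree(inds)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    allele_freqs
        Optional (2, n_markers) array of line-1 and line-2 allele-1
        frequencies.  When None, frequencies are drawn per marker per line
        from U(0, 1) — the default mixed-informativeness regime.
    founder_haplotypes
        Optional explicit founder haplotypes (founder id -> (2, n_markers)
        0/1 array), overriding the frequency model entirely — e.g. to study
        designed informativeness patterns.
    missing_rate / error_rate
        Per-genotype probabilities of masking a call or flipping one
        allele; both default to 0 (error-free genotyping).
    """

    gmap: GeneticMap = field(default_factory=default_marker_map)
    pedigree: Pedigree = field(default_factory=default_pedigree)
    seed: int = 0
    allele_freqs: np.ndarray | None = None
    founder_haplotypes: dict[str, np.ndarray] | None = None
    missing_rate: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self):
        if self.allele_freqs is not None:
            freqs = np.asarray(self.allele_freqs, dtype=float)
            if freqs.shape != (2, self.gmap.n_markers):
                raise InputError(
                    f"allele_freqs must have shape (2, {self.gmap.n_markers}), got {freqs.shape}"
                )
            if freqs.min() < 0 or freqs.max() > 1:
                raise InputError("allele frequencies must lie in [0, 1]")
            object.__setattr__(self, "allele_freqs", freqs)
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class HaplotypeTruth:
    """True line origin of one transmitted haplotype along the chromosome."""

    start_line: int  # line origin at position 0
    crossovers: np.ndarray  # sorted positions in (0, length)

    def origin_at(self, positions) -> np.ndarray:
        """Line origin (1 or 2) at each query position."""
        positions = np.atleast_1d(np.asarray(positions, dtype=float))
        flips = np.searchsorted(self.crossovers, positions, side="right")
        other = 3 - self.start_line
        return np.where(flips % 2 == 0, self.start_line, other)


class TruthTrack:
    """Ground-truth line origins and crossovers for all F2 haplotypes."""

    def __init__(self, entries: dict[tuple[str, str], HaplotypeTruth]):
        self.entries = dict(entries)

    def __getitem__(self, key: tuple[str, str]) -> HaplotypeTruth:
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self):
        return self.entries.keys()

    def origin_at(self, individual: str, haplotype: str, positions) -> np.ndarray:
        return self.entries[(individual, haplotype)].origin_at(positions)

    def true_crossovers(self):
        """Yield ``(individual, haplotype, position_cM, direction)`` for every crossover.

        ``direction`` is ``"1to2"`` or ``"2to1"`` — the origin change at
        that crossover (origins alternate from ``start_line``).
        """
        for (ind, hap), entry in self.entries.items():
            line = entry.start_line
            for pos in entry.crossovers:
                direction = "1to2" if line == 1 else "2to1"
                yield ind, hap, float(pos), direction
                line = 3 - line


@dataclass(frozen=True)
class GameteDrop:
    """One simulated meiosis: the gamete and where it switched haplotypes."""

    alleles: np.ndarray
    start_haplotype: int  # 0 or 1: which parental haplotype the gamete starts on
    crossovers: np.ndarray

    def haplotype_at(self, positions) -> np.ndarray:
        positions = np.atleast_1d(np.asarray(positions, dtype=float))
        flips = np.searchsorted(self.crossovers, positions, side="right")
        return (self.start_haplotype + flips) % 2


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw founder haplotypes from the per-line allele-frequency model.

    Returns ``(haplotypes, freqs)`` where ``haplotypes`` maps founder id to
    a (2, n_markers) int8 array and ``freqs`` is the realised (2, n_markers)
    allele-1 frequency array (index 0 = line 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.gmap.n_markers
    freqs = config.allele_freqs
    if freqs is None:
        freqs = rng.uniform(0.0, 1.0, size=(2, n))
    if config.founder_haplotypes is not None:
        haplotypes = {}
        for founder in config.pedigree.founders():
            if founder.id not in config.founder_haplotypes:
                raise InputError(f"founder_haplotypes lacks founder {founder.id}")
            haps = np.asarray(config.founder_haplotypes[founder.id], dtype=np.int8)
            if haps.shape != (2, n) or not np.isin(haps, (0, 1)).all():
                raise InputError(f"founder {founder.id}: haplotypes must be a (2, {n}) 0/1 array")
            haplotypes[founder.id] = haps
        return haplotypes, freqs
    haplotypes = {}
    for founder in config.pedigree.founders():
        f = freqs[founder.line - 1]
        haplotypes[founder.id] = (rng.random((2, n)) < f).astype(np.int8)
    return haplotypes, freqs


def drop_gamete(parent_haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> GameteDrop:
    """Simulate one meiosis by gamete dropping.

    Crossover count ~ Poisson(length in Morgans), positions i.i.d. uniform
    on (0, length), starting haplotype a fair coin; alleles are copied from
    the current haplotype and switch at each crossover.
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, gmap.n_markers):
        raise InputError(f"parent haplotypes must be (2, {gmap.n_markers})")
    length = gmap.length_cM
    n_xo = rng.poisson(length / 100.0) if length > 0 else 0
    crossovers = np.sort(rng.uniform(0.0, length, size=n_xo))
    start = int(rng.integers(2))
    flips = np.searchsorted(crossovers, gmap.positions_cM, side="right")
    hap_idx = (start + flips) % 2
    alleles = parent_haplotypes[hap_idx, np.arange(gmap.n_markers)]
    return GameteDrop(alleles.astype(np.int8), start, crossovers)


@dataclass
class SimResult:
    """Everything a simulation produced: data, truth and provenance."""

    config: SimConfig
    genotypes: GenotypeMatrix  # all generations
    truth: TruthTrack  # per F2 haplotype
    parental_phase: dict[str, np.ndarray]  # F1 id -> (n_markers, 2) true (line-1, line-2) alleles
    founder_haplotypes: dict[str, np.ndarray]
    allele_freqs: np.ndarray


def simulate_cross(config: SimConfig) -> SimResult:
    """Simulate genotypes for all generations plus the F2 truth track.

    Deterministic given the config (including its seed).  F1 individuals
    are built from founder gametes; F2 individuals from F1 gametes, with
    the maternal haplotype taken from the dam's meiosis.  Genotyping error
    and missingness, if configured, are applied to the recorded genotypes
    only — the truth track always reflects the error-free transmission.
    """
    rng = np.random.default_rng(config.seed)
    gmap, ped = config.gmap, config.pedigree
    n = gmap.n_markers
    founder_haps, freqs = simulate_founders(config, rng)

    # F1: one gamete from each founder parent; haplotype 0 from the sire.
    f1_haps: dict[str, np.ndarray] = {}
    f1_hap_lines: dict[str, tuple[int, int]] = {}
    parental_phase: dict[str, np.ndarray] = {}
    for f1 in ped.f1():
        sire, dam = ped[f1.sire], ped[f1.dam]
        g_sire = drop_gamete(founder_haps[sire.id], gmap, rng)
        g_dam = drop_gamete(founder_haps[dam.id], gmap, rng)
        haps = np.stack([g_sire.alleles, g_dam.alleles])
        f1_haps[f1.id] = haps
        f1_hap_lines[f1.id] = (sire.line, dam.line)
        line1_hap = 0 if sire.line == 1 else 1
        parental_phase[f1.id] = np.stack([haps[line1_hap], haps[1 - line1_hap]], axis=1).astype(int)

    # F2: one gamete from each F1 parent; the truth track records the line
    # origin of each transmitted haplotype.
    truth_entries: dict[tuple[str, str], HaplotypeTruth] = {}
    f2_haps: dict[str, np.ndarray] = {}
    for f2 in ped.f2():
        g_pat = drop_gamete(f1_haps[f2.sire], gmap, rng)
        g_mat = drop_gamete(f1_haps[f2.dam], gmap, rng)
        f2_haps[f2.id] = np.stack([g_mat.alleles, g_pat.alleles])
        for hap, g, parent in (("maternal", g_mat, f2.dam), ("paternal", g_pat, f2.sire)):
            start_line = f1_hap_lines[parent][g.start_haplotype]
            truth_entries[(f2.id, hap)] = HaplotypeTruth(start_line, g.crossovers)

    ids = ped.ids()
    codes = np.empty((len(ids), n), dtype=np.int8)
    for k, iid in enumerate(ids):
        ind = ped[iid]
        if ind.generation == "founder":
            codes[k] = founder_haps[iid].sum(axis=0)
        elif ind.generation == "F1":
            codes[k] = f1_haps[iid].sum(axis=0)
        else:
            codes[k] = f2_haps[iid].sum(axis=0)

    if config.error_rate > 0:
        flip = rng.random(codes.shape) < config.error_rate
        # flip one randomly chosen allele of the call
        direction = rng.integers(2, size=codes.shape)  # het -> hom0 or hom2
        new = np.where(codes == 1, np.where(direction == 0, 0, 2), 1)
        codes = np.where(flip, new, codes).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes = np.where(mask, MISSING, codes).astype(np.int8)

    genotypes = GenotypeMatrix(ids, gmap.marker_ids, codes)
    return SimResult(config, genotypes, TruthTrack(truth_entries), parental_phase, founder_haps, freqs)


# -- parent phasing --------------------------------------------------------


@dataclass
class ParentPhase:
    """Inferred phase of an F1 parent by founder-line origin.

    ``allele_line1[j]`` / ``allele_line2[j]`` give the allele carried on
    the line-1 / line-2 haplotype at marker ``j`` (-1 where unresolved).
    ``support`` is +inf for markers forced by single-marker Mendelian
    logic, the incompatibility-count margin for linkage-inferred markers,
    and 0 where unresolved.
    """

    allele_line1: np.ndarray
    allele_line2: np.ndarray
    support: np.ndarray

    @property
    def resolved(self) -> np.ndarray:
        return self.allele_line1 >= 0

    def as_array(self) -> np.ndarray:
        """(n_markers, 2) int array suitable for ``parental_phase`` inputs."""
        return np.stack([self.allele_line1, self.allele_line2], axis=1)


def _pair_compatible(g_off1, g_off2, hap_options, other1, other2) -> bool:
    """Can the offspring pair of genotypes arise from one focal haplotype?

    ``hap_options`` are the focal parent's two candidate transmitted
    haplotypes (no recombination between the two markers); ``other1/2`` are
    the allele sets the other parent can transmit at each marker.
    """
    a1 = {MISSING: None, 0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(g_off1)]
    a2 = {MISSING: None, 0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(g_off2)]
    for h1, h2 in hap_options:
        ok1 = a1 is None or any(tuple(sorted((h1, o))) == a1 for o in other1)
        ok2 = a2 is None or any(tuple(sorted((h2, o))) == a2 for o in other2)
        if ok1 and ok2:
            return True
    return False


def phase_parent(
    parent_id: str,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    max_passes: int = 10,
) -> ParentPhase:
    """Phase an F1 parent's markers by founder-line origin.

    Step 1 resolves the straightforward markers with single-marker
    Mendelian logic (parent homozygous, or heterozygous with a homozygous
    founder pinning the origin).  Step 2 handles the remaining heterozygous
    markers by pairing each with the nearest already-resolved heterozygous
    marker and picking the phase that implies fewer offspring genotype
    pairs incompatible with a non-recombinant transmission between the two
    markers; ties stay unresolved.  Passes repeat until no further marker
    resolves.
    """
    parent = pedigree[parent_id]
    if parent.generation != "F1":
        raise InputError(f"phase_parent expects an F1 parent, got {parent_id} ({parent.generation})")
    gp1, gp2 = pedigree.grandparents_by_line(parent_id)
    p_row = genotypes.row(parent_id)
    g1_row, g2_row = genotypes.row(gp1.id), genotypes.row(gp2.id)
    n = gmap.n_markers

    a1 = np.full(n, -1, dtype=int)
    a2 = np.full(n, -1, dtype=int)
    support = np.zeros(n)
    for j in range(n):
        if p_row[j] == MISSING:
            continue
        s1, s2 = transmissible_alleles(int(p_row[j]), int(g1_row[j]), int(g2_row[j]))
        if len(s1) == 1 and len(s2) == 1:
            a1[j], a2[j] = next(iter(s1)), next(iter(s2))
            support[j] = np.inf

    offspring = [i for i in pedigree.f2() if parent_id in (i.sire, i.dam)]
    if not offspring:
        raise InputError(f"parent {parent_id} has no offspring to phase from")
    off_rows = np.stack([genotypes.row(i.id) for i in offspring])
    other_ids = [i.dam if i.sire == parent_id else i.sire for i in offspring]
    other_rows = np.stack([genotypes.row(i) for i in other_ids])

    def other_options(row_val):
        if row_val == MISSING:
            return (0, 1)
        return tuple(sorted(set({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(row_val)])))

    het_unresolved = lambda: np.nonzero((p_row == 1) & (a1 < 0))[0]
    for _ in range(max_passes):
        targets = het_unresolved()
        anchors = np.nonzero((p_row == 1) & (a1 >= 0) & (a1 != a2))[0]
        if targets.size == 0 or anchors.size == 0:
            break
        progressed = False
        for j in targets:
            k = anchors[np.argmin(np.abs(gmap.positions_cM[anchors] - gmap.positions_cM[j]))]
            counts = []
            for target_line1_allele in (0, 1):
                haps = [(a1[k], target_line1_allele), (a2[k], 1 - target_line1_allele)]
                bad = 0
                for o in range(len(offspring)):
                    if off_rows[o, j] == MISSING and off_rows[o, k] == MISSING:
                        continue
                    if not _pair_compatible(
                        off_rows[o, k],
                        off_rows[o, j],
                        haps,
                        other_options(other_rows[o, k]),
                        other_options(other_rows[o, j]),
                    ):
                        bad += 1
                counts.append(bad)
            if counts[0] != counts[1]:
                best = int(np.argmin(counts))
                a1[j], a2[j] = best, 1 - best
                support[j] = abs(counts[0] - counts[1])
                progressed = True
        if not progressed:
            break
    if not (a1 >= 0).any():
        import warnings

        warnings.warn(f"no marker could be phased for parent {parent_id}", stacklevel=2)
    return ParentPhase(a1, a2, support)


# -- truth / phase serialisation ------------------------------------------


def write_truth(truth: TruthTrack, path) -> None:
    """Truth TSV: ``individual  haplotype  start_line  crossovers`` (comma list)."""
    rows = [
        {
            "individual": ind,
            "haplotype": hap,
            "start_line": entry.start_line,
            "crossovers": ",".join(f"{x:.10g}" for x in entry.crossovers),
        }
        for (ind, hap), entry in sorted(truth.entries.items())
    ]
    pd.DataFrame(rows, columns=["individual", "haplotype", "start_line", "crossovers"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> TruthTrack:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "crossovers": str}, keep_default_na=False)
    entries = {}
    for row in df.itertuples(index=False):
        xs = np.array([float(x) for x in row.crossovers.split(",") if x], dtype=float)
        entries[(row.individual, row.haplotype)] = HaplotypeTruth(int(row.start_line), xs)
    return TruthTrack(entries)


def write_phase(phase: dict[str, np.ndarray], marker_ids, path) -> None:
    """Phase TSV: one row per (parent, marker) with the line-1/line-2 alleles."""
    rows = []
    for parent in sorted(phase):
        arr = np.asarray(phase[parent])
        for j, marker in enumerate(marker_ids):
            rows.append(
                {
                    "parent": parent,
                    "marker_id": marker,
                    "allele_line1": int(arr[j, 0]),
                    "allele_line2": int(arr[j, 1]),
                }
            )
    pd.DataFrame(rows, columns=["parent", "marker_id", "allele_line1", "allele_line2"]).to_csv(
        path, sep="\t", index=False
    )
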