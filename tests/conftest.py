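"""Shared fixtures: tiny maps, minimal pedigrees and designed crosses."""

import numpy as np
import pytest

from lineorigin import GeneticMap, SimConfig, simulate_cross
from lineorigin.pedigree_io import Individual, Pedigree


@pytest.fixture
def small_map():
    """Five markers over 40 cM."""
    return GeneticMap([f"m{i}" for i in range(5)], [0.0, 5.0, 12.0, 25.0, 40.0])


@pytest.fixture
def minimal_pedigree():
    """Smallest valid cross: 2 founders, 2 F1s, 1 F2."""
    return Pedigree(
        [
            Individual("gs", sex="M", line=1),
            Individual("gd", sex="F", line=2),
            Individual("s1", sire="gs", dam="gd", sex="M"),
            Individual("d1", sire="gs", dam="gd", sex="F"),
            Individual("x1", sire="s1", dam="d1"),
        ]
    )


def make_pedigree(n_f2, n_sires=1, n_dams=2):
    """Compact intercross pedigree with one founder pair per parent sex."""
    inds = [
        Individual("A1", sex="M", line=1),
        Individual("B1", sex="F", line=2),
        Individual("A2", sex="M", line=1),
        Individual("B2", sex="F", line=2),
    ]
    sires = [f"S{i}" for i in range(n_sires)]
    dams = [f"D{i}" for i in range(n_dams)]
    inds += [Individual(s, sire="A1", dam="B1", sex="M") for s in sires]
    inds += [Individual(d, sire="A2", dam="B2", sex="F") for d in dams]
    inds += [
        Individual(f"X{k:04d}", sire=sires[k % n_sires], dam=dams[k % n_dams])
        for k in range(n_f2)
    ]
    return Pedigree(inds)


def per_haplotype_informative_cross(n_markers=903, length_cM=451.0, n_f2=773, seed=9):
    """Cross where each haplotype has a fully informative marker every other marker.

    Line-1 founders carry all-0 haplotypes.  The line-2 founder of the F1
    sires carries allele 1 at even-index markers only, the line-2 founder
    of the F1 dams at odd-index markers only.  Hence at even markers every
    father is heterozygous with forced phase while every mother is
    homozygous (paternal haplotype resolved), and vice versa at odd
    markers.
    """
    gmap = GeneticMap.evenly_spaced(n_markers, length_cM)
    ped = make_pedigree(n_f2, n_sires=4, n_dams=37)
    even = (np.arange(n_markers) % 2 == 0).astype(np.int8)
    zero = np.zeros((2, n_markers), dtype=np.int8)
    founder_haps = {
        "A1": zero,
        "A2": zero,
        "B1": np.tile(even, (2, 1)),
        "B2": np.tile(1 - even, (2, 1)),
    }
    config = SimConfig(gmap=gmap, pedigree=ped, seed=seed, founder_haplotypes=founder_haps)
    return simulate_cross(config)


@pytest.fixture(scope="session")
def default_scale_run():
    """One full default-size simulation + inference, shared across tests."""
    import lineorigin as lo

    sim = simulate_cross(SimConfig(seed=101))
    grid = lo.infer(sim.genotypes, sim.config.pedigree, sim.config.gmap)
    return sim, grid
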