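"""Simulate a three-generation intercross with known line-origin truth.

Builds a small version of the default design — two outbred lines, F1
hybrids, an F2 mapping generation — genotyped at a dense SNP map where
marker informativeness is mixed because both lines segregate for many of
the same alleles.
"""

import numpy as np

import lineorigin as lo

gmap = lo.default_marker_map(n_markers=300, length_cM=100.0)
pedigree = lo.default_pedigree(n_f2=50)
sim = lo.simulate_cross(lo.SimConfig(gmap=gmap, pedigree=pedigree, seed=4))

print(f"markers: {gmap.n_markers} over {gmap.length_cM} cM "
      f"(mean spacing {np.mean(gmap.distances_cM()):.3f} cM)")
print(f"individuals genotyped: {len(sim.genotypes.individual_ids)} "
      f"({len(pedigree.founders())} founders, {len(pedigree.f1())} F1, {len(pedigree.f2())} F2)")

n_xo = sum(e.crossovers.size for e in sim.truth.entries.values())
print(f"true crossovers across {len(sim.truth)} F2 haplotypes: {n_xo} "
      f"(expected ~{len(sim.truth) * gmap.length_cM / 100:.0f} = meioses x length in Morgans)")

# where does one F2 haplotype switch lines?
iid = pedigree.f2()[0].id
entry = sim.truth[(iid, "maternal")]
print(f"{iid} maternal haplotype: starts on line {entry.start_line}, "
      f"crossovers at {np.round(entry.crossovers, 1)} cM")
# The truth track is what the inference engine is later scored against:
# line origin is piecewise constant and flips at each listed crossover.
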