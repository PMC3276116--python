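"""Infer line-origin posteriors and read them alongside the truth.

Runs the forward-backward engine on a simulated cross and prints the four
state probabilities for one individual around a true crossover: watch the
maternal line-1 probability fall from ~1 to ~0 across the breakpoint.
"""

import numpy as np

import lineorigin as lo

sim = lo.simulate_cross(
    lo.SimConfig(gmap=lo.default_marker_map(600, 200.0), pedigree=lo.default_pedigree(n_f2=40), seed=8)
)
grid = lo.infer(sim.genotypes, sim.config.pedigree, sim.config.gmap, grid_step_cM=1.0)

# pick an individual whose maternal haplotype recombines mid-chromosome
iid = next(
    ind for (ind, hap), e in sim.truth.entries.items()
    if hap == "maternal" and e.crossovers.size and 20 < e.crossovers[0] < 180
)
xo = sim.truth[(iid, "maternal")].crossovers[0]
print(f"individual {iid}: true maternal crossover at {xo:.2f} cM\n")
print("pos_cM   P(1,1)  P(1,2)  P(2,1)  P(2,2)  p1_maternal  true_maternal_origin")
window = np.arange(max(0, int(xo) - 3), int(xo) + 5)
probs = grid.for_individual(iid)
p1m = grid.p1(iid, "maternal")
truth = sim.truth.origin_at(iid, "maternal", grid.positions_cM)
for p in window:
    row = probs[p]
    print(f"{grid.positions_cM[p]:6.0f}  {row[0]:.4f}  {row[1]:.4f}  {row[2]:.4f}  {row[3]:.4f}"
          f"     {p1m[p]:.4f}            line {truth[p]}")
print("\nThe p1_maternal column is P(1,1)+P(1,2): the marginal probability that")
print("the maternal haplotype is of line-1 origin; it crosses 0.5 at the breakpoint.")
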