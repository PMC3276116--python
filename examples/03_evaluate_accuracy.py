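"""Score inferred posteriors against simulation truth.

Computes the line-origin error (per-position and grand mean), detects
recombination switches in the probability series, and matches them to the
true crossovers to measure detection rate, imprecision (width of the
0.975 -> 0.025 interval) and inaccuracy (distance from the 0.5-crossing to
the true breakpoint).
"""

import numpy as np

import lineorigin as lo

sim = lo.simulate_cross(
    lo.SimConfig(gmap=lo.default_marker_map(900, 300.0), pedigree=lo.default_pedigree(n_f2=100), seed=15)
)
grid = lo.infer(sim.genotypes, sim.config.pedigree, sim.config.gmap)

errors = []
for iid in grid.individuals:
    for hap in ("maternal", "paternal"):
        truth = sim.truth.origin_at(iid, hap, grid.positions_cM)
        errors.append(lo.line_origin_error(grid.p1(iid, hap), truth))
summary = lo.summarize_error(np.stack(errors))
print(f"grand mean line-origin error: {summary.grand_mean:.4f} "
      f"({100 * summary.grand_mean:.2f}% of the 0-1 range)")
print(f"mean per-position SD:         {summary.per_position_sd.mean():.4f}")

switches = lo.detect_all_switches(grid)
result = lo.match_switches(switches, sim.truth)
imprec = np.array([s.imprecision_cM for s in switches])
inacc = np.array([s.inaccuracy_cM for s in switches if s.inaccuracy_cM is not None])
print(f"true crossovers: {result.n_true}; detected switches matched: {result.n_matched} "
      f"({100 * result.detection_fraction:.0f}%)")
print(f"imprecision: median {np.median(imprec):.1f} cM "
      f"(minimum possible is the 1 cM grid step); {100 * (imprec == 1).mean():.0f}% at minimum")
print(f"inaccuracy:  median {np.median(inacc):.2f} cM; {100 * (inacc <= 0.5).mean():.0f}% within half a grid step")
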