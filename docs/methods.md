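# Methods

## Model

Line origin along a chromosome of an F2 individual from a two-line
intercross is modelled as a four-state hidden Markov chain over the merged
sequence of marker positions and test positions. The state is the ordered
pair (maternal-haplotype origin, paternal-haplotype origin), each in
{line 1, line 2}; the fixed state order is (1,1), (1,2), (2,1), (2,2).

**Transitions.** The two meioses are independent, so the 4x4 kernel over an
interval factorises as the Kronecker product (maternal factor first) of two
2x2 kernels with off-diagonal r = ½(1 − e^(−2d/100)), d in cM (Haldane's
map function). Haldane's function is forced by the Markov assumption
itself: it is the map function of a crossover process with no
interference, which is what makes origin probabilities depend only on the
neighbouring interval. Distinct maternal and paternal distances are
accepted (sex-specific maps); the default uses one map for both.

**Emissions.** The observed variable at a marker is the unordered
biallelic genotype. For each F1 parent we precompute, per marker and per
line, the *transmissible allele set*: the alleles the parent could carry on
a haplotype of that line origin, obtained by enumerating the two
assignments of its allele pair to its line-1 and line-2 founder parents and
keeping the Mendelian-consistent ones. A state emits 1 if the F2 genotype
can be composed from one maternal and one paternal allele drawn from the
corresponding sets, and the error floor ε otherwise; missing genotypes emit
1 everywhere. Mendelian-inconsistent parent/founder trios (possible
genotyping errors) drop the founder constraint at that marker and are
logged rather than aborting — the ε floor exists precisely so such errors
cannot zero the likelihood. An optional frequency-weighted emission
(probability of the genotype under uniform draws from the transmissible
sets) is available behind `EmissionConfig(frequency_weighted=True)`; the
compatibility model is the default and the documented semantics.

**Algorithm.** Standard scaled forward-backward: the initial distribution
is uniform (an F2's two origins are a priori fair independent coins, and
any non-degenerate prior is dominated by flanking data), variables are
renormalised at every position with the log normaliser retained, and the
posterior at a position is the normalised elementwise product of α and β.
Test positions are pseudo-observations with all-1 emissions, so the whole
computation is one linear sweep over markers plus grid points. A
brute-force reference (`enumerate_posteriors`) sums all 4^n complete state
sequences on small chains; the engine is required (and tested) to agree
with it to 1e-10, and with an independent log-space implementation to
1e-12 on 10,000-position chains.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `error_floor` ε | 0.01 | emission for Mendelian-incompatible states; absorbs genotyping error. Only the order of magnitude matters: posteriors change smoothly in ε. |
| `grid_step_cM` | 1.0 | spacing of test positions (0, 1, 2, … ≤ length). |
| `upper` / `lower` | 0.975 / 0.025 | probability range a switch must traverse to be called. |
| pedigree template | 4 F1 sires, 37 F1 dams, 773 F2, 1 + 3 shared founders | the study design the defaults emulate. |
| marker map | 1508 markers evenly spaced on 451 cM | mean spacing ≈ 0.3 cM. |

## What the simulator emulates — and what it does not

`simulate_cross` gamete-drops a three-generation pedigree: crossover
count per meiosis ~ Poisson(length in Morgans), positions i.i.d. uniform,
starting haplotype a fair coin, alleles copied with a switch at every
crossover (no interference, matching the inference model). Founder
haplotype alleles are drawn independently per marker with per-line allele
frequencies themselves uniform on (0,1). This reproduces the *mixed
informativeness* regime of SNP-chip data in outbred crosses — some markers
fully informative, many partially informative, long stretches without full
information — which is the regime the method exists for. Under this model
the expected fraction of markers fully informative for a given F1 is 4/9
(verified in the tests against a numeric-integration oracle).

It does **not** reproduce within-line linkage disequilibrium (alleles are
independent across markers), a specific gap structure (the default map is
evenly spaced; real maps have clustered markers and multi-cM gaps, which
locally raise the error), genotyping error or missingness unless switched
on (`error_rate`, `missing_rate`), or crossover interference. Passing
tests therefore demonstrate correctness of the machinery and realistic
aggregate error levels, not the exact error profile of any particular real
dataset — with even spacing and no missing founder genotypes the grand
mean error (~0.7%) sits below what a real cross with gaps would give
(~2%). Explicit founder haplotypes can be supplied via
`SimConfig(founder_haplotypes=...)` to study designed informativeness
patterns.

Ties in genetic position are resolved before any computation by spreading
each run of co-located markers evenly over [x − 0.05, x + 0.049] cM
(endpoints as stated, including the asymmetric upper bound), so all
inter-position distances are positive.

## Parent phasing

`phase_parent` reconstructs which allele an F1 carries on its line-1 and
line-2 haplotypes. Step 1 resolves markers where the parent is homozygous
or a founder genotype pins the assignment. Step 2 takes each remaining
heterozygous marker, pairs it with the *nearest resolved heterozygous
marker* (an interpretation: no search order is canonical), and counts, for
each candidate phase, the offspring whose two-marker genotypes are
incompatible with receiving either parental haplotype unrecombined; the
phase with fewer incompatibilities wins, ties stay unresolved, and passes
repeat until nothing changes. On dense heterozygous maps with ≥ 20
offspring the recovered phase matches truth at ≥ 99% of resolved markers.

## Evaluation definitions and numerical choices

* **Line-origin error**: e(i) = 1 − p1(i) if the true origin at grid
  position i is line 1, else p1(i). Per-position mean and *sample* (n−1)
  SD over all haplotypes; the grand mean averages every entry.
* **Switch detection**: for each 0.5-crossing of a p1 series, scan outward
  until the series attains ≥ 0.975 on the high side and ≤ 0.025 on the low
  side; stop at any other 0.5-crossing (such truncated switches, and
  chromosome-end switches missing one endpoint, are not emitted).
  Thresholds are inclusive so that hard 0/1 series qualify.
* **Crossing position**: linearly interpolated between the two grid values
  straddling 0.5; a run of exact-0.5 values uses its central position. The
  interpolated crossing is *not* snapped to the grid: snapping would make
  the inaccuracy of a perfectly hard switch depend on which side of the
  interval midpoint the true breakpoint fell, up to a full grid step,
  whereas the interpolated midpoint is never more than half a step away.
* **Matching**: greedy nearest-distance within (individual, haplotype,
  direction) groups, each switch and each true crossover used at most
  once. Two crossovers inside one grid interval cancel in any grid-sampled
  series and are undetectable by construction — an information limit of
  the grid, not of the detector.

## Identifiability of the mixed states

A single unordered biallelic genotype can never separate (1,2) from (2,1):
if both parents are heterozygous with known opposite phase, a heterozygous
F2 is exactly compatible with both mixed states, and in a design where
*every* marker has that structure the two assignments are globally
exchangeable — the posterior is correctly 50/50 and the per-haplotype
error is irreducibly ~0.25 in such regions. What breaks the symmetry in
real (and default-simulated) data is informativeness that differs
*between* the parents: wherever one parent is heterozygous with resolved
phase while the other is homozygous, the transmitted allele of the first
is pinned. The dense-marker recovery test therefore interleaves
mother-informative and father-informative markers (each haplotype gets a
fully informative marker every 1 cM), under which the grand mean error
falls below 0.005.

## Problem sizes

Default full-scale runs are 1508 markers x 773 F2 x 452 grid positions
(about 3 s for simulation + inference + evaluation on one CPU); the
acceptance script uses nine full-pedigree simulations for the crossover
count and three full-scale replicates for the error, chosen to keep the
Monte-Carlo error of each reported quantity well inside its comparison
tolerance.

## Known limitations

* Single chromosome per run; multi-chromosome data is a loop over maps.
* Three generations exactly; deeper pedigrees and grandparental (16-state)
  origin tracking are out of scope.
* No joint two-position posteriors (epistasis scans) and no phenotype
  association — this package stops at origin probabilities.
* The enumeration oracle is for verification only (≤ 12 positions).
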