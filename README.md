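# lineorigin

Hidden-Markov inference of chromosomal **line origin** for QTL analysis of
F2 crosses between outbred lines, with a matching intercross simulator and
breakpoint-evaluation statistics.

## The problem

In an F2 intercross between two outbred lines (e.g. Red Junglefowl x White
Leghorn chickens), interval mapping needs, at every test position along the
genome, the probability that each of an F2 individual's two haplotypes —
the maternal and the paternal one — descends from founder line 1 or
line 2. With SNP-chip genotyping most markers are only *partially*
informative (the same alleles segregate in both lines), and classical
algorithms that enumerate every origin combination between fully
informative markers scale exponentially in the length of partially
informative stretches. `lineorigin` instead treats line origin as the
hidden state of a Markov chain along the chromosome and computes exact
posteriors with the forward-backward algorithm, in time linear in the
number of markers.

## The model

The hidden state at position *p* is the pair (maternal origin, paternal
origin) ∈ {1,2}², in the fixed order (1,1), (1,2), (2,1), (2,2). Between
adjacent positions separated by *d* cM each haplotype's origin switches
independently with probability given by Haldane's map function

&nbsp;&nbsp;&nbsp;&nbsp;r = ½ (1 − e^(−2d/100)),

so the 4x4 transition kernel is the Kronecker product of two 2x2 kernels
(no crossover interference — exactly the assumption that makes origin a
Markov process). The observation at a marker is the unordered SNP
genotype; its emission probability under a state is 1 when the genotype is
Mendelian-compatible with the alleles the F1 parents can transmit on
haplotypes of that origin (derived from parental and grandparental
genotypes), and a small floor ε (default 0.01) otherwise, which absorbs
genotyping errors. Test positions enter the chain as pseudo-observations
compatible with everything. With forward variables α and backward
variables β, the posterior at test position *t* is

&nbsp;&nbsp;&nbsp;&nbsp;P(i,j | data) = α_t(i,j) β_t(i,j) / Σ_{k,l} α_t(k,l) β_t(k,l),

and the per-haplotype line-1 probabilities are the marginals
p1_maternal = P(1,1)+P(1,2), p1_paternal = P(1,1)+P(2,1). A brute-force
oracle that enumerates all 4^n complete state sequences is included and
the engine reproduces it to 1e-10 on small chains.

The package also ships:

* a **simulator** (`lineorigin.simulate`) that gamete-drops a
  three-generation pedigree (default: 4 F1 sires, 37 F1 dams, 773 F2 on a
  1508-marker / 451 cM chromosome) with Poisson crossover counts and
  uniform positions, mixed marker informativeness from uniform per-line
  allele frequencies, true line-origin tracks for every F2 haplotype, and
  the two-step parent-phasing procedure (`phase_parent`);
* **evaluation statistics** (`lineorigin.evaluate`): the line-origin error
  e(i) = 1 − p1(i) (truth line 1) or p1(i) (truth line 2), and
  recombination-switch detection with *imprecision* (width of the
  0.975 → 0.025 interval) and *inaccuracy* (distance from the 0.5-crossing
  to the true breakpoint).

## Worked example

```python
import numpy as np
import lineorigin as lo

sim = lo.simulate_cross(
    lo.SimConfig(gmap=lo.default_marker_map(600, 200.0),
                 pedigree=lo.default_pedigree(n_f2=40), seed=8)
)
grid = lo.infer(sim.genotypes, sim.config.pedigree, sim.config.gmap, grid_step_cM=1.0)
```

Printing the posteriors for one individual around a true maternal
crossover at 45.93 cM (`examples/02_infer_line_origin.py`):

```
pos_cM   P(1,1)  P(1,2)  P(2,1)  P(2,2)  p1_maternal  true_maternal_origin
    44  0.0000  0.0000  0.0000  1.0000     0.0000            line 2
    45  0.0000  0.0000  0.0000  1.0000     0.0000            line 2
    46  0.0000  0.2541  0.0000  0.7459     0.2541            line 1
    47  0.0000  0.9827  0.0000  0.0172     0.9827            line 1
    48  0.0000  0.9925  0.0000  0.0075     0.9925            line 1
```

The maternal line-1 probability rises through 0.5 inside the interval
containing the true breakpoint while the paternal haplotype stays firmly
on line 2. Scoring a larger run against the truth
(`examples/03_evaluate_accuracy.py`) prints:

```
grand mean line-origin error: 0.0073 (0.73% of the 0-1 range)
mean per-position SD:         0.0512
true crossovers: 617; detected switches matched: 558 (90%)
imprecision: median 2.0 cM (minimum possible is the 1 cM grid step); 16% at minimum
inaccuracy:  median 0.26 cM; 82% within half a grid step
```

i.e. the inferred origin probabilities are within about 1% of the truth on
average, and most recombination breakpoints are localised to a couple of
centimorgans.

## Command line

```bash
lineorigin simulate --seed 1 --n-f2 773 --out-prefix runs/sim
lineorigin infer --map runs/sim.map.tsv --pedigree runs/sim.pedigree.tsv \
    --genotypes runs/sim.genotypes.tsv --grid-step 1 --out runs/posteriors.tsv
lineorigin evaluate --posteriors runs/posteriors.tsv --truth runs/sim.truth.tsv \
    --out-prefix runs/eval
lineorigin pipeline --seed 1 --replicates 3 --out-dir runs/pipeline
```

All file formats are plain TSV (see module docstrings in
`lineorigin.pedigree_io`); `pipeline` accepts a YAML config file and
writes its resolved configuration for exact reproduction.

## Documentation

`docs/methods.md` describes the model, the simulator's generative
assumptions and their limits, numerical choices and known limitations.
Narrative usage scripts live in `examples/`.
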