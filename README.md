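# contigpath

**How significant is a contiguous residue pathway in a protein?**

Allosteric proteins transmit a signal from an effector-binding site to a
distal active site, and one proposed mechanism is a *contiguous pathway*: a
chain of residues, each within a contact cutoff of the next, linking the two
sites.  Methods such as statistical coupling analysis propose candidate
pathways of roughly 20% of a protein's residues — but a pathway is only
evidence of signaling if finding one is *unlikely by chance*.  `contigpath`
computes that null model: it selects 20% of residues uniformly at random
(always including the two sites), asks whether the selection contains a
contiguous path between the sites in the residue contact graph, and reports
the success rate over many random selections.  A high rate (as in compact
single-domain globules) means pathways arise frequently by chance and carry
little significance on their own; a low rate (as in large multidomain
structures with thin inter-domain linkers) means an observed pathway is
unlikely to be coincidental.

The package is aimed at structural bioinformaticians who have a structure
(PDB), a pair of residues, and a candidate pathway hypothesis to calibrate.

## Method

1. **Contact graph.** For residues *i*, *j*, the distance `d(i,j)` is the
   minimum over all inter-atomic distances between their (heavy) atoms.  The
   graph `G = (N, E)` has residues as nodes and an edge whenever
   `d(i,j) ≤ c` (default cutoff `c` = 6 Å).
2. **Null model.** A selection of `k = round(0.2 n)` residues is drawn
   uniformly at random with the start (allosteric-site) and end
   (active-site) residues fixed.  The selection *succeeds* iff the subgraph
   of `G` induced by the selection contains any path between the two sites.
   Path existence is decided by A\* search (`f = g + h`, straight-line
   heuristic; complete on finite graphs), cross-validated by an exhaustive
   depth-first search and a heuristic-free BFS connectivity oracle.
3. **Rates and convergence.** A *trial* evaluates `S` selections and yields
   a success rate (%); an *experiment* repeats trials with independent
   derived sub-seeds and is converged when the across-trial standard
   deviation falls below a tolerance.  For tiny systems the exact
   probability is computed by exhaustive enumeration instead.
4. **Cutoff sweep.** Sweeping `c` from bond length to the structure's
   diameter takes the rate from 0% to 100% sigmoidally; the curve is
   summarized by the asymmetric five-parameter logistic
   `y = d + (a − d)/[1 + (x/c)^b]^m`.

Synthetic protein-like structures (compact self-avoiding bead globules, and
multidomain chains with thin linkers that force a connectivity bottleneck)
make the entire pipeline testable with no downloads.

## Worked example

Generate a 115-residue synthetic globule and measure the pathway rate
between residues 313 and 376 at an 8 Å cutoff:

```sh
python -c "from contigpath import make_globule, write_structure; \
           write_structure(make_globule(115, seed=7, start_number=301), 'globule.pdb')"
contigpath nullmodel --structure globule.pdb --start A:313 --end A:376 \
    --cutoff 8 --selections 2000 --trials 10 --seed 1 --out run/
```

prints (log on stderr, rate on stdout):

```
INFO contigpath: parsed globule.pdb: 115 protein residues
INFO contigpath: mean rate 19.37% (stdev 0.799 pp, converged=True)
19.37
```

i.e. 19.37% of random 20% selections contained a contiguous 313→376 pathway,
and the 10 independent trials agree to within ~0.8 percentage points.
`run/` contains `trials.csv` (one row per trial), `summary.json`, and
`config.json` — the fully resolved configuration that reproduces the run
bit-exactly.  A cutoff sweep with a 5PL fit:

```sh
contigpath sweep --structure globule.pdb --start A:313 --end A:376 \
    --selections 500 --trials 3 --seed 1 --out sweep/
```

yields a rate curve rising from 0% (≤4 Å: no contacts beyond the backbone)
through 18.1% (8 Å) and 92.7% (12 Å) to 100% (≥16 Å), and `fit.json` with
the fitted sigmoid (location c ≈ 9.1 Å for this globule).  Because every
cutoff replays the same selection streams (common random numbers), the curve
is non-decreasing exactly, not just on average.

As a library:

```python
from contigpath import build_distance_matrix, make_globule, run_experiment

s = make_globule(115, seed=7)
dm = build_distance_matrix(s)
stats = run_experiment(dm, cutoff_c=8.0, fraction=0.2, start=12, end=75,
                       n_selections=2000, n_trials=10, base_seed=1,
                       coords=s.rep_coords())
print(stats.mean_rate, stats.stdev_rate, stats.converged)
```

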