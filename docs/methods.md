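# Methods

## Model

A protein is reduced to an ordered list of residues with atom coordinates;
residue identity is the author key `(chain, number, insertion code)` exactly
as in the source file, since that is how sites are referred to in the
allostery literature.  The inter-residue distance is the **minimum over all
atom pairs** of the two residues, computed over heavy atoms by default
(crystal files usually lack hydrogens; a flag retains them, and the
sensitivity of neighbor lists to this choice is the main reason rate
benchmarks on crystal structures carry a few-percentage-point tolerance).
The contact graph at cutoff `c` joins residues with `d(i,j) ≤ c`.  The
threshold is closed (`≤`) by convention; on real coordinates the boundary
case has measure zero, but a fixed convention makes tests exact.
Sequence-adjacent residues receive edges like any other pair — at the 6 Å
default they always qualify.

The null model draws `k = round(fraction · n)` residues (half-away-from-zero
rounding), *including* the two fixed endpoints, the remaining `k − 2`
uniformly without replacement.  The default fraction 0.2 matches the typical
size of coevolution-derived candidate networks.  A selection succeeds iff
the induced subgraph contains any start–end path.  Path existence — not
path length — is the statistic; a fewest-hop BFS path is available purely
for reporting worked examples.

## Search

Three independent routes decide existence: A\* (best-first on
`f = g + h`; `g` accumulates straight-line step lengths between
representative coordinates, `h` is the straight-line distance to the end
node), an exhaustive DFS with an explicit stack (no recursion, so deep
subgraphs of very large proteins cannot overflow), and a heuristic-free BFS
connectivity oracle.  On a finite graph A\* terminates and finds the end iff
it is reachable, whatever the heuristic, so existence is heuristic-invariant;
the suite property-tests tri-route agreement on ≥10⁴ random induced
subgraphs.  When representative coordinates are not supplied, the heuristic
falls back to the end residue's distance-matrix row (closest-atom geometry);
this changes only expansion order, never the answer.  All tie-breaks are by
node index, so a fixed seed reproduces runs bit-exactly.

A selection in which the start or end residue has no selected neighbor is
scored a failure without searching.  This fast path is exactly equivalent to
searching (an isolated endpoint is unreachable) and is asserted as such in
the tests.

## Monte Carlo design

Trials use sub-seeds derived from one user seed via seed-sequence spawning,
giving independent, reproducible streams.  An experiment of `T` trials ×
`S` selections reports the per-trial rates, their mean, and the sample
standard deviation (percentage points); it is *converged* when that stdev is
within a tolerance (default 1 pp).  The across-trial spread should track the
binomial prediction `100·sqrt(p(1−p)/S)`; the suite checks agreement within
a factor of 3.  For systems with `C(n−2, k−2)` below a configurable limit
(default 10⁶) the exact probability is computed by exhaustive enumeration
with the BFS oracle, which anchors the Monte Carlo path: at `S = 10⁴` the
estimate must fall within 3 exact binomial standard errors for ≥95% of
seeds.

Cutoff sweeps reuse the same base seed — hence identical selection streams —
at every cutoff.  Because the edge set at a smaller cutoff is a subset of
the edge set at a larger one, per-selection success is monotone, and the
measured rate curve is non-decreasing *exactly*, an invariant the tests
assert without statistical slack.

## Five-parameter logistic

Rate-versus-cutoff curves are fitted with the asymmetric sigmoid
`y = d + (a − d)/[1 + (x/c)^b]^m` (`a = y(0)`, `d` the far plateau, both in
%, `c` in Å, `b, m > 0`).  Evaluation is done in log space
(`m·log1p((x/c)^b)` via `logaddexp`), which stays finite for the extreme
asymmetry exponents (`m ~ 10⁷`) that published fits of this curve family can
exhibit; at `x = 0` the value is exactly `a`.  Fitting uses
Levenberg–Marquardt least squares on `(a, d, log b, log c, log m)` — the log
parameterization enforces positivity without bound constraints — with
initialization `a = min(y)`, `d = max(y)`, `c` at the half-range crossing,
`b = 5`, `m = 1`.  Such extreme-`m` fits are *non-identifiable in their
parameters* even when the curve is well determined, so all quality checks
compare predicted curves, never parameter tuples.  Constant data return a
flagged flat fit rather than an error.

## Synthetic structures

The generator emulates the two geometric regimes that drive the null
model's behavior:

* **Globule** — a self-avoiding bead chain (one CA per residue, consecutive
  spacing 3.8 Å, the alpha-carbon virtual bond) grown inside a confinement
  sphere of radius `0.85 · 3.8 · n^(1/3)` Å with excluded volume
  `≥ 0.9 × spacing`.  The compactness constant 0.85 is fixed so that a
  100-bead globule at 6 Å has a mean contact degree in the 4–10 band of real
  residue contact graphs.
* **Multidomain** — globular domains joined serially by straight linkers of
  `L` beads, every junction spaced exactly 3.8 Å.  Candidates are rejected
  until deleting the linker beads disconnects the chain ends in the contact
  graph at `1.6 × spacing` (~6 Å), so inter-domain connectivity is forced
  through the linkers.  This reproduces the connectivity bottleneck of
  multidomain allosteric proteins, and the suite verifies that such a chain
  yields strictly fewer random pathways than an equally sized globule.

Generation is a pure function of the shape parameters and seed.  What the
bead model does **not** capture: side-chain geometry and packing
heterogeneity, secondary structure, and the higher contact degree of
all-atom minimum-distance graphs (a bead globule at 6 Å is sparser than a
real protein at 6 Å, so synthetic success rates at a given cutoff sit lower
than crystal-structure rates — compare the worked example's 19% at 8 Å with
a real single-domain protein's ~51% at 6 Å).  Passing synthetic tests
therefore validates the graph/statistics machinery, not chemical realism;
the crystal-structure benchmarks in the acceptance tests cover the latter
and require the real PDB files.

## Numerical and design choices

* Alternate locations: highest occupancy wins, ties to first occurrence.
  Multi-model files: model 1 only.  Non-standard residues MSE/SEC/PYL map to
  MET/CYS/LYS and are retained (configurable).
* The distance matrix is computed exactly (no approximate neighbor search)
  with blocked evaluation: atom-pair distance blocks reduced to per-residue
  minima via `minimum.reduceat`, so ~12,000-atom structures never
  materialize an atom-pair tensor.
* Selection size includes both endpoints (`k = round(0.2 n)`, e.g. `k = 23`
  at `n = 115`, endpoints + 21 random).
* Default problem sizes: 1,000 selections × 10 trials for routine runs; the
  crystal-structure benchmark uses 10 trials × 10⁴ selections, which leaves
  the Monte Carlo standard error well under the tolerance of the check.
* MutS-like multi-chain cases: chain assignment of the endpoint residues is
  genuinely ambiguous from residue numbers alone, so presets leave the
  chain to the user; the benchmark test scans chains and requires the
  residue name to match (Val561, Leu41).
* The full-length p53-style analysis depends on a prediction-server model
  that cannot be regenerated deterministically; the package therefore runs
  the preset on any user-supplied model file and reports the rate without a
  pass/fail bound.

## Limitations

* Rates depend on the atom set (hydrogens, altloc handling) through the
  6 Å neighbor lists; benchmarks on crystal structures therefore use
  ±few-pp tolerances rather than exact targets.
* The exhaustive enumerator is exponential and refuses beyond its
  combination limit by design.
* No variance reduction (importance sampling) is implemented; raw rates are
  the reported statistic.
* Biological-assembly reconstruction and structure preparation (protonation,
  minimization) are out of scope; the package consumes coordinates as given.
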