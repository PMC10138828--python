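# Methods

## Scope and model

`ssmdscan` assigns secondary-structure patterns to frames of MD
trajectories using only the geometry of one representative point per
residue — the MARTINI backbone bead (`BB`) or, for atomistic input, the
Cα — so the same criteria apply across coarsening levels. The method
rests on three components: distance-thresholded binary contact maps, a
library of binary shift matrices describing idealized strand-pair
arrangements, and graph clustering of classified molecule pairs.
Everything downstream (domain detection, time-series metrics) is
deterministic given a frame.

Distances are plain Euclidean in Å; periodic-boundary minimum-image
distances are not computed and no PBC option is exposed. Trajectories
whose molecules are wrapped across the box must be unwrapped upstream.

## Contact criteria

* β: `D_ij ≤ D₀`, default `D₀ = 5.3 Å`. Cross-β inter-strand spacing
  spans 4.7–5.3 Å; the upper end is used so that in-register strand
  pairs at typical spacings are retained while the nearest off-register
  neighbour (≈ 5.9 Å for a 3.5 Å intra-strand step and 4.8 Å gap)
  stays excluded.
* α: `5.1 Å ≤ D_ij ≤ 6.3 Å`, intramolecular only, sequence separation
  `|i−j| ≥ 3`. The band is the backbone-centre distance range of
  helical (i, i+4) pairs. A closed band rather than a single threshold
  is required: a one-sided cut at 6.3 Å would also fire on the much
  shorter (i, i±1) distances.

The separation gate of 3 deserves a note: an ideal Cα helix has
`d(i, i+2) ≈ 5.43 Å`, inside the α band, while `d(i, i+3) ≈ 5.05 Å`
falls just below it. With a gate of 2 every genuine helix would
accumulate spurious "β-turn" contacts from its own (i, i+2) pairs;
requiring `|i−j| ≥ 3` keeps the turn channel specific to actual chain
reversals while the "non-consecutive residues" requirement remains
satisfied. This is the package's choice; the gate is configurable on
`ContactCriterion.alpha`.

## Kernel library

For strands of `RES` residues (0-based indices, `n = RES−1`) the four
families at shift `s ∈ [0, RES)` are: P+ (`j−i = s`), P− (`i−j = s`),
A+ (`i+j = n+s`), A− (`i+j = n−s`). Stacked in that order the library
holds exactly `4·RES` kernels; a family-`s` kernel has `RES−s` ones.
Family index ranges are half-open (`[m·RES, (m+1)·RES)`), which keeps
the boundary indices defined and the declared library size exact. At
shift 0, P+ ≡ P− (the identity) and A+ ≡ A− (the anti-diagonal); both
indices are kept and argmax ties resolve to the lowest index, so the
degenerate classes report as P and AP+ respectively. Reporting
collapses P± to a single "P" class; antiparallel keeps its sign
(AP+/AP−), which distinguishes the two possible shift directions of an
antiparallel pair.

## NCC scoring

A pair's contact block `BB` is scored against kernel `L_k` as
`Σ BB∘L_k / √(ΣBB · ΣL_k)` — the overlap normalized by the geometric
mean of the two supports (equivalently, cosine similarity of the
flattened binary matrices, the standard zero-mean-free NCC for binary
templates). The denominator must involve the kernel size at the square
root: normalizing by the plain product of the sums would let any
single-entry kernel contained in the block tie or beat the full-size
match (a one-point kernel inside an 8-contact anti-diagonal block
scores 1/8 either way), destroying self-recovery and all noise
robustness. With the geometric mean, deleting or adding one contact of
a block built from a kernel with ≥ 4 ones provably cannot change the
parallel/antiparallel call (the competing family overlaps a given
diagonal in at most one point).

Pairs need `min_contact` contacts to be classified; the default 3 is
the smallest count that determines a line's direction in the block and
is user-configurable. The alignment matrix stores winning kernel
indices shifted by +1 internally (0 = unclassified) because kernel
index 0 is itself a valid arrangement; exports report plain indices
with −1 for unclassified.

## β-sheet domains

For classified pairs `p < q` the block's column sums give a row vector
(per-residue contact tally of strand q); for `q < s` the (q, s) block's
row sums give a column vector. A nonzero dot product means both pairs
engage overlapping residues of the shared strand q, confirming a
three-strand sheet (p, q, s); classified pairs absorbed into no triplet
are reported as two-strand sheets. A domain's run length is the longest
stretch of consecutive nonzero entries of the defining pair's reduced
vector — the number of consecutive structured residues along the
covalent direction. Intramolecular hairpins are not detected: domain
search operates on molecule pairs only, a known fidelity limit.

## α-helix / β-turn assignment

Scanning all intramolecular α contacts `i < j`: `j−i ∈ {4, 5}` counts
as an α contact (updating the running mean "helix pace", ≈ 4 for an
ideal helix), anything else as a β-turn contact (running mean "turn
length"). The running means are plain incremental means,
`mean ← mean + (x − mean)/count`, verified against the batch mean to
1e−12. Contents are the percentage of residues covered by the union of
the inclusive spans `[i, j]` of each class's contacts; a lone (i, i+4)
contact on an 8-mer therefore scores 62.5 %, the ceiling typically seen
for short helical peptides.

## Time-series metrics

* **Stability** = `100 · |{t : x_t > mean(x)}| / N` (strict
  inequality, so constant series score 0).
* **Transition entropy** = `Σ_t β(t) log₂(β(t)/α(t))` after both
  series are normalized to empirical distributions over frames; terms
  with `β(t) = 0` vanish and `α(t) = 0` under positive β is floored at
  1e−12. Normalization is the default (KL divergence is defined on
  distributions); raw-content evaluation is available via
  `normalize=False` for comparison experiments. An all-zero β series
  returns 0 by convention.
* **Mutual information** uses 10 equal-width bins per series over its
  own observed range (binning choice of this implementation; the count
  matters more than the scheme at the trajectory lengths involved) and
  the joint empirical histogram, in bits. Constant series occupy one
  bin and give 0.
* **Organizational index**: both AP/P and AP/(AP+P) are reported per
  frame; AP/P is NaN when no parallel contacts exist and both are NaN
  for frames with no classified contacts.
* **Frames at max** uses exact floating-point equality on contents,
  which are ratios `k/RES·100` and therefore exactly representable for
  the molecule sizes in scope.

## Synthetic generators

The generators produce the three motif classes with exact ground truth:

* **Helix**: points on `(r cos(iθ), r sin(iθ), i·h)` with r = 2.3 Å,
  h = 1.5 Å, θ = 100°/residue — ideal α-helix Cα geometry, giving
  `d(i,i+4) = 6.203 Å` (in-band) and `d(i,i+3) = 5.054 Å` (just below
  band).
* **Sheet ladder**: straight strands along x (step 3.5 Å) stacked
  along y (gap 4.8 Å, inside the cross-β window), with per-pair
  orientation and register shift applied as affine index maps. The
  step is chosen slightly below the 3.8 Å Cα-trans value so
  off-register distances (5.94 Å) clear the 5.3 Å threshold with
  margin; both step and gap are configurable.
* **Coil**: fixed-step (3.8 Å) self-avoiding random walk with a 4.0 Å
  minimum approach between non-bonded residues.

`make_system` assembles motifs into one frame with ≥ 20 Å clearance
between disconnected units; `morph_frames` linearly interpolates two
conformations of the same layout into a synthetic "trajectory",
written as multi-model PDB (the one trajectory dialect writable
without binary tooling). All generators are seed-deterministic;
noise-free output is reproducible to 1e−12.

What the generators do **not** emulate: realistic dihedral statistics,
side chains, solvent, thermal breathing of sheets, periodic boundaries,
or gradual (physical) folding pathways — morphs are geometric
interpolations. Passing closed-loop tests therefore demonstrates the
correctness of the pattern recognition on its own geometric terms, not
calibration against experimental secondary-structure populations.

## Problem sizes and numerical choices

Tests and the acceptance script run systems of 2–30 molecules of 4–12
residues and trajectories of up to 10 frames — sizes at which every
quantity is exactly checkable against brute-force oracles (triple-loop
kernel enumeration, exhaustive NCC scoring, union-find components,
hand-traced domain assignments). The recovery sweep classifies 360
noisy ladders (2- and 3-strand, both orientations, shifts 0–2,
σ = 0.3 Å); at this noise level an occasional ladder loses enough
contacts to fall below `min_contact` and is left unclassified rather
than misclassified, so measured recovery is ≥ 99 % rather than exactly
1.

Output determinism: CSV/TSV/JSON floats are formatted at 6 significant
digits, rows are emitted in fixed (frame, molecule/pair) order, and
JSON keys are sorted, making repeated runs byte-identical.

## Known limitations

* Equal-length molecules are required for β classification
  (rectangular kernel matching is out of scope); mixed-length systems
  can still be explored and α-scored.
* No intramolecular β-hairpin detection.
* The "gpu" device option is accepted for interface compatibility but
  maps to the serial CPU backend with a warning.
* Chain-id recycling in large multi-copy PDB files is handled by
  treating a residue-number restart as a molecule boundary; exotic
  numbering schemes (non-monotonic resids within one chain) would
  over-split.
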