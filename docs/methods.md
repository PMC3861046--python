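# Methods

## Coarse-grained dihedrals and their free-energy profiles

The backbone of a protein is reduced to its Cα trace; the pseudo-dihedral
γ<sub>i</sub> of residue *i* is the dihedral of the virtual bonds joining
Cα(*i−1*), Cα(*i*), Cα(*i+1*), Cα(*i+2*). The zero is the *cis* arrangement
of Cα(*i−1*) and Cα(*i+2*); the sign is positive for a clockwise rotation
of the distal bond viewed from Cα(*i*) towards Cα(*i+1*). This coincides
with the standard IUPAC dihedral convention (verified against mdtraj in the
test suite). Values live in the half-open interval (−180°, +180°]; an exact
±180° tie is reported as +180° so histogram binning is unambiguous.
Dihedrals are declared undefined when a cross-product norm of consecutive
virtual bonds falls below 1e−10 Å² (numerically collinear points).

Profiles are Boltzmann inversions of binned circular densities:
V<sub>b</sub> = −ln p<sub>b</sub> in k<sub>B</sub>T (temperature kept as
metadata, 300 K default), shifted so the finite minimum is zero; empty bins
are +∞ and are treated as impassable everywhere downstream. The bin width
is 5° (72 bins over the circle), chosen so runs of ~10⁵ frames keep ≳10
expected counts in occupied bins; samples at exactly +180° fall in the last
bin. No kernel smoothing is applied, so every H value and profile is
bit-reproducible from the raw counts.

## Similarity index and replicate gating

Two histograms of the same angle are compared with
H = Σ<sub>b</sub> √(p1<sub>b</sub>·p2<sub>b</sub>), the Bhattacharyya
coefficient: symmetric, 1 exactly when the histograms coincide, 0 for
disjoint support, invariant under simultaneous circular shifts. The
histogram-overlap kernel Σ<sub>b</sub> min(p1<sub>b</sub>, p2<sub>b</sub>)
is available as a configuration alternative; by Cauchy–Schwarz it never
exceeds the Bhattacharyya value, so the default gate is the more permissive
of the two.

Replicate gating keeps an angle when H between two independent runs of the
same ligand state is **strictly** greater than 0.5 (the DATA set). The two
replicate histograms of each retained angle are then averaged bin-wise,
P = (p1 + p2)/2, and all state-to-state comparisons use these average
densities, restricted to the intersection of the two states' DATA sets.

## Dissimilarity bins and the specificity rule

State-pair dissimilarity 1−H is binned as weak (< 0.3), significant
([0.3, 0.7)) and strong (≥ 0.7). Both boundaries are assigned upward; a
comparison is *influenced* exactly when 1−H ≥ 0.3 (evaluated with a 1e−12
guard so two-decimal inputs with H = 0.70 classify as influenced). With
three states the per-angle pattern of influenced comparisons yields one of
five categories: X-specific (the pair excluding X uninfluenced, both pairs
involving X influenced), each-specific (all three influenced), or none.
The rule is label-equivariant: permuting state labels permutes categories.

The packaged 27-angle DnaK matrix carries, besides the three H columns,
per-cell influenced flags (the source table's emphasis marks) and
subdomain labels; classification can be driven by the threshold or by the
flags, and the two routes agree on this matrix. An angle's residues are
*i−1 … i+2*; a network's subdomain tally assigns each angle by its central
residue *i* against the packaged subdomain map (NBD-IA 4–37, 112–182,
363–383; NBD-IB 38–111; NBD-IIA 183–227, 311–362; NBD-IIB 228–310; linker
384–393; SBD-β 394–502; SBD-α 503–603).

## Contact maps

A residue pair's interaction is probed by the per-frame smallest
heavy-atom distance (heavy = element ≠ H, so united-atom models pass
unchanged). A pair enters a state's map when its occupancy (fraction of
frames strictly below 4 Å) is ≥ 0.5 in both replicate runs, the per-run
mean minimum distances (over **all** frames) agree within 0.5 Å, and the
sequence separation is ≥ 2 (`min_seq_sep=0` restores the unrestricted
reading). Raising the cutoff or lowering the occupancy floor can only grow
the retained set. The state-pair difference is the two set differences of
retained pairs.

## Dihedral PCA

Each angle is embedded as the unit vector (cos γ, sin γ), which removes
the circular boundary. The 2n × 2n covariance uses the population (1/N)
normalizer — a plain average over frames. Eigenvalues are clipped at zero
and sorted descending; each eigenvector's sign is fixed so its
largest-magnitude component is positive, making projections reproducible
across BLAS implementations. The influence of angle *i* on mode *k* is
Δ<sub>i</sub><sup>k</sup> = e<sup>k</sup>(cos slot)² + e<sup>k</sup>(sin
slot)², the unique quadratic form satisfying Σ<sub>i</sub>
Δ<sub>i</sub><sup>k</sup> = 1 and the exact decomposition
MSF<sub>i</sub> = Σ<sub>k</sub> λ<sup>k</sup> Δ<sub>i</sub><sup>k</sup>
(both asserted in tests against direct averages).

The cosine content of a principal component p(t) on a uniform time grid is
CC = (2/T)·(∫cos(kπt/T)p(t)dt)² / ∫p(t)²dt, trapezoid-discretized, with
the harmonic index k defaulting to the component's rank (exposed as a
parameter). A zero-energy series has CC = 0 by convention. Values near 1
mean the component fluctuates like a free random walk on the trajectory's
time-scale, in which case basins of any surface built on it are sampling
artifacts; the pipeline warns when CC of the leading component exceeds 0.5.

## 2-D free-energy surface and the pathway of minimum energy

The surface is the 2-D histogram of the two leading components on a 0.1 ×
0.1 grid, Boltzmann-inverted like the 1-D profiles, with per-bin lists of
the frames it holds (the lists partition the trajectory, so any feature of
the surface maps back to conformations and times). Minima are strict local
minima of the finite grid under the 8-neighbourhood, retained within 3
k<sub>B</sub>T of the global minimum, ordered by first-visit time; flat
ties resolve to the lowest (row, column) bin.

The pathway between two minima is a greedy perpendicular-scan recursion:
advance one bin width from the current point along the straight line to
the target, scan the perpendicular segment through that point at one-bin
resolution, move to the finite bin of lowest free energy (ties to the
lowest bin coordinate), re-aim, and stop once within one bin of the
target. The scan segment is clipped to the circle whose **diameter is the
current interpolation segment** (current point → target). This choice is
deliberate: clipping instead to a circle fixed at the leg's endpoints
allows mid-path chords to reach back into the start basin of a curved
valley, where the recursion provably cycles (reproduced on banana-shaped
two-basin test surfaces). With the per-step circle, every candidate bin is
strictly closer to the target than the current point, so the approach
distance is monotone and termination is guaranteed; a step budget of
10·(leg length / bin) guards degenerate inputs. Infinite (unsampled) bins
are impassable, and a perpendicular segment with no finite bin is a
reported path error. Multi-leg paths concatenate leg-wise; each leg's
saddle is the free-energy maximum strictly between its end minima, and the
barrier is measured from the leg's starting minimum. Per-step dihedral
profiles are ordinary 1-D profiles restricted to the frames of that step's
bin; the most probable γ at a step is the bin center of that profile's
minimum.

## Observables

R<sub>g</sub> is mass-weighted over heavy atoms (standard atomic masses;
unknown elements fall back to carbon). P(r) is the frame-averaged
histogram over all unordered heavy-atom pairs, self-pairs excluded,
intra-residue pairs included, 1 Å bins, normalized to unit integral; a
single-frame mode takes an explicit frame list. Side-chain
center-of-mass distances use mass-weighted heavy atoms excluding backbone
N/CA/C/O (glycine falls back to Cα). Threshold fractions use a strict
">". Gaussian summaries are multi-start nonlinear least squares of a
sum-of-Gaussians on the distance histogram (8 seeded starts, components
reported in order of mean); least squares on the histogram, not EM on the
samples, because the quantity summarized is the plotted subpopulation
shape. RMSD convergence superposes each frame on the reference by Kabsch
SVD (a `fit=False` flag gives the unfitted alternative) and reports the
earliest time from which every rolling 10-ns window has standard
deviation below 0.5 Å through the end of the trajectory, sustained for at
least 50 ns; shorter trajectories report a reason instead.

## Synthetic-data generator

The generator produces the controlled inputs the toolkit is validated on;
it makes no attempt at physically realistic protein dynamics (no solvent,
no force field, no inertia), only at the *statistical* structure the
analyses consume.

- **Per-angle samplers.** Metropolis chains (uniform ±40° proposals by
  default, 500-step burn-in, one `numpy` Generator per seed, bit
  reproducible) target exp(−V) for harmonic, mixture-of-wells
  (V = −ln Σ exp(−(depth + ½·stiffness·d²)), d the circular distance in
  degrees) or tabulated potentials, so the stationary density is known in
  closed form and sampled profiles can be checked exactly. Wells separated
  by barriers much larger than the proposal width are deliberately not
  crossed — equilibrium tests use barriers a chain can actually traverse,
  and occupancy checks thin the chain (stride 25) so binomial error bounds
  apply to approximately independent draws.
- **Chain builder.** Internal-coordinate construction with fixed virtual
  bond length 3.8 Å and planar angle 120° (typical Cα geometry; any
  non-degenerate values satisfy the contract) places each next Cα from the
  declared dihedral convention, so extraction recovers the inputs to
  machine precision — the round-trip is the oracle for the dihedral sign
  convention itself.
- **State ensembles.** Three states × n runs share per-angle harmonic
  generators (default stiffness 0.008 k<sub>B</sub>T/deg², sd ≈ 11°);
  a planted X-specific angle keeps identical generators in the two non-X
  states and a well displaced by 90° in X; each-specific angles get three
  wells 90° apart. Replicates differ only in sampling seed. Unplanted
  angles reuse the same chain across states within a run, making the
  null comparison exact.
- **2-D walks.** Gaussian-step Metropolis on a tabulated or callable
  surface inside a bounded box; the long-run histogram converges to the
  surface's Boltzmann density, which is what the FES and pathway machinery
  need. Dynamics-dependent diagnostics (cosine content) use cumulative-sum
  random walks instead, since Metropolis time has no physical meaning.

What passing tests show, and do not show: recovery of planted
state-specific angles under these generators demonstrates the
classification logic and its thresholds, not robustness to force-field
artifacts, correlated backbone motion, or replicate pairs whose
differences are dynamical rather than distributional. Real trajectories
converge far more slowly than independent-well Metropolis chains; the
replicate gate exists precisely because of that, and its 0.5 threshold is
a study convention, not a fitted constant.

## Numerical choices and edge cases

- Histogram probabilities must sum to 1 within 1e−12; H is clamped at 1
  against rounding.
- A zero-variance embedding fits without error and reports all-zero
  eigenvalues; the pipeline reports such inputs as degenerate (total
  variance < 1e−12) rather than building a surface.
- TSV interchange writes %.17g and reads with round-trip float parsing,
  so table round-trips are bit-exact; PDB round-trips are exact to the
  format's 1e−3 Å field width.
- The packaged similarity matrix stores exactly the printed two-decimal
  values; one printed percentage of the accompanying count table (6/388 as
  1.6 %) differs from standard rounding (1.5 %) by one unit in the last
  digit, so recomputed percentages are compared to printed ones at that
  precision.

## Problem sizes used in the test suite

Equilibrium checks sample 10⁵ Metropolis steps per angle; ensemble
classification tests use 50 angles × 3 states × 2 runs × 10⁴ frames; FES
and pathway checks use 1–2 × 10⁵ walk steps and 20 seeded analytic
surfaces. These sizes put counting noise well below every asserted
tolerance while keeping the whole suite under a minute on one CPU.

## Known limitations

- The pathway recursion is greedy and local; it does not refine toward the
  true minimum-energy path (no string method or nudged elastic band) and
  can hug one wall of a broad flat valley at bin resolution.
- Empty-bin impassability ties path topology to sampling density: a
  genuinely low barrier that was never sampled is a blocked path, not a
  low barrier.
- The similarity gate compares marginal distributions only; two runs with
  identical per-angle histograms but different kinetics pass the gate.
- Binary MD formats (XTC/DCD) are out of scope; convert to multi-model
  PDB or the TSV table first.
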