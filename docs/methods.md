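# Methods

## The descriptor

`l1npi` computes a size-agnostic topological descriptor of molecular point
clouds, aimed at comparing the network structure of simulated water across
interaction potentials and system sizes.

**Point cloud.** Each trajectory frame is reduced to the positions of its
oxygen atoms (for water, one third of the atoms). Hydrogens are deliberately
excluded: it is the tetrahedral oxygen network that carries the structural
signal, and treating all atoms equally would largely measure densely sampled
3-space instead. Coordinates are always in Å; no unit conversion is implicit.

**Vietoris–Rips persistence.** At scale δ the VR complex contains a simplex
for every point set with all pairwise distances ≤ δ; a simplex's filtration
value is therefore its longest edge. Sweeping δ yields a filtration whose
homology is tracked in degrees 0 (connected components), 1 (loops) and
2 (enclosed voids); every feature is a (birth, death) pair, with death = ∞
for classes that survive to the filtration cap. Pairs are computed by the
standard boundary-matrix reduction over GF(2), with columns stored as integer
bitsets; an independent brute-force oracle (explicit boundary operators and
GF(2) ranks at a frozen scale, ≤ 10 points) cross-checks the reduction in
the test suite. The guiding worked example is the regular hexagon with
nearest-neighbour distance d: six components at δ = 0, five dying at d, one
loop (d, √3 d), one void (√3 d, 2d).

Numerical conventions:

* simplices appear at δ *equal to* their longest edge (≤ rather than the
  strict <; the difference is measure-zero in the inputs considered);
* ordering ties are broken by (value, dimension, lexicographic vertices), so
  output is deterministic across platforms;
* zero-persistence pairs are retained in diagrams, flagged, and contribute
  nothing to images (the diagonal weighting vanishes there);
* the filtration cap δ_max is a required configuration value — VR complexes
  on thousands of points are infeasible without one. For water-like clouds
  (O–O nearest neighbour ≈ 2.8 Å) the working default is 6 Å, past the
  second neighbour shell. Deaths beyond the cap are reported as ∞.
* degree-2 homology needs simplices up to dimension 3 only, so `max_dim` is
  capped at 3.

**Persistence images.** Per degree, finite pairs are mapped to
(b, p = d − b), smoothed with a Gaussian g centred at each point, multiplied
by a weighting φ with φ(x, 0) = 0, and integrated over a fixed pixel grid
(midpoint rule: centre value × pixel area), default 50 × 50. Midpoint
integration keeps the image exactly additive in the diagram; its quadrature
error is negligible when σ spans several pixels. Choices that the
formulation leaves open:

* **Gaussian convention.** The default kernel uses 2πσ² in the exponent
  denominator, `g = 1/(2πσ²)·exp(−((x−b)²+(y−p)²)/(2πσ²))`; the usual
  bivariate-normal form with 2σ² is available as `kernel="canonical"`. The
  two differ only by an effective √π rescaling of σ (and a constant factor
  π in total mass, which L1 normalisation removes). The convention is
  recorded in image metadata and enforced at aggregation time.
* **Weighting φ.** A piecewise-linear ramp in persistence,
  φ = clip(p / p_hi, 0, 1), independent of birth: zero on the diagonal for
  stability, saturating at the grid's persistence ceiling.
* **σ.** Defaults to 0.1 × the persistence extent of the grid; stored in
  metadata so images computed at different σ can never be silently mixed.
* **Grid ranges.** Fixed per experiment, never per frame — pixels must mean
  the same thing across frames and systems. `auto_grid` scans a sample of
  diagrams and pads the observed extent by 5% as a convenience; the result
  must then be shared by every frame of the experiment. Points outside the
  grid still contribute their Gaussian tails.

**L1 normalisation.** The image integral scales with the number of features
and hence with system size. Dividing each frame's image by its total pixel
mass (`L1NPI[i,j] = I[i,j] / ΣI[i,j]`) yields a unit-mass descriptor
comparable across system sizes. Averaging is per-frame-then-mean (the mean
of L1NPIs); this is *not* the L1-normalised mean image whenever raw frame
totals differ, and both orderings are exposed. All-zero images (empty
diagrams, e.g. degree 2 on small clouds) raise rather than propagate NaNs;
batch normalisation skips such frames with a warning and records the count.
Statistical analysis consumes per-frame L1NPIs flattened row-major to
ℝ^(nx·ny) (2500 at defaults); the flattening is lossless so linear-model
coefficients can be un-flattened back into images.

## Statistical layer

A linear SVM (exact libsvm solver, soft-margin C = 1 by default, one-vs-rest
for k > 2 classes) is the deliberately simple readout: if a linear function
of L1NPI pixels separates two ensembles, the descriptor exposes the
difference directly, and the weight vector un-flattens into a *separating
hyperplane image* whose pixels may be negative — absolute pixel value is
that pixel's importance. Descriptors enter raw (they are normalised masses
already); per-pixel standardisation would destroy the interpretability of
those images. The train/test protocol is a stratified 70/30 split with a
fixed seed, logged with every report. PCA is mean-centred, with each
component's sign fixed so its largest-magnitude loading is positive.

## Synthetic data

No simulation trajectories ship with the package; every input is generated:

* **Exact fixtures** (hexagon, square, point pair) with closed-form
  barcodes, used as oracles.
* **Sampled manifolds**: a noisy circle, and a torus sampled area-uniformly
  (minor angle rejection-corrected by the Jacobian (R + r cos θ)/(R + r)).
  A dense torus sample must show its two independent loops as the dominant
  degree-1 features — "dominant" meaning persistence ≥ half the maximum,
  with essential deaths capped at δ_max.
* **Perturbed lattices** standing in for MD oxygen clouds: diamond (8 sites
  per conventional cell; nearest-neighbour distance spacing·√3/4 — the
  tetrahedral geometry of the water oxygen network) or simple cubic sites,
  jittered by isotropic Gaussian noise and optionally subsampled. Jitter
  width plays the role of the structural differences between potentials: it
  directly sets the width of the neighbour-distance distributions the
  descriptor reads. Ensembles are fully deterministic per seed, and frame i
  is independent of the frame count (counter-based per-frame seeds).

The generators reproduce the *statistical shape* a descriptor consumes —
neighbour-distance distributions, their widths, system size — not
thermodynamics: there is no energy model, no hydrogen-bond orientation
correlation, no diffusion. Passing tests therefore demonstrate the
descriptor's geometric and statistical behaviour, not fidelity to any
specific water model.

Two subsampling modes are provided because they answer different questions.
`random` deletes sites uniformly: this *dilutes* the lattice, lowering
density and introducing vacancies — a structural change, useful when a
defect signal is wanted. `block` keeps the leading fraction of sites in
lexicographic position order: a contiguous sub-volume at unchanged density
and local structure, i.e. a genuinely smaller system of the same material.
Size-independence experiments must use `block`: removing molecules from a
liquid at constant pressure leaves the surviving structure unchanged, which
is exactly what the block crop emulates, whereas random dilution builds a
vacancy concentration that any structure descriptor (correctly) detects.

## Reference experiments

Study conditions, chosen once (see `l1npi.experiments`): diamond lattice,
6.4 Å cell edge (O–O nearest neighbour 2.77 Å), jitter 0.25 Å, δ_max 6 Å,
degree-1 homology, 50 × 50 grid on birth ∈ [0, 6] Å × persistence ∈ [0, 3] Å
(σ = 0.3 Å), stratified 70/30 split, C = 1.

* **Size independence** — size classes 0.9/0.8/0.7 (block crops), 60 frames
  each, at 4×4×4 cells = 512 sites, a typical coarse-grained system size.
  Size independence is a statement about bulk behaviour and genuinely
  weakens at small sizes (smaller systems have proportionally more surface
  and noisier per-frame images), so it is evaluated at the largest system
  the conditions afford. The raw-image SVM separates the classes easily
  (total image mass tracks molecule count); the L1NPI SVM on the very same
  frames drops to near-chance among three classes, and the strong PC1–size
  rank correlation of raw images collapses for L1NPIs.
* **Structure discrimination** — at 2×2×2 cells (64 sites), ensembles with
  jitter 0.15 vs 0.30 Å (40 frames each) are classified from degree-1
  L1NPIs, and a four-level jitter sweep (0.1–0.4 Å, 25 frames per level) is
  projected onto PC1, which rank-orders the levels. The small system
  suffices here because the jitter signal is strong; it also keeps the
  experiment fast.

## Known limitations

* The boundary-matrix reduction is pure Python over integer bitsets —
  entirely adequate for hundreds of points per frame, not for the ~10⁴-point
  frames of large atomistic simulations.
* Periodic boundaries are supported in distance computation only
  (orthorhombic minimum image); the filtration itself has no periodic
  topology, so a fully wrapped box acquires artificial essential classes at
  large δ. The default treats coordinates as an open cluster.
* Only degrees 0–2 (dimension ≤ 3 simplices) are computed; triclinic boxes,
  element-weighted filtrations and representative cycles are out of scope.
* L1NPIs are *more* size-independent than raw images, not perfectly so:
  frames of larger systems have more features and hence individually
  smoother images, which narrows their distribution in descriptor space.
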