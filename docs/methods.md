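# Methods

## The segmentation criterion

`entroseg` segments a gray image by choosing `m` gray-level cut points that
maximize the sum of Shannon entropies of the normalized within-class
histograms (Kapur-style maximum-entropy thresholding).  Only the histogram
enters the criterion: two images with identical histograms receive identical
thresholds regardless of pixel arrangement.  The method assumes the tissue
classes of interest occupy distinct intensity ranges; it has no spatial
regularization.

Conventions, and why:

- **Interval convention.**  Class `i` is `[u_i, u_{i+1})` with sentinels
  `u_0 = 0`, `u_{m+1} = Z`.  This yields a total partition, reproduces the
  classic single-threshold rule (`o < U → 0`, `o ≥ U → 1`) exactly, and
  assigns gray level 0 to class 0.  A second dialect, `paper-eq2`, applies
  left-open classes `(u_i, u_{i+1}]` literally: pixels lying exactly on a cut
  land one class lower, and gray level 0 — which the left-open rule does not
  cover — is assigned to class 0 as a documented extension.  The two dialects
  differ precisely at cut-valued pixels and nowhere else.
- **Entropy bounds.**  Sums run over each class's full level range with the
  convention `0·log 0 = 0`; gray level 0 participates like any other level.
- **Class normalizers.**  `e_i` is the total histogram mass of class `i`, so
  each class's normalized sub-histogram sums to 1 and `J_i` is a genuine
  entropy (non-negative, zero for a single-level class).
- **Log base.**  A parameter (2, e, or 10); the argmax is base-invariant, and
  bits are the default reporting unit.
- **Feasibility.**  A threshold vector inducing a zero-mass class is
  infeasible and excluded from the argmax rather than scored 0.  Without this
  rule the criterion degenerately prefers piling all mass into one class
  (visible on a two-spike histogram, where an empty middle class would score
  the same as the correct split).

## Optimizers

**Exhaustive oracle.**  Enumerates all `C(Z−1, m)` candidate vectors in
lexicographic order (guarded at 2·10⁶ evaluations by default) and keeps the
strictly best, so ties resolve to the lexicographically smallest optimum.
Each candidate is scored by the direct normalized sum, which returns exactly
0.0 for single-level classes — this keeps tie-breaking stable and
bit-reproducible.  The oracle is the correctness anchor for everything else.

**Population search.**  An elitist integer-coded genetic algorithm:
chromosomes are sorted cut vectors; fitness is the Kapur objective with
infeasible candidates at −∞; binary-tournament selection (ties toward the
lexicographically smaller vector), uniform crossover of aligned genes
(rate 0.9), and per-gene mutation (rate 0.1) that takes a ±geometric local
step (mostly ±1/±2, capped at `max(4, Z/8)`) with probability 0.75 and
otherwise redraws the cut uniformly in `[1, Z−1]`.  Sort + de-duplicate (lost
genes redrawn from unused levels) is the only repair.  Stopping: 100
generations or 20 without improvement.  The mutation mix was chosen so the
search can refine near-optimal vectors by single-level moves — with a purely
uniform mutation the run often plateaus one or two gray levels short of the
optimum before patience expires.  The defaults (population 30, rates above)
are conventional GA settings, fully overridable, and the final best vector is
re-scored with the reference objective so the reported value is always a
plain re-evaluation.  Internally, populations are scored by an equivalent
prefix-sum evaluator (`log e − (Σ q log q)/e` per class from two cumulative
arrays, O(m) per candidate); it can differ from the direct sum in the last
ulp, which is why reported optima are re-evaluated.

Batch comparisons against the oracle (20 random histograms per cell,
`m ∈ {1,2}`, `Z ∈ {16,64,256}`) show the GA reaching the exact optimum in
≳95% of runs and staying within a few 10⁻⁵ relative in the rest; this is the
test suite's operating point, at roughly 3,000 objective evaluations per run
versus up to 32,385 for the oracle at `Z = 256, m = 2`.

## Synthetic phantom

The phantom emulates an abdominal-CT-like slice: tissue regions (background,
liver ellipse, tumor disk; optionally a gallbladder ellipse) painted in
declaration order, later regions overwriting earlier ones, so ground truth is
exact by construction.  Pixel values are `round(mean + N(0, sd·scale))`
clipped to `[0, Z−1]`; randomness comes from `numpy.random.Generator(PCG64)`
and the algorithm name is recorded in the spec echo, making outputs
bit-reproducible for a fixed seed.  An analytic expected histogram
(region-fraction-weighted mixture of discretized, clipped Gaussians) is
provided; the empirical histogram converges to it as the frame grows, which
the tests check by Monte-Carlo.

The default `liver3` scene is a 256×256 liver-centered field of view with
class means 40/120/200, noise SD 10, and compartment areas of roughly
0.33/0.40/0.27 of the frame.  The comparable areas are deliberate: the
unweighted entropy sum is known to pull cuts toward classes with large mass
and wide tails, so a scene with a tiny lesion (a few percent of the frame)
would see its upper cut dragged ~2σ into the liver mode and the lesion Dice
drop to ~0.91 even at these well-separated means.  With balanced areas the
recovered cuts land between adjacent means and every class is recovered with
Dice ≥ 0.97.  This sensitivity to class-mass imbalance is a real property of
the criterion, not of the phantom; scenes with realistic small lesions can be
built by configuring the geometry, and the evaluation module will quantify
the degradation.

What the phantom does *not* model: CT physics (beam hardening, streaks,
partial-volume mixing at boundaries), spatially correlated noise, intensity
inhomogeneity, 3D context.  Passing the phantom tests therefore demonstrates
correct histogram-domain behavior of the criterion and optimizers — not
segmentation quality on clinical CT, where class-conditional intensities
overlap more heavily.

## Numerical choices and degenerate inputs

- Entropies use `scipy.special.xlogy`, so zero-probability levels contribute
  exactly 0.
- Tie-breaks are lexicographic everywhere (oracle enumeration order; GA
  accepts an equal-fitness vector only if lexicographically smaller), making
  both optimizers deterministic.
- A constant image (or any histogram with fewer than `m+1` occupied levels)
  raises a feasibility error rather than returning a degenerate vector.
- Histogram validity is enforced to `Σq = 1` within 1e-12; the closed-form
  entropy identities hold to the same tolerance in the tests.
- Rounding in the phantom uses `numpy.rint` (banker's rounding at exact .5);
  with continuous Gaussian noise the event has probability zero and the
  analytic histogram model ignores it.

## Test problem sizes

The suite validates the oracle against an independent naive double-loop at
`Z ≤ 16`, the GA against the oracle at `Z ≤ 256`, and recovery on 64–256 px
phantoms; these sizes keep the full suite under a minute while covering every
code path at full gray resolution.

## Known limitations

- The criterion is histogram-global: no spatial coherence, so salt-and-pepper
  class noise at Gaussian overlap boundaries is expected and visible in the
  phantom label maps.
- Kapur's unweighted entropy sum biases cuts under heavy class-mass
  imbalance (see above).
- Single 2D slices only; 8/16-bit PNG/TIFF and single-slice NIfTI with an
  explicit linear window.  DICOM, 3D volumes and multi-channel images are out
  of scope.
- The GA is single-threaded by contract; no parallel evaluation.
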