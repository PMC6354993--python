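# Methods

## The analysis

Exhaled tracer aerosols deposit at the mouth in a spatial pattern — an
"aerosol fingerprint" — that encodes the structure of the lung that shaped
the exhaled flow. The question addressed here is whether small-airway
obstructions of graded severity (a normal airway A0 and four constrictions
A1–A4 in the G7–G9 bronchioles, 74.5%–99.5% loss of cross-sectional area)
can be read off such images, and which feature-extraction strategy reads
them best.

Images are flattened to columns of a snapshot matrix. Within each test
condition (inhalation flow rate × particle size × replicate) the five stage
images are stacked in disease-progression order A0→A4, so that consecutive
columns of a group form a short trajectory. Four SVD-based decompositions
supply candidate feature bases:

- **POD** — left singular vectors of the raw snapshot matrix `X`.
- **PCA** — POD of `X − X̄` (the ensemble-mean image subtracted); the mean
  is stored and re-subtracted before projecting new images.
- **DMD** (exact variant) — fits the linear one-step operator `X″ ≈ A X′`
  where `X′`/`X″` hold the stage-k / stage-(k+1) columns of every group:
  `X′ = UΣV*` truncated at r, `Ã = U*X″VΣ⁻¹`, `ÃW = WΛ`, modes
  `Φ = X″VΣ⁻¹W` (normalized to unit columns), `b = Φ†x₀`.
- **DMDC** — additionally models exogenous controls,
  `X″ ≈ A X′ + C Y` with `Ω = [X′; Y]`, via the two-SVD recipe (input SVD of
  `Ω` at rank p, output SVD of `X″` at rank r); returns the reduced control
  operator `C̃` alongside the modes. The controls are the per-transition
  (particle size, flow rate, severity of the target stage), standardized
  per row. Note that target-stage severity is label-derived: using it as a
  control input leaks class information into feature extraction. The
  pipeline reproduces this design faithfully; interpret DMDC accuracies
  with that caveat.

Discrete eigenvalues are reported with their continuous transforms
`ω = log λ / (2π)` (principal branch, `Im ω ∈ (−1/2, 1/2]`, with the
boundary value `−1/2` normalized to `+1/2`): `|λ| < 1 ⇔ Re ω < 0`, and
`|Im ω|` is the oscillation frequency per progression step.

Per-image features are the real parts of least-squares projection
coefficients on the leading r modes (σ-ranked for POD/PCA; |b|-ranked, ties
by |λ|, for DMD/DMDC). Classification uses a random forest (1,000 trees by
default, √r features per split, no depth limit) and an RBF support vector
machine (cost 1, kernel width 1/n_features, one-vs-one, features z-scored
with training-fold statistics only — the defaults of the classical e1071
implementation). Ten-fold cross-validation, stratified by class, is
re-randomized over many repeats; accuracy is 1 − misclassified/total, and
misclassification is also accounted per unordered class pair, the pair
rates summing exactly to 1 − accuracy.

## The synthetic data generator

The original image database was produced by CFD airflow and particle
transport simulations and is not available in machine-readable form, so the
generator emulates its *structure* rather than its physics: 405 images =
5 stages × 3 flow rates (27/30/33 L/min) × 9 particle sizes (0.2–10 μm) ×
3 stochastic replicates, a shared background pattern, and severity-ordered
perturbations.

Within a group the images are snapshots of a planted linear latent system

    z_{k+1} = A z_k + C y_k,      x_k = clip(m + Φ z_k + ε_k, 0)

with latent rank 8. `A` is block-diagonal: three damped rotation pairs at
angles 2π/3, 2π/5, 2π/9 (damping 0.98) and two real decays (0.7, 0.45).
The rotations put oscillatory content at frequencies 1/3, 1/5 and 1/9 —
associated with the flow-rate, disease-stage and particle-size factors —
so the dynamic-mode amplitude spectrum of the default dataset shows its
three dominant peaks at exactly those frequencies. `C` routes only the
severity control into the state (0.25 into the fast decay, weakly into the
period-5 pair): flow and size are constant within a group, and a constant
forcing would merely shift the group fixed point while biasing the
eigenvalue estimates of any control-blind decomposition, so those condition
effects enter through the initial state instead. The severity sequence is
the fractional area loss of the target stage (from the tabulated airway
dimensions in `aeromode.airway`), standardized over the design; its strictly increasing values order the stages and make
A2–A3 the closest pair (smallest standardized gap), which is also where
misclassification concentrates.

The initial state carries the condition and replicate structure: each
rotation pair starts at a fixed amplitude (3.0, 2.4, 2.7, scaled by the
per-factor effect sizes) with a **uniformly random phase per group**, plus
loadings of the standardized flow/size values and Gaussian jitter
(sd 0.6). The random phases are deliberate: with deterministic phases every
stage was identifiable from rotation phase alone and all methods scored
100%; randomizing them confines class information to the severity-driven
coordinates and produces the moderate difficulty the evaluation needs.

The mean pattern `m` (base intensity plus five vortex-like Gaussian blobs
and two curved streaks, echoing the qualitative background features of the
averaged fingerprint) rides along every snapshot unchanged, i.e. it is a
fixed point of the effective pixel-space operator; noiseless data therefore
follow an exactly linear map with eigenvalues {1} ∪ eig(A). The spatial
modes Φ are fixed unit-norm Gabor/blob/streak patterns defined in
normalized coordinates (any resolution ≥ 8 px), deliberately
**non-orthogonal** (a shared broad component is mixed into each): an
orthogonal decomposition cannot align single modes with single latent
coordinates, whereas operator-eigenvector methods can — the structural
reason the dynamic decompositions out-classify POD/PCA here.

Two heavy-tailed ingredients emulate the erratic components of a real
breath test and are what separates the random forest from the SVM:

- **bursty replicates** — with probability 0.1 a group's initial jitter is
  drawn 6× wider (an erratic inlet profile);
- **noisy acquisitions** — with probability 0.12 an image's pixel noise
  (baseline sd 0.02) is 4× larger.

Feature tables built from such data contain genuine outliers; a C=1 RBF-SVM
suffers both through its z-scoring (outliers inflate the per-feature scale
estimates) and through kernel-distance distortion, while the forest's
quantile splits are indifferent. Under purely Gaussian noise the two
classifiers were statistically indistinguishable on dynamic features; the
heavy tails reproduce the robust-classifier ordering without touching the
linear dynamics. These settings were calibrated once, jointly with the
effect sizes, to a moderate-difficulty regime (mean accuracies roughly
0.2–0.8 across cells, severity orderings and spectrum peaks stable across
generator seeds) and are not tuned per run.

What the generator does **not** emulate: particle-count statistics (images
are smooth intensity fields, not point deposits), fractal/multiscale
deposition structure, nonlinear flow–structure interactions, and any
physical relation between flow rate or particle size and deposition
morphology beyond low-rank linear effects. Passing results therefore
demonstrate that the pipeline recovers planted structure and reproduces the
qualitative method orderings under the stated noise model — not that the
classifier would reach any particular accuracy on CFD-generated or clinical
images.

## Identifiability of the recovery checks

Noiseless recovery is verified in two runs because the two checks impose
incompatible conditions on one dataset. Plain DMD is exact only if the data
are autonomous-linear, i.e. the control signal is either absent or exactly
reconstructible from the pixel state; but if the controls are linearly
reconstructible from `X′`, the rows of `Ω = [X′; Y]` are dependent and the
split of `G = [A C]` is no longer identifiable — DMDC's `Ã`/`C̃` would be
one of infinitely many valid attributions. Hence: a control-free noiseless
run (severity column zeroed) verifies DMD eigenvalue recovery to 1e-6, and
the default noiseless run (severity control active, not linearly
reconstructible because the random initial jitter masks it) verifies DMDC
eigenvalue and control-operator recovery to 1e-6, the oracle being the
planted operators lifted through the stored spatial modes and the explicit
pseudoinverse solution `G = X″Ω†`.

## Numerical choices

- Singular values below `1e-10 · σ_max` are excluded from every
  pseudo-inversion (tall, nearly rank-deficient matrices are the norm here);
  a requested rank above the numerical rank is truncated with a warning.
- Exact-DMD modes are normalized to unit columns with the norm folded into
  the amplitudes, so |b| measures contributed energy.
- Amplitudes average the **magnitudes** of `Φ†x₀` over the group-initial
  columns (complex averaging would cancel the random per-group phases) and
  use the median across groups, which is robust to outlier snapshots.
- The amplitude spectrum is aggregated into 32 equal frequency bins on
  [0, 1/2]; a peak is a bin strictly above both neighbours. The first bin
  (zero frequency: the mean/background component) has no left neighbour and
  is never a peak. Spectrum diagnosis uses operator rank 30 — the planted
  dynamics are low-rank and higher ranks admit junk modes from the
  heavy-tailed images — while classification features use r up to 100.
- DMDC's input rank defaults to `r + 3` (the state rank plus the three
  controls).
- k-fold partitions come from seeded (Stratified)KFold; one master seed
  fans out independent streams per repeat, per sweep cell, and per
  classifier, so any cell is reproducible in isolation.
- PNG export quantizes to 16 bits with fixed full scale 8.0 (wide enough
  for burst replicates at low resolutions); a write→read round trip is
  exact on that grid, and the first write is accurate to half a quantum
  (1.2e-4 relative), far below the pixel noise.

## Evaluation profiles and problem sizes

The default "quick" profile evaluates 405 images at 128×128 (the analysis
depends only on the column space, not pixel count; the original images were
600×600) with 20 CV repeats and 200-tree forests — a single-CPU desk-scale
setting (the full sweep in minutes) whose mean accuracies differ negligibly
from larger forests. The "fidelity" profile restores the reference
configuration of 100 repeats and 1,000 trees. CVConfig defaults themselves
remain at the reference values.

## Known limitations

- A group is one (flow, size, replicate) triple — 81 trajectories of 5
  stages. Arrangements that concatenate or average replicates into 27
  groups have no clean dynamical reading and are not provided.
- Disease progression across stages is a pseudo-time: each "trajectory"
  stitches together five different airway geometries, exactly as the
  snapshot arrangement assumes.
- DMDC's severity control leaks label information (above); the comparison
  DMDC ≥ DMD should be read as "with extra label-derived input", not as a
  like-for-like algorithmic improvement.
- Reported accuracies quantify the synthetic benchmark only; absolute
  values are not comparable to those obtainable on CFD or clinical data.
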