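# Methods

## Scope and model

`volnma` predicts the low-frequency flexibility of a macromolecular
complex directly from a 3D EM density volume, without an atomic model.
The chain of models is:

**Density → pseudo-atoms.** The masked density `V(r)` is approximated by
`V̂(r) = Σᵢ wᵢ exp(−|r − rᵢ|²/2σ²)`: `N` isotropic Gaussians of shared
standard deviation σ, unit peak amplitude, scaled by positive weights
`wᵢ` (density units). σ is configured in voxels — the working rule is a σ
comparable to the voxel size, between 1 (small pseudo-atoms) and 5 (large
ones) — and stored on the model in Å. Rendering truncates each Gaussian at
4σ (relative truncation error ~3·10⁻⁴ of the analytic Gaussian mass).

**Pseudo-atoms → elastic network.** Every pair closer than a cutoff `R_c`
is linked by a spring of stiffness `C` whose rest length is the pair's
distance in the input conformation:
`E = (C/2) Σ_{d⁰ij < R_c} (d_ij − d⁰ij)²`. The input conformation is the
energy minimum by construction, so no minimization precedes the analysis.
The edge condition is strict (`<`); `C = 1` by default — it only sets the
energy scale, so eigenvalues and frequencies are reported in arbitrary
units.

**Network → modes.** The 3N×3N Hessian at the reference has, per edge,
the off-diagonal block `−C (Δr)(Δr)ᵀ/|Δr|²` and diagonal blocks that
negate the sum of their row's off-diagonal blocks, giving a symmetric
positive-semidefinite matrix with zero row sums. All pseudo-atoms get unit
mass: they carry no physical mass, and uniform masses change only the
frequency scale, not mode shapes. (Whether weighting by the Gaussian
weight `wᵢ` would be preferable is an open modelling question; unit masses
keep the modes a property of the shape alone.) Eigenpairs come from dense
`eigh` for 3N ≤ 3000 and from sparse shift-invert Lanczos (shift −0.05,
keeping the factorized matrix nonsingular despite the six-dimensional
null space) above; both paths agree to tight tolerance and are tested
against each other. Modes are unit-norm over all 3N coordinates, sorted by
ascending eigenvalue, 1-based, sign-fixed so the largest-magnitude
component is positive. Modes with `λ < 10⁻⁶·max(λ, 1)` are flagged
rigid-body: exactly 6 for a connected, mechanically rigid network, 6 per
component otherwise.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `target_error` | 0.06 | — | relative L1 error at which growth stops |
| `sigma_voxels` | 1 | voxels | pseudo-atom radius (1–5 reasonable) |
| `max_atoms` | 9999 | atoms | hard cap forwarded to NMA |
| `cutoff` | auto | Å | spring range; auto = 95% neighbor-distance rule |
| `spring_constant` | 1 | arbitrary | overall energy scale only |
| `n_modes` | 20 | — | lowest modes computed |
| `amplitude` | 50 | Å·(unit-mode) | animation amplitude: atom i moves ≤ 50·|uₙᵢ| Å |
| `n_frames` | 10 | — | frames per animation cycle |

The error metric is the masked relative L1 deviation
`Σ_mask|V − V̂| / Σ_mask|V|`: dimensionless, in [0, 1] for non-negative
maps, robust to bright outliers, and 0 iff the fit is exact on the mask.

The 9999-atom cap bounds the eigenproblem (3N ≤ 29997) and fits PDB's
4-digit serial/residue fields in the export dialect; volumes needing more
atoms should be downsampled first (`volnma.volume_io.downsample`).

## The adaptive fit

The conversion is a residual-seeded growth loop, deterministic given its
seed:

1. draw `initial_atoms` (default 100) voxel centers with probability
   proportional to the masked density, jittered uniformly inside the
   voxel;
2. alternate weight and position refinement until the per-round error
   improvement falls below 1%: weights by multiplicative nonnegative
   least-squares updates `w ← w·(AᵀV)/(AᵀV̂)` (the Gaussian design and the
   data are both nonnegative, so the update keeps every weight strictly
   positive and decreases the L2 misfit); positions by damped Gauss-Newton
   steps capped at half a voxel. Every update is accepted only if the
   reported L1 error improves (with damping/backtracking otherwise), so
   the per-iteration error is non-increasing by construction;
3. prune atoms whose weight falls below 10⁻⁶ of the maximum (at the cap
   they are clamped to that floor instead — removing them would only
   trigger another add round);
4. if the error still exceeds the target and `N < max_atoms`, add a batch
   of `max(32, N/10)` atoms at the voxels of largest positive residual,
   initialized at 0.1× the residual amplitude (a clustered batch of
   overlapping Gaussians started at full amplitude overshoots), and
   repeat. If a batch cannot be refined back below the best error seen,
   the fit reverts to that best model and stops growing.

Termination: error ≤ target, or `N = max_atoms` (followed by an in-place
polish), or the outer-iteration budget (80). The per-iteration error
history is recorded on the returned model.

## Cutoff suggestion

"Neighboring distances" are read as per-atom nearest-neighbor distances;
`suggest_cutoff` returns their 95% quantile, raised — if the resulting
graph is disconnected — to just above the smallest radius that connects
it (bisection on the connectivity radius). Note that a nearest-neighbor
quantile is a *lower* bound on a useful cutoff: it guarantees coverage
and connectivity but not mechanical rigidity, and point sets with
inhomogeneous density can remain floppy (extra near-zero modes from
atoms with fewer than 3 neighbors). The network report therefore carries
the rigid-mode count; raising the cutoff to ~3σ or more removes spurious
mechanisms, which is why the worked example uses 14 Å for a σ = 4 Å
model.

## Collectivity, overlap, animation

Collectivity uses per-atom squared displacement magnitudes
`pᵢ = |uᵢ|²` normalized by `α = 1/Σpᵢ`:
`κ = (1/N)·exp(−Σ αpᵢ ln αpᵢ)` (natural log; zero-displacement atoms
contribute nothing). κ is scale-invariant and spans [1/N, 1], both bounds
attained exactly.

Overlap between a mode and an observed displacement Δr is
`|uₙ·Δr|/(|uₙ||Δr|)`. The rigid-body component of the target is projected
out first (basis: 3 translations + 3 centroid rotations, orthonormalized),
so residual superposition error between two conformations cannot inflate
the scores; the conformations should still be pre-superposed.

Animations run one full sine cycle per trajectory,
`a_k = A sin(2πk/K)`, so frame 0 is the reference and the exported
multi-model PDB loops seamlessly; a linear −A→+A ramp is available as an
alternative schedule.

## Synthetic phantom

The phantom emulates the standard validation protocol for this class of
method: a point model rendered to a 64³ grid at 2 Å/voxel and low-pass
filtered to 10 Å. Its geometry is two anisotropic Gaussian clouds of 150
atoms each, 40 Å apart, joined by a thin bridge; draws are truncated at
2 sd because EM density blobs are compact and untruncated outliers would
dangle off the elastic network as spurious mechanisms. The ground-truth
conformational change is geometric — every atom on one side of the hinge
plane rotates 25° about the hinge axis — so the same displacement field
can be evaluated at the ground-truth atoms *or* at any fitted model's
positions, making fitted-mode recovery testable. The low-pass filter is a
Fourier-space Gaussian with amplitude 1/e at spatial frequency
1/resolution; it preserves the DC term (total density) and the tiny
negative ringing it introduces is clamped to zero. Additive map noise is
zero-mean Gaussian, clamped at zero.

What the phantom does not emulate: microscope optics (CTF, envelope
decay), reconstruction artifacts, solvent background, or anisotropic
resolution. Passing the phantom tests shows the pipeline recovers a
designed hinge from a clean band-limited map; real maps add noise and
artifacts that primarily affect the masking and conversion stages.

## Numerical choices and limitations

- Rigid-mode tolerance `10⁻⁶·max(λ, 1)`; two-sided float32 storage for
  volumes; PDB coordinates at 3 decimals and weights as 2-decimal
  occupancies with a full-precision scale factor in a REMARK.
- The fit is stochastic (seeded); identical seed + config + volume gives
  bit-identical models. Achieved errors on the canonical phantom vary by
  ~±0.002 across seeds.
- Problem sizes used in validation: 64³ phantom fits run in ~1 s and a
  full 9999-atom cap run on a 48³ noise volume in ~1 min on one CPU;
  these sizes exercise every code path including the sparse eigensolver
  branch.
- Degenerate inputs: constant volumes have no threshold; empty masks and
  all-zero masked volumes are rejected; disconnected networks are
  analyzed with a warning (6 zero modes per component); requesting a
  rigid-body animation warns but proceeds.
- The collectivity of near-zero rigid modes is reported but not
  physically meaningful (their vectors are an arbitrary basis of the
  null space).
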