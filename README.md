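# volnma

Normal-mode analysis of electron-microscopy density volumes via Gaussian
pseudo-atoms.

When a macromolecular complex is only available as a 3D EM reconstruction
(no atomic model), its large-scale flexibility can still be predicted:
coarse-grain the density into point masses, connect them with springs, and
diagonalize. `volnma` implements that workflow end to end:

1. **mask** — threshold the input volume (MRC2014 or SPIDER), automatically
   (Otsu first guess) or at a user-chosen density;
2. **convert** — approximate the masked density `V(r)` by a weighted sum of
   isotropic 3D Gaussians ("pseudo-atoms"),

   `V̂(r) = Σᵢ wᵢ · exp(−|r − rᵢ|² / 2σ²)`,

   growing the atom count `N` adaptively until the relative error
   `Σ|V − V̂| / Σ|V|` reaches a target (default 0.06), up to a hard cap of
   9999 atoms;
3. **nma** — build an elastic network: every atom pair closer than a cutoff
   `R_c` gets a harmonic spring with rest length equal to its reference
   distance, so the potential `E = (C/2) Σ (d_ij − d⁰_ij)²` is minimal at
   the input conformation and needs no minimization. Diagonalizing the
   Hessian yields orthonormal normal modes `u_n` with eigenvalues `λ_n`;
   a connected network has six zero modes (rigid translations/rotations),
   so flexible motion starts at mode 7. A useful `R_c` makes ~95% of
   neighboring-atom distances fall below the cutoff; `suggest_cutoff`
   implements that rule;
4. **animate** — score each mode's collectivity
   `κ = (1/N)·exp(−Σ α|uᵢ|² ln α|uᵢ|²)` (κ = 1/N for a one-atom motion,
   1 for a fully collective one), deform the model along modes
   (`r′ = r + Σ aₙ uₙ`), and export looping multi-model PDB trajectories
   and per-frame volumes.

A synthetic-phantom module generates two-domain test volumes with a known
hinge motion so the whole pipeline can be validated without external data.

## Worked example

```sh
python - <<'EOF'
from volnma import phantom, volume_io as vio
from volnma.phantom import PhantomSpec, make_two_domain_phantom, structure_to_volume

spec = PhantomSpec(seed=0)                     # 64³ voxels, 2 Å, 10 Å low-pass
model, hinge = make_two_domain_phantom(spec)
vol = structure_to_volume(model, spec.grid_dims, spec.voxel_size, spec.resolution)
vio.write_volume(vol, "phantom.vol")
EOF
volnma run phantom.vol --sigma 2 --target-error 0.06 --cutoff 14 \
    --n-modes 20 --animate-modes 7-9 --out-dir demo_run
```

which prints:

```
threshold 2.75251: 5231 voxels kept
100 pseudo-atoms, achieved error 0.0565 (target 0.06)
20 modes (6 rigid-body) at cutoff 14.000 Å; 836 springs
animated modes [7, 8, 9] (10 frames, amplitude 50.0)
```

Reading the output: the Otsu guess kept the bilobed density region; the
converter reached the 6% error target with 100 Gaussians of σ = 4 Å
(2 voxels); the 14 Å elastic network is connected and mechanically rigid
(exactly 6 rigid-body modes, so modes 7–20 are genuine flexible motions);
`demo_run/` now holds the masked volume, the pseudo-atom PDB, the
approximated volume, per-mode vector files, a collectivity table, the
neighbor-distance histogram and looping multi-model PDB animations.
Scoring the modes against the phantom's built-in hinge displacement
(`volnma.mode_tools.mode_overlap`) identifies mode 9 with overlap ≈ 0.87 —
the opening/closing motion the phantom was constructed to have.

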