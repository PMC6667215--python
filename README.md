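# minwaves

Bulk-surface reaction–diffusion analysis of MinD/MinE ("Min") wave generation
under cell-sized confinement.

The package implements two nondimensional models of Min-protein dynamics on a
membrane coupled to a diffusing cytosolic bulk — Model I (single cytosolic
MinD pool) and Model II (separate ATP-/ADP-bound MinD pools with nucleotide
exchange) — including a spontaneous MinE membrane-binding level `ce0` that
controls wave extinction under confinement. On top of the models it provides:

- **`minwaves.models`** — reaction kinetics with flux-matched bulk boundary
  terms, homogeneous stationary states on spheres and slabs, unit
  (de-)dimensionalization, the closed-form cytosol/membrane partition index
  `cm_theory`, and parameter-file I/O (a canonical rate set is bundled:
  ωD=0.1, ωdD=5, ωE=0.1, ωed=100, D=100, ωe=1).
- **`minwaves.sphere_sim`** — pseudo-spectral (spherical harmonics × radial
  finite volumes) IMEX simulation on a closed sphere; conserves total MinD
  and MinE to round-off.
- **`minwaves.plane_sim`** — planar geometries: 2D membrane/3D bulk, 1D
  membrane/2D bulk, and the 0D-membrane/1D-bulk reduction used for
  excitability analysis (`excitability_threshold` bisects the smallest
  perturbation that triggers a large excursion).
- **`minwaves.stability`** — linear stability of the stationary state by two
  independent routes: a Chebyshev-collocation full eigenproblem and the
  analytic bulk elimination `det(Λ_l(0) + Γ·M(σ) − σI) = 0` with modified
  spherical Bessel (sphere) or cosh/sinh (slab) bulk factors; plus phase
  diagrams and critical-parameter bisection.
- **`minwaves.wave_metrics`** — rotationally invariant mode norms, normalized
  wave amplitudes, kymographs, and pattern classification
  (stationary / pulsing / pole-to-pole / traveling / homogeneous-oscillation).
- **`minwaves.synthetic_cm`** — synthetic droplet line scans with known
  membrane partitioning, the c/m measurement procedure (higher edge peak vs
  10-pixel center average), and seeded logistic fits of wave probability
  vs c/m.

## Tests

```sh
python -m pytest                  # fast suite (long simulations deselected)
python -m pytest -o addopts= -q   # everything, including slow pattern runs
```

## CLI

All tools are subcommands of a single `minwaves` entry point:

```sh
minwaves simulate-sphere --radius 5 --model II --ce0 0.0 --d0 0.5 --e0 0.8 \
    --lmax 16 --tmax 50 --out sphere.h5
minwaves simulate-plane --height 256 --length 48 --n-grid 48 --init band
minwaves excitability-scan --geometry slab --size 256 --ce0 0.07
minwaves stability --ce0 0.02 --modes 0,1,2,3 --out dispersion.csv
minwaves phase-diagram --d0-range 0.1 1.0 10 --e0-range 0.1 1.5 10
minwaves analyze sphere.h5 --kymograph kymo.png
minwaves cm-generate --diameter 20 --membrane-fraction 0.8 --out profiles.csv
minwaves cm-measure profiles.csv
minwaves cm-fit table.csv --seed 1
```

Trajectories are written as HDF5 (`/time`, `/totals`,
`/membrane/{d,de,e}/coeffs` or `.../grid`).

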