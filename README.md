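# trip3p

Geometric-ambiguity analysis of triangle stimuli through the
Perspective-3-Point (P3P) problem: how many 3D interpretations does a
triangle of known shape admit for a given retinal image?

A triangle `ABC` seen from an eye `E` is described by its vertex angles
`(omega_A, omega_B, omega_C)` (shape) and the three visual angles
`(theta_BC, theta_CA, theta_AB)` subtended at `E` (retinal image).  With
the size fixed (`|AB| = 1`), each admissible placement is a triple of
positive distances `(l_A, l_B, l_C)` along the sight rays satisfying three
law-of-cosines constraints; there are 0 to 4 such placements.

The package provides:

- **`trip3p.geometry`** — validated domain types (`TriangleShape`,
  `RetinalImage`, `SightRays`, `Interpretation`, `SolutionSet`), forward
  projection, and shape-from-given-orientation recovery.
- **`trip3p.solver`** — the P3P solver via the quartic resultant reduction
  (companion-matrix roots, Newton polishing, residual verification,
  deduplication), a vectorized batch counter, and a depth-reversal test
  for solution pairs.
- **`trip3p.oracle`** — an independent brute-force solution counter
  (dense 1D scan + bisection) used to cross-check the solver.
- **`trip3p.sampling`** — constrained-uniform rejection samplers for
  shapes (all vertex angles in 10-170 degrees) and images (visual angles
  in a box under the apex constraints), with seedable substreams.
- **`trip3p.experiments`** — the Monte-Carlo frequency study: distribution
  of solution counts 0-4 as a function of the image-size bound
  `theta_max`, in `full` mode (angles in `(0.1, theta_max)`) and `half`
  mode (angles in `(theta_max/2, theta_max)`).
- **`trip3p.shape_maps`** — solution-count maps over `(omega_A, omega_B)`
  shape space for a fixed image, binocular combination, and the bundled
  stimulus images of two classic psychophysics experiments (Beck &
  Gibson; Watanabe left/right eye).

## Command line

```sh
# Monte-Carlo frequencies of solution counts
trip3p frequency --theta-max 14 --mode full --trials 100000 --seed 1 \
    --output-dir out/freq --plot

# solution-count map for one image
trip3p shapemap --theta-bc 90 --theta-ca 100 --theta-ab 110 \
    --grid-step 0.5 --output-dir out/map --plot

# audit the bundled psychophysics stimuli (all, or selected)
trip3p stimuli-audit --stimulus watanabe_left --stimulus watanabe_right \
    --grid-step 0.5 --output-dir out/audit
```

Each run writes CSV/JSON outputs plus a `manifest.json` (resolved config,
seed, version, timings).  A YAML config file with flat keys mirroring the
flags can be passed via `--config`; explicit flags override it.  Identical
seed and config reproduce outputs byte for byte.

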