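# rotascape

Relative-orientation conformational landscapes from paired focused cryo-EM
refinements.

Large flexible complexes such as the homodimeric fatty acid synthase (FASN)
consist of two rigid bodies — a condensing wing and a modifying wing — that
rotate against each other, so no single consensus refinement resolves both.
The standard workaround is to refine each body separately (focused
refinement) from the *same* particle stack, which leaves every particle with
two sets of ZYZ Euler angles, one per body. `rotascape` turns those paired
angle assignments into a quantitative picture of the complex's flexibility:

1. **Relative orientation.** For each particle, with per-body rotation
   matrices `R_mod` and `R_cond` built from the refinement Euler angles
   (`R = Rz(psi) Ry(tilt) Rz(rot)`), the orientation of the condensing body
   in the modifying-body frame is `R_rel = R_modᵀ R_cond`, decomposed into
   intrinsic z–y–x (Tait–Bryan) angles `R_rel = Rz(α) Ry(β) Rx(γ)`. α is
   the swivel about the long inter-wing axis; β and γ are the two swing
   angles.
2. **Landscape.** Plotting every particle at its (α, β, γ) coordinate and
   binning (2° bins, light Gaussian smoothing, periodic in α and γ) gives a
   3D particle-distribution landscape whose local density measures how
   favoured each inter-body orientation is. Local density maxima are
   *hotspots*.
3. **Subset export.** Particles within a radius of any landscape coordinate
   are selected (wrapped Euclidean metric, ≤ boundary) and written to a
   STAR file carrying the condensing-body angles, ready for
   `relion_reconstruct`; ~200 particles are enough for an interpretable
   ~20 Å reconstruction.
4. **Substate recombination.** C2 symmetry expansion lets each monomer be
   classified independently (five ACP-engagement groups for the condensing
   wing, resolved/unresolved Ψ-domains for the modifying wing). Folding
   the two expanded copies of each particle back into one dimer yields the
   substate inventory: 5·6/2 = 15 unordered condensing pairs × 4 sided
   modifying combinations = 60 dimeric substates, each with its own
   landscape.
5. **Tether reach.** The carrier protein (ACP) delivers substrates on a
   phosphopantetheine arm with a finite reach budget (default 80 Å).
   Scanning the anchor-to-site distance over the swivel angle α gives the
   α-interval within which each catalytic site — and their intersection —
   is reachable.

A fully deterministic synthetic-scene generator produces paired refinement
STAR files with known ground truth (mixtures of wrapped Gaussians in
(α, β, γ), per-body angular noise, C2 expansion, per-monomer class labels),
so the entire pipeline is testable without any experimental data.

## Worked example

```python
import rotascape as rs

# simulate a paired focused-refinement scene with two favoured orientations
truth = rs.default_scene(n=20_000, seed=42)
paths = rs.simulate_scene(truth, "scene/demo")

# read the two STAR files and join them on particle identity
cm = {"class": "rotClassLabel"}
paired = rs.pair_refinements(
    rs.read_particle_star(paths["mod"], column_map=cm),
    rs.read_particle_star(paths["cond"], column_map=cm),
)
print(f"paired particles: {len(paired)}")

# per-particle relative orientations and the landscape (expansion copy 0)
copy0 = rs.ParticleTable(paired.df[paired.df.expansion_index == 0].reset_index(drop=True))
orients = rs.compute_orientations(copy0)
grid = rs.build_landscape(orients, bin_width=2.0, smooth_sigma=1.0)
for h in rs.find_hotspots(grid, percentile=97.5)[:2]:
    print(f"hotspot at ({h.center[0]:+.0f}, {h.center[1]:+.0f}, {h.center[2]:+.0f}) deg, "
          f"density {h.density:.2e}")

# select particles around the strongest hotspot and export for reconstruction
spec = rs.SelectionSpec(center=(13, 0, 14), radius=14.0)
indices = rs.select_within_radius(orients, spec)
rs.export_reconstruction_star(copy0, indices, "scene/hotspot_subset.star")
report = rs.selection_report(spec, indices)
print(f"selected {report['n_selected']} particles around (13, 0, 14); "
      f"too few to reconstruct: {report['too_few_particles']}")
```

Output:

```
paired particles: 40000
hotspot at (+13, +1, +13) deg, density 1.18e-03
hotspot at (-3, -9, -7) deg, density 1.09e-03
selected 7588 particles around (13, 0, 14); too few to reconstruct: False
```

The scene was generated with favoured orientations at (13, 0, 14) and
(−3, −8, −8) plus a broad background; both modes are recovered within one
2° bin, and the 7,588-particle subset around the first hotspot is written
as a reconstruction-ready STAR file (hand off with
`relion_reconstruct --i scene/hotspot_subset.star --o hotspot.mrc`).

The same pipeline is available from the shell:

```sh
rotascape simulate -n 20000 --seed 42 -o scene/demo
rotascape pair --mod scene/demo_mod.star --cond scene/demo_cond.star -o paired.star
rotascape landscape --mod scene/demo_mod.star --cond scene/demo_cond.star \
    -o grid.npz --plot grid --hotspots hotspots.tsv
rotascape select --mod scene/demo_mod.star --cond scene/demo_cond.star \
    --center 13 0 14 --radius 14 -o subset.star --report subset.json
rotascape substates enumerate -k 5
rotascape reach --structure model.pdb --anchor A/2112/CA \
    --site KS=A/161/SG --site MAT=A/581/OG --reach 80 --step 1 -o scan.tsv
```

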