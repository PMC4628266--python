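# parenchyma3d

3D morphometry of fruit parenchyma tissue from X-ray micro-CT, and a
structure-informed model of its effective oxygen diffusivity.

Fruit flesh (the cortex parenchyma of apple and pear) is a wall-to-wall
packing of roughly convex cells, 150–250 μm across, with 5–25 % of the
volume occupied by narrow intercellular air channels.  How well oxygen
reaches the interior of the fruit — which decides fermentation risk in
controlled-atmosphere storage — depends on the 3D architecture of that
air-channel network, not just on its volume fraction.  This package
implements an automated analysis chain for micro-CT stacks of such
tissue, for postharvest physiologists and plant anatomists:

* **segmentation** — global Otsu thresholding of the attenuation image
  into cell and void phases, plus a connected-component noise filter;
* **cells** — marker-controlled watershed on the Euclidean distance map
  to isolate individual cells, removal of border-cut cells, a "virtual
  sieve" (maximum caliper length ≤ 400 μm, sphericity ≥ 0.75) against
  unseparated clumps, and per-cell morphometrics (volume, triangulated
  surface, equivalent spherical diameter, elongation, fraction of the
  cell wall exposed to air);
* **voids** — 26-connected void labelling, edge-corrected void counting
  by the Miles–Lantuéjoul weighting
  `w = IxIyIz / ((Ix−Px)(Iy−Py)(Iz−Pz))`,
  the void shape factor `τ = A·d_eq/(4V)` (1.5 for a sphere), porosity,
  mean-intercept-length (MIL) anisotropy, and the fragmentation index
  (ΔA/ΔV under one dilation — lower means better connected);
* **skeleton** — topology-preserving 3D thinning of the void space to a
  centerline spatial graph with per-point local thickness, branch
  counts and total path length per mm³;
* **stats_fitting** — volume-weighted size histograms with normal /
  Weibull maximum-likelihood fits and a parametric-bootstrap
  goodness-of-fit test;
* **phantom** — a synthetic-tissue generator (Voronoi cells of a
  Poisson-disk process; voids as slabs along the cell–cell interfaces,
  calibrated to a target porosity, with tunable fragmentation and
  anisotropy) that provides ground truth for every stage;
* **diffusivity** — the effective oxygen diffusivity model

      D_eff = 1 / ( w/D_par + (1−w)/D_ser ),
      D_par = ε·D_air/τ²,
      D_ser = Maxwell–Eucken(ε; D_cell, D_air),
      D_cell = D_water·R·T·H  (≈ 9.3×10⁻¹¹ m² s⁻¹),

  a weighted series combination of diffusion through the connected pore
  network (parallel porous-medium term, tortuosity τ estimated by the
  void shape factor) and diffusion across cells between disconnected
  pores (Maxwell–Eucken dispersion of voids in a continuous cell
  matrix).  Because air conducts oxygen ~10⁵ times better than cell
  sap, a few percent of serial pathway (w slightly below 1) collapses
  D_eff by orders of magnitude — which is why measured tissue
  diffusivities sit far below classical porous-media predictions.  The
  weighing factor w can be estimated from a measured diffusivity in
  closed form.

## Worked example

Analyze a 1.2 mm³ synthetic tissue phantom (12 % porosity, strongly
fragmented channel network) end to end:

```python
from parenchyma3d.pipeline import run_analyze

summary = run_analyze({
    "input": {"phantom": {"shape_um": (1200, 1200, 1200), "pitch_um": 8.0,
                           "porosity": 0.12, "fragmentation": 0.75, "seed": 11}},
    "voids": {"mil": {"n_directions": 64, "seed": 0}},
})
print(f"porosity             {summary.porosity_fraction:.4f}")
print(f"cell ESD (um)        {summary.cell_panel['esd_um']['mean']:.1f}")
print(f"weighted void count  {summary.weighted_void_count_per_mm3:.1f} /mm3")
print(f"void shape factor    {summary.void_panel['shape_factor']['mean']:.2f}")
print(f"path length          {summary.total_path_length_mm_per_mm3:.1f} mm/mm3")
print(f"anisotropy           {summary.anisotropy:.3f}")
print(f"fragmentation index  {summary.fragmentation_index_per_mm:.1f} /mm")
```

prints (about 45 s on one CPU):

```
porosity             0.1203
cell ESD (um)        229.8
weighted void count  8.8 /mm3
void shape factor    1.65
path length          38.8 mm/mm3
anisotropy           0.056
fragmentation index  27.7 /mm
```

The porosity matches the phantom target to the third decimal; the cell
ESD reflects the ~200 μm Voronoi cells; the shape factor sits above the
spherical limit 1.5 because voids are moulded between cells; anisotropy
is near zero for this isotropic phantom; and 96 % of the void volume
sits in border-crossing components, which is why the edge-corrected
weighted count matters for unbiased void densities.

The same pipeline runs from the shell on a real stack or a phantom:

```bash
parenchyma3d phantom --shape-um 1200 1200 1200 --pitch-um 8 \
    --porosity 0.12 --fragmentation 0.75 --seed 11 --out ph/
parenchyma3d analyze --config config.yaml --out results/
parenchyma3d diffusivity --epsilon 0.254 --tau 2.29 --d-measured 10.1e-9
parenchyma3d report results/summary.json
```

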