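# synecto

Quantitative analysis of **synaptic ectosomes (SE)** — the sub-100 nm
extracellular vesicles that helper T cells bud into the immunological
synapse, carrying TCR, CD40L, ICOS and other effectors to the antigen
presenting cell.

`synecto` implements the full measurement chain used to characterise these
vesicles, and a synthetic-data generator that makes every stage testable
end to end without any experimental data:

| stage | module | what it does |
|---|---|---|
| synthetic data | `synecto.simulate` | ground-truth scenes (cells, vesicles, protein clusters, fiducials), dSTORM localization tables and raw frames, flow-cytometry panels with MESF bead ladders, LFQ proteome tables |
| localization | `synecto.localization` | peak detection, 2-D Gaussian fitting, photon-count filtering (≥ 2000), re-blink merging (within 1 pixel in consecutive frames), Gaussian rendering at the localization precision σ/√N |
| drift & registration | `synecto.registration` | drift from 500-frame sub-stack image correlation; fiducial-based polynomial mapping of the 488 nm channel onto the 640 nm channel |
| vesicle analysis | `synecto.vesicles` | DBSCAN segmentation of the membrane channel (WGA/CD81), FWHM diameter with disk-blur deconvolution, per-vesicle protein positivity classes, per-cell statistics |
| colocalization | `synecto.colocalization` | coordinate-based colocalization (CBC), angular-averaged pair cross-correlation C(r), nearest-neighbor distances, image Pearson correlation |
| quantification | `synecto.quantify` | MESF calibration curves, isotype-corrected percent transfer, SE surface geometry and site densities, cytokine-array fold changes |
| proteome network | `synecto.network` | LFQ fold-change candidate filtering and Markov clustering (MCL) of confidence-scored interaction networks |

## The statistics at the core

**Percent synaptic transfer** of a marker from T cells to bead-supported
lipid bilayers (BSLB), from isotype-corrected geometric mean fluorescence
intensities:

```
% transfer = 100 · GMFI_BSLB / (GMFI_BSLB + GMFI_Tcell)
```

with absolute molecule numbers from a log-log MESF bead calibration.

**CBC** assigns every localization *a* of channel A a parameter in
[−1, +1]: the Spearman rank correlation of the radial neighbor-density
distributions `D_A(r) = N_A(r)/r² · Rmax²/N_A(Rmax)` and `D_B(r)` over
r = 10…50 nm, weighted by `exp(−d_NN(a→B)/Rmax)`. −1 means segregated, 0
uncorrelated, +1 colocalized.

**Pair cross-correlation** `C(r)` is the A–B pair-distance histogram (bins
up to 1000 nm) normalized by its expectation for the same point counts
distributed completely at random in the analysis mask; `C(r) = 1` under
randomness, and a peak at r = d indicates channels co-organized at
separation d.

**Vesicle diameter** is the full width at half maximum of the radially
averaged rendered intensity profile of a segmented cluster, inverted
through the disk ⊛ Gaussian blur model so the reported value estimates the
physical disk diameter.

**SE surface geometry** treats each vesicle as a sphere: n vesicles of
diameter d release `n·π·d²` of membrane, from which CD40L trimer density
and the fraction of T-cell surface follow.

## Worked example

```python
from synecto import quantify as qt

geometry = qt.SEGeometry(diameter_nm=84.0, n_vesicles=37, molecules=510.0)
print(geometry.report())
```

prints

```
{'diameter_nm': 84.0, 'n_vesicles': 37,
 'total_area_um2': 0.8201818772579945, 'molecules': 510.0,
 'trimer_density_per_um2': 207.27110012274167,
 'percent_of_cell_surface': 0.20004436030682793,
 'cell_area_um2_assumed': 410.0}
```

37 vesicles of 84 nm diameter carry 0.82 µm² of membrane — about 0.2 % of
the T-cell surface (for an assumed 410 µm² cell) — and 510 CD40L monomers
on that area correspond to ~207 trimers/µm², a far higher density than the
bulk plasma membrane.

A full simulated microscopy run:

```python
from synecto import simulate as sim, vesicles as ves

scene = sim.generate_scene(sim.SceneParams(double_positive_fraction=0.545), seed=1)
data = sim.simulate_localizations(scene, sim.BlinkModel(),
                                  sim.AcquisitionConfig(n_frames=1000), seed=1)
clusters = ves.segment_vesicles(data.tables["CD81"], eps_nm=50, min_pts=5)
for c in clusters:
    ves.estimate_diameter(c, data.tables["CD81"], channel_label="reference")
ves.assign_channels(clusters, {"TCR": data.tables["TCR"],
                               "CD40L": data.tables["CD40L"]}, 100.0)
print(len(clusters), "vesicles,",
      ves.positivity_fractions(clusters)["double-positive"], "% double positive")
```

There is also a thin CLI (`synecto simulate-locs`, `synecto localize`,
`synecto driftcorrect`, `synecto register`, `synecto vesicles`,
`synecto coloc`, `synecto geometry`, `synecto network`); run
`synecto --help` for details.

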