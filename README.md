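# punctakit

Image-analysis pipeline for TIRF microscopy of IP₃ receptor (IP₃R) puncta
and the Ca²⁺ puffs they produce.  IP₃Rs appear as diffraction-limited
fluorescent puncta at the cell cortex; only a subpopulation — immobile
puncta tethered to cortical actin by KRAP — responds to IP₃ with local Ca²⁺
release.  Quantifying that claim requires a chain of image computations,
each of which this package implements as a tested, reusable module:

* **`spots`** — puncta segmentation by seeded radial growth around local
  intensity maxima, with a radial-profile border threshold, monotone-descent
  region growth and sub-pixel Gaussian-fit localization;
* **`coloc`** — object-based colocalization: nearest-neighbour
  centre-to-centre distances (colocalized if < 160 nm; 130 nm for
  65-nm-pixel super-resolution data), a randomization null that relocates
  the segmented reference objects inside the cell mask (100 iterations,
  add-one permutation p-value, cumulative-distance 95% band), Manders split
  coefficients against Gaussian-filtered (σ = 0.5) filament masks, and
  per-region analysis (peripheral annulus of 15 px = 2.4 µm vs central
  core);
* **`tracking`** — particle linking by gated min-cost assignment
  (1.5 µm s⁻¹ displacement threshold, gap closing), time-averaged MSD,
  anomalous-diffusion fits γ² = 4Dt^α, and mobility classes from α
  (immobile α < 0.1; trajectories ≥ 45 frames), plus 30-s two-colour
  temporal overlays;
* **`frap`** — fluorescence-recovery normalization and mobile fraction
  Mf = (F_plateau − F_post)/(F_pre − F_post) from a single-exponential fit;
* **`puffs`** — ΔF/F₀ and ΔF/F_max movies, transient-event detection by
  smoothing + thresholding + space-time connected components, release-site
  mapping by single-linkage clustering (500 nm), event-to-punctum distances,
  and [Ca²⁺] calibration [Ca²⁺] = K_D(F − F_min)/(F_max − F) with
  K_D = 389 nM for Fluo-8;
* **`synth`** — synthetic microscopy generators with known ground truth for
  every input class (two-channel puncta fields with a controllable
  colocalized fraction, filament textures, mixed mobile/immobile movies,
  FRAP curves, puff movies);
* **`core` / `pipeline` / `cli`** — calibrated TIFF I/O, background
  correction, masks, end-to-end seeded workflows with JSON reports, and a
  `punctakit` command-line interface.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic two-channel cell in which exactly 30% of channel-A
puncta are placed within 80 nm of a channel-B punctum, then run the full
object-based colocalization analysis:

```python
import numpy as np
from punctakit import synth, segment_spots, coloc
from punctakit.core import CellMask

mask = CellMask(np.ones((200, 200), bool), pixel_size_nm=100.0)  # 20x20 um
chan_a, chan_b, truth = synth.make_puncta_field(
    mask, n_a=300, n_b=300, coloc_fraction=0.30, seed=1)

seg_a = segment_spots(chan_a)
seg_b = segment_spots(chan_b)
res = coloc.nearest_neighbour_distances(seg_a, seg_b, criterion_nm=160.0)
null = coloc.randomize_null(seg_a, seg_b, mask, n_iterations=100,
                            criterion_nm=160.0, seed=1)

print(f"A puncta detected:   {res.n_a}")
print(f"B puncta detected:   {res.n_b}")
print(f"observed fraction <160 nm: {res.colocalized_fraction:.3f}")
print(f"true generated fraction:   {truth.colocalized.mean():.3f}")
print(f"null fraction (100 randomizations): {null.mean_fraction:.3f}")
print(f"p-value: {null.p_value:.4f}")
```

Output:

```
A puncta detected:   300
B puncta detected:   300
observed fraction <160 nm: 0.300
true generated fraction:   0.300
null fraction (100 randomizations): 0.065
p-value: 0.0099
```

All 300 spots per channel are recovered; the measured colocalized fraction
equals the generated truth; randomizing the B objects inside the mask
collapses the fraction to the chance level (≈ 1 − exp(−λπr²) for this
density), and the add-one permutation p-value is at its floor 1/101 — the
observed colocalization is far beyond chance.

The same analyses are available from the shell, e.g.:

```sh
punctakit simulate puncta --out-dir demo --n-a 300 --n-b 300 --seed 1
punctakit segment --in demo/channel_a.tif --pixel-size-nm 100 --out demo/pa.csv
punctakit segment --in demo/channel_b.tif --pixel-size-nm 100 --out demo/pb.csv
punctakit coloc --a demo/pa.csv --b demo/pb.csv --mask demo/mask.tif \
    --pixel-size-nm 100 --criterion-nm 160 --seed 1 --out demo/coloc.json
```

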