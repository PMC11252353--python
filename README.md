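# fpolcyto

Automated fluorescence-polarization (Fpol) cytology analysis.

Methylene blue (MB) is a cationic cytological stain whose fluorescence
polarization is elevated in malignant cells, which makes MB Fpol a
quantitative marker for cancer detection in fine-needle-aspiration (FNA)
cytology — for example for thyroid nodules that conventional cytopathology
leaves indeterminate. The measurement images each field twice, with
emission detected parallel (`I_co`) and perpendicular (`I_cross`) to the
excitation polarization, and scores each cell by

```
Fpol = (I_co − G · I_cross) / (I_co + G · I_cross)
```

where `G` (0.75 here) is the instrument calibration factor that corrects
the polarization bias of the detection path. Doing this manually — an
expert outlining every diagnostically relevant cell — takes about an hour
per sample; this package automates it end to end:

1. **phantom** — synthetic co/cross image pairs with known per-cell Fpol,
   cell clusters, out-of-focus ("ambiguous") cells and 8-bit quantization,
   so every downstream stage is testable without clinical images;
2. **segnet** — a U-Net-style encoder-decoder (five resolution levels,
   skip connections, implemented in NumPy with seeded training, online
   augmentation, Adam, per-pixel cross-entropy) classifying each pixel as
   background / ambiguous signal / high-quality cell;
3. **postproc** — binarization of the high-quality probability map at 0.5,
   then dilation (3×3, 3 iterations), the mirroring erosion, a 15×15
   elliptical opening, and connected-component labeling of the cells;
4. **quant** — per-cell Fpol and area (µm²) from channel means over valid
   pixels (counts in [3, 254]; saturated and background pixels excluded);
5. **compare** — one-to-one matching of automated (AU) against manual (MA)
   cells by pixel overlap, symmetric percent differences
   `ΔFpol = 100 (Fpol_AU − Fpol_MA) / ((Fpol_AU + Fpol_MA)/2)` (likewise
   for areas), and the AU-over-MA selection excess;
6. **stats** — per-diagnosis-group means ± SD and two-tailed Student
   t-tests with Bonferroni correction at α = 0.01.

The intended users are biomedical-optics and quantitative-pathology groups
who need a reproducible, auditable Fpol pipeline rather than per-study
manual tracing.

## Worked example

Generate a small synthetic cohort, train a desk-scale model, and run the
whole pipeline:

```
fpolcyto phantom --out data --n-samples 3 --image-size 128 --n-cells 5 --seed 7
fpolcyto train --manifest data/manifest.csv --out model.npz --epochs 15 --seed 1
fpolcyto run --manifest data/manifest.csv --model model.npz --out results --seed 0
```

Or per stage, from Python:

```python
from fpolcyto import (PhantomSpec, generate_sample, quantify_sample,
                      pct_diff, selection_excess)

sample = generate_sample(PhantomSpec(image_size=256, n_cells=3,
                                     fpol_targets=(0.30, 0.15, 0.25),
                                     cluster_fraction=0, ambiguous_fraction=0,
                                     noise_sd=0, seed=6,
                                     cell_radius_range=(6, 12)))
for cell in quantify_sample(sample.pair, sample.truth_label_mask()):
    print(cell.cell_id, round(cell.fpol, 4), round(cell.area_um2, 1))
```

prints

```
1 0.2999 8.2
2 0.15 8.7
3 0.2503 13.1
```

— the quantification recovers each cell's specified Fpol (0.30, 0.15,
0.25) to within the 8-bit quantization bound of 0.01, alongside the cell
areas in µm² at the default 0.205 µm pixel pitch. On an analysis of a real
cohort the same per-cell records feed the AU-vs-MA comparison
(`pct_diff`, `selection_excess`, `match_cells`) and the grouped
malignant/benign/normal t-tests.

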