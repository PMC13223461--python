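# pallorscan

Non-invasive anemia screening from conjunctival pallor.

Anemia — low blood hemoglobin (Hb) — is conventionally diagnosed by an
invasive complete blood count. Pallor of the palpebral conjunctiva (the
vascular membrane lining the inner eyelid) is one of the most reliable
physical signs of anemia and is largely independent of skin tone, which makes
the conjunctiva a natural target for camera-based screening in settings where
laboratory testing is scarce. `pallorscan` implements that screening pipeline
as a tested Python library and CLI for researchers working on image-based
hematology screening:

1. **ROI detection** — a color-prior baseline detector boxes the reddish
   conjunctiva region (any external detector can substitute via bounding-box
   or mask files).
2. **Segmentation** — K-means clustering (Lloyd's algorithm, k = 3) of the
   ROI pixels in the CIELAB *a\*b\** chroma plane; the cluster with the
   largest centroid *a\** (the reddest) is kept as the conjunctiva mask.
   Externally produced binary masks (e.g. from a promptable segmentation
   model) can be ingested instead.
3. **Features** — seven scalars per segmented region: mean grayscale
   intensity μ = Σᵢ Iᵢ / N with I = (R+G+B)/3, the red/green channel ratio
   mean(R)/mean(G) and difference mean(R) − mean(G), the population standard
   deviation σ of intensity, the Shannon entropy H = −Σ pᵢ log₂ pᵢ of the
   256-bin intensity histogram, the high-hue ratio HHR (fraction of pixels
   with HSI hue ≥ 300°, the red–magenta band), and the red pixel percentage
   RPP (fraction of pixels whose red channel dominates both others by a
   margin δ).
4. **Classification** — a single-hidden-layer MLP (25 ReLU units, softmax
   output) on z-scored features, three classes graded from the Hb gold
   standard: anemic (Hb < 10.5 g/dL, both sexes), moderately anemic
   (10.5–13.5 g/dL male, 10.5–12 g/dL female), normal (above). Evaluation
   uses a stratified 90/10 split and co-reports resubstitution and held-out
   confusion matrices, accuracy, precision/PPV, sensitivity, specificity, F1,
   FDR and one-vs-rest AUC.
5. **Prevalence mapping** — geotagged screening records are aggregated on an
   equal-degree grid and high-prevalence cells flagged, exported as GeoJSON.

Because clinical eye images cannot be redistributed, the package ships a
**synthetic eye-image generator** that renders labeled scenes (skin, sclera,
conjunctiva crescent whose color encodes the class, plus noise and
illumination gradient) together with exact ground-truth masks and Hb values
consistent with the grading table. Every pipeline stage is tested end-to-end
against this generator, including six-condition white-balance augmentation
(tungsten, cloudy, daylight, flash, fluorescent, shade) that grows a
611-image dataset to 3,666 records.

## Worked example

```python
import pallorscan as ps
from pallorscan.synth import SyntheticSpec, render_eye_image

spec = SyntheticSpec()
img, truth = render_eye_image("anemic", spec, seed=42)   # 256x256 RGB + mask

mask, box = ps.segment_conjunctiva(img, k=3, seed=0)
fv = ps.extract_feature_vector(img, mask)
print(box, mask.sum())
print(fv.red_pixel_pct, fv.high_hue_ratio, fv.mean_rg_diff)
```

prints

```
BoundingBox(x_min=38, y_min=142, x_max=225, y_max=211) 5013
0.4133 0.7249 76.1871
```

The detector boxed the lower-lid crescent, K-means kept a 5,013-pixel mask
(99.6 % of the ground-truth conjunctiva), and the features show the anemic
signature: only 41 % of pixels are saturated vascular red (a normal-class
render scores ≈ 100 %) and the red–green separation is 76 intensity levels
(normal ≈ 130). The same pipeline from the shell:

```sh
pallorscan simulate --n-anemic 132 --n-moderate 169 --n-normal 310 --seed 1 --out data/
pallorscan features --manifest data/manifest.csv --out features.csv
pallorscan evaluate --features features.csv --seed 1 --out report.json
pallorscan train    --features features.csv --seed 1 --out model.joblib
pallorscan predict  --model model.joblib --image data/images/S0000.png
pallorscan map      --records screenings.csv --cell-size 0.5 --out prevalence.geojson
```

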