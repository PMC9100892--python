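# rootball

Non-destructive surface-root phenotyping of plug-seedling root balls from
multi-view color+depth (RGBD) images.

Root phenotypes — total-root diameter, surface area, length, volume — are
key selection criteria for vegetable rootstocks (e.g. pumpkin under grafted
watermelon or cucumber), but the standard workflow destroys the seedling:
the root system is washed free of substrate and measured on a flatbed
scanner. For a plug seedling, however, a useful fraction of the root system
is visible on the *surface* of the root ball, and surface-root traits
correlate strongly with whole-root traits. `rootball` implements an imaging
pipeline that measures the surface roots in situ and predicts the total-root
phenotypes from them:

1. **Stitching.** Four RGBD views (plant rotated 90° between shots) are
   registered against a high-texture fiducial curtain behind the plant:
   Harris corners → adaptive non-maximal suppression → normalized patch
   descriptors → ratio-test matching → RANSAC homography, then feathered
   compositing (depth is composited first-valid, never blended).
2. **Preprocessing.** Gain/gamma enhancement; edge-based background removal
   (Sobel → morphological consolidation → largest-component filter);
   homomorphic filtering to suppress uneven illumination while keeping fine
   roots.
3. **Segmentation.** Multi-scale Hessian vesselness. With eigenvalues
   |λ₁| ≤ |λ₂| of the σ²-normalized Hessian at scale σ, the tubularity
   response is

       V = 0                                   if λ₂ > 0
       V = exp(−R_B²/2β²)·(1 − exp(−S²/2c²))   otherwise,

   R_B = |λ₁|/|λ₂|, S = √(λ₁²+λ₂²), maximized over a geometric scale
   ladder; Otsu thresholding inside the root-ball mask yields the root mask.
4. **Phenotyping.** Depth calibration gives the physical pixel scale
   (S_pix = S_ROI/ΣPix, L_pix = √S_pix). Non-overlapping roots are isolated
   morphologically (erosion destroys them; dilation cannot restore them),
   their skeleton length is L = N_skel · 1.2 · L_pix, and the average
   total-root diameter is ADTR ≈ SASR_NO / L. Encapsulation is
   DSR = ΣPix_root/ΣPix_ball · 100%. Total-root quantities follow from
   published allometric models:

       SATR = 2.16556·SASR + 7.6522      [cm²]
       LTR  = SATR_pred / ADTR,  LTRP = 2.9723·LTR + 16.83062   [cm]
       VTR  = π·(ADTR/2)²·LTRP           [cm³]

A fully synthetic scene generator (fiducial curtain, speckled substrate,
anti-aliased tubular roots with analytic ground truth, cylinder depth model,
overlapping views) makes every stage testable without a camera.

## Worked example

`python examples/01_simulate_and_measure.py` simulates a plant (12 roots,
400–900 μm, four noisy views), runs the whole chain and prints:

```
ADTR  (avg diameter of total root):   539.8 um   (true 610.8 um)
SASR  (surface-root area)         :   0.966 cm2  (true 0.782 cm2)
DSR   (encapsulation)             :    6.60 %
SATRP (predicted total-root area) :   9.744 cm2
LTRP  (predicted total-root length):  553.4 cm
VTR   (predicted total-root volume): 1.2664 cm3
```

ADTR and SASR are measured from the stitched image (here within the method's
characteristic accuracy — the area-to-length diameter estimate carries a
skeleton-length bias discussed in `docs/methods.md`); SATRP/LTRP/VTR are
model predictions for quantities only a destructive measurement could
verify. The other examples demonstrate the vesselness segmenter and
refitting the allometric models.

## Command line

```
rootball simulate --seed 1 --n-roots 12 --out scene/
rootball pipeline --simulate --seed 1 --out run/
rootball pipeline --input scene/ --out run/        # measure saved frames
rootball validate --report run/plant_report.json --truth run/truth_summary.json
```

Subcommands `stitch`, `preprocess`, `segment`, `measure` expose the
individual stages; parameters come from a YAML config (`--config`), and exit
codes are 0 (ok), 2 (bad input), 3 (stage failure).

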