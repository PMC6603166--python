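# histostyle

Virtual H&E staining of confocal laser endomicroscopy (CLE) images by
Gram-matrix style transfer, plus the dual-axis rater-score statistics used to
evaluate such transformations.

## The problem

Fluorescein-sodium CLE lets a neurosurgeon image brain-tumor tissue *in vivo*
at cellular resolution, but the frames are grayscale and frequently occluded
by artifacts (motion blur, background noise, red blood cells), while
neuropathologists are trained on pink-and-purple hematoxylin & eosin (H&E)
slides. Paired CLE/H&E training data cannot be collected — the same tissue
location cannot be imaged by both modalities — so supervised translation is
out. Style transfer needs only **one** image of each modality: it keeps the
CLE frame's structures (content) while adopting the H&E micrograph's texture
and palette (style).

## The method

A fixed convolutional feature extractor maps an image to named-layer
activations F^l. Content is the activation tensor at one deep layer
(`Conv4_2`); style is the list of Gram matrices

    G^l_ij = Σ_p F^l_i(p) · F^l_j(p)

at five layers (`ReLU1_1` … `ReLU5_1`) — a spatial-position-invariant texture
statistic. Starting from a copy of the content image, the **target image's
pixels** are optimized by L-BFGS (network weights frozen, pixels
box-constrained to [0, 1]) to minimize

    L = D_c(C_CLE, C_Target) + α · Σ_i w^i · D_s(S_H&E^i, S_Target^i)

with α = 100 and w^i = 0.2. By default D_c is the per-element mean squared
content distance and D_s = ‖ΔG‖² / (4 C² M²); see `docs/methods.md` for the
normalization rationale and alternates. The production budget is 1,600
L-BFGS iterations per image.

Downstream, stylized images are presented for blinded rating in four color
groups (gray, green-coded, red-coded, intact), and `histostyle.rater_stats`
reproduces the full evaluation battery for 0–6 dual-axis scores (added
structures / removed artifacts): per-axis histograms, the 7×7 intensity map
and its modal cell, one-way chi-square, the paired t-test, and per-image
improvement categories (mean > 3 improved, < 3 degraded, = 3 neutral).

Two feature extractors share one layer registry: a VGG-19 loaded from a
user-supplied `.npz` weights file (production), and a small seeded random
extractor (`build_test_backbone`) so the entire pipeline runs and is tested
without any download.

## Worked example

```python
from histostyle import (
    CLESynthParams, RatingSynthParams, TransferConfig,
    build_test_backbone, make_cle_image, make_he_style_image, stylize,
    make_rating_table, intensity_map, modal_combination, categorize_images,
    paired_t_test,
)

backbone = build_test_backbone(seed=0)
content, _ = make_cle_image(CLESynthParams(size=64, seed=0))
style, _ = make_he_style_image(size=64, seed=1)
target, trace = stylize(content, style, backbone, TransferConfig(n_iterations=50))
print(f"initial loss {trace.total[0]:.4f}, final loss {trace.total[-1]:.4f}")

records, _ = make_rating_table(RatingSynthParams(seed=0))
m = modal_combination(intensity_map(records))
print("modal score cell:", (m.added, m.removed))
print("improved on both axes:",
      categorize_images(records).counts["improved_both"], "of 100")
added = [r.added_score for r in records]
removed = [r.removed_score for r in records]
t, df, p, gap = paired_t_test(added, removed)
print(f"paired t: t={t:.2f}, df={df}, p={p:.2e}")
```

prints

```
initial loss 1.7943, final loss 0.2221
modal score cell: (5, 4)
improved on both axes: 84 of 100
paired t: t=7.93, df=499, p=1.41e-14
```

The loss falls 8-fold in 50 iterations (content term starts at exactly 0
under content-copy initialization and rises as style is traded in). The
synthetic rating table plants a modal score cell of (5, 4) — "moderately
adding structures, slightly removing artifacts" — and 84 of 100 images
improved on both axes; the analysis recovers both, and the paired t-test
detects that added-structure scores exceed removed-artifact scores.

## Command line

```sh
histostyle synth cle --n 10 --seed 0 --out cle/          # pseudo-CLE frames
histostyle synth he --seed 0 --out style.png             # pseudo-H&E style
histostyle stylize --content cle/ --style style.png --iterations 1600 --out out/
histostyle colorize --in out/ --mode assign --seed 0 --out coded/
histostyle synth ratings --seed 0 --out scores.csv
histostyle evaluate --scores scores.csv --out report/
histostyle run-all --n-images 4 --iterations 20 --out run/   # end-to-end
```

Exit codes: 0 success, 1 usage, 2 data validation, 3 numeric failure.

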