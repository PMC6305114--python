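# lesionvario

Geostatistical analysis of binary white-matter-lesion masks for longitudinal
multiple-sclerosis cohorts.

MS lesion burden is usually summarised by the total lesion volume (TLV),
which correlates poorly with disability and says nothing about *shape*:
whether a pattern consists of a few smooth, extended lesions or of many
small, complexly shaped aggregates, and how that morphology evolves over
repeated MRIs. `lesionvario` quantifies exactly that, for anyone working
with binary lesion masks in a common brain space (e.g. LST/LGA output in
MNI): neuroimaging researchers studying lesion evolution, and
methodologists who want a reproducible, fully seeded reference
implementation of indicator variography on voxel masks.

## Method

For the indicator field z (lesion voxels = 1) the empirical variogram along
an axis-aligned lag h (mm) is

    γ(h) = 1/(2 n(h)) · Σᵢ (z(xᵢ) − z(xᵢ+h))²,

computed separately along x (left–right), y (posterior–anterior) and z
(inferior–superior). Each directional variogram is fitted with the
exponential model

    γ(h) = c · (1 − e^(−3|h|/a)),

giving a range `a` (mm) — the spatial-correlation scale, a proxy of pattern
surface smoothness — and a sill `c`, which for a binary field approximates
the indicator variance p(1−p) and hence tracks TLV. A mask is then mapped
to a single point in the **lesion discrimination plot (LDP)**:

    A = ⅓(ln aₓ + ln a_y + ln a_z),   C = ⅓(ln cₓ + ln c_y + ln c_z).

Smooth patterns plot at high A, fragmented ones at low A; longitudinal
series become evolution paths whose vectors point up-right under
growth/confluence and down-left under shrinkage/breakup. On top of the
descriptors the package provides per-gender 2-component Gaussian-mixture
subgrouping of baseline (A, C), box-whisker/Kruskal–Wallis/Mann–Whitney
longitudinal summaries, and a linear mixed model (random intercept + slope
per subject, REML) estimating the gender offset at the centred timepoint.

A synthetic cohort generator (ellipsoid-union patterns with
morphological grow/confluence/shrink/breakup dynamics and correlated EDSS
trajectories) makes the whole pipeline testable without any imaging data.
See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Contrast a "smooth" pattern (5 extended blobs) with a "complex" one
(150 small blobs) of similar lesion volume:

```python
import lesionvario as lv

smooth = lv.generate_pattern(
    lv.PatternSpec(n_blobs=5, radius_mean=4.5, radius_sd=0.8,
                   anisotropy=(1.2, 1.3), seed=5))
complex_ = lv.generate_pattern(
    lv.PatternSpec(n_blobs=150, radius_mean=1.3, radius_sd=0.5,
                   anisotropy=(1.2, 1.3), seed=5))

for name, mask in [("smooth", smooth), ("complex", complex_)]:
    d = lv.describe_pattern(mask)
    print(f"{name:8s} TLV {d.tlv_cm3:.2f} cm³  A {d.A:.2f}  C {d.C:.2f}")
```

prints

```
smooth   TLV 3.15 cm³  A 3.25  C -4.00
complex  TLV 2.92 cm³  A 1.81  C -4.37
```

Nearly equal lesion volumes, but the smooth pattern's longer correlation
ranges (a ≈ 17–34 mm vs ≈ 5–7 mm per axis) put it 1.4 log-units higher in
A — the separation the LDP is built to expose. The fits behind these
numbers carry r² ≈ 0.96–1.00 per axis (kept in `d.a_mm`, `d.c`, `d.r2` for
audit).

A full cohort analysis — simulate (or load NIfTI masks + metadata CSV),
describe, subgroup, vectors, longitudinal stats, plots, manifest — is one
call or one command:

```bash
lesionvario run --seed 7 --out results/run1
```

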