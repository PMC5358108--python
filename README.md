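# lamina

Quantification of laminar organisation in re-aggregated retinal
organoid sections by isocontour fluorescence profiling.

## The problem

Dissociated retinal progenitors re-aggregated in culture can
self-organise into concentric layers that mirror retinal lamination:
in a three-reporter ("spectrum of fates") line, CFP-positive
bipolar/photoreceptor cells (Crx reporter) gather at the aggregate
centre, GFP-positive amacrine/horizontal cells (Ptf1a reporter) form a
ring around them, and RFP (Atoh7 reporter) is broadly distributed.
Judging such organisation by eye does not scale and cannot be compared
across conditions.  `lamina` turns a single multichannel confocal
section into a scalar lamination score:

1. **Segmentation** — the aggregate footprint is found on the DAPI
   channel by a Chan-Vese active contour plus morphological clean-up,
   or supplied as a manual mask.
2. **Profiling** — mean intensity of each channel in concentric bands
   (default width w = 5 px) along isocontours of the Euclidean
   distance from the aggregate outline (robust to non-circular
   shapes; centroid-based crowns are also available).
3. **Normalisation & ECDF** — each profile is rescaled to a 0–100
   radial-unit (ru) axis and normalised to unit integral; its
   cumulative curve F(x) is compared with the diagonal that a
   spatially uniform signal would give.
4. **Score** — trapezoidal areas beneath the curves:

       score = ∫₀¹⁰⁰ F_CFP dx − ∫₀¹⁰⁰ F_GFP dx   (ru)

   Positive scores mean CFP sits more centrally than GFP, i.e. the
   aggregate is laminated in the expected order; ~0 means the two
   markers are distributed alike.
5. **Statistics** — cohort-average profiles with an error band, and
   two-tailed Mann-Whitney U comparison of scores between conditions
   (exact for small tie-free samples, normal approximation with tie
   correction otherwise).

A seeded synthetic-image generator (`lamina.synthetic`) produces
aggregates with known ground-truth organisation — the `organization`
parameter λ interpolates between radially zoned (λ = 1) and random
(λ = 0) cell placement — so the whole pipeline is testable without
microscope data.

## Worked example

Simulate three laminated aggregates and run the full pipeline:

```sh
lamina simulate --out sim --n 3 --seed 7
lamina run sim/aggregate_000.tif sim/aggregate_001.tif sim/aggregate_002.tif --out res
```

which prints

```
group a: n=3 mean score 27.78 ru
```

and writes, per aggregate, the mask, band profile, normalised profile,
ECDF samples and a score file (`res/aggregate_000_score.json`):

```json
{
  "area_cfp": 63.46875109769836,
  "area_gfp": 37.45643744247932,
  "area_rfp": 48.33045919798331,
  "deviation_cfp": 13.468751097698359,
  "deviation_gfp": -12.54356255752068,
  "deviation_rfp": -1.6695408020166909,
  "mask_provenance": "auto",
  "mode": "periphery",
  "band_width": 5.0,
  "score": 26.01231365521904
}
```

Read: the CFP ECDF lies well left of the diagonal (area 63.5 ru vs the
uniform 50), GFP lies right of it (37.5 ru), RFP is nearly uniform
(48.3 ru) — the aggregate is laminated with CFP inside GFP, score
≈ 26 ru.  A disorganised aggregate scores near 0.

The same stages are available as library calls
(`segment_aggregate`, `radial_profile`, `normalize_profile`, `ecdf`,
`lamination_score`, `average_profiles`, `mann_whitney`) and as the CLI
verbs `simulate`, `segment`, `profile`, `score`, `average`, `compare`
and `run` (`lamina run a/*.tif --group-b b/*.tif` adds the group
comparison).

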