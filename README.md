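# sisterres

Quantitation of **sister chromatid resolution** — how far the two
identical DNA copies of a replicated chromosome have separated into
distinct territories before mitosis — from fluorescence microscopy and
from sister-chromatid-sensitive Hi-C (scsHi-C) contacts.

The package is aimed at chromosome-biology labs that label one sister
chromatid per chromosome (e.g. with F-ara-EdU after one labelled S phase
plus one unlabelled cycle) and/or phase Hi-C contacts as *cis*
(same chromatid) vs *trans* (between sisters). It provides:

- **separation score** — per cell, the mean Spearman correlation ρ
  between the DNA stain and the single-sister label over Otsu chromatin
  masks of 11 central z-slices, normalized so that

      score = (ρ̄₂ − ρ̄) / (ρ̄₂ − ρ̄₁)

  where ρ̄₂ and ρ̄₁ are the mean correlations of two-sister-labelled
  (score 0) and one-sister-labelled prometaphase (score 1) reference
  cells;
- **line profiles** — peak analysis of 5-pixel-wide lines drawn across
  SMC (cohesin/condensin) axes: min/max normalization, the
  DNA-minus-label subtraction that isolates the unlabelled sister, peak
  classification, sister peak-to-peak distance, signed radial
  displacement, axis-aligned mean curves, and per-cell percentage
  summaries;
- **intensity quantification** — central-slice masked means per cell
  (Li/Otsu) and watershed nuclear segmentation of fields, with affine
  background/control normalization;
- **genomic resolution score** — from phased contacts: log-binned
  cis/trans contact-probability curves, their ratio R(s), cubic-spline
  interpolation + Savitzky–Golay smoothing, and the first genomic
  distance where R(s) reaches the threshold 1.25:

      resolution = min { s : R_smooth(s) ≤ 1.25 }   (scanning short → long)

- **synthetic generators** with exact ground truth: 3D two-tube
  chromatid image phantoms (controlled separation, PSF, Poisson noise)
  and contact tables with R(s) = 1 + (R0−1)·e^(−s/λ), whose crossover
  s* = λ·ln((R0−1)/(t−1)) is closed-form.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```sh
sisterres demo --out demo_out --seed 1
```

prints (numbers from that exact run):

```
sisterres 0.1.0 demo (seed=1)

imaging workflow (phantoms):
  reference mean SCC: two-sister 0.8566, one-sister -0.3031
  separation score at 300 nm (n=4): 0.476

contact workflow (simulated scsHi-C):
  true resolution: 6.931 Mb
  recovered: 7.179 Mb (resolved)
```

Reading this: the two reference phantom populations (both sisters
labelled at separation 0; one sister labelled at 600 nm) anchor the
score scale at 0 and 1, so a one-sister population at 300 nm separation
scoring ≈ 0.48 sits, as it should, halfway along the resolution axis.
On the contact side, a simulated table whose true cis/trans ratio decays
with λ = 5 Mb from a plateau of 2 has a closed-form 1.25-crossing at
5·ln 4 ≈ 6.93 Mb; the full binning + spline + smoothing pipeline
recovers 7.18 Mb from 2·10⁵ contacts.

Individual steps are available as subcommands
(`simulate-images`, `simulate-contacts`, `separation-score`,
`line-profiles`, `intensity`, `genomic-resolution`); every command
writes a config echo (parameters, version, seed) beside its outputs.

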