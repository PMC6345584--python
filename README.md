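# fluorokit

Quantitative analysis of fluorescence-microscopy experiments around membrane
receptor trafficking, written for cell biologists who image receptors (such as
EGFR) in keratinocytes and need the downstream numbers: how many vesicles, how
colocalized two channels are, how fast a bleached membrane pool recovers, how
fast cells migrate, how tightly two proteins bind, and how much FRET a
donor–acceptor pair shows.

Every analysis is paired with a seeded synthetic-data generator that records
its ground truth, so the whole pipeline is testable end to end without any
external data.

## What it computes

**Vesicle detection** (`fluorokit.spotdetect`). Diffraction-limited vesicles
are detected by the undecimated à trous wavelet transform with the B3-spline
kernel [1, 4, 6, 4, 1]/16. Detail planes d_j are hard-thresholded at
k·MAD/0.6745 per plane; the support is the positive product of the retained
mid-scale planes; touching spots are split by watershed; per-vesicle area,
centroid and intensity are measured on the raw image.

**Colocalization** (`fluorokit.coloc`). Pearson's r over paired pixels in a
cell ROI or a 10-px-wide leading-edge band; the asymmetric overlap fraction
|A ∩ B| / |A| of vesicle pixels; surface/total receptor levels via a
membrane-band mask normalized to control cells; FACS background subtraction
against a secondary-antibody-only sample.

**FRAP kinetics** (`fluorokit.frapfit`). Traces are corrected for whole-image
photofading, normalized to the prebleach mean (first three frames), and fitted
to F(t) = plateau − (plateau − floor)·e^(−kt), giving T½ = ln 2 / k and the
percentage mobile fraction 100·(plateau − floor)/(1 − floor).

**Migration speed** (`fluorokit.motility`). Mean speed = path length / elapsed
time per cell from tracked (x, y) coordinates at 10-minute frame intervals;
condition summaries are means of per-cell means with SEM.

**Binding affinity** (`fluorokit.bindfit`). Thermophoresis titrations at a
fixed 50 nM labeled target T are fitted with the depletion-corrected
single-site mass-action model,

    f(L) = [(Kd + L + T) − sqrt((Kd + L + T)² − 4LT)] / (2T),

response = unbound + (bound − unbound)·f(L). Fluorescence lifetimes come from
a Poisson maximum-likelihood mono-exponential tail fit, and FRET efficiency is
E = 1 − τ_DA / τ_D.

**Pipeline** (`fluorokit.pipeline`, `fluorokit.cli`). YAML-configured
end-to-end runs with a per-output checksum manifest; identical config and seed
reproduce byte-identical outputs.

## Worked example

```sh
$ fluorokit simulate frap --seed 42 --out demo   # k = ln2/30, 75% mobile, noise 0.02
$ fluorokit frap fit --trace demo/trace.csv
FRAP mono-exponential recovery fit
  n post-bleach points : 36
  rate k               : 0.0239105 /s
  T1/2                 : 28.9892 s
  plateau              : 0.802713
  floor                : 0.182615
  mobile fraction      : 75.86 %
  residual RMS         : 0.0175
```

The generator's truth (`demo/frap_truth.json`) has k = 0.0231 s⁻¹ (T½ = 30 s)
and a 75% mobile fraction; with realistic acquisition noise the fit recovers
the half-time within ~3% and the mobile fraction within one percentage point.

```sh
$ fluorokit simulate titration --seed 42 --out demo   # true Kd = 250 nM
$ fluorokit binding fit-kd --csv demo/titration.csv
Single-site mass-action Kd fit
  Kd               : 2.577e-07 mol/L (257.7 nM)
  unbound response : -0.000893589
  bound response   : 1.00412
  residual RMS     : 0.0082

$ fluorokit binding fret --tau-d 2.5 --tau-da 2.0
{"tau_donor": 2.5, "tau_da": 2.0, "efficiency": 0.19999999999999996, "negative": false}
```

A 2.5 ns donor shortened to 2.0 ns in the presence of acceptor corresponds to
20% FRET efficiency.

The same workflows are available from Python; see the docstrings of
`detect_vesicles`, `pearson_coloc`, `fit_recovery`, `fit_kd`, `fit_lifetime`
and `track_speed`, and `docs/methods.md` for the models and their assumptions.

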