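# ceusdro

A digital reference object (virtual phantom) and time-intensity-curve (TIC)
analysis tool for **contrast-enhanced ultrasound (CEUS) perfusion
quantification**, with sensitivity experiments that identify the acquisition
settings — receive gain, log-compression dynamic range, transmit frequency —
minimising quantification error.

## Who this is for

Quantitative CEUS turns the grey-level enhancement of a microbubble contrast
bolus into perfusion biomarkers: **MTT** (mean transit time, operationally the
full width at half maximum of the enhancement peak), **AUC** (area under the
baseline-subtracted curve up to the end of washout), **MI** (maximum
intensity above baseline) and **TTP** (time to peak).  These numbers depend
not only on physiology but on scanner settings.  `ceusdro` lets imaging
scientists measure that dependence on synthetic acquisitions whose truth is
known exactly, and provides the same analysis chain for real exported video.

## The model

Bolus kinetics follow the local density random walk (LDRW) indicator-dilution
model,

```
C(t) = (m/Q) e^λ sqrt(λ / (2π μ t)) exp(−(λ/2)(t/μ + μ/t))
```

with injected mass `m`, flow `Q`, mean arrival time `μ` (s) and diffusion
shape parameter `λ`; the peak sits at `t* = μ(−1 + sqrt(1 + 4λ²))/(2λ)`.
The measurement chain models the scanner: echo amplitude with
frequency-dependent attenuation and focus weighting, receive gain
`V → V·10^{g/20}`, log-compression of a `LC_DR`-dB amplitude window onto
8-bit grey levels,

```
QL(V) = clip₀²⁵⁵ round( 255 (20/LC_DR) log₁₀( (V/V_max) 10^{LC_DR/20} ) ),
EP(QL) = ( V_max 10^{(QL/255 − 1) LC_DR/20} )²,
```

and the linearisation `EP` back to echo power, so that analysed intensity is
proportional to contrast concentration.  The phantom renders a bolus through
a vessel with a parabolic (Poiseuille) flow profile into 8-bit frames
(default 200 frames of 512×512 px) with Gaussian noise, and reports the
perfusion parameters it imposed — ground truth independent of the
acquisition settings.

## Worked example

`python examples/simulate_and_analyze.py` synthesizes a small phantom at
gain 15 dB / dynamic range 60 dB / 1.5 MHz, analyses a vessel ROI and prints:

```
phantom: 50 frames of 64x64 px, ROI 104 px
parameter        truth    measured   error %
MTT            42.6493     42.6709     0.050
AUC             0.9195      0.9117    -0.842
MI              0.0200      0.0198    -0.887
TTP            23.4233     23.4410     0.076
(MTT/TTP in seconds; AUC/MI in normalized echo-power units)
```

Sub-percent errors mean the compression/linearisation chain is nearly
transparent at these settings.  The other examples show LDRW curve fitting
(`fit_bolus_curve.py`), the dynamic-range sensitivity sweep
(`dynamic_range_sweep.py` — at 30 dB the washout tail clips and the AUC error
jumps to ~5%), and Pearson/Bland-Altman comparison of two analysis
conventions (`method_agreement.py`).

A thin CLI wraps the same API:

```sh
ceusdro simulate --out phantom.tif --scale medium --seed 1
ceusdro analyze --stack phantom.tif --roi roi.png --out result.json
ceusdro sweep --config sweep.yaml --out errors.csv
ceusdro compare --a a.csv --b b.csv --out agreement.json
```

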