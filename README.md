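# cerecoh

Analysis toolkit for **cerebello–prefrontal interaction electrophysiology**:
state-segmented LFP spectra and coherence, frequency-domain directed
coherence, stimulus-evoked field-potential metrics, permutation-based
single-unit response classification, shuffle-corrected spike correlograms,
and spike-cluster quality gating — together with a synthetic-data generator
that emulates this kind of recording so that every stage can be verified
against known ground truth.

It is written for systems neurophysiologists who record paired field
potentials (e.g. cerebellar fastigial nucleus, FN, and prelimbic cortex,
PrL), stimulate one site while recording units at the other, and need the
full analysis chain from raw traces and spike times to statistics.

## The science in brief

**Coherence and its theta ratio.** Multitaper spectra use 2-s windows with
half-bandwidth W = 1 Hz, hence NW = 2 and K = 2NW − 1 = 3 Slepian tapers.
Magnitude coherence between channels x and y is

&nbsp;&nbsp;&nbsp;&nbsp;C(f) = |S̄ₓᵧ(f)| / √(S̄ₓₓ(f) S̄ᵧᵧ(f)),

averaged over window×taper estimates pooled within a behavioral state, with
leave-one-window-out jackknife error bars (arctanh-stabilized) and the
analytic null level √(1 − α^{1/(n−1)}) at α = 0.05. Band specificity is
summarized by the **theta ratio**: mean coherence in 5–10 Hz divided by
mean coherence at all other frequencies up to 45 Hz.

**Directed coherence.** A bivariate AR model (order by AIC, signals
decimated to 200 Hz) gives the transfer matrix
H(f) = (I − Σₖ Aₖ e^{−i2πfk/fs})⁻¹ and the noise-weighted, row-normalized
directed transfer function

&nbsp;&nbsp;&nbsp;&nbsp;θᵢⱼ(f) = σⱼ |Hᵢⱼ(f)| / √(Σₖ σₖ² |Hᵢₖ(f)|²) ∈ [0, 1],

with per-frequency significance from surrogate pairings of
non-simultaneous windows. Zero-lag covariance is reported separately so
volume conduction cannot masquerade as directionality.

**Units.** PSTHs cover −2 to +5 s around each 1-s, 100-Hz stimulus train in
100-ms bins with bootstrapped errors; per-bin significance combines a
≥10,000-permutation rotation test (statistic: deviation from pre-stimulus
baseline) with the bootstrap-interval criterion; ≥2 consecutive significant
bins define a response phase, classifying units as increase / decrease /
biphasic / none. Correlograms (40-ms bins, ±1 s) are shuffle-corrected
across trials and normalized by spike count. Sorted clusters enter analysis
only with isolation distance > 15 and L-ratio < 0.35.

## Worked example

```python
import numpy as np
from cerecoh import simulate as sim, spectral, directed
from cerecoh.config import AnalysisConfig
from cerecoh.core import EpochSet

cfg = AnalysisConfig()
x, y, truth = sim.gen_coupled_lfp(sim.CoupledLFPParams(duration=60, seed=11))
eps = EpochSet([[0.0, 60.0]], "locomotion")

coh = spectral.multitaper_coherence(x, y, eps, cfg)
band = (coh.freqs >= 5) & (coh.freqs <= 10)
print(f"theta coherence  {coh.coherence[band].mean():.2f}")
print(f"theta ratio      {spectral.theta_ratio(coh, cfg):.2f}")

res = directed.fit_bivariate_ar(x, y, eps, fs_target=cfg.ar_fs)
print(res.summary())
fwd, rev = res.directed_coherence().band_mean((5, 10))
print(f"directed 5-10 Hz x→y {fwd:.2f}   y→x {rev:.2f}")
```

Output:

```
theta coherence  0.52
theta ratio      3.78
Bivariate AR model (directed coherence)
========================================
channels       : x, y
model rate     : 200 Hz
order (AIC)    : 20
n observations : 11980
stable         : True
AIC            : 165160.4
residual cov   : [[938.2, 39.15], [39.15, 1023]]
instantaneous r: +0.040
directed 5-10 Hz x→y 0.36   y→x 0.20
```

The pair was simulated with x driving y through a 13-ms delayed theta-band
coupling: coherence concentrates in 5–10 Hz (ratio ≫ 1) and the directed
measure correctly assigns the x→y direction (0.36 vs 0.20).

A command-line interface mirrors the library
(`cerecoh simulate|segment|spectra|directed|evoked|psth|classify|correlogram|quality|stats|run-coherence|run-stimulation`).

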