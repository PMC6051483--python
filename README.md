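# lfpdecode

Unsupervised feature extraction and decoding for multichannel **local field
potentials (LFPs)**, aimed at long-term, low-power neural interfaces.

Spike-based brain–machine interfaces suffer from recording instability and
high sampling-rate power costs. The low-frequency (<5 Hz) LFP — the *local
motor potential* (LMP) — is stable for months and can be sampled at tens of
hertz, but it mixes the contributions of many neurons across electrodes.
`lfpdecode` implements two complementary ways of unmixing it:

1. **Spike-related slow potentials (SRSPs) and firing-rate decoding.**
   Each LFP channel is modelled as a multiple-input single-output (MISO)
   linear time-invariant system driven by the recorded spike trains:

   $$y_c(t) = b_c + \sum_u (h_{u,c} * x_u)(t),$$

   with acausal impulse responses $h_{u,c}$ (the SRSPs) estimated by least
   squares assembled from input auto- and cross-correlation functions, so
   that correlations between recorded spike trains are removed from each
   unit's kernel (unlike a plain spike-triggered average). Across an array
   the SRSPs of a neuron are well approximated by ~3 source waveforms; the
   pseudoinverse of the source loadings gives *source projections* — channel
   mixtures from which each source's time course is recovered — and Wiener
   deconvolution $G(f) = H^*(f)/(|H(f)|^2 + \mathrm{nsr})$ inverts the
   waveforms. The whole chain collapses into per-unit acausal FIR filter
   banks, so firing rates are estimated from LFP alone in real time by pure
   filtering.

2. **Rotational dynamics and areal velocity.** Because the SRSP sources have
   distinct spatio-temporal profiles, submovement-locked low-frequency
   oscillations appear with different phases on different channels and the
   LFP trajectory rotates in channel space. Planes of maximal rotation are
   found with jPCA (a closed-form skew-symmetric fit of
   $\dot{\mathbf l} \approx M\mathbf l$), and rotation amplitude is measured
   by the **areal velocity** — the area swept per unit time by the projected
   trajectory:

   $$AV_{u,v} = \tfrac12\big[(\mathbf u\!\cdot\!\mathbf l)(\mathbf v\!\cdot\!\dot{\mathbf l}) - (\mathbf v\!\cdot\!\mathbf l)(\mathbf u\!\cdot\!\dot{\mathbf l})\big]
             = \sum_{i<j}(u_i v_j - u_j v_i)\,AV_{i,j},
   \qquad AV_{i,j} = \tfrac12(l_i \dot l_j - l_j \dot l_i).$$

   $N$ channels give $\tfrac12 N(N-1)$ pairwise signals. AV rejects all
   in-phase components shared across channels regardless of gain, has zero
   mean for phase-unstructured noise, and in a 3-PC space the cross product
   $\tfrac12\,\mathbf x \times \dot{\mathbf x}$ is a vector whose magnitude
   tracks submovement speed and whose direction (the rotation axis) decodes
   submovement direction, scored with an angular coefficient of
   determination against a permutation null.

A seeded synthetic generator (`lfpdecode.synth`) produces spike trains,
SRSP-mixed LFP, and submovement kinematics with ground truth for every
stage, so the full pipeline is testable without animal data.

## Worked example

Everything is available as a library (`import lfpdecode`) and as a CLI:

```bash
lfpdecode simulate --seed 7 --duration 120 --preset rotation --out session
lfpdecode jpca --lfp session/lfp.csv --out planes.h5
lfpdecode areal-velocity --lfp session/lfp.csv --planes planes.h5 --vector3 --out av.csv
lfpdecode submovements --kin session/kinematics.csv --out events.csv
lfpdecode decode-direction --av3 av.csv --events events.csv --shuffles 1000 --seed 7 --out direction.json
```

prints

```
wrote session (6 units, 8 channels, 120 s) to session
found 2 rotational planes (2.68 Hz, 0.53 Hz)
wrote 5 areal-velocity signals to av.csv
detected 284 submovements (2.37 /s)
angular CoD 0.055 vs shuffle 95th -0.015 (significant)
```

The simulated session contains submovements at 2.37 per second (within the
physiological 1–4/s band); jPCA finds the dominant rotational plane at
2.68 Hz (the generator rotates at 2.5 Hz); and submovement direction decoded
from the 3-D areal-velocity vector scores an angular CoD of 0.055, above the
95th percentile of 1000 direction-shuffled controls — the per-direction axis
tilt is only 10°, so the effect is subtle but reliably detectable.

The spike-rate pipeline runs the same way:

```bash
lfpdecode simulate --seed 7 --duration 120 --out session
lfpdecode fit-miso --spikes session/spikes.csv --lfp session/lfp.csv --out srsp.h5
lfpdecode build-decoder --model srsp.h5 --spikes session/spikes.csv \
    --lfp session/lfp.csv --out dec.h5
lfpdecode estimate-rates --decoder dec.h5 --lfp session/lfp.csv --out rates.csv
```

```
fitted 6 units x 8 channels; median VAF 0.920
built decoder for 6 units (3 sources, nsr=0.01)
estimated rates for 6 units, 12000 bins
```

`rates.csv` holds the per-unit firing-rate estimates (Hz) obtained from the
LFP alone; on held-out synthetic data their correlation with the true rates
is typically 0.2–0.6 per unit, and the leading population-rate component is
recovered with higher fidelity than any typical single unit.

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.

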