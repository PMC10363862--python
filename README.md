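# headturn

Speech intelligibility during self-rotation: room-acoustic and binaural
modelling plus the behavioral/psychometric analysis for spatialized
speech-in-noise experiments with freely rotating listeners.

When a talker appears at an unexpected azimuth while a noise interferer stays
in front, a listener who turns toward the talker changes the spatial
unmasking they receive: the head shadow improves the target-to-interferer
ratio (TIR) at one ear ("better-ear listening"), and interaural phase
differences of target and masker yield a binaural masking level difference
(BMLD). `headturn` predicts, for every horizontal head orientation, the
effective TIR of that orientation in a simulated reverberant room and turns
head-motion trajectories into per-word intelligibility predictions, which it
then confronts with (synthetic) behavioral word scores.

## The model

For gammatone bands *i* with SII importance weights *w_i* (Σ*w_i* = 1), the
effective target-to-interferer ratio at head yaw θ is

```
TIR(θ) = Σ_i w_i [ BE_i(θ) + BMLD_i(θ) ]
BE_i   = max over ears of 10 log10( E_target,i / E_interferer,i )
BMLD_i = max(0, 10 log10[ (k_i − cos(φ_T,i − φ_I,i)) / (k_i − ρ_I,i) ])
k_i    = (1 + σ_ε²) · exp( (2π f_i σ_δ)² ),  σ_ε = 0.25, σ_δ = 105 µs
```

where band energies *E*, interaural phases φ and the interferer's interaural
coherence ρ come from binaural room impulse responses (BRIRs) rendered by a
shoebox image-source model (Allen–Berkley mirror images, octave-band wall
absorptions, optional surface scattering with a statistical diffuse tail) to
a rigid-sphere head (Woodworth ITDs, head-shadow ILDs). The
**head-orientation benefit map** is TIR(θ) on a 1° yaw grid; referenced to
the co-located target/interferer configuration it is the spatial unmasking
itself, and orientations within 1 dB of its peak form the *acoustically
optimal region*.

Behavioral word scores (five-word matrix sentences, ten alternatives per
word) are linked to predicted benefit through a random-intercept logistic
psychometric function, `logit p = β₀ + β₁·benefit + u_j`, fitted by maximum
likelihood with Gauss–Hermite integration of the participant intercepts
`u_j`; scores are analyzed in rationalized arcsine units (RAU) with
within-subject ANOVAs (Greenhouse–Geisser corrected) and circular statistics
(circular median/variance, permutation two-sample Kuiper tests) of the
orientation distributions.

A synthetic-cohort generator emulates the experiment's design — 6 blocks ×
48 trials, 12 per target location (0°, ±90°, 180°), conditions Static /
Audio-only / Audio-Visual — with reaction-time + minimum-jerk rotation
trajectories (150 °/s peak), condition-dependent undershoot, word timing
from the sentence-duration statistics, and an injectable dynamic-motion
deficit δ (dB) that degrades words spoken while the head is turning.

## Worked example

```python
import numpy as np
from headturn import paper_scene, benefit_map, optimal_region, bmld
from headturn.cohort import CohortConfig, gen_static_scores
from headturn.psychometrics import fit_glre

# antiphasic BMLD of a 500 Hz tone in coherent noise
print(round(bmld(np.pi, 0.0, 1.0, 500.0), 2))        # 10.73 dB

# lateral-target scene: interferer at 0 deg, target at +90 deg, 2.1 m
scene = paper_scene(target_azimuth_deg=90.0)
bm = benefit_map(scene, target_index=1, interferer_index=0, grid_step_deg=5.0)
print(round(bm.peak_unmasking_db, 2))                # 4.46 dB
region = optimal_region(bm, margin_db=1.0)           # 21 of 72 grid yaws

# psychometric slope recovered from one synthetic Static cohort
cfg = CohortConfig()
fit = fit_glre(gen_static_scores(cfg, seed=42), cfg.static_benefit_db)
print(round(fit.slope_per_db, 3))                    # 0.078 proportion/dB
```

The 10.73 dB value is the equalization–cancellation limit of binaural
unmasking for an antiphasic 500 Hz target in fully coherent noise. The
4.46 dB peak is the largest spatial unmasking any head orientation can buy
in the simulated room for a lateral target (computed here on a coarse 5°
grid; the full analysis uses 1°), and the fitted slope of ≈0.08/dB says a
1 dB change in effective TIR moves word accuracy by about 8 percentage
points at the steepest part of the psychometric function.

The same pipeline is scriptable from the shell:

```bash
headturn benefit-map --target 90 --grid-step 5 --out map.tsv
headturn analyze --seed 1 --out run_out/
```

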