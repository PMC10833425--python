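# steerpr

Ensemble-steered phase retrieval for coherent X-ray diffraction imaging
(XDI).

## The problem

XDI reconstructs the projected electron density of a single, isolated,
non-crystalline particle (a colloidal-gold aggregate, a cell organelle)
from its oversampled far-field diffraction amplitudes. The Fourier phases
are lost in the measurement and must be recovered iteratively; beamstop
shadow, detector gaps, saturation and Poisson noise make the inverse
problem multi-modal, so independent hybrid input-output (HIO) trials
frequently converge to different, unrealistic maps and many hundreds of
trials are needed before a believable reconstruction appears.

`steerpr` implements a steering protocol for an *ensemble* of
HIO + shrink-wrap trials. The ensemble is periodically paused; all maps
are aligned (translation + π-rotation) and scored pairwise with the
similarity metric

    T_ij = Σ |ρ_i − ρ_j| / Σ (ρ_i + ρ_j)   ∈ [0, 1],

where pairs with T < 0.2 empirically indicate realistic maps. The
lower-index member of the minimal-T pair becomes a reference, a consensus
map ρ̄ is formed as the unweighted mean of all reference-aligned maps
with T < 0.2 against it, and every trial is blended toward it,

    ρ ← (1 − w) ρ + w ρ̄,   w = min(0.05 s, 0.50) at stage s,

every 500 cycles until cycle 9000. An adaptive shrink-wrap rule (blur
width ζ = 2 px while the oversampling ratio still jumps by ≥ 2 between
support updates, then 0.9 px, latched) keeps the early ensemble diverse
and defines the steering trigger. The package also provides an
oversampling-smoothness (OSS) refinement mode, PCA/K-means trajectory
analytics, and a synthetic diffraction simulator (disk aggregates and
low-contrast ellipsoid phantoms, Poisson noise, beamstop, gap stripes,
saturation) so the whole protocol is testable without experimental data.

See `docs/methods.md` for the full model description and the numerical
conventions.

## Worked example

Simulate a degraded pattern of a seven-disk aggregate, run paired
16-trial ensembles with and without steering, and compare the yield of
realistic maps against the known phantom:

```python
from steerpr import (
    PhantomSpec, PhasingConfig, SteeringConfig,
    make_disk_aggregate, forward_diffract, degrade_pattern, embed_map,
    run_ordinary_ensemble, run_steered_ensemble, realistic_fraction,
)

spec = PhantomSpec(n_particles=7, diameter_px=10, seed=105)
phantom = make_disk_aggregate(spec, 64)            # 64 px field
pattern = degrade_pattern(
    forward_diffract(phantom, pad_factor=2),       # 128 x 128 pattern
    photon_budget=1e7, beamstop_radius_px=3, gap_rows=[32], seed=15,
)
truth = embed_map(phantom, 2)

config = PhasingConfig(n_cycles=3000)
seeds = list(range(16))
ordinary = run_ordinary_ensemble(pattern, config, 16, seeds)
steered = run_steered_ensemble(pattern, config, SteeringConfig(), 16, seeds)

print("first modification at cycle", steered.trigger_cycle)
print("ordinary realistic fraction", realistic_fraction(ordinary.final_maps, truth))
print("steered  realistic fraction", realistic_fraction(steered.final_maps, truth))
print("steered ensemble converged:", steered.converged)
```

Output:

```
first modification at cycle 600
ordinary realistic fraction 0.4375
steered  realistic fraction 0.6875
steered ensemble converged: False
```

Every trial's adaptive shrink-wrap blur settled by cycle 500, so the
consensus modification started at cycle 600 (on noisy patterns the
trigger typically lands between cycles 500 and 1000). By cycle 3000 the
steered ensemble has pulled 11 of 16 trials into the realistic basin
(aligned similarity T < 0.2 against the phantom) versus 7 of 16 for the
uncommunicating ordinary ensemble; its score histogram has not yet
collapsed to the single narrow sub-0.2 peak that would signal full
convergence (that typically needs the full 10000-cycle schedule). On
easier phantoms from the same family (3-6 disks) this benchmark reaches
steered fractions of 1.0 with the convergence flag set.

The same pipeline is scriptable from the shell:

```sh
steerpr simulate --kind disk --n 7 --field 64 --photons 1e7 \
        --beamstop 3 --gap-row 32 --seed 105 -o run.h5
steerpr steer run.h5 --n-trials 16 --cycles 3000 --seed-base 0
steerpr analyze run.h5 --k 3 --heatmap visits.png --csv proj.csv
```

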