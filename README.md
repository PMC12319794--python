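# vasim

Biophysical simulation of cortical-depth-dependent gradient-echo (GE) and
spin-echo (SE) BOLD fMRI signals at 7 T, driven by explicit 3D vascular
networks.

Laminar (cortical-depth-resolved) fMRI interprets BOLD profiles in terms
of neuronal activity per cortical layer, but the measured signal is shaped
as much by the vasculature as by neurons: large pial veins dominate the
surface, capillary beds the depths, and GE and SE sequences weight those
compartments very differently. `vasim` is for MR physicists and modelers
who want to quantify those effects. It takes a vectorized vascular graph
(segments with position, radius, length, connectivity), assigns
per-compartment physiology, and computes the laminar MR signal from first
principles:

1. **Vascular model** — classify segments (capillary < 6 µm radius;
   pial-seeded artery 6–11 µm / vein 11–36 µm labels propagated along
   vessel paths), impose the human ~3:1 artery:vein trunk ratio, partition
   the cortex into 16 equal laminae, and compute baseline blood volume
   (CBV) per lamina and compartment as `Σ πR²L / V_slab`.
2. **Field synthesis** — every segment contributes the external field of
   an infinite paramagnetic cylinder,
   `δω = ½ γ B0 Δχ (R/r)² cos 2θ sin²ψ` with
   `Δχ = 4π·0.276·10⁻⁶·Hct(R)·(1 − SO₂)`, superposed on a regular grid
   with an inside-vessel mask.
3. **Monte-Carlo dephasing** — extravascular water diffuses
   (D = 1 µm²/ms, dt = 25 µs) through the field; impermeable walls,
   periodic in-plane boundaries, invalidation at the pial/white-matter
   faces; SE refocuses at TE/2. Output is the complex laminar attenuation
   A(t).
4. **Signal composition** — `S(t) = S_EV + S_aIV + S_vIV` with empirical
   7 T blood and tissue relaxation constants; metrics
   `ΔR2⁽*⁾ = (R2/R2_tissue − 1)·100` (log-linear fit over [0, TE]) and
   `ΔBOLD = (S(TE)/S_tissue(TE) − 1)·100`.
5. **Experiments** — venous SO₂ sweeps (15 levels, 50–92 %), laminar
   depth profiles, extravascular/intravascular contribution shares, and
   systemic hematocrit sweeps (35–55 %), with slope fits, 95 % CIs and
   pairwise Welch comparisons per four-lamina group (top, top-middle,
   middle-bottom, bottom).

A synthetic vasculature module generates the inputs: mono-sized
random-cylinder phantoms (the classic vessel-size validation geometry) and
cortical-like voxels with pial + penetrating macrovessels at 3:1 and a
capillary bed reproducing the depth-dependent CBV statistics of two-photon
vascular reconstructions (high CBV in the top 250 µm, ~1–2 % total).

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from vasim.synth import CortexSpec, generate_cortical_network
from vasim.experiments import (MonteCarloSettings, run_so2_sweep,
                               fit_laminar_slopes, group_means)

net = generate_cortical_network(CortexSpec(xy_extent=600.0, seed=0))
mc = MonteCarloSettings(n_spins=50_000, n_reps=2, grid_spacing=3.0, seed=1)
df = run_so2_sweep(net, so2_levels=(0.50, 0.56, 0.62, 0.68,
                                    0.74, 0.80, 0.86, 0.92), mc=mc)

g = group_means(df, "dR2_pct")
print(g.pivot_table(index="so2_vein", columns=["sequence", "lamina_group"],
                    values="dR2_pct").round(2))
for seq in ("GE", "SE"):
    slopes = fit_laminar_slopes(df, "dR2_pct", "so2_fraction", sequence=seq)
    print(seq, {k: round(v.slope, 2) for k, v in slopes.items()})
```

prints (~2 min on one core; abridged):

```
sequence         GE                                      SE
lamina_group bottom middle_bottom     top top_middle bottom middle_bottom    top top_middle
so2_vein
0.50           2.05          1.96   17.46       2.57   1.64          1.57   5.19       1.98
0.62           1.30          1.28   13.85       1.70   1.04          1.01   4.36       1.30
0.74           0.70          0.75   10.57       1.02   0.56          0.56   3.49       0.73
0.86           0.29          0.38    6.39       0.54   0.21          0.21   1.79       0.29
0.92           0.16          0.25    3.49       0.39   0.09          0.07   0.33       0.08
GE {'top': -31.9, 'top_middle': -5.21, 'middle_bottom': -4.09, 'bottom': -4.51}
SE {'top': -10.74, 'top_middle': -4.5, 'middle_bottom': -3.56, 'bottom': -3.69}
```

Read: the relative relaxation-rate change falls linearly as venous
oxygenation rises in the deep laminar groups, with GE responding more
steeply than SE (slopes per unit SO₂ fraction); the top group, dominated
by pial veins, is several-fold stronger and nonlinear.

## Command line

```bash
vasim synth cortex --seed 0 --out net.csv
vasim graph label --in net.csv --ratio 3:1 --out labeled.csv
vasim field --net labeled.csv --so2-vein 0.62 --hct 0.45 --out field.h5
vasim mc --field field.h5 --seq se --spins 1e5 --seed 1 --out att.h5
vasim run --config cfg.yaml --seed 1 --out results/
```

`vasim run` executes label → field → Monte Carlo → composition → analysis
from a validated YAML config and writes CSV tables plus a JSON manifest
from which every output can be regenerated.

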