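# omeflux

Quantitative analysis of membrane-protein dynamics and outer-membrane
exchange (OME) in rod-shaped bacteria such as *Myxococcus xanthus*, where
polymorphic TraA receptors perform an allele-specific "molecular handshake"
at cell–cell contacts: compatible receptors cluster into foci at the contact
interface and gate the bidirectional transfer of outer-membrane cargo
between cells. `omeflux` is written for microscopists and modellers who need
the standard quantifications of this system — FRAP curve fitting, kymograph
and demograph construction, protease-accessibility statistics, transfer and
population-mixing indices — together with a particle-based synthetic
microscopy generator that provides ground truth for validating every step.

## What it computes

**FRAP.** From a bleached-area series `I_FRAP(t)` and whole-cell series
`I_total(t)` (pre-bleach frame 0, first post-bleach frame t0):

    I(t)      = I_FRAP(t)/I_FRAP(0) × I_total(0)/I_total(t)
    I_norm(t) = (I(t) − I(t0)) / (I(0) − I(t0))

so `I_norm(pre) = 1` and `I_norm(t0) = 0` exactly. Recovery kinetics are
fitted with

    Y(t) = A · (1 − e^{ln(0.5)/t_half · t})

giving the mobile fraction `A` and half-time `t_half`. The diffusion
coefficient comes from prebleach-minus-postbleach difference profiles fitted
with a Gaussian `C·exp(−2(s−µ)²/R²)` (R is the 1/e² half-width); the depth
series obeys

    C(t) = C0 · R0 · (R0² + 8·D·t)^{−1/2}

with `C0, R0` from the first post-bleach frame — the exact free-diffusion
solution under this Gaussian convention.

**Profiles.** Axial intensity profiles (perpendicular averaging over the cell
width), per-frame mean-normalized kymographs (invariant to acquisition
photobleaching), peak-anchored dual-channel normalization, and length-sorted
junction demographs.

**Exchange.** Donor/recipient transfer fractions `F_d/(F_d+F_r)`,
proteinase-K accessibility ratios `F_PK/F_0` with unpaired two-tailed
t-tests between groups, junction colocalization summaries, and a
population homogenization index `H = 1 − 2·mean|b_i − 0.5|` over per-cell
channel balances `b_i` (both explicitly package-defined summaries).

**Simulation.** Brownian particles on the 1-D cell axis with reflecting
poles, probabilistic pulse-train photobleaching, allele-gated receptor
trapping in contact zones, receptor-pair-gated cargo transfer, and rendering
with Gaussian PSF, Poisson shot noise and read noise. Same seed + config ⇒
bit-identical stacks.

## Worked example

Simulate a FRAP experiment on a 4 µm cell (true D = 0.02 µm²/s, immobile
fraction 0.3, 45 frames at 5 s) and re-fit it:

```python
from omeflux.workbench import RunConfig, run_pipeline

report = run_pipeline(RunConfig(stages=["simulate", "frap", "kymo"],
                                outdir="demo", rng_seed=42))
print(report.stages["frap"])
```

prints (abridged):

```
mobile_fraction_A : 0.695      # truth: 1 − 0.3 = 0.7
t_half_s          : 6.28
D_um2_per_s       : 0.0217     # truth: 0.02
C0                : 1.096
R0_um             : 0.391
C_inf             : 0.261      # immobile-pool floor of the depth decay
```

The mobile fraction recovers the simulated 70% mobile pool and the depth-decay
fit recovers D within ~8%; `demo/` contains the TIFF stack with its JSON
sidecar (pixel size, frame interval, channel names, bleach frame), the
ground-truth record, normalized curves as CSV, the kymograph as CSV + PNG,
and a run report listing every output with its SHA-256 checksum (identical
seed + config reproduce identical bytes).

The same steps are available from the shell:

```sh
omeflux simulate --seed 42 --outdir demo
omeflux frap-fit --stack demo/frap_stack.tif --roi demo/geometry.json
omeflux kymo     --stack demo/frap_stack.tif --roi demo/geometry.json
omeflux pk       --table pk_table.csv
omeflux transfer --table transfer_series.csv
omeflux mix      --table per_cell_channels.csv
omeflux fixtures --seed 0 --outdir fixtures
```

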