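# penosome

Quantitative analysis of **compartmentalised PEN DNA reactions in
proteinosomes**: a simulation and analysis toolkit for experiments in which
micron-scale, semi-permeable protein capsules (proteinosomes) carry an
immobilised DNA template while primers and the PEN enzymes (Polymerase,
Exonuclease, Nickase) diffuse in and out, so that autocatalytic and linear
DNA reaction nodes run inside the droplets and communicate through the bulk
phase.

The package is aimed at people analysing fluorescence time-lapse data of such
dispersions (or planning experiments on them). It covers the full chain:

- **`penosome.synth`** — a mechanistic two-compartment reaction model (lumped
  saturating production with product inhibition, Michaelis-type exonuclease
  degradation, first-order membrane exchange, integrated with fixed-step RK4)
  plus synthesizers for time-lapse image stacks and FRAP traces, each with
  ground truth. These stand in for raw microscopy data so every downstream
  stage is testable offline.
- **`penosome.imaging`** — droplet detection (blur → threshold → fill →
  watershed → circularity 0.7–1.0 and diameter 17–25 µm filters), per-droplet
  trace extraction (integrated intensity / area), size statistics, and the
  proteinosome-count ↔ fluorescence calibration with the 0.12 µM
  per-droplet template rule.
- **`penosome.kinetics`** — the rate-extraction procedure for autocatalytic
  growth curves: the logistic model `A(x) = L / (1 + exp(k(x − x₀)))` fitted
  from t = 0 to the data-derived window end `t_f = b₁ + c₁·√(ln(a₁/f))`,
  where (a₁, b₁, c₁) come from a Gaussian fit to the discrete differences of
  the signal and `f = a₁/2`; reported rate is |k| (or the max slope |k|·L/4
  for unnormalised traces). Plus dr/d[T] slopes, Tukey box statistics, and
  profile classification (flat / sigmoidal / pulse).
- **`penosome.frap`** — FRAP normalization, recovery fitting
  `I(t) = 1 − A·exp(−(t−t₀)/τ)` with an F-tested free plateau and immobile
  fraction, the diffusion relation `D = 0.88 r² / (4 τ ln 2)`, multi-event
  aggregation, and the partition coefficient `K = F_in / F_out`.
- **`penosome.pipeline` / `penosome.cli`** — a seeded, checksummed
  end-to-end pipeline (`penosome run --seed 1 --outdir out`) with
  subcommands `simulate`, `segment`, `fit-kinetics`, `fit-frap`, `calibrate`.

The numbered scripts under `analysis/` are thin drivers that run each study
and write tables and figures under `results/`.

## Worked example

```sh
python analysis/03_rate_extraction.py
```

prints (numbers from an actual run):

```
logistic rate recovery: noiseless max err 4.00e-14%, 2%-noise median err 1.28%
fit-window closed form vs numerical inversion: max |err| 2.84e-14 min over 1000 draws
switch-off: compartments fully off at 9.6 nM exonuclease while the 1 uM buffer reaction keeps rate 0.019 /min
template sweep (0.2, 0.41, 0.81, 1.63) nM: median rates [3.511, 3.517, 3.529, 3.553] RFU/min (monotone: True), dr/d[T] = 29.2 RFU/min/uM
```

Reading: the rate pipeline reproduces known logistic rates essentially
exactly without noise and to ~1% median error at 2% noise; the window rule
is an exact inversion of the Gaussian; in the simulated dispersion (total
template in the nanomolar range because only ~0.5% of the volume is droplet
interior at 0.12 µM internal template) the autocatalytic reaction is fully
switched off at 9.6 nM exonuclease while the same chemistry in buffer at
1 µM template keeps growing — the hallmark of compartmentalisation: total
production and degradation become commensurate, so exonuclease becomes an
on/off handle. Droplet rates also rise with droplet density (total
template), and a two-node network (`analysis/05_two_node_network.py`) shows
a pulse in the linear population, a delayed sigmoid in the autocatalytic
population whose rate is tuned by the linear-template level, and a flat
no-communication control.

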