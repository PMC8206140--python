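# mayleonard

An off-lattice simulator of cyclic three-species competition
(rock–paper–scissors ecology) with a tunable environment, plus the
analysis pipeline for the population oscillations it produces.

## The model

Three species A, B, C inhabit a periodic square of side L (continuous
coordinates).  Dominance is cyclic — A preys on B, B on C, C on A — and
predation ("selection") is decoupled from reproduction, making this a
May–Leonard scheme: the total population N = n_A + n_B + n_C fluctuates.
In one elementary Monte Carlo step a random living individual either

* **moves** by exactly ℓ_m in a uniform random direction (probability m),
* **predates** — the closest prey within ℓ_p dies (probability p), or
* **reproduces** (probability r): if fewer than M individuals of any
  species lie within ℓ_r of it, a newborn of its species appears within
  a disk of radius ℓ_o around it.

A full MC step repeats this N₀ times (N₀ frozen at the step's start).
The local carrying capacity M is the single environmental dial: small M
is a harsh environment, large M a benign one.  Reference parameters:
m = 0.5, p = r = 0.25, ℓ_p = ℓ_r = 0.02, ℓ_m = ℓ_o = 0.01, L = 1,
10⁴ individuals per species initially.

The phenomenology this package measures:

* the stationary mean ⟨N⟩ grows **linearly in M**, with a slope that is
  robust to microscopic details such as ℓ_m;
* the species fraction ρ(t) = n_A(t)/N(t) oscillates (rotating spiral
  waves); the peak of the ensemble-averaged power spectrum
  ⟨|ρ(f)|²⟩, with ρ(f) = (1/N_G) Σ_t ρ(t) e^(−2πift), defines a
  characteristic frequency that grows **logarithmically in M** (about
  107 cycles per 10⁴ MC steps at M = 30, with N_G = 10⁴);
* when ℓ_m becomes comparable to the box the system is effectively
  well mixed and one species goes extinct;
* when ℓ_p = ℓ_r ≈ 0.1·L, empty space acts like an extra species and
  even large M supports only a sparse population.

See `docs/methods.md` for conventions, numerical choices and the
desk-scale protocol (reduced box, preserved local density).

## Worked example

A single simulation in a quarter-scale box, exported as plain text:

```sh
$ mayleonard run --box-length 0.25 --capacity 15 --relax-steps 500 \
      --measure-steps 1000 --seed 3 --out-dir out-run
wrote 1000 steps to out-run/series.csv (final N=806)

$ head -4 out-run/series.csv
t,nA,nB,nC,N
1,305,165,378,848
2,289,171,376,836
3,284,175,380,839
```

The counts of the three species oscillate around N/3 while N itself
fluctuates around its M-dependent mean.  The oscillation frequency is
measured from ensemble spectra (here at half scale, 10 replicates per M;
takes minutes):

```sh
$ mayleonard spectrum --m-values 10,15,20,25,30 --replicates 10 --seed 42
M=  10  f_peak=  61 cycles / 10000 steps  peak_power=3.071e-04
M=  15  f_peak=  78 cycles / 10000 steps  peak_power=2.647e-04
M=  20  f_peak=  90 cycles / 10000 steps  peak_power=2.855e-04
M=  25  f_peak=  97 cycles / 10000 steps  peak_power=2.781e-04
M=  30  f_peak= 104 cycles / 10000 steps  peak_power=3.400e-04
f_peak = -28.21 + 39.04*ln(M) (r^2 = 0.9975)
```

`f_peak` is the location of the non-DC maximum of ⟨|ρ_A(f)|²⟩ in cycles
per 10⁴-step window: at M = 30 the species-A fraction completes ~104
oscillations per 10⁴ MC steps, and the peak frequency climbs
logarithmically with M — oscillations get faster as the environment
improves.  (At full scale the peak also gets *higher* with M; in this
reduced box the low-M peak heights are inflated by near-extinction drift,
see `docs/methods.md`.)

The library surface mirrors the CLI (`mayleonard.run`,
`mayleonard.spectrum_sweep`, `mayleonard.capacity_scenario`, ...) and
returns numpy/pandas objects; every export is a plain-text table with a
flat key-value manifest naming the parameters and seeds that produced it.

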