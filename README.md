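# aquavital

Non-invasive vitality monitoring for live fish transported under waterless,
cold-dormancy conditions. A wearable bioimpedance analyzer (WBIA) sweeps the
fish at 30–100 kHz and reports, per frequency, the real part *R* and
imaginary part *I* of the tissue response; `aquavital` turns those sweeps
into physiological stress estimates and a five-level health classification.

The package is aimed at aquaculture and cold-chain researchers who want the
full measurement-to-classification chain — including a synthetic-data
generator with known ground truth, since matched WBIA + biomarker datasets
are rarely public.

## Method

1. **Sweep conversion.** Magnitude `M = √(R² + I²)`, phase `θ = arctan(I/R)`
   (principal value), and calibrated impedance `Z = 1/(M·K)` with the gain
   `K` obtained from a known reference resistor per frequency.
2. **Preprocessing.** Gross errors are rejected per channel by the
   Romanovsky criterion — the suspect `x_i` is removed while
   `|x_i − x̄_rest| > K(n, α)·σ_rest`, with `K` a Student-t coefficient — and
   the signals are smoothed with a Savitzky–Golay least-squares filter.
   Sparse hourly biomarker checkpoints are completed to the sweep grid with
   natural cubic splines.
3. **Weighting and screening.** Grey relational analysis (GRA) scores each
   stress factor (serum glucose, muscle lactate, serum cortisol) against the
   muscle-nutrient decline, ζ(k) = (Δmin + ρΔmax)/(Δ(k) + ρΔmax), and the
   normalized relational grades become the stress weights `W`. WBIA features
   are screened by the maximal information coefficient,
   `MIC(x;y) = max_{XY<B} I(X;Y)/log₂ min(X,Y)`, keeping features with
   MIC ≥ 0.9 against every stress factor.
4. **Stress estimation.** A sliding window (length 15) of screened features
   feeds a two-stage estimator: a 1-D CNN + LSTM with additive attention
   predicts the stress value one horizon ahead, and a bidirectional GRU with
   attention regresses the first stage's training residuals; the final
   estimate is the sum of the stages. LSTM/GRU/CNN-LSTM/CNN-GRU baselines
   share the protocol.
5. **Health mapping.** The weighted total stress
   `S_total(t) = Σ W_i · norm S_i(t)` is mapped through a Z-shaped fuzzy
   membership function `HQ(S_total; a, b)` to a health-quality value in
   [0, 1] and classified into SLL/MLL/BLL/WLL/DS (strong/medium/basic/weak
   live level, death status) by zone-specific average-stress breakpoints.
   The near-death time point is the first observation checkpoint at which
   cohort survival drops below 60%.

## Worked example

```python
from aquavital import (SimulationConfig, simulate_experiment, death_schedule,
                       near_death_point)

cfg = SimulationConfig(seed=0)           # 84 h, 5-min sweeps, 1-3 degC zone
frames, stress, nutrients, truth = simulate_experiment(cfg)
print(len(frames), "sweeps,", len(truth.outlier_positions), "injected spikes")

schedule = death_schedule(cfg, cohort_size=25)   # observed-cohort fixture
print(schedule)
print(near_death_point(schedule, cohort=25))
```

prints

```
1009 sweeps, 27 injected spikes
[(60.0, 2), (72.0, 5), (78.0, 8), (84.0, 11)]
(84.0, 0.56)
```

— 1009 five-minute sweeps over 84 h with 27 recorded gross-error spikes, the
cumulative deaths of the 25-fish observation cohort, and the near-death
point: at 84 h survival is 14/25 = 56%, the first checkpoint below the 60%
threshold.

The full pipeline runs from the command line:

```bash
aquavital simulate --out runs/sim --seed 1
aquavital run --out runs/exp1 --seed 1
```

`runs/exp1/assessment.csv` then holds one `(time_h, total_stress, hq,
level)` row per assessed time point, and `manifest.json` records a SHA-256
digest of every artifact so a rerun with the same config and seed is
bit-reproducible.

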