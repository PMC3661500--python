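# dispersim

A spatially explicit, individual-based simulator of animal natal dispersal
and home-range establishment on vector-polygon landscapes.

Natal dispersal — the one-way movement of a juvenile from its birth site to
its first breeding site — is hard to observe in the field, yet it drives
population expansion, rescue of habitat patches, and response to landscape
change. `dispersim` simulates it mechanistically: virtual animals walk a
correlated random walk through GIS-style polygon maps, budget energy, risk
predation, remember what they perceive, and try to claim an exclusive home
range before the dispersal season ends. Population-level quantities
(survivorship, cause-specific mortality, weight distributions, settlement
times and distances) emerge from those individual rules. The landscape can
change *during* a run — maps are swapped on a schedule to represent seasonal
food pulses or day/night predation regimes.

It is aimed at spatial/behavioural ecologists who want to ask how behavioural
complexity (state switching, boundary responses, habitat memory) and
landscape dynamics shape dispersal outcomes, without committing to a single
species: everything is parameterized from data.

## The model

Time is discrete (user-chosen step length, dispersal-season length, years);
the rest of the year is a single inter-dispersal period carrying resident
mortality and reproduction. Each animal, each active step:

* **Movement** — heading turns by a wrapped-Cauchy angle with concentration
  ρ ∈ [0, 1] (ρ = 0 a pure random walk, ρ = 1 straight-line movement); step
  length is Normal(μ, σ) truncated at 0. Both come from the polygon the
  animal stands in (the movement map). At each polygon boundary met along the
  step, the animal crosses with probability q_to/(q_from + q_to), where q is
  the crossing rank of each class — a rank-0 class is never entered. A
  refused crossing truncates the step; the landscape edge reflects specularly.
* **Energetics** — the step costs the local energy rate; with probability
  p_capture the animal gains a truncated-Normal prey size (food map). The
  reserve clamps at E_max and the animal starves below E_min.
* **Risk** — a per-step Bernoulli death at the local p_mortality (risk map),
  so survival under constant hazard is exactly (1 − p)^n.
* **Behaviour** — two state axes: activity mode (searching/foraging,
  switched by an energy threshold) and vigilance (risky/safe, switched
  stochastically). Sex, state, hour and date multiply any baseline parameter
  through a modifier table; a table of 1s is exactly the null model.
* **Memory and settlement** — the path, buffered by the perception radius,
  is the step's perceptual window; suitability and occupancy inside it enter
  the animal's memory map (latest observation wins). Once a trigger (active
  steps or suitable sites visited) is passed, candidate home-range centers
  are sampled from remembered suitable, un-occupied area and scored by
  Q·exp(−d/w) — proximity always, food and/or safety depending on the chosen
  criterion — and a stochastic 12-gon range is generated at the chosen site.
  Settlement succeeds only if the range, clipped to suitable habitat not
  occupied by the same sex, still holds the sex-specific minimum area:
  same-sex home ranges never overlap. Animals still dispersing at season end
  die.
* **Demography** — residents survive the off-season with 1 − p_inter;
  surviving females are pregnant with probability p_preg and bear
  round(Normal(litter)) young (negatives → 0) that disperse next season from
  the mother's range center.

One seeded random stream drives everything, so a (configuration, seed) pair
reproduces every output byte.

## Worked example

The packaged `studies` module carries a ready-made seasonal food-pulse
experiment: a 4 km × 4 km agricultural matrix with sparse suitable woodlots
where food is scarce for 37 days, superabundant for 76, then scarce again.

```python
import numpy as np
from dispersim import run
from dispersim.studies import food_swap_landscape, food_swap_config
from dispersim.io_synth import summarize

landscape = food_swap_landscape(seed=2, n_animals=20)
result = run(food_swap_config(seed=1), landscape)

s = summarize(result)["overall"]
print(f"dispersers: {s['n_dispersers']}  settled: {s['n_settled']}  "
      f"mortality: {s['mortality_overall']:.2f}")
print(f"mean energy change of settlers: {s['energy_change_mean']:+.1f} "
      f"(sd {s['energy_change_sd']:.1f})")

settled = [a for a in result.animals[1] if a.status == "settled"]
pre = [a.energy - a.e_init for a in settled if a.settle_time.day < 38]
post = [a.energy - a.e_init for a in settled if a.settle_time.day >= 38]
print(f"settled before the day-38 food swap: {len(pre)}, "
      f"net energy {np.mean(pre):+.1f}")
print(f"settled after the swap: {len(post)}, net energy {np.mean(post):+.1f}")
```

prints

```
dispersers: 20  settled: 15  mortality: 0.25
mean energy change of settlers: +137.6 (sd 647.3)
settled before the day-38 food swap: 13, net energy -42.8
settled after the swap: 2, net energy +1310.0
```

Thirteen animals settled while food was still scarce and finished with a
small net energy loss; the two that were still searching when the pulse
arrived fed through it and settled far heavier — the timing of settlement
relative to the landscape change, not habitat quality per se, splits the
weight distribution. The five animals that never settled died at season end
(the 0.25 overall mortality; predation is off in this study).

There is also a CLI for file-driven runs:

```
dispersim validate config.yaml
dispersim run config.yaml --seed 5 --out-dir out/
dispersim summarize out/
```

`run` writes `step_log.csv` (one row per animal per time-step),
per-season home-range and perception-corridor GeoJSON layers, and
`summary.json`.

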