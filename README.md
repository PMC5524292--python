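# cardioresp

A closed-loop lumped-parameter (0-D) cardiorespiratory simulator that
reproduces the evolution of hemodynamics from rest to peak bicycle
exercise in severe heart failure (HF), with and without a continuous-flow
ventricular assist device (VAD), including VAD speed modulation.

The model couples:

* four cardiac chambers (time-varying elastance ventricles with an
  exponential diastolic stiffness `P = a·exp(b·V)`, atria with a
  late-diastolic contraction),
* a systemic + pulmonary Windkessel network with five parallel systemic
  districts, venous collapse laws, Starling-resistor leg veins driven by
  the pedalling muscle pump, and congestive stiffening of the pulmonary
  arterial compliance,
* baroreflex / central-command autonomic control with exercise
  set-point resetting, plus local metabolic vasodilation,
* O2/CO2 transport (Hill dissociation, alveolar gas stores) and a
  chemoreflex ventilation controller with breathing mechanics,
* an axial rotary blood pump (H-Q characteristic with inlet inertance)
  connected from LV apex to ascending aorta.

Everything is integrated as one stiff ODE system with a fixed-step
classical Runge-Kutta scheme (JIT-compiled with numba); runs are fully
deterministic and bit-reproducible.

## Quick start (CLI)

Run the packaged severe-heart-failure scenario (rest, then a ramp to
peak exercise at VO2 = 11.5 ml/min/kg), writing CSV time series, JSON
summaries and run metadata under `results/`:

```sh
cardioresp run --scenario hf --out results
```

Each phase prints its 15-cardiac-cycle steady-state summary, e.g. for
the peak-exercise phase (flows in l/min, pressures mmHg, volumes cm^3):

```
peak_exercise: {"hr": 109.8, "co": 6.66, "pas": 96.5, "pap": 47.7,
  "pwedge": 27.0, "pra": 9.4, "ved": 349.5, "ves": 288.8, "ve": 33.1,
  "avo2": 12.65, "q_lv": 6.66, "q_vad": 0.0, "ef": 17.4, "vo2": 843.7}
```

The VAD scenario adds a third phase in which pump speed is raised from
9500 to 12000 rpm at fixed workload (VO2 = 15.2 ml/min/kg):

```sh
cardioresp run --scenario hf-vad --out results
cardioresp run --scenario hf-vad --vad-speed 11000 --out results  # speed override
```

Other subcommands:

```sh
cardioresp fit-stiffness --points points.csv   # fit P = a*exp(b*V), with outlier exclusion
cardioresp summarize --result results/rest_timeseries.csv
```

## Quick start (Python)

```python
from cardioresp import engine, packaged_scenario

outcomes = engine.run_protocol(packaged_scenario("hf-vad"))
for o in outcomes:
    s = o.summary
    print(f"{o.name}: CO {s.co:.2f} l/min = native {s.q_lv:.2f} "
          f"+ pump {s.q_vad:.2f}, wedge {s.pwedge:.1f} mmHg")
```

```
rest: CO 4.30 l/min = native 0.00 + pump 4.30, wedge 13.9 mmHg
peak_exercise: CO 7.36 l/min = native 2.06 + pump 5.30, wedge 19.7 mmHg
peak_exercise_speed: CO 8.04 l/min = native 0.00 + pump 8.04, wedge 16.3 mmHg
```

At rest and at maximum speed the pump provides full support (the aortic
valve never opens); at peak exercise with baseline speed the recovering
native ventricle ejects again. Raising speed to 12000 rpm restores full
support and lowers wedge pressure, but adds comparatively little total
cardiac output.

Scenario files are plain YAML validated against a strict schema; see
`src/cardioresp/data/hf.yaml` and `hf_vad.yaml` for the two packaged
fixtures and `docs/methods.md` for the model description, units, and
calibration notes.

## Tests and acceptance targets

```sh
python -m pytest -q tests/                      # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline steady-state quantities
(cardiac output, heart rate, wedge pressure, ventilation, ejection
fraction, pump and transaortic flows at both pump speeds) from scratch
and writes them as JSON. Both packaged protocols complete in well under
a minute on a single CPU (plus one-off JIT compilation).

## Layout

```
src/cardioresp/      package (core numerics, physiology modules, config, CLI)
src/cardioresp/data/ packaged scenario fixtures (YAML)
tests/               pytest suite
scripts/acceptance.py
docs/methods.md      model equations, units, calibration
```
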