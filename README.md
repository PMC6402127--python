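# chwcea

Trial-based cost-effectiveness analysis of community health worker
(CHW) diabetes care.

Community health worker programs are a task-shifting strategy for
chronic-disease management in low-resource settings: lay workers
deliver culturally tailored home visits supporting type 2 diabetes
self-management. Whether such a program is worth funding is a
cost-effectiveness question — did the intervention's cost, net of any
savings from changed health-care utilization, buy enough health?
This package implements that analysis end to end for a
cluster-randomized CHW home-visiting trial in American Samoa
(104 intervention / 164 control patients), from the societal
perspective over a 2-year horizon, and ships both a synthetic
trial-data generator and a deterministic dataset calibrated to the
study's published tables.

## The model

For intervention arm *I* vs control *C*, the incremental
cost-effectiveness ratio is

    ICER = ΔC / ΔE

where the incremental cost ΔC per patient per year sums, over service
categories *k*, utilization difference-in-differences priced at unit
costs, plus program and patient-time costs:

    ΔC = Σ_k  DiD_k · c_k  +  c_program  +  ΔC_indirect
    DiD_k = [Σ_I(post) − Σ_I(pre)] / py_I  −  [Σ_C(post) − Σ_C(pre)] / py_C

Unit costs c_k come from activity-based micro-costing: overhead cost
centers are step-allocated to activity centers by work-management
drivers (staff, floor space, patients, inpatient-equivalent days), and
each activity center's total cost is divided by its output volume.
Program cost is quarterly consumables per visit plus fixed costs
(staff share, depreciated startup capital, donated-space opportunity
cost) spread over busiest-month throughput. Patient time is valued at
the minimum wage with time-and-a-half beyond 8 h per episode.

Effectiveness uses a surrogate-to-utility model: with utility
decrement d per HbA1c percentage point and reduction r achieved
linearly over the follow-up year,

    QALYs gained = d · r / 2

The ICER is classified (interior / dominant / dominated / undefined)
and compared against willingness-to-pay thresholds λ from $39 000
(3× local GDP per capita) to $154 353 (3× US GDP per capita) per QALY,
with one-way sensitivity analysis over the effect and the decrement.

## Worked example

```python
from chwcea import DiabetesCEA

results = DiabetesCEA.from_fixture().fit()   # calibrated study dataset
print(results.summary())
```

prints (abbreviated):

```
Incremental cost-effectiveness
------------------------------------------------------------------------
Incremental cost                               $594.27
HbA1c reduced (percentage points)                 0.53
QALYs gained                                   0.04505
ICER (per HbA1c point)                       $1 121.26
ICER (per QALY)                             $13 191.34
Dominance classification                      interior

Service utilization and cost differences (per patient per year)
------------------------------------------------------------------------
                                       Utilization DiD        Cost DiD
Intervention (use)                                1.00         $677.43
ED (visits)                                      -0.61         -$83.77
Ambulatory (visits)                              -0.18         -$38.38
Hospitalizations (inpatient days)                -0.14          $19.29
Surgery (procedures)                             -0.10         -$12.92
Intervention indirect (hours)                    10.03          $47.76
Medical indirect (hours)                         -3.74         -$15.14
Total                                                          $594.27
```

Reading: the program itself cost $677.43 per participant, partly
offset by fewer ED and ambulatory visits; hospitalization costs rose
slightly despite fewer inpatient days because ICU days (expensive)
increased; the net $594.27 bought a 0.53-point HbA1c reduction, i.e.
0.04505 QALYs, so each QALY cost ≈ $13 191 — cost-effective at every
threshold considered (the strictest being $39 000/QALY). A one-way
sensitivity run with a conservative utility decrement:

```python
sens = results.sensitivity({"utility_decrement": [0.03, 0.17]})
print(sens.max_icer)   # 74750.94 — above $50 000, below 2x US GDP per capita
```

Synthetic data with known ground truth, and the CLI:

```bash
chwcea simulate --seed 7 --out-dir data/   # cluster-randomized tables
chwcea fixture --out-dir fixture/          # the calibrated dataset
chwcea run --in-dir fixture/ --out-dir out/
```

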