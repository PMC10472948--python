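# strokecea

Decision-analytic cost-effectiveness modelling of intravenous thrombolysis
strategies for acute ischemic stroke: **tenecteplase 0.25 mg/kg versus
alteplase 0.9 mg/kg**, from a healthcare-payer perspective.

The model couples a 90-day decision tree (thrombolysis costs, optional
endovascular thrombectomy for large-vessel occlusion, 90-day modified Rankin
Scale outcomes) to a five-state Markov cohort model
(mRS 0–1, mRS 2–3, mRS 4, mRS 5, dead) that runs in annual cycles to a
10-year horizon, merging disease-specific transitions with age-based
background mortality by independent competing risks. Discounted totals feed
the standard comparison statistics

- **ICER** = ΔC/ΔE with dominance classification on the CE plane,
- **INMB** = ΔE·λ − ΔC at willingness-to-pay thresholds λ (€50k/€80k per QALY),

plus one-way (tornado) sensitivity at ±20 %, probabilistic sensitivity
analysis (10,000 Monte-Carlo draws; Dirichlet outcome vectors, beta
utilities, gamma costs) with cost-effectiveness acceptability curves, and a
declarative scenario runner. It is aimed at health-economics researchers who
want a scriptable, testable alternative to spreadsheet/TreeAge models whose
every input is a diffable YAML document.

## Worked example

```python
from strokecea import fixtures
from strokecea.economics import compare_arms

spec = fixtures.paper_base_fixture()   # trial-anchored base case
result = compare_arms(spec)
print(result.as_dataframe().to_string(index=False))
```

```
   treatment          cost  increment_cost     qaly  increment_qaly     icer  inmb_50000  inmb_80000
   alteplase  73908.638624             NaN 3.772944             NaN     None         NaN         NaN
tenecteplase  73124.075087     -784.563537 3.846721        0.073777 dominant 4473.403781 6686.707927
```

Over ten years the tenecteplase cohort gains 0.074 QALYs and saves €785 per
patient — tenecteplase *dominates* alteplase (cheaper and more effective), so
no ICER ratio is reported and the incremental net monetary benefit at
€50,000/QALY is €4,473. The higher tenecteplase drug price (€987 vs €791) is
more than offset by the cheaper long-term state mix that follows from better
90-day outcomes (mRS 0–1: 36.9 % vs 34.8 %; death: 15.1 % vs 15.6 %).

The numbered drivers under `analysis/` run the full study and write CSV
tables to `results/`:

```bash
python analysis/01_base_case.py    # two-arm summary + accrual breakdowns
python analysis/02_scenarios.py    # base case + six scenarios
python analysis/03_tornado.py      # one-way sensitivity at €50k/QALY
python analysis/04_psa.py          # 10,000-draw PSA, CE plane + CEAC
```

The same pipeline is available as a CLI over any configuration file:

```bash
strokecea fixtures --out configs          # emit the built-in YAML configs
strokecea run --config configs/paper_base.yaml --out results
strokecea tornado --config configs/paper_base.yaml --lambda 50000
strokecea psa --config configs/paper_base.yaml --seed 7 --n 10000
strokecea scenarios --config configs/paper_base.yaml
```

Every parameter in the emitted YAML carries a provenance tag
(`paper-text` for publicly printed anchors, `assumption` for declared
fixture values); replacing assumption cells with your own parameter tables
is a plain text edit. See `docs/methods.md` for the model's assumptions,
conventions and limitations.

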