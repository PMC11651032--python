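# delphi-codes

A tested, reusable implementation of a Delphi consensus pipeline for
classifying ICD-9-CM diagnosis and procedure codes as **for inclusion**
— a clinical condition for which systemic (oral/IV) antibiotic or
antifungal therapy is administered in at least 60% of hospital stays —
or **for exclusion**. Code lists validated this way support
antimicrobial-stewardship (AMS) surveillance: in settings where drug
prescriptions are not centrally computerized, hospital discharge
records coded in ICD-9-CM may be the only scalable signal of
antimicrobial consumption.

The package is aimed at epidemiologists and biostatisticians running
(or replicating) expert-panel consensus procedures over large code
sets: it provides the agreement statistic, the round-iteration engine,
strict file-format handling, and a seeded synthetic panel for testing
every stage at full scale.

## The procedure

1. **Dual review.** Two specialists independently classify every code
   by the ≥60% rule; a third reviewer adjudicates discordant pairs.
2. **Panel voting.** An expert panel (18 voting units in
   study-replication mode) scores its agreement with each proposed
   classification on a 9-point Likert scale (1 = totally disagree,
   9 = totally agree).
3. **Agreement rule.** For each code, with panel quartiles
   (q₁, median, q₃) and IQR = q₃ − q₁, the RAND/UCLA disagreement
   threshold is

       IPRAS = 2.35 + 1.5 · |5 − (q₁ + q₃)/2|

   The round outcome is tripartite:
   - median ≥ 7 and IQR ≤ IPRAS → **agreement** (proposal endorsed);
   - median < 4 → **agreement** (proposal rejected, hence overturned);
   - median in [4, 7), or median ≥ 7 with IQR > IPRAS → **no
     agreement**: the code is re-voted in the next round.
4. **Iteration** until every code reaches agreement (with an explicit
   partial outcome if a round cap is hit).

Quantile convention, the IPRAS constants, cut points, and the
low-median dispersion rule are all configurable
(`AgreementConfig`); the defaults are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from delphi_codes import (
    classify_round, simulate_study, run_delphi, flow_summary, SimulationConfig,
)

# A polarized panel: 6 votes in the low tail, 12 in the high tail.
res = classify_round([1] * 6 + [9] * 12)
print(f"median={res.median}, IQR={res.iqr}, IPRAS={res.ipras:.2f}, "
      f"status={res.status.value}")

# A tight high panel: nine 7s and nine 8s.
res2 = classify_round([7] * 9 + [8] * 9)
print(f"median={res2.median}, IQR={res2.iqr}, IPRAS={res2.ipras:.2f}, "
      f"status={res2.status.value}")

# A full study-scale synthetic run: 16,227 codes, 18 panelists.
codes, latents, proposals, source = simulate_study(SimulationConfig(seed=42))
outcome = run_delphi(proposals, source)
summary = flow_summary(outcome)
print(f"{summary.total_codes} codes, {summary.rounds_used} rounds")
print(f"round 1: {summary.round1_agreed} agreed "
      f"({summary.round1_included} in / {summary.round1_excluded} out), "
      f"{summary.contested} re-voted")
print(f"final: {summary.final_included} for inclusion "
      f"({100 * summary.final_included / summary.total_codes:.1f}%)")
```

prints

```
median=9.0, IQR=8.0, IPRAS=2.35, status=no_agreement
median=7.5, IQR=1.0, IPRAS=6.10, status=agree_high
16227 codes, 2 rounds
round 1: 16148 agreed (3170 in / 12978 out), 79 re-voted
final: 3207 for inclusion (19.8%)
```

The first panel is polarized: its interquartile midpoint sits on the
scale center, so IPRAS takes its 2.35 floor and the IQR of 8 far
exceeds it — no agreement, re-vote. The second panel is tight and
high: IQR 1 is well inside the threshold, so the proposal is endorsed.
The study-scale run reproduces the characteristic shape of the
procedure — the overwhelming majority of codes settle in round one, a
fraction of a percent are genuinely contested, and the panel converges
on all of them in round two, ending with roughly one code in five
classified for inclusion.

## Command line

```
delphi-codes simulate --seed 42 --out fixtures/          # synthetic study dataset
delphi-codes run --proposals fixtures/proposals.csv \
    --votes fixtures/round_1.csv --votes fixtures/round_2.csv \
    --roster-size 18 --out outcome/
delphi-codes report --outcome outcome/ --codes fixtures/codes.csv --out report/
```

`run` exits nonzero if any code remains unresolved. File formats are
plain delimited text; see the module docstrings in
`src/delphi_codes/` for the exact schemas.

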