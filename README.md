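# markovcua

Markov cohort cost-utility analysis of **proton beam therapy (PBT)**
versus **three-dimensional conformal radiotherapy (3D-CRT)** in definitive
chemoradiotherapy for locally advanced esophageal cancer, from the
perspective of Japan's social-insurance payer.

Chemoradiotherapy with photons can injure the lung, pleura and
pericardium; proton beams spare those organs, so the clinical question is
whether the much higher proton fee is justified by the quality-of-life
gained through fewer late toxicities — under the stringent assumption
that overall and progression-free survival are identical in both arms.

## Who this is for

Health-economics and HTA analysts who want a fully scriptable,
reproducible implementation of this evaluation: the deterministic base
case, one-way (tornado) sensitivity analysis, and probabilistic
sensitivity analysis (PSA) with cost-effectiveness acceptability curves
(CEACs) — plus the machinery to swap in their own parameter tables.

## The model

A decision tree chooses the arm; each arm then runs the same Markov
cohort model with 3-month cycles over a 60-month horizon:

* **States.** Event-free ("no late adverse events"), radiation
  pneumonitis (RP) Grades 1–3, pleural effusion (PE) Grades 1–3,
  pericardial effusion (PCE) Grades 2–3, three overlap states
  (RP1+PE1, RP1+PCE2, PCE3+PE2), one-cycle tunnel states for pericardial
  drainage and pericardiotomy, resolved PCE, best supportive care (BSC)
  and death.
* **Transitions.** Per-cycle onset probabilities from the event-free
  state, arm-specific and time-windowed (RP onset during the first year;
  PE/PCE onset until the table's zero rows apply); recovery transitions
  between grades; a shared per-cycle hazard of 0.0542 from every alive
  state to BSC (identical survival by assumption); BSC lasts one cycle
  and ends in death.
* **Outcomes.** Effectiveness is quality-adjusted life years:
  `E = Σ_k d(k) Σ_s occ_k(s) · u(s) · ¼`, with utility weights `u` in
  [0, 1] and annual discounting `d(k) = 1.03^(−k/4)`.  Costs (integer
  yen, social-insurance fees) combine the upfront radiotherapy +
  admission/chemotherapy fee, per-cycle follow-up, per-cycle treatment
  costs, and one-off hospitalization costs charged on state entry.
* **Decision rule.** The incremental cost-effectiveness ratio
  `ICER = ΔC/ΔE` is compared with Japan's willingness-to-pay threshold
  for anticancer therapy, 7,500,000 yen per QALY.  Two base cases differ
  only in the proton fee: 2,375,000 yen (*rare*-cancer fee schedule) or
  1,600,000 yen (*non-rare*).

Sensitivity analyses perturb every utility, cost and transition
probability: ±20% one-at-a-time for the tornado ranking, and
Triangular(0.8·b, b, 1.2·b) draws with utility grade-ordering enforcement
for the PSA.  See `docs/methods.md` for every convention and assumption.

## Worked example

```python
from markovcua import run_base_case

res = run_base_case("rare")
print(res.cea.icer, res.verdict)
```

or, from the shell, `python examples/base_case.py`, which prints:

```
=== rare cancer fee level ===
  PBT    cost    4,458,794 yen   effectiveness 2.6094 QALY
  3DCRT  cost    2,919,440 yen   effectiveness 2.4988 QALY
  incremental cost    1,539,354 yen
  incremental effectiveness 0.1107 QALY
  ICER 13,909,384 yen/QALY -> not cost-effective at 7,500,000 yen/QALY

=== non_rare cancer fee level ===
  PBT    cost    3,683,794 yen   effectiveness 2.6094 QALY
  3DCRT  cost    2,919,440 yen   effectiveness 2.4988 QALY
  incremental cost      764,354 yen
  incremental effectiveness 0.1107 QALY
  ICER 6,906,594 yen/QALY -> cost-effective at 7,500,000 yen/QALY
```

Reading: proton therapy gains 0.1107 discounted QALYs by avoiding severe
pneumonitis and pericardial/pleural effusions.  At the higher fee the
extra cost works out to ~13.9M yen per QALY gained — above the 7.5M
threshold, so not cost-effective; at the lower fee it is ~6.9M yen/QALY
and passes.  The same flip appears probabilistically
(`python examples/psa_ceac.py`): the proton arm is cost-effective at the
threshold in 21.3% of 1000 PSA draws under the rare fee and 54.4% under
the non-rare fee.

Other examples: `examples/tornado.py` (parameter ranking),
`examples/custom_model.py` (your own YAML configurations),
`examples/microsim_check.py` (patient-level cross-validation).

## Command line

Every analysis is also a CLI verb with CSV/JSON outputs and a run
manifest:

```sh
markovcua base-case --fee-level rare
markovcua owsa --fee-level rare --outdir out/ --figure
markovcua psa --fee-level non_rare --n-draws 1000 --seed 20240927 --outdir out/
markovcua validate my_model.yaml
markovcua make-synthetic demo.yaml --seed 7
markovcua microsim-check --n 100000
```

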