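# agnor-screen

Analysis pipeline for AgNOR-based oral-cancer screening: synthetic
silver-stained cytology smears with exact ground truth, automated
per-nucleus dot counting, patient/group summary tables, ROC diagnostic
cut-offs, and human-vs-automated agreement statistics.

## The problem

Argyrophilic nucleolar organizer regions (AgNORs) are silver-stainable
nucleolar proteins that appear as well-defined dark dots inside the
nucleus of an exfoliative cytology smear. The number of dots per
nucleus reflects cell-proliferation rate and increases from healthy oral
mucosa through potentially malignant disorders to squamous cell
carcinoma, which makes the per-patient mean AgNORs/nucleus a cheap,
minimally invasive screening marker. Turning that marker into a
screening decision needs four pieces, all implemented here for anyone
studying AgNOR quantification or validating automated counters:

- **Counting rules.** Each well-defined dark intranuclear dot is one
  NOR; overlapping or fused dots count as a single structure; nuclei
  that overlap another nucleus, touch the annotation box edge, carry no
  label, or cannot be segmented are excluded with an explicit reason
  (`agnor_screen.quantify`).
- **Summaries.** The unit of analysis is the patient: mean
  AgNORs/nucleus over the analyzable cells, and the percentage of cells
  with 1, 2, 3, 4 and 5+ dots; groups report mean ± SD of patient means
  (`agnor_screen.summarize`).
- **Diagnostics.** A smear is suspicious when the patient mean is at or
  above a cut-off. The cut-off is the ROC point closest to perfect
  sensitivity and specificity, i.e. the threshold t minimizing
  (1 − sens(t))² + (1 − spec(t))²; the AUC is the Mann-Whitney statistic
  P(case > control) + ½P(tie). The supporting power computation for a
  two-group mean difference is n = ⌈(z₁₋α/₂ + z_power)²(σ₁² + σ₂²)/Δ²⌉
  (`agnor_screen.diagnostics`).
- **Agreement.** Human vs automated counts on the same nuclei are
  compared with the intraclass correlation ICC(A,1) — two-way, single
  measures, absolute agreement — with F-based confidence intervals;
  ICC ≥ 0.75 is read as good reliability (`agnor_screen.agreement`).

Because no public AgNOR smear dataset exists, `agnor_screen.synthetic_data`
generates both cohorts (per-cell counts with the published group
structure: CG 2.89 ± 0.62 up to OSCCG 4.08 ± 0.46 mean AgNORs/nucleus)
and rendered smear images with per-nucleus ground truth, including
fused-dot and overlapping-nucleus cases, so every stage is testable end
to end.

## Worked example

```python
from agnor_screen import synthetic_data as sd, summarize as sm, diagnostics as dx

cells = sd.simulate_cohort(sd.default_group_params(),
                           n_per_group=15, cells_per_patient=50, seed=42)
patients = sm.summarize_cohort(cells)
print(sm.group_table(patients).round(2).to_string(index=False))

ref  = patients.loc[patients.group_id == "CG",    "mean_nors"].to_numpy()
case = patients.loc[patients.group_id == "OSCCG", "mean_nors"].to_numpy()
res = dx.evaluate_contrast(ref, case, "CG", "OSCCG")
print(f"CG vs OSCCG: AUC {res.auc:.2f}, cut-off {res.cutoff:.2f}, "
      f"sens {res.sens:.2f}, spec {res.spec:.2f}, accuracy {res.accuracy:.2f}")
```

prints

```
group_id  n_patients  mean_nors  sd_nors  pct_1  pct_2  pct_3  pct_4  pct_5plus  top_class
      CG          15       2.80     0.56  19.07  30.13  22.80  18.53       9.47          2
      EG          15       3.47     0.71  12.53  20.93  26.53  15.33      24.67          3
   OPMDG          15       3.25     0.88  14.40  20.53  26.27  24.40      14.40          3
   OSCCG          15       3.98     0.58   4.00  14.80  23.47  26.40      31.33          5

CG vs OSCCG: AUC 0.93, cut-off 3.56, sens 0.87, spec 0.93, accuracy 0.90
```

The group table recovers the simulated means within sampling error of a
15-patient cohort; the control profile peaks at 2 dots/nucleus while the
carcinoma profile peaks at 5+. The contrast line says a cut-off of 3.56
mean AgNORs/nucleus separates carcinoma from control patients with 87%
sensitivity and 93% specificity in this replicate.

The same pipeline runs from a shell:

```bash
agnor-screen run-all --seed 17 --out results/
```

writes `cohort.csv`, rendered slides with LabelMe annotations,
per-nucleus counts with exclusion reasons, patient/group tables,
diagnostics for all six group contrasts, and the truth-vs-automated
agreement CSV. Each stage is also available as its own subcommand
(`simulate-cohort`, `render`, `quantify`, `summarize`, `diagnose`,
`agree`).

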