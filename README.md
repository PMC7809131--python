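# exmirna

Statistical analysis of infant plasma extracellular miRNA (exmiRNA) panels
as biomarkers of prenatal alcohol exposure (PAE). The package implements
the full analysis chain for a two-group infant cohort assayed on 2×384-well
qPCR miRNA panels (752 assays) at two postnatal ages: panel quality
control and ΔCT normalization, covariate-adjusted effect-size screening,
within-group co-expression networks with chromosomal annotation,
confirmatory factor analysis (CFA) with a small-sample correction and
reliability coefficients, mediation of exposure effects on growth and
cognition, and Monte Carlo power simulation — plus a synthetic-cohort
generator with exported ground truth so every stage can be exercised and
validated without access to the original cohort.

It is intended for biostatisticians and epidemiologists working with
small-cohort qPCR biomarker panels.

## Methods at a glance

- **Normalization.** Each sample's expressed-miRNA CT values are centered
  at their global mean: ΔCT = CT − mean(CT). Lower ΔCT means higher
  expression; a unit change is a twofold expression difference.
  Non-detects are imputed per miRNA as max(detected CT) + 1; samples fail
  hemolysis QC only when A414 > 0.3 **and** ΔCT(miR-23a − miR-451a) > 7;
  miRNAs count as expressed when detected in ≥ 80% of one group × age
  cell.
- **Effect sizes.** Per miRNA, an ANCOVA (ΔCT ~ group + cigarettes/day)
  supplies adjusted means; Cohen's *d* = (x̄_C − x̄_E)/s_pooled with
  Hedges' g = J·d, J = 1 − 3/(4(n−2)−1), and a normal-approximation 95% CI
  with SE = √((n_C+n_E)/(n_C n_E) + d²/(2(n_C+n_E))). Screening keeps
  |d| ≥ 0.40 (U3 = Φ(d) ≈ 66%, OR = exp(dπ/√3) ≥ 2, BESD ≈ 20 points).
  A 2000-iteration bootstrap, stratified by group and run combined and
  per sex, classifies sex-specific responses.
- **CFA.** Σ(θ) = ΛΦΛᵀ + Ψ fitted by minimizing the ML discrepancy
  F = log|Σ| + tr(SΣ⁻¹) − log|S| − p with analytic gradients; χ² = (n−1)F;
  CFI/TLI/RMSEA/SRMR, AIC/BIC/SABIC, nested Δχ² tests; Bartlett's factor
  1 − (4k+2p+5)/(6n) (n = sample size + 1); ω = (Σλ)²/((Σλ)² + ΣVar(ε) +
  2Σcov(ε)) and maximal reliability H = Σ(l²/(1−l²))/(1 + Σ(l²/(1−l²))).
- **Mediation.** Standardized paths a (exposure→factor score), b
  (factor→outcome, exposure-adjusted), c′ (direct); the specific indirect
  effect is a·b with a Sobel z-test and a bias-corrected bootstrap CI
  (10,000 case resamples by default); total = c′ + a·b exactly.
- **Power.** Monte Carlo operating characteristics (power, 95%-interval
  coverage, percentage bias 100·(mean θ̂ − θ)/θ) for the 3-factor CFA
  (loadings 0.50, factor covariances 0.50, residual variances 0.75,
  n = 59) and the standardized mediation system (all paths 0.40, n = 58).

## Worked example

```python
import pandas as pd
from exmirna import (CohortConfig, generate_cohort, generate_ct_panel,
                     run_qc, compute_effects, screen_by_effect)
from exmirna.cfa import CFAModel, CfaSpec

config = CohortConfig(seed=7)            # 31 control / 37 exposed infants
records, truth = generate_cohort(config)
newborn = [r for r in records if r.timepoint == "T2wk"]
panel = generate_ct_panel(newborn, config)
meta = pd.DataFrame(
    {"group": [r.group for r in newborn],
     "cigarettes_per_day": [r.cigarettes_per_day for r in newborn]},
    index=[r.sample_id for r in newborn])

expr, report = run_qc(panel, meta["group"])
effects = compute_effects(expr.delta_ct, meta["group"],
                          meta["cigarettes_per_day"])
screen = screen_by_effect(effects, cutoff=0.40)

spec = CfaSpec({"F1": truth.responsive_ids[:8],
                "F2": truth.responsive_ids[8:13],
                "F3": truth.responsive_ids[13:]})
model = CFAModel(spec).fit(expr.delta_ct.loc[spec.items].T)
```

This prints (via the obvious `print` calls):

```
148 expressed miRNAs, 483 non-detects imputed
screened 25 miRNAs at |d| >= 0.40, 16 with CI excluding zero
                  d      g  ci_low  ci_high      p
MIMAT9000015  0.763  0.755   0.269    1.258  0.003
MIMAT9000016  0.798  0.788   0.302    1.293  0.002
MIMAT9000017  0.973  0.962   0.468    1.477  0.000
3-factor CFA: chi2(132) = 140.19, CFI = 0.936, RMSEA = 0.030
Bartlett-corrected: chi2 = 122.24 (factor 0.872), p = 0.717
omega(F1) = 0.462, H(F1) = 0.513
```

Reading this: of 148 reliably detected miRNAs, 25 differ between exposed
and control infants with at least a medium effect; the configured true
effects (d up to 0.9 on the last responsive assays) are recovered with
CIs excluding zero. The 3-factor measurement model fits (CFI > 0.9,
RMSEA < 0.05) and the Bartlett correction, appropriate at n = 68, moves
the omnibus test further from rejection. ω and H quantify how reliably
the factor-score composites measure the latent expression dimensions.

The same pipeline is scriptable from the shell:

```bash
exmirna simulate --out sim --seed 7
exmirna qc --ct sim/ct_T2wk.tsv --metadata sim/metadata.csv \
           --hemolysis sim/hemolysis_T2wk.csv --out qc
exmirna run --out full_run --seed 7     # all stages + manifest.json
```

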