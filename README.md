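# combostat

Statistical detection of synergy and antagonism in two-drug combination
viability screens.

Checkerboard screens expose cells to all pairs of two concentration ladders
(I non-zero concentrations of drug A, J of drug B, plus single-drug rows and
untreated controls), replicated over K plates, and read out a survival index
S(i, j, k) per well. `combostat` answers the question *does this drug pair
interact?* against both of the field's null models:

* **Bliss independence** — the combination survives as the product of the
  single-drug survivals: `S(cA, cB) = S(cA, 0) · S(0, cB)`;
* **Loewe additivity** — the combination behaves as a dilution of one drug;
  concentration pairs of equal effect lie on straight isoboles,
  `cA / R_A⁻¹(s) + cB / R_B⁻¹(s) = 1`, with the single-drug
  concentration-response curves `R` fitted as two-parameter Hill models
  `R(c) = 1 / (1 + (c/c50)^H)`.

Per well, the interaction index is *model-predicted minus observed mean
survival* (`I(i,j) > 0` = synergy direction). Uncertainty is quantified by a
non-parametric residual bootstrap that respects **heteroscedasticity**:
each well resamples residuals only from the 10% of wells with the closest
mean survival, with random sign flips (symmetric but otherwise arbitrary
error distribution). The headline inference is a **global (omnibus) test**
on the extremal index — observed `I_max` against the upper 2.5% tail of its
resampled null distribution (and `I_min` against the lower tail for
antagonism) — which tests all wells at once without a Bonferroni-style
correction. A drug pair is called synergistic (`X`) or antagonistic (`O`)
only when **both** models reject; `--` means neither joint call, `NA` means
the Loewe analysis was impossible (essentially flat single-drug response).

Raw fluorescence input is supported (blank/control normalization, assay QC:
control/blank ratio > 5, control CV < 30%) and replicates are screened by
iterative CV-based outlier removal. A synthetic-screen generator with known
ground truth (Hill, Loewe-additive or exponential surfaces, level-dependent
noise, injectable interactions and outliers) makes every stage testable.

## Worked example

Simulate a 9×7 checkerboard (K = 4 plates) with a synergistic shift of 0.25
injected at one well, then analyze it:

```python
import json
from combostat import AnalysisConfig, SimSpec, make_batch, run_analysis
from combostat.plate_io import write_plate_csv

spec = SimSpec(seed=5, interaction_map={(3, 3): 0.25})
write_plate_csv(make_batch(spec), "screen.csv")

result = run_analysis(AnalysisConfig(seed=11), "screen.csv", "out")
summary = json.load(open("out/summary.json"))
print(summary["joint_symbol"], summary["bliss"]["observed_Imax"])
```

This run prints `X 0.2560`: the observed Bliss `I_max` of 0.256 exceeds its
bootstrap null bound of 0.195, the Loewe `I_max` of 0.214 exceeds its bound
of 0.116, so both omnibus synergy tests reject and the joint call is `X`
(neither antagonism test rejects: observed `I_min` −0.079 and −0.062 stay
above the lower bounds −0.185 and −0.125). The fitted Hill curves recover
the generating parameters (c50 ≈ 0.956/5.32, H ≈ 2.02/0.88 versus true
1/5 and 2/1). `out/` also contains per-well index matrices with their
bootstrap intervals as CSV and the run configuration.

The same pipeline is available from the shell:

```sh
combostat simulate --out screen.csv --seed 5
combostat analyze --input screen.csv --out results --seed 11
```

## Layout

| module | contents |
| --- | --- |
| `combostat.plate_io` | long-format CSV schema, `ConcentrationGrid`, `PlateBatch`, result writing |
| `combostat.preprocess` | survival index, assay QC, CV-based outlier removal |
| `combostat.doseresponse` | Hill model: evaluation, exact inverse, least-squares fit |
| `combostat.synergy_models` | Bliss/Loewe per-well indices, isobole inversion |
| `combostat.bootstrap_stats` | residual pools, screen resampling, omnibus + per-well calls |
| `combostat.simulate` | ground-truth surfaces, noise/outlier injection, fixtures |
| `combostat.cli_report` | pipeline orchestration, network figures, `combostat` CLI |

See `docs/methods.md` for the statistical details and design choices.
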