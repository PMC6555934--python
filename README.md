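# nbreg — net benefit regression for trial-based cost-effectiveness analysis

`nbreg` analyzes person-level cost-effectiveness data from a two-arm trial:
one row per patient with a treatment indicator TX (1 = new treatment, 0 =
usual care), a cost `c_i` and a health effect `e_i` (typically QALYs). It is
aimed at health economists and trial statisticians who want regression-based
economic evaluation — covariate adjustment, subgroup interactions, and honest
uncertainty for the cost-effectiveness summary — without leaving a standard
OLS workflow.

## The method

The conventional summary is the incremental cost-effectiveness ratio,

    ICER = ΔC / ΔE,

where ΔC and ΔE are the between-arm differences in expected cost and effect.
Both are estimated as the TX coefficient of an OLS regression of cost or
effect on TX (plus optional covariates). Ratios are awkward statistically
(no finite moments, sign ambiguity when ΔC and ΔE disagree in sign), so the
package centers on the **incremental net benefit**. For a willingness-to-pay
threshold λ ($/QALY), each patient's net benefit is

    NB_i = λ · e_i − c_i,

and regressing NB on TX gives the treatment coefficient

    INB(λ) = λ·ΔE − ΔC,

whose confidence interval is exact OLS machinery that *includes* the
cost-effect correlation (separate cost and effect CIs do not). As a function
of λ, INB is a line with y-intercept −ΔC, slope ΔE and x-intercept at the
ICER; the WTP values where the INB confidence bounds cross zero are the
Fieller's-theorem confidence limits for the ICER. Sweeping λ over a grid
yields the INB-by-WTP curve and, from one-sided p-values (or bootstrap
resampling), the cost-effectiveness acceptability curve (CEAC): the
probability the new treatment is cost-effective at each λ.

Mixed-sign (dominant / dominated) estimates suppress the ICER and report the
quadrant label instead — the INB stays well-defined there, which is the point
of the framework.

## Worked example

Real trial-level cost data are rarely shareable, so the package ships a
synthetic-trial generator with a preset that emulates a two-stratum biomarker
trial (strata of 150 and 216 patients; per-stratum incremental truths
ΔC = $13,787 / $30,843 and ΔE = −0.0172 / 0.1769 QALYs):

```bash
nbreg simulate --preset co17 --seed 11 --out sim.csv
nbreg analyze --input sim.csv --subgroup-col subgroup --outdir out \
              --bootstrap 500 --seed 4
```

`out/incremental_summary_formatted.csv` then contains (seed 11):

| group | n   | effect (ΔE)      | cost (ΔC)         | NB($0)            | NB($200k)       | NB($500k)         |
|-------|-----|------------------|-------------------|-------------------|-----------------|-------------------|
| MUT   | 150 | 0.0019 (0.9502)  | 13,431 (< 0.0001) | −13,431 (< 0.0001)| −13,043 (0.0260)| −12,460 (0.4027)  |
| WT    | 216 | 0.1789 (< 0.0001)| 33,149 (< 0.0001) | −33,149 (< 0.0001)| 2,634 (0.6246)  | 56,309 (< 0.0001) |
| ALL   | 366 | 0.1064 (< 0.0001)| 25,068 (< 0.0001) | −25,068 (< 0.0001)| −3,791 (0.3425) | 28,125 (0.0045)   |

Reading the WT row: the new treatment costs $33,149 more per patient and
gains 0.1789 QALYs; its INB turns positive between λ = $150k and $200k,
consistent with the ICER block in `out/icer.json`:

```json
"WT": {"icer": 185278, "quadrant": "trade-off",
       "fieller_lower": 138542, "fieller_upper": 258357}
```

i.e. a point ICER of $185,278/QALY with a Fieller 95% CI of roughly
$138.5k–$258.4k — the WTP range over which the INB confidence bounds cross
zero. `out/ceac.csv` holds the parametric and bootstrap acceptability curves,
and `out/interaction_table.csv` the treatment-by-subgroup interaction fits
across the WTP grid. (Note the MUT stratum's ΔE is generated around a
slightly *negative* truth; at n = 150 a given seed may estimate either sign.)

The same analysis is available as a library:

```python
import nbreg

ds = nbreg.generate(nbreg.co17_like_preset(), seed=11).filter_subgroup("WT")
curve = nbreg.sweep_inb(ds, nbreg.DEFAULT_WTP_GRID)
print(curve.zero_crossing)        # point ICER ~ 185278
print(curve.ci_crossings)         # Fieller interval
print(nbreg.extrapolate_inb(-13154, 100_000, 123_456, 0.1769))  # -9005
```

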