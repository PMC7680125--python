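# nucshift

Detecting nucleosome repositioning from MNase-seq dyad maps, with the
statistics used to characterize the chromatin remodeler driving it.

ATP-dependent chromatin remodelers such as yeast ISW1a set the spacing of
the +1, +2, … nucleosome arrays downstream of transcription start sites.
When a remodeler (or one of its subunits) is lost, nucleosomes drift —
typically ~10 bp downstream at the +2 position and beyond — and detecting
that drift genome-wide takes a specific chain of analysis: fragment
midpoints → normalized dyad-density tracks → greedy nucleosome calls →
between-condition matching → a per-nucleosome shift test → +1-aligned
metagene summaries. `nucshift` implements that chain end to end, together
with the gene-set overlap statistic used to compare the resulting gene
lists and the quantitative biochemistry (Hill binding fits, initial
remodeling/ATPase rates, fold-ratio comparisons) used to characterize the
remodeler in vitro. A seeded synthetic-data generator produces every
input the pipeline consumes, so all claims are testable at desk scale.

## The statistics at the core

- **Dyad track.** Fragment dyad = `⌊(start + end − 1)/2⌋`; per-bp counts
  normalized so the mean over non-excluded positions is 1.
- **Nucleosome calls.** Gaussian-smoothed track (σ = 20 bp), greedy peak
  picking with a 147 bp exclusion zone; each call reports dyad position,
  dyad SD *s* and occupancy *n* over its 147 bp footprint.
- **Shift test.** Calls match across conditions when footprints overlap
  ≥ 73 bp (|Δ| ≤ 74 bp). Each pair is tested with Welch's t,

      t = (m_A − m_B) / √(s_A²/n_A + s_B²/n_B),

  Welch–Satterthwaite df, two-sided p, significant at p < 0.01. Shifts
  are signed along the gene (positive = downstream, away from the TSS)
  and summarized as the **median shift per array position** over genes
  (> 560 bp, ≥ 4 nucleosomes) aligned at their wild-type +1 dyad.
- **Gene-set overlap.** Hypergeometric enrichment,
  P(X ≥ x) with P(X = x) = C(D,x)·C(N−D,n−x)/C(N,n), in exact
  log-binomial arithmetic.
- **Binding & kinetics.** Hill fits f([E]) = [E]^H/(K_D^H + [E]^H) with
  profile-likelihood 95% CIs and R²; initial rates v0 from a saturating
  exponential with delta-method errors; fold ratios with conventional
  rounding.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Run the shipped demo: 40 genes with five-nucleosome arrays (165 bp
spacing, 20 bp dyad fuzziness, 300 fragments per nucleosome); the mutant
condition has its +2/+3/+4 nucleosomes programmed 10 bp downstream.

```sh
nucshift run --config examples/demo_config.yaml --out-dir demo_run
```

```
 position_index  median_shift  mean_shift  n
              1           0.0      -0.450 40
              2          10.0      10.000 40
              3          10.5      10.175 40
              4          10.0       9.600 40
```

The pipeline recovers the programmed repositioning: the +1 nucleosome is
unmoved (median 0 bp), while +2..+4 sit ~10 bp downstream in the mutant;
120 of 200 matched pairs are significant at p < 0.01 (the 120 truly
shifted nucleosomes), and all 40 genes are selected as shifted. The run
directory contains every stage output (fragment BEDs, bedGraph tracks,
call and shift TSVs, the metagene profile) plus `provenance.json`.

The same objects are available as a library, statsmodels-style, for the
biochemistry:

```python
from nucshift import synth
from nucshift.bindkin import HillModel, fold_ratio

curve = synth.simulate_titration(5.29, 1.43, [0, 0.5, 1, 2, 4, 6, 10, 15, 20, 30, 45, 60],
                                 noise_sd=0.03, replicates=3, seed=20000)
print(HillModel.from_dataframe(curve).fit().summary())
print(fold_ratio(0.77, 0.060))   # initial rates in nM/s
```

```
Hill equation fit (fraction bound vs concentration)
  n points      : 36
  K_D (nM)      : 5.33   95% CI [5.05, 5.61]
  H             : 1.43   95% CI [1.34, 1.53]
  R^2           : 0.9934
  CI method     : profile
  converged     : True
13x
```

A titration simulated at a dinucleosome affinity of K_D = 5.29 nM with
Hill coefficient 1.43 is recovered within its confidence interval, and a
0.77 vs 0.060 nM s⁻¹ rate comparison reads as 13-fold.

Other subcommands: `simulate`, `dyads`, `call`, `shift`, `metagene`,
`overlap`, `hillfit`, `ratefit` (see `nucshift --help`).

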