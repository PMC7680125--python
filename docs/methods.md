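# Methods

`nucshift` implements a desk-scale, fully testable version of the analysis
used to detect ATP-dependent remodeler-driven nucleosome repositioning in
yeast: MNase-seq dyad maps, greedy nucleosome calling, overlap matching
between conditions with a Welch shift test, +1-aligned metagene summaries,
hypergeometric gene-set overlaps, and Hill/initial-rate fits of the
accompanying biochemistry. Every stage runs on synthetic data generated by
the package itself, so the whole pipeline is verifiable without any
sequencing archive.

## Synthetic data model

The generator emulates the features of promoter chromatin the pipeline
must resolve, and nothing more:

- **Genome.** Equally sized chromosomes carrying non-overlapping genes on
  both strands, each with a defined TSS and TES. Gene lengths are uniform
  in [min, 2·min] (default min 1000 bp) with a 300 bp intergenic gap.
- **Nucleosome arrays.** Each gene gets a regular array: the +k dyad at
  `TSS + NFR/2 + (k−1)·spacing` along the direction of transcription
  (defaults: NFR 140 bp, spacing 165 bp, five nucleosomes). A condition's
  repositioning is *programmed* by displacing chosen array positions a
  signed number of bp downstream (positive = away from the TSS), e.g.
  +2/+3/+4 moved 10 bp, matching the magnitude the original study reports
  at the +2 nucleosome.
- **Fragments.** Per nucleosome, `round(weight × fragments_per_nucleosome)`
  mononucleosome-sized fragments (length Normal(147, 10) bp, floored at
  50 bp). A fragment's dyad is Normal(true dyad, fuzziness SD); fuzziness
  is i.i.d. Gaussian per fragment because the per-call statistic the
  pipeline estimates is exactly a dyad standard deviation. Fragments are
  laid out so the downstream midpoint convention recovers the drawn dyad
  bit-exactly — truth and estimate share one convention.
- **Titrations and time courses.** Binding curves follow the Hill equation
  with additive Gaussian noise on fraction bound (clipped to [0, 1] with a
  flag); time courses follow a single saturating exponential
  `A(1 − e^{−(v0/A)t})` whose analytic slope at t = 0 is v0 — the paper-level
  quantity is the initial rate, so any smooth form with that property
  serves.

What the generator does **not** emulate: sequence composition (no
FASTA/FASTQ), MNase sequence bias, sub- and di-nucleosomal fragment
classes, mappability, replication or transcription artifacts, or
nucleosome-free-region turnover. Passing recovery tests therefore
demonstrates the *statistical pipeline* is correct and calibrated, not
that real chromatin satisfies its assumptions.

All randomness flows from one integer seed per call; repeated calls with
identical arguments are bit-identical.

## Dyad tracks

The dyad of a paired-end fragment on the 0-based half-open interval
[start, end) is `floor((start + end − 1)/2)` — the centre of the closed
base range, rounded down for even lengths (the source analysis says
"center" without a rounding rule; flooring keeps integers and is
strand-free). Dyads inside exclusion regions — e.g. the repetitive rDNA
locus chrXII:451275–469084 (1-based), stored internally as the half-open
interval [451274, 469084) — are removed, and excluded positions are masked
out of the normalization denominator rather than zero-filled: "filtered
out" is read as removal from coverage statistics. Counts are divided by
(total dyads / non-excluded genome length), so the non-excluded mean is
exactly 1 (asserted to 1e−9). Replicates are pooled by concatenating raw
dyads before normalizing (`pool: raw`); averaging per-replicate normalized
tracks is available because the original order of pooling and
normalization is not documented.

## Nucleosome calling

The normalized track is convolved with a unit-sum Gaussian kernel
(default σ = 20 bp, truncated at ±4σ; excluded positions contribute
zero). Calls are selected greedily: take the global maximum of the
smoothed signal, record a call, suppress every position within 147 bp
centre-to-centre, repeat. With that suppression the closed 147 bp
footprints [dyad−73, dyad+73] of accepted calls are disjoint (at worst
abutting), which is what makes the downstream ≥73 bp overlap-matching
criterion internally consistent. Ties in the maximum go to the smallest
coordinate, then lexicographic chromosome name — fully deterministic, and
verified against a brute-force sort-all-positions-by-height oracle.

Each call carries: the peak position (`dyad`), the footprint dyad count
(`occupancy`), the n−1 sample SD of footprint dyads (`dyad_sd`, 0 by
convention below two dyads, in which case the call is flagged
untestable), the footprint dyad mean (`dyad_mean`), and the smoothed peak
height (`score`). Candidates with occupancy below `min_occupancy`
(default 10) are rejected but still suppress their window; because
accepted footprints are disjoint, occupancy accounting is exact and
raising `min_occupancy` can only remove calls. The smoothing σ, exclusion
width and minimum occupancy are not documented for the original caller;
the defaults here (20 bp / 147 bp / 10) are exposed everywhere.

## Shift testing

Calls from two conditions are matched one-to-one when their footprints
overlap by ≥ 73 bp (equivalently |Δdyad| ≤ 74, asserted on every pair),
greedily by smallest distance with symmetric tie-breaking, so
`match(A,B)` and `match(B,A)` agree with negated deltas.

Each matched pair is tested with Welch's two-sample t-test assembled from
the per-call summaries: `t = (m_A − m_B)/√(s_A²/n_A + s_B²/n_B)` with s =
dyad SD and n = occupancy, df by Welch–Satterthwaite, two-sided p, and a
raw p < 0.01 significance cutoff (no multiple-testing correction; a BH-FDR
column is emitted for reference but never used for the flag). Treating
each raw dyad as one observation of the nucleosome's position is the only
reading that uses all three per-call statistics the source analysis names;
it makes p-values coverage-dependent, which is why a sensitivity mode
capping n is provided.

One numerical choice matters and is deliberate: **the position entering
the t-statistic is the footprint dyad mean, not the smoothed peak.** The
peak is a mode estimator whose variance at these settings (σ = fuzziness
= 20 bp) is ~1.5× that of the mean, so using it would overdisperse t and
break null calibration; with the mean, the test is exactly Welch on the
reconstructed dyad multisets, and on zero-shift simulations the p-value
distribution is uniform (KS < 0.05 at 2000 pairs) with ~1% of pairs
significant at α = 0.01. The *reported* shift stays peak-to-peak, signed
along the gene (positive = downstream, away from the TSS), and the
`position_stat="peak"` option restores the literal peak-based test.
Pairs with zero SD on both sides (noise-free synthetic data) are counted
as untestable, never significant.

## Metagene summaries

Calls are assigned to genes as +1, +2, … walking downstream from the TSS;
the +1 is the first call no more than 30 bp upstream of the TSS (the
slack is this package's choice — no published window exists — and is
configurable). Genes qualify for metagene analysis when |TES − TSS| >
560 bp, they carry ≥ 4 assigned nucleosomes, and TSS/TES are defined;
both thresholds are strict. "Shifted" genes have ≥ 1 significant pair at
positions +1..+4. Profiles average the normalized tracks across genes
after anchoring every gene at its **condition-A (wild-type) +1 dyad** and
orienting offsets downstream; anchoring both conditions on the same
wild-type dyad is what makes mutant repositioning visible as peak
displacement. The per-position summary is the **median** signed shift
(means are emitted alongside for diagnostics).

## Gene-set overlap

Overlap significance uses the hypergeometric distribution computed with
log-binomial coefficients (exact to ~1e−12 against rational-arithmetic
enumeration for small universes and against an independent library
implementation at genome scale), with the upper (enrichment) tail by
default and depletion by flag. The RNA-seq selection filter keeps genes
with fold change strictly over 1.5 (signed-ratio or log2 input, declared
explicitly) and FDR strictly below 10%.

## Binding and kinetics

The Hill model `f([E]) = [E]^H/(K_D^H + [E]^H)` is fitted by unweighted
least squares with multi-start over a log-spaced K_D grid (the original
fitting software's weighting options are undocumented; unweighted is the
assumption here). Free enzyme is approximated by total enzyme — no
ligand-depletion correction — mirroring standard EMSA practice even
though probe and enzyme concentrations are comparable; treat fitted K_D
values as apparent constants. 95% intervals are profile-likelihood via
the F-threshold `SSR(θ) ≤ SSR_min(1 + F_{1,n−2;0.95}/(n−2))`, chosen over
bootstrap for determinism at small replicate counts, with asymptotic
(J'J) intervals as fallback; on zero-residual data the interval
degenerates to the estimate. On titrations simulated at the published
dinucleosome parameters (K_D 5.29 nM, H 1.43, noise SD 0.03, 3
replicates, 12 concentrations in 0–60 nM) the mean fitted K_D and H land
within a fraction of a percent of truth and the 95% CI covers truth in
~94 of 100 seeds.

Initial rates fit `A(1 − e^{−kt})` and report v0 = A·k with a
delta-method standard error; `linear-early` regresses points with signal
below 30% of maximum (the 30% cutoff is this package's choice; the
source states only "initial rates") and is the automatic fallback when
the exponential fit fails to converge. Fold ratios report the exact
quotient plus a conventionally rounded value: nearest integer at ≥ 6,
one decimal below — the convention implied by how such ratios are quoted
(2.6, 5.3, 5.4 with a decimal; 8, 12, 13, 20 as integers). One published
pair of ratios ("5.4 and 10 times") is not reproducible from its own
printed rates (0.23/1.2/2.8 nM s⁻¹ give 5.2 and 12.2); the package
reproduces the rates' arithmetic and does not silently reconcile the
text.

## Problem sizes and determinism

The shipped recovery analyses use a 200-gene genome (500 kb, five
nucleosomes per gene, 300 fragments per nucleosome, ~300 k fragments per
condition) for shift recovery and 400 genes (1 Mb) for the 2000-pair null
calibration; both are the package's standard demonstration scale and run
in seconds on one CPU. All stages are deterministic given the config
seed: reruns produce bit-identical outputs, and the pipeline writes a
provenance record (config, seeds, version, per-stage counts) with every
run.

## Known limitations

- Occupancy-as-n makes shift p-values depend on sequencing depth; at high
  coverage, biologically trivial sub-bp displacements can reach
  significance. The effect-size column (signed shift) should always be
  read alongside p.
- The caller reports one nucleosome per 147 bp at most: overlapping or
  fuzzy alternative positions are not deconvolved.
- The hypergeometric test assumes a fixed, correctly specified gene
  universe; the filter thresholds are strict inequalities and boundary
  rows are dropped.
- Hill K_D values are apparent constants under the no-depletion
  approximation.
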