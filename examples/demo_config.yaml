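# Demo pipeline run: 40 genes with +1..+5 nucleosome arrays; the mutant
# condition has its +2/+3/+4 nucleosomes programmed 10 bp downstream.
# Run:  nucshift run --config examples/demo_config.yaml --out-dir demo_run
seed: 11
n_chromosomes: 1
chromosome_length: 120000
n_genes: 40
min_gene_length: 1000

nfr_length: 140
spacing: 165
n_per_gene: 5
fuzziness_sd: 20.0
shift_spec:
  2: 10
  3: 10
  4: 10

fragments_per_unit_weight: 300
fragment_length_mean: 147.0
fragment_length_sd: 10.0

sigma: 20.0
exclusion_width: 147
min_occupancy: 10
alpha: 0.01
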