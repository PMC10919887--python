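# Four-set batch configuration (Table-1 layout).
# Set3/Set4 use 2N = 10,000 and are long runs at full scale; Set1/Set2
# complete in minutes.
format_version: 1
n_replicates: 100
base_seed: 1000
gene_model:
  spec: {total_length: 1678, n_exons: 2, exon_fraction: 0.5, seed: 7}
sets:
  Set1: {mu: 1.0e-8, r0: 1.0e-6, pop_chromosomes: 100, generations: 100000}
  Set2: {mu: 1.0e-8, r0: 1.0e-8, pop_chromosomes: 100, generations: 100000}
  Set3: {mu: 1.0e-8, r0: 1.0e-6, pop_chromosomes: 10000, generations: 100000}
  Set4: {mu: 1.0e-8, r0: 1.0e-8, pop_chromosomes: 10000, generations: 100000}
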