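# Demo S-phase simulation: three origins of graded competence on one
# chromosome, with Okazaki, ribonucleotide and SbfI loading-control reads.
# Run:  replifork simulate --config examples/sim_demo.yaml --out scratch/demo
genome: {chrI: 150000}
origins:
  - {chrom: chrI, start: 34900, end: 35100, id: early}
  - {chrom: chrI, start: 74900, end: 75100, id: mid}
  - {chrom: chrI, start: 114900, end: 115100, id: late}
model:
  competence: [0.9, 0.6, 0.4]
  firing_mean: [5.0, 12.0, 18.0]
  firing_sd: 2.0
  fork_speed: 1500.0       # bp/min
  fragment_rate: 1.0       # Okazaki fragments per lagging-strand kb
  ribo_rate_pol_eps: 1.0   # ribonucleotides per nascent kb
  ribo_rate_pol_delta: 1.0
  sbfi_sites: [[chrI, 20000], [chrI, 95000]]
sample_time: 25.0          # minutes after release
n_cells: 300
sbfi_depth: 200.0
seed: 1
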