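# Demo study: run `mrmediation simulate --out demo_study --seed 7 \
#   --n-snps 50 --param n_mediator_snps=50` first, then
#   `mrmediation run-all --config examples/demo.yaml`
traits:
  adiposity: demo_study/exposure.tsv
  metabolite: demo_study/mediator.tsv
  disease: demo_study/outcome.tsv
pairs:
  - [adiposity, disease]
triples:
  - [adiposity, metabolite, disease]
p_threshold: 5.0e-8
clump_r2: 0.001
clump_kb: 10000
f_min: 10.0
fdr_alpha: 0.05
mediation_method: delta
presso_n_sim: 1000
n_boot: 1000
seed: 7
outdir: demo_output
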