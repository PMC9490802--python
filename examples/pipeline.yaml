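# Small synthetic pipeline configuration; run with
#   aquagate run --config examples/pipeline.yaml --seed 3
seed: 3
outdir: pipeline_out
input:
  synthetic:
    preset: default        # nine-residue gating registry
    duration_ns: 100
    variants: [wt]
    replicas: 1
    chains: [A, B, C, D]
model:
  chains: 2
  iterations: 400
  warmup: 200
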