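# Full-pipeline configuration: synthetic cohort matching the published
# marginals, bootstrap scaled down for a quick demonstration run.
generator:
  n: 1785
bootstrap_B: 2000
optimism_B: 500
candidates: [dxr, mtx, pem, gem, cpi, vegf, capecitabine, s1, vp16, no_mg, sh]
out_dir: akiscore_out
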