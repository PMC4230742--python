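# Small demonstration configuration: runs the full pipeline in well under a
# minute on one CPU while keeping the default study conditions otherwise.
outdir: hotspotdrive_demo
seed: 1
filter_tier: F2
m_bins: 5
lossrate_repeats: 20
sim:
  L_HM: 600
  L_CM: 600
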