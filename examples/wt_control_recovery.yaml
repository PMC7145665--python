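# Simulate a wild-type/control stopped-flow dataset at the published rate
# constants and recover them with the standard constraint policy.
# Usage: polbkin pipeline --config examples/wt_control_recovery.yaml --seed 7 --out scratch/wt-run
run: pipeline
params: wt_control        # named preset; an explicit rate block also works
dntp_concs: [1.0, 2.5, 5.0, 10.0, 25.0, 100.0]
noise:
  sigma: 0.02             # fraction of each trace's dynamic range
multistart: 3
init_offset: 2.0          # start the fit this factor away from the truth
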