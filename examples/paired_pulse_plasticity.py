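"""Very short-term plasticity: the paired-pulse ratio (PPR).

Two APs 40 ms apart; PPR = P_r2 / P_r1.  Synapses releasing much of their
readily releasable pool on the first pulse depress (PPR < 1); the FAD
synapse keeps a longer Ca2+ history and holds a higher PPR than WT.
"""
from boutonsim import load_parameters, run_paired_pulse

for cond in ("WT", "AD"):
    ps = load_parameters(condition=cond)
    s = run_paired_pulse(ps, n_vgcc=35, trials=40, seed=3,
                         det_profile_trials=0)
    print(f"{cond}: P_r1 = {s.pr[0]:.3f}, P_r2 = {s.pr[1]:.3f}, "
          f"PPR = {s.ppr:.2f}")
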