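"""Estimate the Granger causality index for one coupled channel pair.

Simulates a two-channel VAR(1) process in which channel 1 drives channel 2
with weight 0.5, then estimates the GCI in both directions. The index in
the true direction should be clearly positive; the reverse should be near
zero — GCI is the log-ratio of the univariate to the bivariate residual
variance, i.e. how much the other channel's past improves prediction.
"""

from braingc import CouplingGraph, MVARSpec, gci_pair, generate_mvar

graph = CouplingGraph(2, ((0, 1),), (0.5,), ("ch1", "ch2"))
spec = MVARSpec(
    coupling=graph,
    self_dynamics=((0.5,), (0.5,)),
    noise_sd=(1.0, 1.0),
    sample_rate=1000.0,
    seed=7,
)
rec = generate_mvar(spec, 20_000)
fwd, rev = gci_pair(rec.data[0], rec.data[1], p=1)
print(f"GCI ch1 -> ch2 (true direction): {fwd:.4f}")
print(f"GCI ch2 -> ch1 (reverse):        {rev:.6f}")
print("A strong asymmetry recovers the simulated coupling direction.")
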