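"""Exact trainable-parameter budgets of the four ablation arms.

Builds each architecture variant from the shipped default configuration
and enumerates every trainable scalar. The baseline (0.29 M) and the
full model (1.20 M) are the two pinned budgets; the ordering
baseline < +interaction < full reflects what each module adds.
"""

from hdcseg import arch_config, build, count_parameters

for arch in ("baseline", "cga", "gam", "full"):
    net = build(arch_config(arch))
    n = count_parameters(net)
    print(f"{arch:9s}: {n:9,d} parameters  ({n / 1e6:.2f} M)")
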