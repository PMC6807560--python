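"""The epsilon rule on a network small enough to follow by hand.

Builds a two-layer dense network, decomposes its logit with the epsilon
rule, and verifies the conservation property (total relevance == logit for
a bias-free network at epsilon=0) plus the equivalence of gradient*input
and LRP on a purely linear stack.
"""

import numpy as np

from relvox.layers import Dense, Flatten, Network, Sigmoid
from relvox.relprop import RelpropConfig, gradient_times_input, lrp_explain

rng = np.random.default_rng(0)
d1, d2 = Dense(4, 3), Dense(3, 1)
d1.W = rng.normal(size=(3, 4))
d2.W = rng.normal(size=(1, 3))
net = Network([Flatten(), d1, d2, Sigmoid()], (4, 1, 1))
x = rng.normal(size=(4, 1, 1))

score, logit, _ = net.forward(x)
print(f"f(x) = {score:.4f}   logit = {logit:.4f}")

hm0 = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
print(f"LRP(eps=0)    relevances: {np.round(hm0.data.ravel(), 4)}  sum={hm0.total():.4f}")

hm = lrp_explain(net, x, RelpropConfig(epsilon=0.001))
print(f"LRP(eps=1e-3) relevances: {np.round(hm.data.ravel(), 4)}  sum={hm.total():.4f}")

gi = gradient_times_input(net, x)
print(f"gradient*input:           {np.round(gi.data.ravel(), 4)}  sum={gi.total():.4f}")
# At eps=0 on this bias-free linear stack all three sums equal the logit
# (conservation); the small eps damps relevance at near-zero denominators,
# which is why its total drifts slightly from the logit.
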