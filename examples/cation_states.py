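"""Cation binding-site state traces and rotamer/occupancy summaries.

Classifies a synthetic cation-to-Na2 distance trace into Na1 / transition /
Na1' states, reports dwell segments, and computes the conditional occupancy
ratio among the most "open" frames.
"""

import numpy as np

from mdain.observables import conditional_occupancy, trace_from_distances
from mdain.synthetic import make_cation_trace

# a trace that dwells in Na1, excurses through the transition zone, and
# settles in the alternative Na1' site
sequence = ["Na1"] * 40 + ["transition"] * 8 + ["Na1prime"] * 30 + \
    ["transition"] * 6 + ["Na1"] * 16
times, distances = make_cation_trace(sequence, noise_sd=0.3, seed=5)
trace = trace_from_distances(times, distances)

recovered = np.mean([a == b for a, b in zip(trace.states, sequence)])
print(f"{len(sequence)} frames; state recovery vs ground truth: {recovered:.1%}")
print("dwell segments (state, first frame, last frame):")
for seg in trace.segments():
    print(f"  {seg}")

# occupancy ratio among the top-20% most open frames: openness here is a
# synthetic EV water count made higher while the ion sits in Na1
rng = np.random.default_rng(5)
openness = np.array([10.0 if s == "Na1" else 7.0 for s in trace.states]) \
    + rng.normal(0, 2.5, len(sequence))
ratio, n_na1, n_prime = conditional_occupancy(openness, trace.states, fraction=0.20)
print(f"\ntop-20% most open frames: {n_na1} Na1 vs {n_prime} Na1' "
      f"-> occupancy ratio {ratio if n_prime else 'inf'}")
# A ratio well above 1 reproduces the coupling planted here between the
# open vestibule and Na1-site occupancy.
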