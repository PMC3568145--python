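"""Segment a noisy copy-number profile and call gains/losses.

A 300-probe log-ratio profile carries an amplified block (+1, probes
101-140) and a deleted block (-0.7, probes 201-230) in Gaussian noise.
Circular binary segmentation recovers the constant-mean segments; genes in
segments with mean >= +0.2 are called gained (+2), <= -0.2 lost (-2).
"""

import numpy as np
import pandas as pd

from oncocis import SegmentationConfig, call_genes, segment_profile

rng = np.random.default_rng(0)
profile = rng.normal(0.0, 0.25, size=300)
profile[100:140] += 1.0
profile[200:230] -= 0.7

cfg = SegmentationConfig(n_permutations=500, seed=1)
segments = segment_profile(profile, cfg)
print("fitted segments (1-based, inclusive):")
print(segments.round(3).to_string(index=False))

genes = pd.Index([f"g{i:03d}" for i in range(300)])
calls = call_genes({"sample1": segments}, genes, cfg)
called = calls["sample1"]
print(f"\ngained genes: {(called == 2).sum()}, lost genes: {(called == -2).sum()}")
print("the true blocks span 40 and 30 genes; boundary probes in noise may")
print("be absorbed into a flanking segment, which is the smoothing the")
print("benchmark exploits at genome scale.")
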