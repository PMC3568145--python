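"""One end-to-end benchmark trial: simulate -> segment -> score.

Generates a full default dataset (10,000 genes, 100 tumors, linear
dosage-expression coupling), segments every tumor profile with CBS, calls
gains/losses at +-0.2, runs both EIS analyses and scores the significant
genes against the 54 dosage-coupled true positives.  Takes a couple of
minutes on one core; shrink the setting for a faster look.
"""

from oncocis import RunConfig, SegmentationConfig, SimulationSetting, run_trial

row = run_trial(
    SimulationSetting(model="LINEAR", n_tumors=100, seed=11),
    SegmentationConfig(n_permutations=200, seed=12),
    RunConfig(n_sampling=1000, seed=13),
)

print(f"genes called copy-number altered after CBS : {row['n_called']}")
print(f"genes evaluated by the EIS analyses        : {row['n_tested']}")
print(f"significant genes (corrected p <= 0.05)    : {row['n_positives']}")
print(f"true positives recovered                   : {row['tp']} / 54")
print(f"sensitivity                                : {row['sensitivity']:.3f}")
print(f"specificity (evaluated genes)              : {row['specificity']:.3f}")
print(f"Matthews correlation (all genes)           : {row['mcc']:.3f}")
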