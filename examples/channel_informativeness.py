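"""Map which channels carry the decodable signal.

Runs the exhaustive channel-subset analysis on a simulated dataset whose
condition contrast is concentrated on a few channels, then ranks channels
by their mean accuracy over all subsets they participate in.
"""

import numpy as np

from nirsmvpa import (
    SyntheticSpec,
    channel_informativeness,
    generate_dataset,
    subset_decoding,
)

# condition signal lives mostly on channels 1-3
patterns = {
    "A": np.array([1.0, 0.9, 0.8, 0.3, 0.3, 0.3, 0.3, 0.3]),
    "B": np.array([0.2, 0.3, 0.4, 0.3, 0.3, 0.3, 0.3, 0.3]),
}
spec = SyntheticSpec(
    n_subjects=18,
    n_channels=8,
    group_patterns=patterns,
    subject_sd=0.1,
    trial_sd=0.25,
    noise_sd=0.25,
    seed=5,
)
dataset = generate_dataset(spec)

report = subset_decoding(dataset, sizes=[2, 3, 8])
print(f"decoded {len(report.table)} subsets")
print(
    "full-set accuracy:",
    float(report.table.loc[report.table["size"] == 8, "accuracy"].iloc[0]),
)

table = channel_informativeness(report, k=3).sort_values(
    "mean_accuracy", ascending=False
)
print("\nper-channel informativeness at subset size 3:")
print(table.to_string(index=False))

# Channels carrying the planted contrast (ch01-ch03) tend to float to the
# top of the ranking, each averaged over the C(7,2)=21 size-3 subsets that
# contain it.  At realistic sample sizes idiosyncratic between-subject
# structure can still push a no-signal channel up the list - which is
# exactly why the ranking is descriptive and group-level significance comes
# from the permutation test, not from this table.
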