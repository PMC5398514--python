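"""Write a dataset in the CSV dialect, read it back, and decode.

The same flow applies to real preprocessed HbO exports: one time-series CSV
(time_s,<ch1>,...) and one events CSV (onset_s,condition) per subject, plus
a JSON config naming conditions, included channels, sampling rate and
analysis window.
"""

import tempfile
from pathlib import Path

from nirsmvpa import (
    SyntheticSpec,
    generate_dataset,
    read_dataset,
    run_loo,
    univariate_contrast,
    write_dataset,
)

root = Path(tempfile.mkdtemp()) / "experiment"
spec = SyntheticSpec(n_subjects=8, n_channels=6, seed=1)
write_dataset(generate_dataset(spec), root)
print("wrote", sorted(p.name for p in root.iterdir())[:4], "...")

dataset = read_dataset(root)  # validates channels, conditions, event bounds
result = run_loo(dataset, level="infant")
print(f"infant-level accuracy: {result.overall_accuracy:.3f}")

# the univariate comparison: one paired t-test per channel, Bonferroni
# corrected at 0.05 / n_channels
table = univariate_contrast(dataset)
print("\nper-channel univariate contrast:")
print(table.to_string(index=False))
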