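"""Run the complete workflow and inspect the machine-readable report.

`run_all` executes lexicon → utterance → annotation → per-subject EEG
simulation → preprocessing → TG decoding → metrics → group statistics and
writes everything (events TSV, TG matrices, widths, cluster results,
summary JSON) under one output directory, alongside the resolved
configuration for provenance.
"""

import json

from phonodyn.decode import DecodeConfig
from phonodyn.pipeline import PipelineConfig, SessionConfig, run_all
from phonodyn.simulate import SimConfig
from phonodyn.stats import TestConfig

cfg = PipelineConfig(
    seed=3,
    out_dir="scratch/example_run",
    groups=("control", "aphasia"),
    session=SessionConfig(n_words=150),
    # 6 subjects per group: the smallest cohort at which the sign-flip
    # cluster test can reach p < 0.05 (its null has only 2^n outcomes)
    simulate=SimConfig(snr=2.0, n_subjects_per_group=6),
    decode=DecodeConfig(train_stride=2),
    stats=TestConfig(n_permutations=500),
    decode_features=("coronal", "labial"),
)
summary_path = run_all(cfg)
summary = json.loads(summary_path.read_text())

print(f"report written to {summary_path}")
print("above-chance diagonal windows per group:")
for group, windows in summary["diagonal_windows"].items():
    print(f"  {group}: {windows}")
print("group-difference clusters:", summary.get("group_clusters"))
print("generalization widths (CI recipe):")
for group, w in summary["widths"].items():
    print(f"  {group}: {[round(x, 4) for x in w['ci']]}")
# With the aphasia-like gain profile the groups share the early window but
# the aphasia group's cluster ends earlier / weaker, mirroring a loss of
# sustained encoding rather than a slower pattern evolution.
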