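"""Detect a group difference in encoding strength with cluster statistics.

Simulates a control group (full response gain throughout) and a clinical-
like group whose gain drops to 0.4 from 0.08 s after phoneme onset, then
compares the groups' diagonal decoding timecourses with a label-exchange
cluster permutation test.  The significant cluster should start near the
gain-drop latency and never reach the pre-onset baseline.
"""

from phonodyn.experiments import group_difference_clusters

clusters = group_difference_clusters(seed=11, n_subjects=6)
print("significant group-difference clusters (start_s, end_s, p):")
for start, end, p in clusters:
    print(f"  {start:+.3f} to {end:+.3f} s, p = {p:.4f}")
print("injected: gain drop to 0.4 from 0.08 s; encoding ends at 0.35 s")
# The cluster onset recovers the moment the groups diverge; anything
# overlapping the pre-onset window would indicate a miscalibrated test.
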