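"""Decode phonetic features from synthetic EEG with temporal generalization.

Simulates one subject whose 'coronal' and 'labial' responses hand off
between orthogonal spatial patterns every 0.08 s for 0.3 s, preprocesses
and epochs the EEG, then trains a logistic-regression decoder at every
train time and tests it at every test time.  Prints the diagonal (when the
feature is decodable) and the generalization width (how long one pattern
stays informative) — the two quantities that separate dynamic from static
coding.
"""

import numpy as np

from phonodyn.decode import DecodeConfig
from phonodyn.pipeline import PipelineConfig, SessionConfig, simulate_session, subject_tg
from phonodyn.simulate import SimConfig, make_ground_truth
from phonodyn.tgmetrics import diagonal, generalization_width, halfmax_width, reorient

features = ("coronal", "labial")
cfg = PipelineConfig(
    seed=11,
    session=SessionConfig(n_words=250, phonotactics="iid"),
    simulate=SimConfig(snr=2.0, dwell_tau_s=0.08, encode_duration_s=0.3),
    decode=DecodeConfig(train_stride=2),
    decode_features=features,
)
_, events, table = simulate_session(cfg)
truth = make_ground_truth(features, cfg.simulate, seed=cfg.seed)
run = subject_tg(events, table, truth, cfg, "control", 0)

tg = run["avg"]
diag = diagonal(tg)
times = tg.train_times_s
above = times[diag > 0.6]
print(f"TG matrix: {tg.values.shape[0]} train x {tg.values.shape[1]} test times")
print(f"peak diagonal AUC {diag.max():.3f} at {times[np.argmax(diag)]:.3f} s")
print(f"diagonal AUC > 0.6 from {above.min():.3f} to {above.max():.3f} s "
      "(injected encoding: 0.05–0.35 s)")

profile = reorient(tg, train_window=(0.0, 0.35))
print(f"generalization width (CI recipe):  {generalization_width(profile):.4f} s")
print(f"generalization width (half-max):   {halfmax_width(profile):.4f} s "
      "(injected dwell: 0.08 s)")
# A width near the dwell time with a much longer diagonal is the signature
# of dynamic coding: information outlives any single spatial pattern.
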