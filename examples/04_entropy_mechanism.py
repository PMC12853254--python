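"""Recover the uncertainty-contingent encoding-duration mechanism.

One simulated group encodes high-lexical-entropy phonemes 0.1 s longer
than low-entropy ones; a second group does not.  Decoders are trained on
all trials and tested separately on the high- and low-entropy subsets; the
group × entropy interaction (independent t per lag, FDR-corrected inside
0.15–0.35 s) should flag the lags where the duration bonus lives.
"""

import numpy as np

from phonodyn.experiments import entropy_interaction_lags

lags = entropy_interaction_lags(seed=11, n_subjects=4)
if len(lags):
    print(f"FDR-significant interaction lags: {np.round(lags, 3).tolist()} s")
    print("expected: inside 0.25–0.35 s (base duration 0.2 s + bonus 0.1 s, "
          "response onset 0.05 s)")
else:
    print("no significant interaction found at this seed/size")
# Only the 'bonus' group extends high-entropy encoding, so the
# high-minus-low difference differs between groups exactly where the
# extension lives — the mechanism linking lexical uncertainty to
# phonetic maintenance.
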