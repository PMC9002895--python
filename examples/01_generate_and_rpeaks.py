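"""Generate a synthetic two-lead record and detect its R peaks.

Both detectors should find exactly the annotated beats on clean data; on
distorted beats they can disagree, which is why the pipeline carries both
counts as features.
"""

import numpy as np

from ecgfusion import (SynthParams, generate_record, normalized_record,
                       pan_tompkins, seeht)

record = normalized_record(generate_record(
    SynthParams(duration=30, fs=250, heart_rate=72, noise_sd=0.02, seed=5)))
truth = np.array([s for s, _ in record.beat_ann])

for detector in (pan_tompkins, seeht):
    result = detector(record.lead(0), record.fs)
    matched = sum(bool(np.any(np.abs(result.r_indices - t) <= 12)) for t in truth)
    print(f"{result.detector:13s} found {len(result):3d} peaks "
          f"({matched}/{len(truth)} annotated beats matched within 50 ms)")

# The counts are the first two rhythm features; equal counts here mean both
# chains resolved every beat of this clean record.
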