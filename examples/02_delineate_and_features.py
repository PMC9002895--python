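"""Delineate heartbeats and assemble the handcrafted feature vectors.

Prints the per-beat fiducials/intervals for a normal and an abnormal beat,
then the 9-dim rhythm vector of one 3-second window.  An absent P wave
demonstrates the zero-sentinel rule: its interval and amplitude entries are
exactly 0, never NaN.
"""

from ecgfusion import (SynthParams, generate_record, normalized_record,
                       extract_heartbeats, slide_rhythm_windows,
                       delineate_beat, measure_intervals,
                       heartbeat_features, rhythm_features)
from ecgfusion.features import HEARTBEAT_FEATURE_NAMES, RHYTHM_FEATURE_NAMES

record = normalized_record(generate_record(SynthParams(
    duration=20, fs=250, heart_rate=60, seed=9,
    anomaly_plan=[{"beat_index": 6, "kind": "absent_p"}])))

for beat in extract_heartbeats(record):
    if beat.symbol in ("N", "J"):
        fid = delineate_beat(beat.samples, beat.fs, beat.r_index,
                             beat.left_r, beat.right_r - 1)
        iv = measure_intervals(fid, beat.left_r, beat.right_r, beat.fs, beat.samples)
        print(f"beat {beat.symbol}: qrs={iv.qrs_len:.3f}s pr={iv.pr_len:.3f}s "
              f"qt={iv.qt_len:.3f}s p_amp={iv.p_amp:.3f} t_amp={iv.t_amp:.3f}")
        if beat.symbol == "J":
            vec = dict(zip(HEARTBEAT_FEATURE_NAMES, heartbeat_features(beat)))
            print("  absent-P beat vector:", {k: round(v, 3) for k, v in vec.items()})
            break

window = slide_rhythm_windows(record)[2]
print("\nrhythm features of window 2:")
for name, value in zip(RHYTHM_FEATURE_NAMES, rhythm_features(window)):
    print(f"  {name:18s} {value:8.4f}")
# n_r_* are the two detector counts; avg_rr near 1.0 s reflects 60 bpm.
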