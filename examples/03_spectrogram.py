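"""Compute an STFT spectrogram of a rhythm window and render it as a PNG.

The rhythm window length is 167 samples (0.668 s at 250 Hz) with 50% overlap,
so a 3-second window yields 8 spectrogram columns; the rendered image is
875 x 656 (width x height), grayscale or jet-colormapped RGB.
"""

from ecgfusion import (SynthParams, generate_record, normalized_record,
                       slide_rhythm_windows, stft, render, save_png)

record = normalized_record(generate_record(
    SynthParams(duration=10, fs=250, heart_rate=80, seed=3)))
window = slide_rhythm_windows(record)[0]

matrix = stft(window.samples, L=167)
print(f"STFT: {matrix.n_bins} frequency bins x {matrix.k} columns "
      f"(window {matrix.window_len} samples = {matrix.window_len / 250:.3f} s)")

for mode in ("gray", "rgb"):
    image = render(matrix, mode=mode)
    path = save_png(image, f"spectrogram_{mode}.png")
    print(f"{mode}: image {image.shape[1]}x{image.shape[0]}x{image.shape[2]} -> {path}")
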