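"""Synthesize one stimulation trial and decode its frequency with CCA.

Generates a 6-channel occipital EEG trial responding to a 12 Hz
motion-reversal stimulus (fundamental-dominant response, 1/f + alpha +
mains background), runs the preprocessing chain — filtering, latency-
shifted epoching, segment averaging, Hamming-windowed spectrum — and
recognizes the frequency against the 40-target grid with training-free CCA.
"""

import ffsmvep as fm

F_STIM = 12.0
cfg = fm.SyntheticSessionConfig(trial_duration_s=4.0, seed=42)
rec = fm.generate_epoch(cfg, F_STIM, seed=42)
print(f"trial: {rec.n_samples} samples x {rec.n_channels} channels at {rec.fs_hz:.0f} Hz")

# preprocessing: band-pass 2-100 Hz, notch 48-52 Hz, 150 ms latency shift
filtered = fm.notch_filter(fm.bandpass_filter(rec.data, rec.fs_hz), rec.fs_hz)
rec_f = fm.MultichannelRecording(filtered, rec.fs_hz, rec.channel_labels, rec.onsets)
(epoch, _), = fm.extract_epochs(rec_f, duration_s=3.5, latency_s=0.150)

# average over one-motion-cycle segments (two reversal periods = 200 samples)
cycle_samples = round(2 * rec.fs_hz / F_STIM)
avg = fm.segment_average(epoch[:, 0], cycle_samples)
spec = fm.amplitude_spectrum(avg, rec.fs_hz)
raw_spec = fm.amplitude_spectrum(epoch[:, 0], rec.fs_hz)
print(f"averaged Oz waveform: dominant frequency {spec.peak_freq():.1f} Hz, "
      f"amplitude {spec.amplitude_at(F_STIM):.2f} at f, "
      f"{spec.amplitude_at(2 * F_STIM):.2f} at 2f")
print(f"raw-epoch spectral SNR at f_stim: {fm.snr(raw_spec, F_STIM):.1f}")

# CCA recognition over the 40-frequency speller grid
outcome = fm.classify_epoch(epoch, fm.layout_frequencies(), rec.fs_hz)
print(f"decoded frequency: {outcome.predicted_hz:.1f} Hz "
      f"(true {F_STIM}), rho = {outcome.rho.max():.3f}")

print("\nThe averaged response oscillates at the motion-reversal frequency with a")
print("single dominant peak (the harmonic is ~7x smaller), and one sin/cos")
print("reference pair per candidate recognizes it without any user training.")
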