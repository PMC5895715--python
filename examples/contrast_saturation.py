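"""Response amplitude vs stimulus contrast: logarithmic rise, early saturation.

Motion-evoked responses are robust to ambient-light washout: the amplitude
rises steeply at low Michelson contrast and saturates near contrast 0.25.
This example evaluates the generator's contrast-response rule and shows its
effect on the decoded canonical correlation.
"""

import ffsmvep as fm

print("contrast -> response multiplier")
for c in (0.06, 0.13, 0.25, 0.50, 1.00):
    print(f"  {c:4.2f}   -> {fm.contrast_response(c):.3f}")

grid = fm.layout_frequencies()
print("\ndecoded rho at 10.0 Hz for decreasing contrast (2 s epochs):")
for c in (1.00, 0.25, 0.06):
    cfg = fm.SyntheticSessionConfig(contrast=c, trial_duration_s=2.2)
    rec = fm.generate_epoch(cfg, 10.0, seed=3)
    (epoch, _), = fm.extract_epochs(rec, 2.0, 0.150)
    out = fm.classify_epoch(epoch, grid, rec.fs_hz)
    print(f"  contrast {c:4.2f}: rho {out.rho.max():.3f}, "
          f"decoded {out.predicted_hz:.1f} Hz")

print("\nAbove the 0.25 saturation knee the response (and decoding) barely")
print("changes with contrast; only well below it does performance degrade.")
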