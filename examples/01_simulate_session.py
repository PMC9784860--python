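"""Render a synthetic training session and inspect its ground truth.

The generator commands a changed-pixel fraction per 0.3 s interval (the
scope-speed proxy), saturated blobs of known area and centroid, and stone
appearance times — so every score the pipeline later measures has a
closed-form expectation.
"""

from endoskill import profile_presets, render

spec = profile_presets("professional", seed=42, trial_index=0)
session = render(spec)

print(f"session {spec.session_id}: {len(session.stream)} frames "
      f"({spec.width}x{spec.height} @ {spec.fps:g} fps)")
print(f"stones detected: {session.annotation.detected_count} of "
      f"{session.annotation.total_targets}, "
      f"procedure time {session.annotation.session_time_min:.2f} min")

truth = session.truth
print("\nfirst five commanded coverages A_i (% of frame changed per 0.3 s):")
print("  ", [round(a, 2) for a in truth.expected_coverage[:5]])
print("expected scores under the default configuration:")
for name, value in truth.expected_scores().items():
    print(f"  {name:>16}: {value:6.2f} %")
# These are the values the scoring pipeline should recover from the pixels
# alone; 02_score_session.py closes that loop.
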