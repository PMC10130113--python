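# Default stimulus battery: nine trajectories.
#
# Extents (total arc length, px) are chosen so that duration =
# extent / speed reproduces the intended battery timing: lines 4.27 s,
# zigzags 10.50 / 4.65 / 2.98 s, spirals 22.46 / 10.47 / 6.75 s at
# 100 / 225 / 300 px/s.  Shape parameters (sigmoid tuning, period
# count, amplitude, spiral turn count) define the geometry; the zigzag
# tiers share one shape scaled to slightly different arc lengths, as do
# the spirals.
format: pursuitkit-battery/1
frame_rate: 60
screen:
  width_px: 800
  height_px: 480
  width_mm: 155.0
trajectories:
  hline:
    family: hline
    extent_px: 427.0
    speed_px_s: 100.0
    profile: minimum_jerk
  tlineR:
    family: tlineR
    extent_px: 427.0
    speed_px_s: 100.0
    profile: constant_speed
  tlineL:
    family: tlineL
    extent_px: 427.0
    speed_px_s: 100.0
    profile: constant_speed
  zigzagA:
    family: zigzag
    extent_px: 1050.0
    speed_px_s: 100.0
    profile: power_law
    beta: 0.333333333333333
    periods: 4.0
    amplitude_deg: 60.0
    sigmoid_k: 0.7
  zigzagB:
    family: zigzag
    extent_px: 1046.25
    speed_px_s: 225.0
    profile: power_law
    beta: 0.333333333333333
    periods: 4.0
    amplitude_deg: 60.0
    sigmoid_k: 0.7
  zigzagC:
    family: zigzag
    extent_px: 894.0
    speed_px_s: 300.0
    profile: power_law
    beta: 0.333333333333333
    periods: 4.0
    amplitude_deg: 60.0
    sigmoid_k: 0.7
  spiralA:
    family: spiral
    extent_px: 2246.0
    speed_px_s: 100.0
    profile: power_law
    beta: 0.333333333333333
    turns: 3.0
    inner_frac: 0.02
  spiralB:
    family: spiral
    extent_px: 2355.75
    speed_px_s: 225.0
    profile: power_law
    beta: 0.333333333333333
    turns: 3.0
    inner_frac: 0.02
  spiralC:
    family: spiral
    extent_px: 2025.0
    speed_px_s: 300.0
    profile: power_law
    beta: 0.333333333333333
    turns: 3.0
    inner_frac: 0.02
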