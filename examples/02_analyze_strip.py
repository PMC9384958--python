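"""Measure one strip image: line positions, background and the three ratios.

Renders a noisy phantom at 444 ng/ml (a 'high' band on visual reading) and
runs the full single-strip analysis. Ratios below 1 mean a visible band:
the further below 1, the darker the line.
"""

from lfaquant import DetectionConfig, PhantomConfig, analyze_strip, render_strip

cfg = PhantomConfig()
img, truth = render_strip(444.0, cfg, seed=7)
m = analyze_strip(img, cfg.roi, DetectionConfig())

print(f"true centers (RoI coords): test {truth.true_test_center - cfg.roi.col0}, "
      f"control {truth.true_control_center - cfg.roi.col0}")
print(f"detected:                  test {m.test_pos}, control {m.control_pos}")
print(f"background mean            {m.background_mean:7.2f} counts "
      f"(sd {m.background_sd:.2f})")
print(f"test / control minima      {m.test_value:7.2f} / {m.control_value:.2f} counts")
print(f"ratio test-background      {m.ratio_tb:7.3f}")
print(f"ratio control-background   {m.ratio_cb:7.3f}")
print(f"ratio test-control         {m.ratio_tc:7.3f}  (<1: test band darker than control)")
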