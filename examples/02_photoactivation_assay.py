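"""Photoactivation assay: midzone stability ratio and sliding velocity.

Simulates a tubulin band photoactivated across the spindle midzone
(10 activation points, 0.8 s frames). The band's two antiparallel halves
slide apart at 1.2 μm/min while turnover removes 30% of the signal every
30 s and mild photobleaching dims everything. The assay then re-measures
both numbers from the rendered movie alone.
"""

import spindleq as sq

pa = sq.PABandSimParams(v_slide=1.2, survival_30s=0.7, bleach_rate=0.004,
                        n_frames=60, background_level=20.0, seed=2)
optics = sq.RenderOptics(background=20.0, seed=2)
optics.flux = sq.flux_for_snr(12, optics, 0.083)
stack, truth = sq.simulate_pa_band(pa, optics=optics)
print(f"photoactivation movie: {stack.n_frames} frames every "
      f"{stack.meta.frame_interval} s")

res = sq.pa_assay(stack, profile_thickness_px=56)
print(f"stability ratio (bleach-corrected): {res.stability_ratio:.3f} "
      f"[truth {pa.survival_30s}]")
print(f"stability ratio (raw):              {res.stability_ratio_raw:.3f} "
      f"— lower because ~{100 * (1 - res.bleach_factor_30s):.0f}% "
      f"of signal also bleached")
print(f"sliding velocity: {res.sliding_velocity.value:.2f} μm/min "
      f"[truth {pa.v_slide}]")
print("a stability ratio near 1 means stable midzone microtubules; the")
print("sliding velocity is the growth rate of the activated band's length")
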