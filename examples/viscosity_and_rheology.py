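"""Viscometry: intercalation lengthens DNA, groove binding does not.

Flow times of a dsDNA solution under incremental drug additions are reduced
to the cube-root relative viscosity (eta/eta0)^(1/3) versus r = [drug]/[DNA]
and trend-tested; a rheometer flow curve is fitted to the Herschel-Bulkley
model tau = tau0 + K*gamma^n.
"""

from dnabind import (
    PAPER_TRUTH,
    gen_flow_times,
    gen_rheogram,
    herschel_bulkley_fit,
    relative_viscosity_series,
    viscosity_trend_test,
)

series = relative_viscosity_series(gen_flow_times(PAPER_TRUTH, seed=6))
trend = viscosity_trend_test(series)
hb = herschel_bulkley_fit(gen_rheogram(PAPER_TRUTH, seed=7))

print(f"(eta/eta0)^(1/3) over r = 0..3: {series[0].value:.3f} .. {series[-1].value:.3f}")
lo, hi = trend.slope_ci
print(f"trend : {trend.classification} (slope {trend.slope:+.4f}, 95% CI [{lo:+.4f}, {hi:+.4f}])")
print(f"Herschel-Bulkley: tau0 = {hb.tau0:.3f} Pa, K = {hb.k:.3g} Pa s^n, n = {hb.n:.2f}")
print(f"apparent viscosity at 1000 1/s: {1e3 * hb.apparent_viscosity(1000.0):.2f} mPa s")
print()
print("A flat relative-viscosity series means the helix is not lengthened:")
print("no intercalation.")
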