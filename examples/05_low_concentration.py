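"""Low-concentration robustness of dip detection versus PCA zoning.

Reruns the full design with all amounts scaled to 10% and 1% of the
standard values: direct dip reading degrades long before the PCA score
plane stops separating amount and composition.
"""

from seiralab import robustness_experiment
from seiralab.pca import BAND_WAVELENGTHS_NM, detect_band_dips, simulate_design

for scale in (1.0, 0.1, 0.01):
    ds = simulate_design(scale=scale)
    detected = {b: False for b in BAND_WAVELENGTHS_NM}
    for sp, mix in zip(ds.spectra, ds.mixtures):
        for band, ok in detect_band_dips(sp, mix).items():
            detected[band] = detected[band] or ok
    report = robustness_experiment(scale, sigma=0.0, seeds=[0])
    zoning = report.per_seed[0]
    print(f"scale {scale:>5}: bands detectable as dips = "
          f"{sum(detected.values())}/4 {sorted(b for b, v in detected.items() if v)}")
    print(f"            PCA zoning: sign separation = {zoning['sign_separation']}, "
          f"rank order = {zoning['rank_order_ok']}")

print("\nat 1% of the standard amounts no vibrational dip survives, yet the")
print("score plane still resolves both the total amount and the composition")
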