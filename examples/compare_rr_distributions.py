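"""Score the agreement of two beat-interval samples with the full metric
bundle.

Two synthetic RR samples are drawn from slightly different normal laws;
every metric is computed on shared unit-width (1 ms) histograms so the
binning cannot favour either sample.
"""

import numpy as np

from cardiosynth import rr_metric_report

rng = np.random.default_rng(0)
rr_reference = rng.normal(800.0, 30.0, size=400)   # ms
rr_candidate = rng.normal(805.0, 35.0, size=380)

report = rr_metric_report(rr_reference, rr_candidate)
print(f"rHI    {report.rhi:.3f}   (overlap fraction; 1 = identical)")
print(f"rRMSE  {report.rrmse:.4f} (quantile-paired error / reference mean)")
print(f"rEMD   {report.remd:.4f} (normalized transport cost)")
print(f"KL     {report.kl:.3f}   KS {report.ks:.3f}")
print(f"MAE_HR {report.mae_hr:.2f} BPM")
print(f"HRV of reference: mean {report.hrv_mean:.1f} ms, "
      f"STD {report.hrv_std:.1f} ms")
print("\nTwo finite samples from nearby laws overlap only partially on a "
      "1 ms grid\n(rHI ~ 0.67 here), yet their quantile-paired error is ~1% "
      "of the mean interval\n— read rHI for per-bin identity and "
      "rRMSE/KS/rEMD for distributional closeness.")
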