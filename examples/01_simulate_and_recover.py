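"""Plant a two-network covariance in synthetic BOLD and recover it.

Builds the default head phantom with the 13 packaged social-brain ROIs,
simulates one 400-volume run in which same-network ROI signals correlate
at 0.6 and cross-network pairs at 0.1, then runs the analysis pipeline
(extract ROI means -> highpass -> Pearson -> Fisher z -> network summary)
and compares the recovered values with the attenuation-corrected analytic
expectation.
"""

import numpy as np

import hemiconn as hc

phantom = hc.generate_phantom(hc.PhantomSpec())
defs = hc.generate_roi_definitions(phantom.spec)
roiset = hc.build_roi_set(defs, phantom.grid, "bilateral")
model = hc.SignalModel()  # within 0.6, between 0.1, 400 volumes at TR 0.7 s

bold, truth = hc.simulate_bold(phantom, roiset, model, seed=1)
ts = hc.gaussian_highpass(hc.extract_mean_timeseries(bold, roiset, tr=model.tr))
summary = hc.summarize_networks(hc.zmatrix_from_timeseries(ts), roiset.membership)

nvox = np.array([m.n_voxels for m in roiset.masks.values()])
expected = hc.expected_pairwise_correlation(model, nvox)
print(f"phantom: {phantom.n_brain_voxels} brain voxels, "
      f"{len(roiset.masks)} ROIs of ~{int(nvox.mean())} voxels")
print(f"recovered within-ToM z  = {summary.within_tom:.3f}")
print(f"recovered within-PAIN z = {summary.within_pain:.3f}")
print(f"recovered between z     = {summary.between:.3f}")
print(f"pooled within - between = {summary.diff:.3f}")
print(f"analytic within z ~ {np.arctanh(expected[0, 1]):.3f}, "
      f"between z ~ {np.arctanh(expected[0, 7]):.3f}")
print("A positive difference means the two networks are distinct, the "
      "signature the analysis looks for in every subject; single-run values "
      "scatter around the analytic expectation by a few hundredths.")
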