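"""ECG preprocessing, R-peak detection and variance-based SNR.

Runs the full chain (90 Hz low-pass, 50/80 Hz notches, 1-s moving-average
baseline removal, variance-based segment rejection), detects R peaks with
the Pan-Tompkins stages, and estimates SNR as the variance ratio between
the whole signal and 100 ms inter-beat noise windows.
"""

import numpy as np

from epibench import (ElectrodeModel, detect_r_peaks, ecg_chain, ecg_snr,
                      sample_cohort_templates, synthesize_ecg)

template = sample_cohort_templates(1, seed=7)[0]
for electrode in (ElectrodeModel.pphg(), ElectrodeModel.agcl()):
    rec = synthesize_ecg(template, leads=1, duration=60.0,
                         electrode=electrode, seed=7)
    clean, mask = ecg_chain(rec)
    r_times = detect_r_peaks(clean)
    snr = ecg_snr(clean, r_times)
    truth = rec.truth["r_times"]
    hits = (np.abs(r_times[:, None] - truth[None, :]).min(axis=1) <= 0.05).sum()
    print(f"{electrode.kind}: {len(r_times)} detections "
          f"({hits}/{len(truth)} truth matched), "
          f"{mask.n_rejected} samples rejected, SNR {snr['snr_db']:.1f} dB")

print("\nBoth electrode models carry the same environmental noise; the")
print("hydrogel model's lower pickup and low-pass transfer yield the")
print("higher SNR, while detection stays essentially perfect for both.")
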