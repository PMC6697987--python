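"""Quantify tremor amplitude in a single noisy movement signal.

Builds a 3 s joint-angle trace containing a 5 Hz tremor of 1.5 degrees
zero-to-peak buried in broadband noise and slow voluntary drift, then runs
the spectral chain: Welch PSD, tremor-peak location, the +/- 1 Hz amplitude
band, heuristic screening, and the calibrated average tremor amplitude
(ATA).  The ATA is calibrated to the peak-to-peak amplitude, so the
expected reading for this signal is ~3 degrees.
"""

import numpy as np

from tremorprofile import ata, ata_band, locate_tremor_peak, reject_estimate, welch_psd

fs = 100.0
t = np.arange(int(3.0 * fs)) / fs
rng = np.random.default_rng(42)

tremor = 1.5 * np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
drift = 2.0 * np.sin(2 * np.pi * 0.3 * t)          # slow voluntary movement
noise = 0.2 * rng.standard_normal(len(t))          # broadband sensor noise
signal = tremor + drift + noise

spectrum = welch_psd(signal, fs)
f_t = locate_tremor_peak(spectrum)
spectrum.f1, spectrum.f2 = ata_band(f_t)
report = reject_estimate(spectrum, duration_s=3.0)
amplitude = ata(spectrum)

print(f"tremor peak          : {f_t:.2f} Hz")
print(f"amplitude band       : {spectrum.f1:.2f}-{spectrum.f2:.2f} Hz")
print(f"screening            : {'accepted' if report.accepted else report.reasons}")
print(f"ATA (peak-to-peak)   : {amplitude:.2f} deg (true 3.00)")
print()
print("The screening accepted the estimate because the spectral peak stands")
print("clear of the comparison band; the ATA reads the tremor's peak-to-peak")
print("amplitude while ignoring the larger sub-2 Hz voluntary drift.")
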