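"""Detect quadratic phase coupling with the bicoherence.

Two signals share the same power spectrum — cosines at 20, 30 and 50 Hz in
noise — but only one couples the phases (φ3 = φ1 + φ2).  The bicoherence at
(30, 20) Hz separates them cleanly; the power spectrum cannot.
"""

import hoseeg as h

grid = h.BiFrequencyGrid(nfft=64, fs=h.BONN_FS)
i, j = grid.nearest_cell(20.0, 30.0)
i, j = max(i, j), min(i, j)  # order into the principal domain (f1 ≥ f2)

for coupled in (True, False):
    spec = h.QPCSpec(f1=20.0, f2=30.0, coupled=coupled, noise_sd=0.05,
                     n_samples=4096, seed=0, phase_block=64)
    record = h.gen_qpc_signal(spec)
    segments = h.make_segments(record.samples, seg_len=64)  # 64 segments
    bic = h.bicoherence(segments, nfft=64, fs=record.fs)
    kind = "coupled  " if coupled else "uncoupled"
    print(f"{kind} triple: bicoherence at (30, 20) Hz = {bic.values[i, j]:.3f}")

print("\nValues near 1 mean nearly all energy at the frequency pair is "
      "phase-coupled; the uncoupled value is the estimator's noise floor "
      "(~1/sqrt(segments)).")
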