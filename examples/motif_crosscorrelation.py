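"""Cross-correlate a coefficient track with a motif affinity landscape.

Plants a TATA-like motif at a fixed offset upstream of simulated
"promoter" positions, builds the pseudo-PSAM affinity landscape of each
1 kb window, and cross-correlates it against a synthetic coefficient
track peaking at the promoters: the correlation peaks at the planted
offset, mirroring how motif occupancy aligns with regulatory signal.
"""

import numpy as np

import suredec as sd

rng = np.random.default_rng(7)
motif = "TATAAA"
counts = np.zeros((4, len(motif)))
for p, base in enumerate(motif):
    counts["ACGT".index(base), p] = 20
    counts[:, p] += 1  # pseudo-counts
psam = sd.counts_to_psam(counts)
print(f"pseudo-PSAM width {psam.shape[1]}, column maxima "
      f"{psam.max(axis=0).tolist()}")

offset = 50  # motif planted 50 bp upstream of each signal peak
signals, references = [], []
for _ in range(120):
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    peak = int(rng.integers(300, 700))
    seq = seq[: peak - offset] + motif + seq[peak - offset + len(motif):]
    profile = sd.affinity_landscape(seq, psam)
    coef = np.zeros(1000)
    coef[peak - 10 : peak + 10] = 0.05  # regulatory signal at the peak
    coef += rng.normal(scale=0.005, size=1000)
    signals.append(coef)
    references.append(profile)

lags, values = sd.cross_correlation(signals, references, max_lag=150, smooth_window=25)
best = lags[np.nanargmax(values)]
print(f"cross-correlation peaks at lag {best} bp "
      f"(motif planted {offset} bp upstream of the signal)")
lag_zero = values[lags == 0][0]
print(f"correlation at lag 0: {lag_zero:.4f}; at the peak: {np.nanmax(values):.4f}")
# A negative peak lag means the motif affinity sits upstream of the
# coefficient signal, as constructed.

alags, avalues = sd.auto_correlation(references, max_lag=150, smooth_window=25)
print(f"affinity auto-correlation max (lag != 0): {np.nanmax(avalues):.4f} "
      "- isolated motifs give a narrow auto-correlation")
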