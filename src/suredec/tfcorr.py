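"""Motif affinity landscapes and their correlation with coefficient tracks.

A motif count matrix is turned into a pseudo position-specific affinity
matrix (pseudo-PSAM) by dividing each column by its most abundant
nucleotide count, so every column's maximum is 1. The affinity of a
sequence window is the product of the matching PSAM entries; the forward-
and reverse-strand window affinities are summed and assigned to the
window's central position, yielding an affinity landscape over a region
(typically a ChIP peak or promoter window). Landscapes are then cross- or
auto-correlated with coefficient tracks per region and averaged per lag.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import Region

__all__ = [
    "counts_to_psam",
    "affinity_landscape",
    "cross_correlation",
    "auto_correlation",
    "promoter_windows",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


def counts_to_psam(counts: np.ndarray) -> np.ndarray:
    """Pseudo-PSAM: each column divided by its maximum count.

    Input is a 4 x m non-negative matrix in A, C, G, T row order; output
    columns all have max 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x width")
    if (counts < 0).any():
        raise ValueError("negative motif counts")
    colmax = counts.max(axis=0)
    if (colmax <= 0).any():
        raise ValueError("all-zero motif column")
    return counts / colmax


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unexpected base {exc.args[0]!r} in sequence") from exc


def affinity_landscape(sequence: str, psam: np.ndarray) -> np.ndarray:
    """Both-strand affinity profile of ``sequence`` under ``psam``.

    For each window start s the forward affinity is the product of PSAM
    entries over the window and the reverse affinity is the same product
    on the reverse-complemented window; their sum is assigned to the
    central position s + floor(m/2) (the right-of-center base for even
    widths). Windows containing N score 0. Returns a full-length array
    with NaN where no complete window is centered; an empty array if the
    sequence is shorter than the motif.
    """
    psam = np.asarray(psam, dtype=float)
    m = psam.shape[1]
    enc = _encode(sequence)
    L = enc.size
    if L < m:
        return np.array([])
    # pad PSAM with a zero row so N (index 4) annihilates its window
    w = np.vstack([psam, np.zeros(m)])
    # reverse-complement PSAM: scoring the revcomp of a window with psam
    # equals scoring the window itself with comp-rows reversed-columns
    w_rc = w[_COMPLEMENT][:, ::-1]
    n_win = L - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, m)
    fwd = np.prod(w[windows, np.arange(m)], axis=1)
    rev = np.prod(w_rc[windows, np.arange(m)], axis=1)
    out = np.full(L, np.nan)
    out[m // 2 : m // 2 + n_win] = fwd + rev
    return out


def _pearson_at_lag(signal: np.ndarray, reference: np.ndarray, lag: int):
    """Pearson r of signal[i] vs reference[i + lag] over the valid overlap."""
    n = signal.size
    if lag >= 0:
        x, y = signal[: n - lag], reference[lag:]
    else:
        x, y = signal[-lag:], reference[: n + lag]
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean, NaN-aware, shrinking at the edges."""
    if window <= 1:
        return values
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        seg = values[max(0, i - half) : i + half + 1]
        out[i] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
    return out


def cross_correlation(
    signal_profiles: list[np.ndarray],
    reference_profiles: list[np.ndarray],
    max_lag: int,
    smooth_window: int = 25,
):
    """Average per-lag Pearson correlation between matched region profiles.

    For each region pair and lag d the correlation between the signal and
    the reference shifted by d is computed over their overlap; per-lag
    values are averaged arithmetically across regions (regions degenerate
    at a lag are skipped), then smoothed last with a centered running mean
    of width ``smooth_window``. Lags run -max_lag..+max_lag; a lag at
    which every region is degenerate is reported NaN.

    Returns ``(lags, values)``.
    """
    if len(signal_profiles) != len(reference_profiles):
        raise ValueError("signal and reference region lists must match")
    if not signal_profiles:
        raise ValueError("no regions")
    for s, r in zip(signal_profiles, reference_profiles):
        if len(s) != len(r):
            raise ValueError("profiles within a region pair must have equal length")
        if max_lag >= len(s):
            raise ValueError("max_lag must be smaller than the region length")
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.full(lags.size, np.nan)
    for li, lag in enumerate(lags):
        rs = [
            r
            for s, ref in zip(signal_profiles, reference_profiles)
            if (r := _pearson_at_lag(np.asarray(s, float), np.asarray(ref, float), int(lag)))
            is not None
        ]
        if rs:
            values[li] = float(np.mean(rs))
    return lags, _smooth(values, smooth_window)


def auto_correlation(
    profiles: list[np.ndarray], max_lag: int, smooth_window: int = 25
):
    """Cross-correlation of each profile with itself; lag 0 is omitted."""
    lags, values = cross_correlation(profiles, profiles, max_lag, smooth_window)
    keep = lags != 0
    return lags[keep], values[keep]


def promoter_windows(
    tss_list: list[tuple[str, int, str]],
    width: int = 1000,
    contig_lengths: dict[str, int] | None = None,
) -> list[Region]:
    """Fixed-width windows centered on TSSs, orientation-aware.

    Each TSS (chrom, position, strand) yields the window
    [tss - width//2, tss + width//2) carrying the TSS strand; profiles
    extracted from '-' windows should be reversed so "upstream" aligns
    across promoters (see :func:`oriented_profile`). Windows running off a
    contig end are truncated with a warning.
    """
    regions = []
    for chrom, tss, strand in tss_list:
        start, end = tss - width // 2, tss + width // 2
        limit = contig_lengths.get(chrom) if contig_lengths else None
        t_start, t_end = max(0, start), min(end, limit) if limit is not None else end
        if (t_start, t_end) != (start, end):
            warnings.warn(
                f"window {chrom}:{start}-{end} truncated to {t_start}-{t_end}",
                stacklevel=2,
            )
        regions.append(Region(chrom, t_start, t_end, strand))
    return regions


def oriented_profile(values: np.ndarray, region: Region) -> np.ndarray:
    """Reverse a profile extracted from a minus-strand window."""
    return values[::-1] if region.strand == "-" else values
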