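"""Expression prediction for hypothetical fragments from a coefficient track.

The predicted expression of a fragment is exp(sum of per-bp coefficients
over its span + theta_L * length): the length coefficient is folded into
every base, while library- and fragment-specific covariates (sequencing
depth, input count) are deliberately excluded, so predictions are on a
depth-normalized scale. Positions without a coefficient (no training
coverage) contribute 0 and their count is surfaced so users can distrust
predictions spanning coverage gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Region, SuREElement
from .track import CoefficientTrack

__all__ = [
    "predict_fragment",
    "predict_batch",
    "PromoterMap",
    "promoter_map",
    "optimal_fragment",
    "grouped_validation",
    "filter_seen",
]


def predict_fragment(
    track: CoefficientTrack, region: Region, return_uncovered: bool = False
):
    """Predicted expression exp(sum coef + theta_L * L) for one region."""
    if not any(k[0] == region.chrom for k in track.data):
        raise ValueError(f"unknown contig {region.chrom!r}")
    total, uncovered = track.interval_sum(
        region.chrom, region.strand, region.start, region.end
    )
    pred = float(np.exp(total + track.theta_L * region.length))
    return (pred, uncovered) if return_uncovered else pred


def predict_batch(track: CoefficientTrack, regions: list[Region]) -> pd.DataFrame:
    """One prediction per region, order-preserving; errors reported per row."""
    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom, "start": r.start, "end": r.end, "strand": r.strand,
            "log_prediction": np.nan, "prediction": np.nan,
            "uncovered_bp": -1, "error": "",
        }
        try:
            pred, uncovered = predict_fragment(track, r, return_uncovered=True)
            row.update(
                log_prediction=float(np.log(pred)), prediction=pred, uncovered_bp=uncovered
            )
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PromoterMap:
    """2D map of predicted expression for all sub-fragments of a window.

    ``log_pred[l - min_len, s - window_start]`` is the log prediction of
    the fragment [s, s + l); entries whose fragment exits the window are
    NaN. Rendered with fragment center on x and size on y.
    """

    chrom: str
    strand: str
    window_start: int
    window_end: int
    min_len: int
    max_len: int
    log_pred: np.ndarray
    uncovered: np.ndarray

    def entry(self, start: int, end: int) -> float:
        """Predicted expression for the fragment [start, end)."""
        return float(np.exp(self.log_pred[end - start - self.min_len, start - self.window_start]))

    def entries(self):
        """Yield (start, end, prediction) over all defined map entries."""
        for li in range(self.log_pred.shape[0]):
            length = li + self.min_len
            for si in range(self.log_pred.shape[1]):
                v = self.log_pred[li, si]
                if not np.isnan(v):
                    start = self.window_start + si
                    yield start, start + length, float(np.exp(v))

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame: rows = fragment size, columns = start."""
        return pd.DataFrame(
            self.log_pred,
            index=pd.Index(range(self.min_len, self.max_len + 1), name="size"),
            columns=pd.Index(
                range(self.window_start, self.window_end), name="start"
            ),
        )


def promoter_map(
    track: CoefficientTrack,
    chrom: str,
    center: int,
    strand: str = "+",
    max_len: int = 600,
    min_len: int = 1,
    step: int = 1,
) -> PromoterMap:
    """Predictions for every (start, end) pair in the window around ``center``.

    The window is [center - max_len, center + max_len); computed via prefix
    sums so each entry costs O(1). ``step`` coarsens the start/length grid.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    w_start, w_end = center - max_len, center + max_len
    key = (chrom, strand)
    if key not in track.data:
        raise ValueError(f"no track coverage for {chrom} strand {strand}")
    # reuse the track's own prefix sums so every map entry is bit-identical
    # to the corresponding predict_fragment call
    if np.searchsorted(track.data[key][0], w_start) == np.searchsorted(
        track.data[key][0], w_end
    ):
        raise ValueError(f"window {chrom}:{w_start}-{w_end} has no track coverage")

    positions, _ = track.data[key]
    track.interval_sum(chrom, strand, w_start, w_end)  # ensure prefix cache
    prefix = track._prefix[key]

    W = w_end - w_start
    n_len = max_len - min_len + 1
    log_pred = np.full((n_len, W), np.nan)
    unc = np.full((n_len, W), -1, dtype=np.int64)
    for li in range(0, n_len, step):
        length = li + min_len
        starts = np.arange(0, W - length + 1, step)
        lo = np.searchsorted(positions, w_start + starts, side="left")
        hi = np.searchsorted(positions, w_start + starts + length, side="left")
        log_pred[li, starts] = (prefix[hi] - prefix[lo]) + track.theta_L * length
        unc[li, starts] = length - (hi - lo)
    return PromoterMap(chrom, strand, w_start, w_end, min_len, max_len, log_pred, unc)


def optimal_fragment(pmap: PromoterMap) -> tuple[Region, float]:
    """Map entry with the highest prediction.

    Ties are broken deterministically: shorter fragment first, then
    smaller start.
    """
    best = -np.inf
    best_key = None
    n_len, W = pmap.log_pred.shape
    for li in range(n_len):  # increasing length => shorter wins ties
        row = pmap.log_pred[li]
        if np.all(np.isnan(row)):
            continue
        si = int(np.nanargmax(row))
        if row[si] > best:
            best = row[si]
            best_key = (li, si)
    if best_key is None:
        raise ValueError("empty promoter map")
    li, si = best_key
    start = pmap.window_start + si
    region = Region(pmap.chrom, start, start + li + pmap.min_len, pmap.strand)
    return region, float(np.exp(best))


def grouped_validation(
    predictions: np.ndarray,
    observations: np.ndarray,
    regions: list[Region],
    bin_size: int = 50,
) -> tuple[pd.DataFrame, float]:
    """Endpoint-binned comparison of predicted vs observed expression.

    Each element (``regions[i]`` with prediction ``predictions[i]`` and
    observed normalized expression ``observations[i]``) is assigned to a
    start bin floor(start / bin_size) and an end bin floor(end / bin_size);
    elements sharing both bins form a group. Per group the mean of log
    predictions and the log of the mean observation are computed, and the
    Pearson correlation between those two group-level vectors (log space)
    is returned. Groups with zero mean observation are dropped.
    """
    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    if len(regions) != predictions.size or predictions.size != observations.size:
        raise ValueError("predictions, observations and regions must align")
    if (predictions <= 0).any():
        raise ValueError("predictions must be positive")
    rows = []
    groups: dict = {}
    for i, r in enumerate(regions):
        key = (r.chrom, r.strand, r.start // bin_size, r.end // bin_size)
        groups.setdefault(key, []).append(i)
    n_dropped = 0
    for key, idx in sorted(groups.items()):
        mean_obs = observations[idx].mean()
        if mean_obs <= 0:
            n_dropped += 1
            continue
        rows.append(
            {
                "chrom": key[0], "strand": key[1],
                "start_bin": key[2], "end_bin": key[3],
                "n_elements": len(idx),
                "mean_log_pred": float(np.mean(np.log(predictions[idx]))),
                "log_mean_obs": float(np.log(mean_obs)),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_dropped_zero_obs"] = n_dropped
    if len(table) < 3:
        raise ValueError(f"only {len(table)} usable groups; correlation is meaningless")
    x = table["mean_log_pred"].to_numpy()
    yv = table["log_mean_obs"].to_numpy()
    r = float(np.corrcoef(x, yv)[0, 1]) if x.std() > 0 and yv.std() > 0 else float("nan")
    return table, r


def filter_seen(
    elements: list[SuREElement], seen: list[SuREElement] | list[Region]
) -> list[SuREElement]:
    """Drop elements whose (chrom, start, end, strand) matches a seen fragment.

    Used before validation so only fragments absent from the training
    libraries (hence purely predicted) are scored.
    """
    seen_keys = {(s.chrom, s.start, s.end, s.strand) for s in seen}
    return [e for e in elements if (e.chrom, e.start, e.end, e.strand) not in seen_keys]
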