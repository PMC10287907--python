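"""Per-base-pair coefficient tracks derived from fitted bin coefficients.

Each position of bin j carries the value beta_j / sqrt(l_j): the additive
contribution, on the natural-log expression scale, of including that base
in a reporter fragment. Summed over the bin this recovers the bin's total
contribution sqrt(l_j) * beta_j to any containing element's linear
predictor, so predictions are invariant to how coverage was partitioned
into bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .binning import Bin
from .glm import BlockFit

__all__ = ["CoefficientTrack", "bins_to_track", "merge_block_fits", "compare_tracks"]


@dataclass
class CoefficientTrack:
    """Sparse per-bp coefficient map, keyed by (chrom, strand).

    ``data[(chrom, strand)] = (positions, values)`` with positions sorted
    strictly increasing. ``theta_L`` (the length coefficient) travels with
    the track so fragment prediction is self-contained.
    """

    data: dict = field(default_factory=dict)
    theta_L: float = 0.0
    metadata: dict = field(default_factory=dict)
    _prefix: dict = field(default_factory=dict, repr=False)

    def add(self, chrom: str, strand: str, positions: np.ndarray, values: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if positions.size and (np.diff(positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        key = (chrom, strand)
        if key in self.data:
            p0, v0 = self.data[key]
            positions = np.concatenate([p0, positions])
            values = np.concatenate([v0, values])
            order = np.argsort(positions, kind="stable")
            positions, values = positions[order], values[order]
            if (np.diff(positions) == 0).any():
                raise ValueError(f"overlapping coefficients for {key}")
        self.data[key] = (positions, values)
        self._prefix.pop(key, None)

    def interval_sum(self, chrom: str, strand: str, start: int, end: int):
        """(sum of coefficients, number of uncovered bp) over [start, end)."""
        key = (chrom, strand)
        if key not in self.data:
            return 0.0, end - start
        positions, values = self.data[key]
        if key not in self._prefix:
            self._prefix[key] = np.concatenate(([0.0], np.cumsum(values)))
        prefix = self._prefix[key]
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, end, side="left")
        return float(prefix[hi] - prefix[lo]), int((end - start) - (hi - lo))

    def values_in(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp values over [start, end); uncovered positions are 0."""
        out = np.zeros(end - start)
        key = (chrom, strand)
        if key in self.data:
            positions, values = self.data[key]
            lo = np.searchsorted(positions, start, side="left")
            hi = np.searchsorted(positions, end, side="left")
            out[positions[lo:hi] - start] = values[lo:hi]
        return out

    @property
    def n_positions(self) -> int:
        return sum(p.size for p, _ in self.data.values())

    def to_bedgraph(self, prefix, strand_mode: str = "suffix") -> list[Path]:
        """Write per-strand bedGraph files plus a JSON metadata sidecar."""
        prefix = Path(prefix)
        written = sio.write_bedgraph(self.data, prefix, strand_mode=strand_mode)
        sidecar = prefix.with_name(prefix.name + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"theta_L": self.theta_L, **self.metadata}, fh, indent=1)
        return written + [sidecar]

    @classmethod
    def from_bedgraph(cls, prefix) -> "CoefficientTrack":
        prefix = Path(prefix)
        track = cls()
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            path = prefix.with_name(prefix.name + f".{suffix}.bedgraph")
            if path.exists():
                for key, pv in sio.read_bedgraph(path, strand=strand).items():
                    track.add(key[0], key[1], *pv)
        sidecar = prefix.with_name(prefix.name + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            track.theta_L = float(meta.pop("theta_L", 0.0))
            track.metadata = meta
        return track


def bins_to_track(bins: list[Bin], beta: np.ndarray, theta_L: float = 0.0) -> CoefficientTrack:
    """Spread bin coefficients onto their positions as beta_j / sqrt(l_j)."""
    beta = np.asarray(beta, dtype=float)
    if len(bins) != beta.size:
        raise ValueError(f"{len(bins)} bins but {beta.size} coefficients")
    track = CoefficientTrack(theta_L=theta_L)
    by_key: dict = {}
    for b, bv in zip(bins, beta):
        by_key.setdefault((b.chrom, b.strand), []).append((b, bv))
    for (chrom, strand), items in by_key.items():
        items.sort(key=lambda t: t[0].start)
        positions = np.concatenate([np.arange(b.start, b.end) for b, _ in items])
        values = np.repeat(
            [bv / np.sqrt(b.length) for b, bv in items],
            [b.length for b, _ in items],
        )
        track.add(chrom, strand, positions, values)
    return track


def merge_block_fits(fits: list[BlockFit], theta_L: float, **metadata) -> CoefficientTrack:
    """Assemble one genome-wide track from independent per-block spatial fits."""
    track = CoefficientTrack(theta_L=theta_L, metadata=dict(metadata))
    for fit in fits:
        sub = bins_to_track(fit.bins, fit.beta)
        for (chrom, strand), (pos, val) in sub.data.items():
            track.add(chrom, strand, pos, val)
    return track


def compare_tracks(
    a: CoefficientTrack,
    b: CoefficientTrack,
    per_strand: bool = False,
    union: bool = False,
):
    """Pearson correlation between two tracks.

    By default the correlation is computed over the intersection of
    covered positions, both strands concatenated. ``union=True`` instead
    uses the union of covered positions with absent values treated as 0.
    ``per_strand=True`` returns a dict keyed by strand.
    """
    def collect(strands):
        xs, ys = [], []
        keys = set(a.data) | set(b.data)
        for key in sorted(keys):
            if key[1] not in strands:
                continue
            pa, va = a.data.get(key, (np.array([], dtype=np.int64), np.array([])))
            pb, vb = b.data.get(key, (np.array([], dtype=np.int64), np.array([])))
            if union:
                pos = np.union1d(pa, pb)
                xa = np.zeros(pos.size)
                xa[np.searchsorted(pos, pa)] = va
                xb = np.zeros(pos.size)
                xb[np.searchsorted(pos, pb)] = vb
            else:
                pos, ia, ib = np.intersect1d(pa, pb, return_indices=True)
                xa, xb = va[ia], vb[ib]
            xs.append(xa)
            ys.append(xb)
        return (np.concatenate(xs) if xs else np.array([]),
                np.concatenate(ys) if ys else np.array([]))

    def pearson(x, y):
        if x.size < 2:
            raise ValueError("need >= 2 jointly covered positions")
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero variance on the compared positions")
        return float(np.corrcoef(x, y)[0, 1])

    if per_strand:
        return {s: pearson(*collect({s})) for s in "+-"}
    return pearson(*collect({"+", "-"}))
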