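import numpy as np
import pytest

from suredec import SuREElement


def make_element(start, end, strand="+", chrom="chr1", lib=1, ipcr=1, cdna=0):
    return SuREElement(
        chrom=chrom, start=start, end=end, strand=strand,
        library_id=lib, ipcr_count=ipcr, cdna_count=cdna,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_elements(rng, n, contig_len, strand=None, chrom="chr1"):
    """Random small fragment set for oracle comparisons."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, contig_len - 1))
        end = int(rng.integers(start + 1, min(start + 400, contig_len) + 1))
        s = strand or ("+" if rng.random() < 0.5 else "-")
        out.append(
            make_element(start, end, s, chrom=chrom,
                         lib=int(rng.integers(1, 3)),
                         ipcr=int(rng.integers(1, 5)),
                         cdna=int(rng.integers(0, 10)))
        )
    return out


def brute_force_bins(elements, strand, chrom="chr1"):
    """Per-position overlap-set oracle: group maximal equal runs.

    Independent of the sweep implementation: materializes the full
    element x position membership matrix, compares the overlap set at
    every single position with its neighbour, and merges equal runs.
    """
    sel = [(i, e) for i, e in enumerate(elements) if e.strand == strand and e.chrom == chrom]
    if not sel:
        return []
    hi = max(e.end for _, e in sel)
    member = np.zeros((len(sel), hi + 1), dtype=bool)
    for row, (_, e) in enumerate(sel):
        member[row, e.start : e.end] = True
    runs = []
    run_start = None
    prev = np.zeros(len(sel), dtype=bool)
    for p in range(hi + 1):
        cur = member[:, p]
        if (cur != prev).any():
            if run_start is not None and prev.any():
                ids = frozenset(sel[r][0] for r in np.flatnonzero(prev))
                runs.append((run_start, p, ids))
            run_start = p if cur.any() else None
            prev = cur
    if run_start is not None and prev.any():
        ids = frozenset(sel[r][0] for r in np.flatnonzero(prev))
        runs.append((run_start, hi + 1, ids))
    return runs
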