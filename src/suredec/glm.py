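"""Design-matrix construction, penalty tuning and the two-step fit.

The model for element i with reporter count y_i is

    y_i ~ Poisson(exp(mu_i))
    mu_i = sum_j x_ij b_j + L_i * th_L
           + sum_k z_ik * (th_k0 + log(n_i) * th_k1 + log(n_i)^2 * th_k2)

where x_ij = sqrt(l_j) if element i contains bin j (0 otherwise), L_i is
the element length, z_ik indicates its library and n_i its input (iPCR)
count. Spatial coefficients b_j are elastic-net penalized; the non-spatial
coefficients th are unpenalized. No covariate standardization is applied:
the sqrt-bin-length coding already equalizes the implied prior variance
across bins of different widths.

Genome-scale fits proceed in two steps: (1) the full model is fit per
block and the unpenalized coefficients averaged across blocks; (2) those
averages are frozen into per-element offsets and only the spatial
coefficients are re-fit per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .binning import Bin, GenomicBlock, build_bins
from .io import SuREElement
from .solver import FitResult, fit_penalized_poisson

__all__ = [
    "DesignMatrix",
    "PenaltyConfig",
    "ModelCoefficients",
    "ThetaBar",
    "BlockFit",
    "TuneResult",
    "build_design",
    "fit_poisson_elasticnet",
    "lambda_max",
    "make_lambda_path",
    "tune_penalties",
    "fit_nonspatial_step",
    "compute_offsets",
    "fit_spatial_step",
    "two_step_fit",
    "deconvolve",
]

MU_LL_CLAMP = 30.0  # exp() guard when scoring held-out elements


@dataclass
class PenaltyConfig:
    """Elastic-net configuration: lam1 = alpha*lam (L1), lam2 = (1-alpha)*lam (L2)."""

    alpha: float
    lam: float
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    tol: float = 1e-7
    max_iter: int = 100
    seed: int = 0
    test_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class DesignMatrix:
    """Sparse design for one (block, strand) fit unit.

    Column layout: ``J`` spatial bin columns, then (unless
    ``spatial_only``) the length column and, per library ``k`` in
    ``libraries`` order, the indicator, indicator*log(n) and
    indicator*log(n)^2 columns.
    """

    X: sp.csc_matrix
    y: np.ndarray
    penalty_factors: np.ndarray
    bins: list[Bin]
    libraries: list[int]
    spatial_only: bool

    @property
    def n_spatial(self) -> int:
        return len(self.bins)

    @property
    def n_obs(self) -> int:
        return self.y.size


@dataclass
class ModelCoefficients:
    """Fitted coefficients: spatial beta per bin plus non-spatial theta."""

    beta: np.ndarray
    theta_L: float = 0.0
    theta0: dict[int, float] = field(default_factory=dict)
    theta1: dict[int, float] = field(default_factory=dict)
    theta2: dict[int, float] = field(default_factory=dict)

    @classmethod
    def from_vector(cls, coef: np.ndarray, design: DesignMatrix) -> "ModelCoefficients":
        J = design.n_spatial
        beta = coef[:J].copy()
        if design.spatial_only:
            return cls(beta=beta)
        K = len(design.libraries)
        th_L = float(coef[J])
        th0 = {lib: float(coef[J + 1 + k]) for k, lib in enumerate(design.libraries)}
        th1 = {lib: float(coef[J + 1 + K + k]) for k, lib in enumerate(design.libraries)}
        th2 = {lib: float(coef[J + 1 + 2 * K + k]) for k, lib in enumerate(design.libraries)}
        return cls(beta=beta, theta_L=th_L, theta0=th0, theta1=th1, theta2=th2)


@dataclass
class ThetaBar:
    """Block-averaged non-spatial coefficients used to build offsets."""

    theta_L: float
    theta0: dict[int, float]
    theta1: dict[int, float]
    theta2: dict[int, float]


@dataclass
class BlockFit:
    """Spatial fit of one (block, strand) unit: bins with their beta."""

    block: GenomicBlock
    strand: str
    bins: list[Bin]
    beta: np.ndarray


@dataclass
class TuneResult:
    alpha: float
    lam: float
    table: pd.DataFrame  # columns: alpha, lam, test_ll
    n_extensions: int


# ---------------------------------------------------------------------------
# design construction


def build_design(
    elements: list[SuREElement], bins: list[Bin], spatial_only: bool = False
) -> DesignMatrix:
    """Build the sparse design matrix for elements on one strand.

    ``bins`` must have been built from these elements, so every element's
    interval is exactly tiled by a contiguous run of bins (verified; a
    violation is an internal error in the binning contract).
    """
    if not elements:
        raise ValueError("no elements")
    strands = {e.strand for e in elements}
    if len(strands) != 1 or (bins and bins[0].strand not in strands):
        raise ValueError("elements and bins must share a single strand")

    bin_starts = np.array([b.start for b in bins])
    bin_ends = np.array([b.end for b in bins])
    bin_len = (bin_ends - bin_starts).astype(np.float64)
    cum_len = np.concatenate(([0], np.cumsum(bin_len)))
    sqrt_len = np.sqrt(bin_len)

    starts = np.array([e.start for e in elements])
    ends = np.array([e.end for e in elements])
    i0 = np.searchsorted(bin_starts, starts)
    i1 = np.searchsorted(bin_starts, ends)
    ok = (
        (i0 < len(bins))
        & (bin_starts[np.minimum(i0, len(bins) - 1)] == starts)
        & (bin_ends[i1 - 1] == ends)
        & ((cum_len[i1] - cum_len[i0]) == (ends - starts))
    )
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        raise RuntimeError(
            "internal error: element "
            f"{elements[bad].chrom}:{starts[bad]}-{ends[bad]} is not exactly tiled "
            "by a contiguous bin run (binning contract violated)"
        )

    counts = (i1 - i0).astype(np.int64)
    indptr = np.concatenate(([0], np.cumsum(counts)))
    indices = np.concatenate([np.arange(a, b) for a, b in zip(i0, i1)]) if len(bins) else np.array([], dtype=np.int64)
    data = sqrt_len[indices]
    X_spatial = sp.csr_matrix(
        (data, indices, indptr), shape=(len(elements), len(bins))
    )

    y = np.array([e.cdna_count for e in elements], dtype=np.float64)
    if spatial_only:
        X = X_spatial.tocsc()
        pf = np.ones(len(bins))
        return DesignMatrix(X, y, pf, list(bins), [], True)

    libraries = sorted({e.library_id for e in elements})
    lib_index = {lib: k for k, lib in enumerate(libraries)}
    K = len(libraries)
    L = (ends - starts).astype(np.float64)
    logn = np.log([e.ipcr_count for e in elements])
    dense = np.zeros((len(elements), 1 + 3 * K))
    dense[:, 0] = L
    rows = np.arange(len(elements))
    kcol = np.array([lib_index[e.library_id] for e in elements])
    dense[rows, 1 + kcol] = 1.0
    dense[rows, 1 + K + kcol] = logn
    dense[rows, 1 + 2 * K + kcol] = logn**2
    X = sp.hstack([X_spatial, sp.csc_matrix(dense)], format="csc")
    pf = np.concatenate([np.ones(len(bins)), np.zeros(1 + 3 * K)])
    return DesignMatrix(X, y, pf, list(bins), libraries, False)


def fit_poisson_elasticnet(
    design: DesignMatrix,
    config: PenaltyConfig,
    offsets: np.ndarray | float = 0.0,
    beta0: np.ndarray | None = None,
) -> tuple[ModelCoefficients, FitResult]:
    """Fit the penalized Poisson GLM on one design; see module docstring."""
    res = fit_penalized_poisson(
        design.X,
        design.y,
        lam=config.lam,
        alpha=config.alpha,
        pf=design.penalty_factors,
        offsets=offsets,
        beta0=beta0,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    return ModelCoefficients.from_vector(res.coef, design), res


# ---------------------------------------------------------------------------
# lambda path


def lambda_max(
    design: DesignMatrix, alpha: float, offsets: np.ndarray | float = 0.0
) -> float:
    """Smallest lam at which all penalized coefficients are zero.

    From the KKT conditions at beta = 0:
    lam_max = max_j |x_j^T (y - mu_null)| / (N * alpha), with mu_null the
    fitted mean of the model containing only unpenalized columns and
    offsets (just the offsets for a spatial-only design).
    """
    if alpha <= 0:
        raise ValueError("lambda_max is undefined for alpha = 0")
    n_obs = design.n_obs
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), (n_obs,))
    J = design.n_spatial
    unpen = np.flatnonzero(design.penalty_factors == 0)
    if unpen.size:
        X_null = design.X[:, unpen]
        res = fit_penalized_poisson(
            X_null, design.y, lam=0.0, alpha=1.0, pf=np.zeros(unpen.size), offsets=offsets
        )
        mu_null = np.asarray(X_null @ res.coef).ravel() + offsets
    else:
        mu_null = offsets
    resid = design.y - np.exp(np.clip(mu_null, -MU_LL_CLAMP, MU_LL_CLAMP))
    grad = np.abs(np.asarray(design.X[:, :J].T @ resid)).ravel()
    # tiny relative guard so a fit exactly at lam_max cannot cross the KKT
    # threshold through floating-point summation-order differences
    return float(grad.max(initial=0.0) / (n_obs * alpha)) * (1.0 + 1e-10)


def make_lambda_path(
    lam_max: float, n_lambda: int = 100, lambda_min_ratio: float = 1e-4
) -> np.ndarray:
    """Decreasing, log-evenly-spaced lam sequence starting at lam_max."""
    if lam_max <= 0:
        raise ValueError("lam_max must be positive")
    if lambda_min_ratio >= 1:
        raise ValueError("lambda_min_ratio must be < 1")
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    if n_lambda == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


# ---------------------------------------------------------------------------
# tuning by held-out log-likelihood


def _positions_values(bins: list[Bin], beta: np.ndarray):
    """Per-bp coefficient positions/values for a bin fit (beta_j / sqrt(l_j))."""
    if not bins:
        return np.array([], dtype=np.int64), np.array([])
    lengths = np.array([b.length for b in bins])
    positions = np.concatenate([np.arange(b.start, b.end) for b in bins])
    values = np.repeat(beta / np.sqrt(lengths), lengths)
    return positions, values


def _interval_sums(positions: np.ndarray, values: np.ndarray, starts, ends):
    """Sum of per-bp values over [start, end) per query; absent positions add 0."""
    if positions.size == 0:
        return np.zeros(len(starts))
    prefix = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    return prefix[hi] - prefix[lo]


@dataclass
class _FitUnit:
    """Training design plus held-out elements for one (block, strand)."""

    design: DesignMatrix
    test_elements: list[SuREElement]
    beta_warm: np.ndarray | None = None

    def test_ll(self, coef: ModelCoefficients) -> float:
        """Poisson log-likelihood (up to the log y! constant) of held-out elements.

        Held-out elements are scored through the per-bp coefficient track
        implied by the training fit: positions outside training coverage
        contribute 0.
        """
        if not self.test_elements:
            return 0.0
        pos, val = _positions_values(self.design.bins, coef.beta)
        starts = np.array([e.start for e in self.test_elements])
        ends = np.array([e.end for e in self.test_elements])
        spatial = _interval_sums(pos, val, starts, ends)
        L = (ends - starts).astype(float)
        logn = np.log([e.ipcr_count for e in self.test_elements])
        th0 = np.array([coef.theta0.get(e.library_id, 0.0) for e in self.test_elements])
        th1 = np.array([coef.theta1.get(e.library_id, 0.0) for e in self.test_elements])
        th2 = np.array([coef.theta2.get(e.library_id, 0.0) for e in self.test_elements])
        mu = spatial + L * coef.theta_L + th0 + logn * th1 + logn**2 * th2
        y = np.array([e.cdna_count for e in self.test_elements], dtype=float)
        return float(np.sum(y * mu - np.exp(np.clip(mu, -MU_LL_CLAMP, MU_LL_CLAMP))))


def _make_fit_units(
    blocks: list[GenomicBlock], test_fraction: float, seed: int
) -> list[_FitUnit]:
    rng = np.random.default_rng(seed)
    units: list[_FitUnit] = []
    n_test_total = 0
    for block in blocks:
        n = len(block.elements)
        n_test = int(round(test_fraction * n))
        test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
        n_test_total += n_test
        train = [e for i, e in enumerate(block.elements) if i not in test_idx]
        test = [e for i, e in enumerate(block.elements) if i in test_idx]
        for strand in "+-":
            train_s = [e for e in train if e.strand == strand]
            if not train_s:
                continue
            bins = build_bins(train_s, strand)
            design = build_design(train_s, bins)
            units.append(_FitUnit(design, [e for e in test if e.strand == strand]))
    if n_test_total == 0:
        raise ValueError("hold-out produced an empty test set; increase test_fraction or data size")
    return units


DEFAULT_ALPHA_GRID = (1e-3, 3e-3, 1e-2, 3e-2, 1e-1)


def tune_penalties(
    blocks: list[GenomicBlock],
    alpha_grid=DEFAULT_ALPHA_GRID,
    test_fraction: float = 0.10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    max_extensions: int = 3,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> TuneResult:
    """Select (alpha, lam) by held-out Poisson log-likelihood.

    Within each block 10% of elements (by default) are held out; models are
    fit on the remainder along a warm-started decreasing lam path for each
    alpha, and held-out elements are scored through the implied per-bp
    track. If the best lam for an alpha sits at the path floor, the path is
    extended downward with the same log-spacing (up to ``max_extensions``
    times) so the reported optimum is interior whenever the data allow.
    """
    if not blocks:
        raise ValueError("tune_penalties requires at least one block")
    if not len(alpha_grid):
        raise ValueError("alpha_grid must be non-empty")
    units = _make_fit_units(blocks, test_fraction, seed)

    rows = []
    total_extensions = 0
    for alpha in alpha_grid:
        lam_hi = max(lambda_max(u.design, alpha) for u in units)
        if lam_hi <= 0:
            lam_hi = 1e-12
        path = list(make_lambda_path(lam_hi, n_lambda, lambda_min_ratio))
        step = path[1] / path[0] if len(path) > 1 else lambda_min_ratio
        for u in units:
            u.beta_warm = None
        alpha_rows: list[tuple[float, float]] = []
        cfg = PenaltyConfig(alpha=alpha, lam=lam_hi, tol=tol, max_iter=max_iter)
        extensions = 0
        i = 0
        while i < len(path):
            lam = path[i]
            cfg.lam = lam
            ll = 0.0
            for u in units:
                coefs, res = fit_poisson_elasticnet(u.design, cfg, beta0=u.beta_warm)
                u.beta_warm = res.coef
                ll += u.test_ll(coefs)
            alpha_rows.append((lam, ll))
            at_end = i == len(path) - 1
            if at_end:
                best_i = int(np.argmax([r[1] for r in alpha_rows]))
                if best_i == len(alpha_rows) - 1 and extensions < max_extensions:
                    n_ext = max(2, n_lambda // 2)
                    path.extend(path[-1] * step ** np.arange(1, n_ext + 1))
                    extensions += 1
            i += 1
        total_extensions += extensions
        rows.extend((alpha, lam, ll) for lam, ll in alpha_rows)

    table = pd.DataFrame(rows, columns=["alpha", "lam", "test_ll"])
    best = table.iloc[int(table["test_ll"].idxmax())]
    return TuneResult(
        alpha=float(best["alpha"]),
        lam=float(best["lam"]),
        table=table,
        n_extensions=total_extensions,
    )


# ---------------------------------------------------------------------------
# two-step genome-wide strategy


def _units_full(blocks: list[GenomicBlock]):
    for block in blocks:
        for strand in "+-":
            elems = [e for e in block.elements if e.strand == strand]
            if not elems:
                continue
            yield block, strand, elems


def _fit_at(design: DesignMatrix, alpha: float, lam: float, offsets=0.0,
            tol: float = 1e-7, max_iter: int = 100, path_len: int = 10) -> ModelCoefficients:
    """Fit at a single (alpha, lam) via a short warm-started path from lam_max."""
    lam_hi = lambda_max(design, alpha, offsets)
    cfg = PenaltyConfig(alpha=alpha, lam=lam, tol=tol, max_iter=max_iter)
    beta = None
    if lam_hi > lam > 0:
        for lam_i in np.geomspace(lam_hi, lam, path_len)[:-1]:
            cfg.lam = float(lam_i)
            _, res = fit_poisson_elasticnet(design, cfg, offsets=offsets, beta0=beta)
            beta = res.coef
    cfg.lam = lam
    coefs, _ = fit_poisson_elasticnet(design, cfg, offsets=offsets, beta0=beta)
    return coefs


def fit_nonspatial_step(
    blocks: list[GenomicBlock], alpha: float, lam: float,
    tol: float = 1e-7, max_iter: int = 100,
) -> ThetaBar:
    """Step 1: fit the full model per (block, strand) unit; average theta.

    The averages are arithmetic across fit units; a library absent from a
    unit contributes nothing to that library's average.
    """
    th_L: list[float] = []
    th0: dict[int, list[float]] = {}
    th1: dict[int, list[float]] = {}
    th2: dict[int, list[float]] = {}
    for block, strand, elems in _units_full(blocks):
        bins = build_bins(elems, strand)
        design = build_design(elems, bins)
        try:
            coefs = _fit_at(design, alpha, lam, tol=tol, max_iter=max_iter)
        except Exception as exc:
            raise RuntimeError(
                f"non-spatial fit failed for block {block.chrom}:{block.start}-"
                f"{block.end} strand {strand}: {exc}"
            ) from exc
        th_L.append(coefs.theta_L)
        for lib in design.libraries:
            th0.setdefault(lib, []).append(coefs.theta0[lib])
            th1.setdefault(lib, []).append(coefs.theta1[lib])
            th2.setdefault(lib, []).append(coefs.theta2[lib])
    if not th_L:
        raise ValueError("no fit units (empty blocks)")
    return ThetaBar(
        theta_L=float(np.mean(th_L)),
        theta0={lib: float(np.mean(v)) for lib, v in th0.items()},
        theta1={lib: float(np.mean(v)) for lib, v in th1.items()},
        theta2={lib: float(np.mean(v)) for lib, v in th2.items()},
    )


def compute_offsets(elements: list[SuREElement], theta_bar: ThetaBar) -> np.ndarray:
    """Frozen non-spatial contribution to mu for each element."""
    out = np.empty(len(elements))
    for i, e in enumerate(elements):
        if e.library_id not in theta_bar.theta0:
            raise ValueError(f"element of unknown library {e.library_id}")
        ln = np.log(e.ipcr_count)
        out[i] = (
            e.length * theta_bar.theta_L
            + theta_bar.theta0[e.library_id]
            + ln * theta_bar.theta1[e.library_id]
            + ln**2 * theta_bar.theta2[e.library_id]
        )
    return out


def fit_spatial_step(
    blocks: list[GenomicBlock], theta_bar: ThetaBar, alpha: float, lam: float,
    tol: float = 1e-7, max_iter: int = 100,
) -> list[BlockFit]:
    """Step 2: per-unit spatial-only fits with non-spatial terms as offsets.

    Units are independent; results do not depend on execution order.
    """
    fits: list[BlockFit] = []
    for block, strand, elems in _units_full(blocks):
        bins = build_bins(elems, strand)
        design = build_design(elems, bins, spatial_only=True)
        offsets = compute_offsets(elems, theta_bar)
        coefs = _fit_at(design, alpha, lam, offsets=offsets, tol=tol, max_iter=max_iter)
        fits.append(BlockFit(block=block, strand=strand, bins=bins, beta=coefs.beta))
    return fits


def two_step_fit(
    blocks: list[GenomicBlock], alpha: float, lam: float,
    tol: float = 1e-7, max_iter: int = 100,
) -> tuple[list[BlockFit], ThetaBar]:
    """Run the two-step strategy: averaged theta, then offset spatial fits."""
    theta_bar = fit_nonspatial_step(blocks, alpha, lam, tol=tol, max_iter=max_iter)
    fits = fit_spatial_step(blocks, theta_bar, alpha, lam, tol=tol, max_iter=max_iter)
    return fits, theta_bar


def deconvolve(
    elements: list[SuREElement],
    alpha_grid=DEFAULT_ALPHA_GRID,
    max_block_bp: int = 8_000_000,
    test_fraction: float = 0.10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    tol: float = 1e-7,
    max_iter: int = 100,
):
    """End-to-end: blocks -> penalty tuning -> two-step fit.

    Returns ``(block_fits, theta_bar, tune_result)``; convert the fits to a
    per-bp track with :func:`suredec.track.merge_block_fits`.
    """
    from .binning import partition_blocks

    blocks = partition_blocks(elements, max_block_bp=max_block_bp)
    tune = tune_penalties(
        blocks,
        alpha_grid=alpha_grid,
        test_fraction=test_fraction,
        seed=seed,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
        max_iter=max_iter,
    )
    fits, theta_bar = two_step_fit(blocks, tune.alpha, tune.lam, tol=tol, max_iter=max_iter)
    return fits, theta_bar, tune
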