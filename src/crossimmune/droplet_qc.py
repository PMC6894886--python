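"""Droplet QC: distributional filtering of barcodes, genes, and multiplets.

Droplet scRNA-seq libraries contain three kinds of barcodes: empty droplets
that only captured ambient RNA, droplets with a single cell, and multiplets
that captured two or more cells.  All three leave characteristic signatures
in the distributions of per-barcode UMI totals and per-barcode gene counts,
both of which are strongly bimodal on a log10 axis.  The filters here operate
directly on kernel density estimates of those distributions:

* cell-less barcodes are removed below the first local minimum above a floor
  (default ``log10(#UMIs) = 2``) of the log10 UMI-total density;
* sparsely captured genes are removed below the first local minimum above a
  floor (default ``log10(#barcodes) = 3``) of the log10 detection-count
  density;
* multiplets are sought as secondary local modes of the log10(#genes) and
  log10(#UMIs) distributions whose location exceeds ``ratio`` (default 1.5)
  times the global mode location and which hold fewer than ``max_frac``
  (default 5%) of all barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde


class DegenerateDistributionError(ValueError):
    """All values identical: no density shape to estimate."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes x barcodes UMI count matrix with identifiers.

    ``counts`` is kept in CSR with genes as rows.  Summary vectors are
    recomputed from the matrix, never trusted from callers.
    """

    genes: np.ndarray
    barcodes: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcode identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def umis_per_barcode(self) -> np.ndarray:
        """U_c: total UMIs per barcode."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_barcode(self) -> np.ndarray:
        """G_c: number of genes with count > 0 per barcode."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def detection_per_gene(self) -> np.ndarray:
        """D_g: number of barcodes with count > 0 per gene."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_barcodes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.genes, self.barcodes[mask], self.counts[:, mask])

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.genes[mask], self.barcodes, self.counts[mask, :])


@dataclass
class DensityCurve:
    """Gaussian-KDE density of log10-transformed values on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def local_maxima(self) -> np.ndarray:
        """Grid locations of strict interior local maxima."""
        d = self.density
        idx = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])) + 1
        return self.grid[idx]

    def global_mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class QcReport:
    """Filtering summary: kept/dropped identifier sets with reason codes."""

    kept_barcodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    dropped_barcodes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["barcode", "reason"])
    )
    kept_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    dropped_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    thresholds: dict = field(default_factory=dict)
    modes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "n_kept_barcodes", "value": len(self.kept_barcodes)},
            {"metric": "n_dropped_barcodes", "value": len(self.dropped_barcodes)},
            {"metric": "n_kept_genes", "value": len(self.kept_genes)},
            {"metric": "n_dropped_genes", "value": len(self.dropped_genes)},
        ]
        for k, v in self.thresholds.items():
            rows.append({"metric": f"threshold:{k}", "value": v})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# density machinery
# ---------------------------------------------------------------------------

_GRID_SIZE = 512


def estimate_log10_density(
    values: np.ndarray,
    bandwidth: float | str = "auto",
    grid_size: int = _GRID_SIZE,
) -> DensityCurve:
    """Gaussian-kernel density of log10(values) on a padded uniform grid.

    ``bandwidth="auto"`` uses Silverman's rule.  The grid covers the data
    range padded by three bandwidths on each side.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"need at least 10 values, got {values.size}")
    if np.any(values <= 0):
        raise ValueError("values must be positive (log10 transform applied)")
    x = np.log10(values)
    if np.ptp(x) == 0:
        raise DegenerateDistributionError("all values identical")
    if bandwidth == "auto":
        kde = gaussian_kde(x, bw_method="silverman")
    else:
        kde = gaussian_kde(x, bw_method=float(bandwidth) / max(x.std(ddof=1), 1e-12))
    bw = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=bw)


def first_local_minimum_above(curve: DensityCurve, x0: float) -> float | None:
    """Smallest grid point > x0 that is a local minimum of the density.

    A grid point qualifies when it is no higher than both neighbours and
    strictly lower than at least one (so exact two-point plateaus at a
    valley bottom still count, but flat stretches and monotone runs do
    not).  Returns None when no such minimum exists above ``x0``.
    """
    d = curve.density
    le = (d[1:-1] <= d[:-2]) & (d[1:-1] <= d[2:])
    lt = (d[1:-1] < d[:-2]) | (d[1:-1] < d[2:])
    interior = np.flatnonzero(le & lt) + 1
    for i in interior:
        if curve.grid[i] > x0:
            return float(curve.grid[i])
    return None


def _mode_members_above_valley(
    curve: DensityCurve, log_values: np.ndarray, candidate: float
) -> np.ndarray:
    """Boolean mask of values above the valley separating the global mode
    from ``candidate`` (candidate assumed right of the global mode)."""
    lo, hi = sorted((curve.global_mode(), candidate))
    in_between = (curve.grid > lo) & (curve.grid < hi)
    if not np.any(in_between):
        return np.zeros(log_values.shape, dtype=bool)
    seg = np.flatnonzero(in_between)
    valley = curve.grid[seg[int(np.argmin(curve.density[seg]))]]
    return log_values > valley


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_barcodes(
    m: CountMatrix, x0: float = 2.0, bandwidth: float | str = "auto"
) -> tuple[CountMatrix, QcReport]:
    """Drop cell-less barcodes below the first local minimum above ``x0``
    of the log10 UMI-total density.  If no minimum is found nothing is
    dropped and that fact is recorded in the report."""
    u = m.umis_per_barcode()
    positive = u > 0
    report = QcReport(kept_genes=m.genes.copy(), dropped_genes=np.array([], dtype=object))
    log_u = np.full(u.shape, -np.inf)
    log_u[positive] = np.log10(u[positive])

    curve = estimate_log10_density(u[positive], bandwidth=bandwidth)
    threshold = first_local_minimum_above(curve, x0)
    report.thresholds["umi_log10_min"] = threshold
    report.modes["umi_log10_modes"] = curve.local_maxima().tolist()

    if threshold is None:
        keep = positive
    else:
        keep = log_u >= threshold
    dropped = m.barcodes[~keep]
    report.kept_barcodes = m.barcodes[keep]
    report.dropped_barcodes = pd.DataFrame(
        {"barcode": dropped, "reason": ["low_umi"] * len(dropped)}
    )
    return m.subset_barcodes(keep), report


def filter_genes(
    m: CountMatrix, x0: float = 3.0, bandwidth: float | str = "auto"
) -> tuple[CountMatrix, QcReport]:
    """Drop sparsely detected genes below the first local minimum above
    ``x0`` of the log10 detection-count density.

    Genes detected in zero barcodes are always removed (their log10 is
    undefined) before density estimation.
    """
    d = m.detection_per_gene()
    detected = d > 0
    report = QcReport(kept_barcodes=m.barcodes.copy())

    threshold = None
    keep = detected.copy()
    if detected.sum() >= 10 and np.ptp(np.log10(d[detected])) > 0:
        curve = estimate_log10_density(d[detected], bandwidth=bandwidth)
        threshold = first_local_minimum_above(curve, x0)
        report.modes["detection_log10_modes"] = curve.local_maxima().tolist()
        if threshold is not None:
            keep &= np.where(detected, np.log10(np.maximum(d, 1)), -np.inf) >= threshold
    report.thresholds["detection_log10_min"] = threshold
    report.kept_genes = m.genes[keep]
    report.dropped_genes = m.genes[~keep]
    return m.subset_genes(keep), report


def detect_multiplets(
    m: CountMatrix,
    ratio: float = 1.5,
    max_frac: float = 0.05,
    bandwidth: float | str = "auto",
) -> tuple[CountMatrix, QcReport]:
    """Flag and remove multiplet barcodes.

    A barcode population is regarded as multiplets when, in either the
    log10(#genes) or the log10(#UMIs) distribution, it forms a local mode
    whose location exceeds ``ratio`` times the global mode location and whose
    members (barcodes above the valley separating it from the global mode)
    comprise fewer than ``max_frac`` of all barcodes.  The input should
    already be barcode-filtered.
    """
    n = m.n_barcodes
    flagged = np.zeros(n, dtype=bool)
    report = QcReport(kept_genes=m.genes.copy())
    for name, vals in (
        ("genes", m.genes_per_barcode()),
        ("umis", m.umis_per_barcode()),
    ):
        positive = vals > 0
        if positive.sum() < 10:
            continue
        try:
            curve = estimate_log10_density(vals[positive], bandwidth=bandwidth)
        except DegenerateDistributionError:
            continue
        log_vals = np.where(positive, np.log10(np.maximum(vals, 1)), -np.inf)
        global_mode = curve.global_mode()
        report.modes[f"{name}_global_mode_log10"] = global_mode
        candidates = [
            mode
            for mode in curve.local_maxima()
            if global_mode > 0 and mode > ratio * global_mode
        ]
        accepted = []
        for mode in candidates:
            members = _mode_members_above_valley(curve, log_vals, mode)
            if 0 < members.sum() < max_frac * n:
                flagged |= members
                accepted.append(float(mode))
        report.modes[f"{name}_multiplet_modes_log10"] = accepted
    report.thresholds["multiplet_mode_ratio"] = ratio
    report.thresholds["multiplet_max_frac"] = max_frac
    keep = ~flagged
    report.kept_barcodes = m.barcodes[keep]
    report.dropped_barcodes = pd.DataFrame(
        {"barcode": m.barcodes[flagged], "reason": ["multiplet"] * int(flagged.sum())}
    )
    return m.subset_barcodes(keep), report


def run_qc(
    m: CountMatrix,
    umi_min_log10: float = 2.0,
    gene_min_log10: float = 3.0,
    multiplet_ratio: float = 1.5,
    multiplet_max_frac: float = 0.05,
) -> tuple[CountMatrix, dict[str, QcReport]]:
    """Full QC pipeline in the declared order: barcode filter, gene filter,
    multiplet removal.  Returns the filtered matrix and the per-stage reports."""
    m1, rep_bc = filter_barcodes(m, x0=umi_min_log10)
    m2, rep_gene = filter_genes(m1, x0=gene_min_log10)
    m3, rep_multi = detect_multiplets(
        m2, ratio=multiplet_ratio, max_frac=multiplet_max_frac
    )
    return m3, {"barcodes": rep_bc, "genes": rep_gene, "multiplets": rep_multi}
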