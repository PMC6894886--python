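"""Cluster marker derivation and reference-based cell-type annotation.

A marker gene of a converged cluster is one significantly overexpressed
(BH-adjusted p < 0.05) in that cluster versus *every* other converged
cluster, under a two-distribution likelihood-ratio test: each cluster's
expression values for a gene are modelled as a point mass at zero (with
probability 1 - pi) plus log-normal positives, and the alternative (two
distributions) is compared to a null in which both clusters share one.
Clusters are then annotated by intersecting their markers with a reference
expression profile in TPM units, keeping only markers strongly and
specifically expressed in a single reference cell type and assigning the
plurality type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2

from .differential_expression import bh_adjust
from .droplet_qc import CountMatrix
from .clustering import depth_scale

_LOG_FLOOR = 1e-8  # variance floor for degenerate positive parts


# ---------------------------------------------------------------------------
# bimodal likelihood-ratio test
# ---------------------------------------------------------------------------

def _zero_lognormal_loglik(n_pos, n_zero, sum_log, sum_sq_log, mu, var):
    """Log-likelihood of a zero-inflated log-normal with Bernoulli MLE and
    given positive-part mean/variance, from sufficient statistics."""
    n = n_pos + n_zero
    ll = 0.0
    if n_pos > 0:
        ll += n_pos * np.log(n_pos / n)
    if n_zero > 0:
        ll += n_zero * np.log(n_zero / n)
    if n_pos > 0:
        sse = sum_sq_log - 2 * mu * sum_log + n_pos * mu**2
        ll += -0.5 * n_pos * np.log(2 * np.pi * var) - sse / (2 * var)
    return ll


def bimod_lrt(x_a: np.ndarray, x_b: np.ndarray) -> tuple[float, float, int]:
    """Two-distribution LRT for a gene between two clusters.

    Each group is modelled as zeros with probability 1 - pi plus log-normal
    positives with a group mean and a variance pooled across both groups;
    the null shares pi and the mean.  statistic = 2(l_a + l_b - l_pooled),
    p from chi-square with 2 df.  Returns (statistic, p, direction) where
    direction is the sign of the mean difference (a minus b).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("both groups must be non-empty")
    stats = []
    for x in (x_a, x_b):
        pos = x[x > 0]
        logs = np.log(pos)
        stats.append(
            (pos.size, x.size - pos.size, logs.sum(), (logs**2).sum())
        )
    (na_p, na_z, sa, qa), (nb_p, nb_z, sb, qb) = stats
    n_pos = na_p + nb_p
    if n_pos == 0:
        return 0.0, 1.0, 0
    mu_a = sa / na_p if na_p else 0.0
    mu_b = sb / nb_p if nb_p else 0.0
    mu_pool = (sa + sb) / n_pos
    # shared variance: within-group SSE of the alternative model
    sse_within = (qa - na_p * mu_a**2) + (qb - nb_p * mu_b**2)
    var = max(sse_within / n_pos, _LOG_FLOOR)
    ll_alt = _zero_lognormal_loglik(na_p, na_z, sa, qa, mu_a, var) + \
        _zero_lognormal_loglik(nb_p, nb_z, sb, qb, mu_b, var)
    ll_null = _zero_lognormal_loglik(
        n_pos, na_z + nb_z, sa + sb, qa + qb, mu_pool, var
    )
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    p = float(chi2.sf(stat, df=2))
    direction = int(np.sign(x_a.mean() - x_b.mean()))
    return float(stat), p, direction


def _bimod_lrt_genes(xa: np.ndarray, xb: np.ndarray):
    """Vectorised bimodal LRT across genes (rows) for two cell groups."""
    def suff(x):
        pos = x > 0
        n_pos = pos.sum(axis=1)
        logs = np.where(pos, np.log(np.where(pos, x, 1.0)), 0.0)
        return n_pos, x.shape[1] - n_pos, logs.sum(axis=1), (logs**2).sum(axis=1)

    na_p, na_z, sa, qa = suff(xa)
    nb_p, nb_z, sb, qb = suff(xb)
    n_pos = na_p + nb_p
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_a = np.where(na_p > 0, sa / np.maximum(na_p, 1), 0.0)
        mu_b = np.where(nb_p > 0, sb / np.maximum(nb_p, 1), 0.0)
        mu_p = np.where(n_pos > 0, (sa + sb) / np.maximum(n_pos, 1), 0.0)
        sse_within = (qa - na_p * mu_a**2) + (qb - nb_p * mu_b**2)
        var = np.maximum(sse_within / np.maximum(n_pos, 1), _LOG_FLOOR)

    def ll(n_p, n_z, s, q, mu):
        n = n_p + n_z
        with np.errstate(divide="ignore", invalid="ignore"):
            bern = np.where(n_p > 0, n_p * np.log(np.maximum(n_p, 1) / n), 0.0)
            bern += np.where(n_z > 0, n_z * np.log(np.maximum(n_z, 1) / n), 0.0)
            sse = q - 2 * mu * s + n_p * mu**2
            norm = np.where(
                n_p > 0, -0.5 * n_p * np.log(2 * np.pi * var) - sse / (2 * var), 0.0
            )
        return bern + norm

    ll_alt = ll(na_p, na_z, sa, qa, mu_a) + ll(nb_p, nb_z, sb, qb, mu_b)
    ll_null = ll(n_pos, na_z + nb_z, sa + sb, qa + qb, mu_p)
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    stat = np.where(n_pos == 0, 0.0, stat)
    p = np.where(n_pos == 0, 1.0, chi2.sf(stat, df=2))
    direction = np.sign(xa.mean(axis=1) - xb.mean(axis=1)).astype(int)
    return stat, p, direction


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------

def find_markers(
    m: CountMatrix,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster marker genes against every other converged cluster.

    For each cluster pair all genes are tested with the bimodal LRT on
    depth-scaled values; BH adjustment is applied per pairwise comparison
    across genes.  A gene is a marker of a cluster iff it is overexpressed
    with adjusted p < ``alpha`` against every opponent.  Singleton clusters
    are skipped.

    Returns one row per (gene, cluster) with the max adjusted p across
    opponents and the marker flag.
    """
    labels = np.asarray(labels)
    clusters = [
        c for c in pd.unique(labels) if (labels == c).sum() >= 2
    ]
    if len(clusters) < 2:
        raise ValueError("need at least 2 non-singleton clusters")
    scaled = np.asarray(depth_scale(m).todense())
    groups = {c: scaled[:, labels == c] for c in clusters}

    n_genes = m.n_genes
    records = []
    pair_cache: dict[tuple, tuple] = {}
    for c in clusters:
        max_q = np.zeros(n_genes)
        over_all = np.ones(n_genes, dtype=bool)
        for o in clusters:
            if o == c:
                continue
            key = (c, o) if str(c) < str(o) else (o, c)
            if key not in pair_cache:
                pair_cache[key] = _bimod_lrt_genes(groups[key[0]], groups[key[1]])
            stat, p, direction = pair_cache[key]
            if key != (c, o):
                direction = -direction
            q = bh_adjust(p)
            max_q = np.maximum(max_q, q)
            over_all &= (direction > 0) & (q < alpha)
        for g in np.flatnonzero(over_all | (max_q < alpha)):
            records.append(
                {
                    "gene": m.genes[g],
                    "cluster": c,
                    "max_adjusted_p": float(max_q[g]),
                    "is_marker": bool(over_all[g]),
                }
            )
    cols = ["gene", "cluster", "max_adjusted_p", "is_marker"]
    df = pd.DataFrame(records, columns=cols).astype(
        {"max_adjusted_p": float, "is_marker": bool}
    )
    return df[df.is_marker | (df.max_adjusted_p < alpha)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation against a reference profile
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    table: pd.DataFrame  # cluster, cell_type, n_support

    def mapping(self) -> dict:
        return dict(zip(self.table.cluster, self.table.cell_type))


def annotate_clusters(
    markers: pd.DataFrame,
    ref: pd.DataFrame,
    min_tpm: float = 50.0,
    fold: float = 4.0,
) -> Annotation:
    """Assign each cluster the reference cell type its markers point to.

    Only markers whose top reference type has TPM >= ``min_tpm`` and at
    least ``fold`` times the second-highest type are retained; the cluster
    label is the plurality type among retained markers, or ``unassigned``
    on ties or when no marker survives.
    """
    tpm = ref.to_numpy(dtype=float)
    col_sums = tpm.sum(axis=0)
    if not np.allclose(col_sums, 1e6, rtol=1e-3):
        raise ValueError("reference columns must sum to 1e6 TPM")
    order = np.argsort(tpm, axis=1)
    top_idx = order[:, -1]
    top = tpm[np.arange(len(ref)), top_idx]
    second = tpm[np.arange(len(ref)), order[:, -2]]
    # second == 0 means exclusively expressed: passes any fold, even inf
    specific = (top >= min_tpm) & ((second == 0) | (top >= fold * second))
    gene_type = pd.Series(
        np.asarray(ref.columns)[top_idx], index=ref.index
    )[specific]

    rows = []
    marker_rows = markers[markers.is_marker] if "is_marker" in markers else markers
    for cluster, sub in marker_rows.groupby("cluster", sort=True):
        votes = gene_type.reindex(sub.gene).dropna()
        if votes.empty:
            rows.append({"cluster": cluster, "cell_type": "unassigned", "n_support": 0})
            continue
        counts = votes.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            rows.append(
                {"cluster": cluster, "cell_type": "unassigned",
                 "n_support": int(counts.iloc[0])}
            )
        else:
            rows.append(
                {"cluster": cluster, "cell_type": counts.index[0],
                 "n_support": int(counts.iloc[0])}
            )
    return Annotation(table=pd.DataFrame(rows, columns=["cluster", "cell_type", "n_support"]))


# ---------------------------------------------------------------------------
# heatmap downsampling
# ---------------------------------------------------------------------------

def downsample_for_heatmap(
    labels: pd.Series | np.ndarray,
    max_total: int = 2500,
    seed: int = 0,
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Proportionally downsample cells to at most ``max_total``.

    Quotas follow largest-remainder rounding of each cluster's share, every
    non-empty cluster retains at least one cell, and sampling within a
    cluster is uniform.  If the total is already within budget the input is
    returned unchanged.
    """
    if cells is None:
        if isinstance(labels, pd.Series):
            cells = labels.index.to_numpy()
        else:
            cells = np.arange(len(labels))
    labels = np.asarray(labels)
    cells = np.asarray(cells)
    n = len(labels)
    if n == 0:
        raise ValueError("assignment is empty")
    if n <= max_total:
        return cells.copy()

    rng = np.random.default_rng(seed)
    uniq, counts = np.unique(labels, return_counts=True)
    exact = counts * max_total / n
    quotas = np.floor(exact).astype(int)
    remainder = max_total - quotas.sum()
    order = np.argsort(-(exact - quotas), kind="stable")
    quotas[order[:remainder]] += 1
    # rounding guard: every non-empty cluster keeps at least one cell,
    # rebalanced from the largest quotas; if there are more clusters than
    # budget the total exceeds max_total by the minimum necessary
    for zero in np.flatnonzero((quotas == 0) & (counts > 0)):
        donor = int(np.argmax(quotas))
        if quotas[donor] > 1:
            quotas[donor] -= 1
        quotas[zero] += 1
    keep = []
    for u, q in zip(uniq, quotas):
        members = cells[labels == u]
        keep.append(rng.choice(members, size=min(q, len(members)), replace=False))
    return np.concatenate(keep)
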