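"""Hurdle mixed-model differential expression, proportion tests, and GSEA.

Single-cell expression of a gene within a cell type is bimodal: a point
mass at zero and a positive component.  A condition (e.g. LPS challenge vs
saline control) can act on either part, so the condition effect is
decomposed into:

* an **expression-induction** effect -- a logistic mixed-effects regression
  (binomial family, logit link) on the binarised outcome (expressed / not),
  giving a log-odds effect; and
* an **expression-level** effect -- a gamma mixed-effects regression (log
  link) fitted only to the cells expressing the gene, giving a natural-log
  fold change.

In both parts the sample of origin enters as a Normal random intercept and
the condition is a fixed categorical effect with control as baseline.  The
marginal likelihood integrates the random intercepts out by Gauss-Hermite
quadrature and is maximised directly; on optimisation failure the model
falls back to a fixed-effects GLM with sample as a covariate and is
flagged.  Complementary tools test cluster-proportion shifts with a
baseline-category multinomial model and run preranked gene-set enrichment
with a weighted running-sum statistic and a permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import gammaln
from scipy.stats import norm
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess1

from .droplet_qc import CountMatrix
from .clustering import depth_scale

_GH_NODES, _GH_WEIGHTS = hermegauss(31)  # probabilists' Hermite: N(0,1) weights
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)
_RIDGE = 1e-6


@dataclass
class FitResult:
    effect: float
    se: float
    p: float
    converged: bool
    fallback: str | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return np.isfinite(self.effect) and np.isfinite(self.se)


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------

def _encode(condition, sample):
    condition = np.asarray(condition)
    sample = np.asarray(sample)
    levels = pd.unique(condition)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(levels)}")
    # control baseline: 'control'/'saline' if present, else first level sorted
    lowered = [str(l).lower() for l in levels]
    baseline = None
    for cand in ("control", "saline", "ctrl"):
        if cand in lowered:
            baseline = levels[lowered.index(cand)]
            break
    if baseline is None:
        baseline = sorted(levels, key=str)[0]
    treat = (condition != baseline).astype(float)
    sample_codes, sample_levels = pd.factorize(sample)
    if len(sample_levels) < 2:
        raise ValueError("need at least 2 samples")
    return treat, sample_codes, len(sample_levels)


def _glmm_nll_factory(y, treat, sample_codes, n_samples, family):
    """Marginal negative log-likelihood with per-sample random intercepts
    integrated out by Gauss-Hermite quadrature."""
    sample_masks = [sample_codes == s for s in range(n_samples)]

    if family == "binomial":
        def nll(theta):
            b0, delta, log_sigma = theta
            sigma = np.exp(log_sigma)
            eta0 = b0 + delta * treat
            total = 0.0
            for mask in sample_masks:
                eta = eta0[mask][:, None] + sigma * _GH_NODES[None, :]
                # log Bernoulli likelihood per node, numerically stable
                ll = np.where(y[mask][:, None] > 0, -np.logaddexp(0, -eta),
                              -np.logaddexp(0, eta)).sum(axis=0)
                total += _logsumexp_weighted(ll)
            return -total + _RIDGE * (b0**2 + delta**2)
        n_par = 3
    elif family == "gamma":
        def nll(theta):
            b0, delta, log_shape, log_sigma = theta
            shape = np.exp(log_shape)
            sigma = np.exp(log_sigma)
            eta0 = b0 + delta * treat
            log_y = np.log(y)
            total = 0.0
            for mask in sample_masks:
                log_mu = eta0[mask][:, None] + sigma * _GH_NODES[None, :]
                # Gamma(shape, mean=mu) log-density
                ll = (
                    shape * (np.log(shape) - log_mu)
                    + (shape - 1) * log_y[mask][:, None]
                    - shape * y[mask][:, None] * np.exp(-log_mu)
                    - gammaln(shape)
                ).sum(axis=0)
                total += _logsumexp_weighted(ll)
            return -total + _RIDGE * (b0**2 + delta**2)
        n_par = 4
    else:
        raise ValueError(f"unknown family {family!r}")
    return nll, n_par


def _logsumexp_weighted(ll):
    m = ll.max()
    return m + np.log(np.dot(_GH_WEIGHTS, np.exp(ll - m)))


def _wald_se(nll, theta_hat) -> float:
    """Wald SE of the condition effect from the observed information.

    The random-intercept SD is parameterised as log(sigma); at the sigma=0
    boundary the likelihood is flat in that direction and the full Hessian
    becomes near-singular, which can corrupt the inverted covariance.  The
    SE is therefore taken from the full Hessian only when it is positive
    definite and well conditioned; otherwise log(sigma) is held fixed and
    the reduced Hessian over the remaining parameters is inverted.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    hess = approx_hess1(theta_hat, nll)
    try:
        eig = np.linalg.eigvalsh(hess)
        if eig.min() > 0 and eig.max() / eig.min() < 1e8:
            return float(np.sqrt(np.linalg.inv(hess)[1, 1]))
    except np.linalg.LinAlgError:
        pass
    fixed = theta_hat[-1]

    def reduced(theta_free):
        return nll(np.append(theta_free, fixed))

    hess_r = approx_hess1(theta_hat[:-1], reduced)
    return float(np.sqrt(np.linalg.inv(hess_r)[1, 1]))


def _glm_fallback(y, treat, sample_codes, family, message):
    """Fixed-effects GLM with sample as covariate (dummy-coded)."""
    x = np.column_stack(
        [np.ones_like(treat), treat]
        + [
            (sample_codes == s).astype(float)
            for s in range(1, sample_codes.max() + 1)
        ]
    )
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gamma(
        link=sm.families.links.Log()
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, x, family=fam).fit(maxiter=100)
        return FitResult(
            effect=float(res.params[1]),
            se=float(res.bse[1]),
            p=float(res.pvalues[1]),
            converged=bool(res.converged),
            fallback="glm_fixed_effects",
            message=message,
        )
    except Exception as exc:  # pragma: no cover - last resort
        return FitResult(np.nan, np.nan, np.nan, False, "glm_fixed_effects", str(exc))


def _fit_glmm(y, condition, sample, family) -> FitResult:
    treat, sample_codes, n_samples = _encode(condition, sample)
    y = np.asarray(y, dtype=float)

    if family == "binomial":
        if y.min() == y.max():
            return FitResult(
                np.nan, np.nan, np.nan, False, None,
                "degenerate outcome: no variation in expression indicator",
            )
        p_obs = np.clip(y.mean(), 0.05, 0.95)
        start = [np.log(p_obs / (1 - p_obs)), 0.0, np.log(0.1)]
    else:
        if np.any(y <= 0):
            raise ValueError("gamma family requires positive outcomes")
        start = [float(np.log(y.mean())), 0.0, 0.0, np.log(0.1)]

    nll, n_par = _glmm_nll_factory(y, treat, sample_codes, n_samples, family)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = minimize(nll, start, method="L-BFGS-B")
            se = _wald_se(nll, opt.x)
        effect = float(opt.x[1])
        if not (np.isfinite(se) and se > 0 and np.isfinite(effect)):
            raise FloatingPointError("non-finite Wald quantities")
    except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
        return _glm_fallback(y, treat, sample_codes, family, str(exc))
    if not opt.success:
        return _glm_fallback(y, treat, sample_codes, family, opt.message)
    z = effect / se
    separated = family == "binomial" and abs(effect) > 8
    return FitResult(
        effect=effect,
        se=se,
        p=float(2 * norm.sf(abs(z))),
        converged=True,
        fallback="penalized" if separated else None,
        message="complete or quasi-separation" if separated else "",
    )


def fit_induction_model(y, condition, sample) -> FitResult:
    """Logistic mixed-effects regression of the binarised outcome.

    ``y`` is 0/1 per cell (gene not expressed / expressed); the condition
    effect (log-odds, control as baseline) is tested with a Wald z.
    """
    y = (np.asarray(y) > 0).astype(float)
    return _fit_glmm(y, condition, sample, "binomial")


def fit_level_model(y, condition, sample) -> FitResult:
    """Gamma (log link) mixed-effects regression on expressing cells only.

    The effect is a natural-log fold change.  The level component is absent
    (NaN result) when either condition has fewer than 2 expressing cells.
    """
    y = np.asarray(y, dtype=float)
    condition = np.asarray(condition)
    sample = np.asarray(sample)
    pos = y > 0
    for level in pd.unique(condition):
        if (pos & (condition == level)).sum() < 2:
            return FitResult(
                np.nan, np.nan, np.nan, False, None,
                f"fewer than 2 expressing cells in condition {level!r}",
            )
    return _fit_glmm(y[pos], condition[pos], sample[pos], "gamma")


# ---------------------------------------------------------------------------
# hurdle differential expression over cell types
# ---------------------------------------------------------------------------

def hurdle_de(
    matrices: dict[str, CountMatrix],
    metadata: pd.DataFrame,
    cell_types: pd.Series | None = None,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene, per-cell-type hurdle decomposition of the condition effect.

    ``matrices`` maps condition name -> CountMatrix (same gene order);
    ``metadata`` must carry barcode, condition and sample columns.
    ``cell_types`` optionally maps barcode -> matched cell type (cells
    without a match are skipped); by default all cells form one type.
    BH adjustment runs across genes within each (cell type, component).

    Returns one row per (gene, cell type) with induction and level effects,
    SEs, p and q values, and fit diagnostics.
    """
    conditions = list(matrices)
    if len(conditions) != 2:
        raise ValueError("need exactly two condition matrices")
    gene_index = matrices[conditions[0]].genes
    for m in matrices.values():
        if not np.array_equal(m.genes, gene_index):
            raise ValueError("condition matrices must share gene order")
    if genes is None:
        genes = gene_index
    meta = metadata.set_index("barcode")

    scaled = {}
    barcodes = {}
    for cond_name, m in matrices.items():
        scaled[cond_name] = np.asarray(depth_scale(m).todense())
        barcodes[cond_name] = m.barcodes
    all_barcodes = np.concatenate([barcodes[c] for c in conditions])
    cond_vec = np.concatenate(
        [np.repeat(c, len(barcodes[c])) for c in conditions]
    )
    sample_vec = meta.loc[all_barcodes, "sample"].to_numpy()
    x = np.concatenate([scaled[c] for c in conditions], axis=1)

    if cell_types is None:
        type_vec = np.repeat("all", len(all_barcodes))
    else:
        type_vec = pd.Series(cell_types).reindex(all_barcodes).to_numpy()

    gene_pos = pd.Index(gene_index).get_indexer(genes)
    rows = []
    for ct in pd.unique(type_vec[pd.notna(type_vec)]):
        in_ct = type_vec == ct
        for g, gi in zip(genes, gene_pos):
            yg = x[gi, in_ct]
            ind = fit_induction_model(yg, cond_vec[in_ct], sample_vec[in_ct])
            lev = fit_level_model(yg, cond_vec[in_ct], sample_vec[in_ct])
            rows.append(
                {
                    "gene": g, "cell_type": ct,
                    "induction_effect": ind.effect, "induction_se": ind.se,
                    "induction_p": ind.p,
                    "level_effect": lev.effect, "level_se": lev.se,
                    "level_p": lev.p,
                    "induction_converged": ind.converged,
                    "level_converged": lev.converged,
                    "induction_fallback": ind.fallback,
                    "level_fallback": lev.fallback,
                }
            )
    out = pd.DataFrame(rows)
    for comp in ("induction", "level"):
        out[f"{comp}_q"] = np.nan
        for ct in out.cell_type.unique():
            sel = out.cell_type == ct
            out.loc[sel, f"{comp}_q"] = bh_adjust(out.loc[sel, f"{comp}_p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# cluster proportion shifts
# ---------------------------------------------------------------------------

def test_proportions(
    labels: np.ndarray,
    condition: np.ndarray,
    baseline_cluster=None,
) -> pd.DataFrame:
    """Baseline-category multinomial regression of cluster label on
    condition (no random effect).

    With a single binary covariate the MLE per non-baseline cluster is the
    2x2 log odds ratio against the baseline cluster, with Woolf SE; cells of
    clusters absent in one condition get an add-0.5 continuity correction.
    Returns per-cluster effect, SE, Wald p, and BH-adjusted p.
    """
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    cond_levels = pd.unique(condition)
    if len(cond_levels) != 2:
        raise ValueError("need exactly 2 conditions")
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(condition, name="condition"))
    if table.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    control, treated = sorted(
        cond_levels, key=lambda l: 0 if str(l).lower() in ("control", "saline") else 1
    )
    if baseline_cluster is None:
        baseline_cluster = table.sum(axis=1).idxmax()

    nb_c = float(table.loc[baseline_cluster, control])
    nb_t = float(table.loc[baseline_cluster, treated])
    rows = []
    for cluster in table.index:
        if cluster == baseline_cluster:
            continue
        nc = float(table.loc[cluster, control])
        nt = float(table.loc[cluster, treated])
        cells = np.array([nt, nb_t, nc, nb_c])
        corrected = bool(np.any(cells == 0))
        if corrected:
            cells = cells + 0.5
        a, b, c, d = cells
        effect = np.log((a / b) / (c / d))
        se = float(np.sqrt((1 / cells).sum()))
        z = effect / se
        rows.append(
            {
                "cluster": cluster, "baseline": baseline_cluster,
                "effect": float(effect), "se": se, "z": float(z),
                "p": float(2 * norm.sf(abs(z))),
                "continuity_corrected": corrected,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _running_sum_es(stat_sorted: np.ndarray, in_set: np.ndarray) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov enrichment score (weight = |statistic|).

    Returns (ES, index of the extreme position)."""
    n = len(stat_sorted)
    n_set = int(in_set.sum())
    weights = np.abs(stat_sorted) * in_set
    total = weights.sum()
    if total == 0:
        weights = in_set.astype(float)
        total = float(n_set)
    hit = np.cumsum(weights) / total
    miss = np.cumsum(~in_set) / (n - n_set)
    running = hit - miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_gsea(
    stats: pd.Series,
    gene_sets: dict[str, list],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a gene-label permutation null.

    ``stats`` maps gene -> signed ranking statistic (e.g. sign(effect) x
    -log10 p); genes are ranked in decreasing order.  The enrichment score
    is the extreme of the weighted running sum; permutation p-values and
    normalised scores use the same-signed part of the null.  Sets with
    fewer than ``min_size`` ranked members are skipped.  BH adjustment over
    the reported sets is included (callers adjust per cell type).
    """
    stats = stats.dropna().sort_values(ascending=False)
    order_genes = stats.index.to_numpy()
    stat_sorted = stats.to_numpy(dtype=float)
    n = len(stat_sorted)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        in_set = np.isin(order_genes, list(members))
        n_set = int(in_set.sum())
        if n_set < min_size or n_set >= n:
            continue
        es, peak = _running_sum_es(stat_sorted, in_set)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=n_set, replace=False)] = True
            null[b], _ = _running_sum_es(stat_sorted, perm)
        # two-sided permutation p on |ES|; smallest attainable is 1/(B+1)
        p = (1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        if es >= 0:
            leading = order_genes[: peak + 1][in_set[: peak + 1]]
        else:
            leading = order_genes[peak:][in_set[peak:]]
        rows.append(
            {
                "gene_set": name, "es": es, "nes": nes, "p": float(p),
                "size": n_set, "leading_edge": list(leading),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_set", "es", "nes", "p", "size",
                                      "leading_edge"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def ranking_statistic(effects: pd.Series, pvalues: pd.Series) -> pd.Series:
    """Signed ranking statistic for GSEA: sign(effect) x -log10 p."""
    p = np.clip(pvalues.to_numpy(dtype=float), 1e-300, 1.0)
    return pd.Series(
        np.sign(effects.to_numpy(dtype=float)) * (-np.log10(p)),
        index=effects.index,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
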