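"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: droplet UMI count
matrices with planted empty/cell/multiplet barcodes and cluster structure,
two-condition experiments with per-gene induction and level effects and
per-sample random intercepts, gene-count histories along a phylogeny,
ISH puncta-bin tables with a species effect, homology hit tables in BLAST
tabular form, and reference expression profiles in TPM units.  All
generators are deterministic under a fixed seed, and each returns a
:class:`PlantedTruth` sufficient to compute downstream recovery metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .droplet_qc import CountMatrix


class InvalidConfigError(ValueError):
    pass


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DropletSimConfig:
    """Knobs for the droplet experiment generator.

    Defaults emulate a 10x-style spleen library: ~2,000 real cells over six
    clusters against ~2,000 ambient-only empty droplets, with the cell and
    empty log10-depth modes separated by several bandwidths so the UMI
    distribution is clearly bimodal, plus a small multiplet population.

    ``multiplet_mode_ratio`` places the multiplet log10-depth mode at that
    multiple of the cell mode: multiplet barcodes mix two parent cells'
    expression profiles resampled at an inflated capture depth, so the
    planted population satisfies the mode-location detection rule.
    ``nb_dispersion`` is the gamma shape of the gamma-Poisson (negative
    binomial) expression noise; larger values approach Poisson.
    """

    n_cells: int = 2000
    n_empty: int = 2000
    n_genes: int = 600
    k_clusters: int = 6
    markers_per_cluster: int = 20
    marker_logfc: float = 2.0
    cell_depth_log10_mean: float = 3.4
    cell_depth_log10_sd: float = 0.2
    empty_depth_log10_mean: float = 1.7
    empty_depth_log10_sd: float = 0.2
    multiplet_fraction: float = 0.03
    multiplet_mode_ratio: float = 1.6
    multiplet_depth_log10_sd: float = 0.08
    ambient_genes: dict[int, float] = field(default_factory=lambda: {0: 0.01, 1: 0.005})
    nb_dispersion: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cells, self.n_empty, self.n_genes, self.k_clusters) <= 0:
            raise InvalidConfigError("sizes must be positive")
        if self.k_clusters > self.n_cells:
            raise InvalidConfigError("k_clusters > n_cells")
        if not (0 <= self.multiplet_fraction < 1):
            raise InvalidConfigError("multiplet_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be positive")
        if self.markers_per_cluster * self.k_clusters > self.n_genes:
            raise InvalidConfigError("not enough genes for the requested markers")
        for g, rate in self.ambient_genes.items():
            if not (0 <= g < self.n_genes) or rate < 0:
                raise InvalidConfigError("invalid ambient gene spec")


@dataclass
class ConditionSimConfig:
    """Planted truth for a two-condition (e.g. LPS vs saline) experiment.

    ``induction_effects`` (delta, log-odds) shift the probability that a
    cell expresses a gene; ``level_effects`` (beta, natural-log fold change)
    shift the positive expression level.  ``sample_random_intercept_sd`` is
    the SD of per-gene, per-sample Normal random intercepts on both scales.
    """

    n_samples_per_condition: int = 2
    cells_per_condition: int = 1000
    sample_random_intercept_sd: float = 0.15
    baseline_induction: np.ndarray | float = 0.3
    induction_effects: np.ndarray | float = 0.0
    level_effects: np.ndarray | float = 0.0
    baseline_level_log_mean: float = np.log(5.0)
    gamma_shape: float = 2.0
    n_genes: int = 200
    seed: int = 0

    def resolved(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        arr = np.broadcast_to(np.asarray(v, dtype=float), (self.n_genes,)).copy()
        return arr

    def validate(self) -> None:
        if self.n_samples_per_condition < 2:
            raise InvalidConfigError("need at least 2 samples per condition")
        if self.gamma_shape <= 0:
            raise InvalidConfigError("gamma_shape must be positive")
        pi0 = self.resolved("baseline_induction")
        if np.any(pi0 <= 0) or np.any(pi0 >= 1):
            raise InvalidConfigError("baseline induction must be strictly inside (0,1)")
        for name in ("induction_effects", "level_effects"):
            if not np.all(np.isfinite(self.resolved(name))):
                raise InvalidConfigError(f"{name} must be finite")


@dataclass
class PlantedTruth:
    """Ground truth labels attached to generated data.

    Only the sections relevant to the generator that produced it are filled.
    """

    # droplet experiment
    barcode_class: np.ndarray | None = None          # cell | empty | multiplet
    cell_cluster: np.ndarray | None = None           # -1 for non-cells
    marker_genes: dict | None = None                 # cluster -> gene indices
    depth_modes_log10: dict | None = None
    # nested experiment
    major_cluster: np.ndarray | None = None
    sub_cluster: np.ndarray | None = None
    # condition experiment
    induction_effects: np.ndarray | None = None
    level_effects: np.ndarray | None = None
    baseline_induction: np.ndarray | None = None
    # gene-count history
    node_counts: dict | None = None                  # node label -> count
    # puncta
    probe_effects: dict | None = None
    # homology
    ortholog_map: dict | None = None
    pseudogene_ids: list | None = None
    putative_pseudogene_intervals: pd.DataFrame | None = None
    confusion_fraction: float | None = None
    # reference profiles
    type_markers: dict | None = None


# ---------------------------------------------------------------------------
# droplet experiment
# ---------------------------------------------------------------------------

def _cluster_profiles(cfg: DropletSimConfig, rng: np.random.Generator):
    """Per-cluster expression profiles (columns sum to 1) and marker map.

    The total marker mass is equalised across clusters before the final
    normalisation, so non-marker genes carry *identical* probabilities in
    every cluster: planted null genes are exactly null.
    """
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    profiles = np.tile(base[:, None], (1, cfg.k_clusters))
    markers: dict[int, np.ndarray] = {}
    order = rng.permutation(cfg.n_genes)
    start = 0
    marker_mass = np.empty(cfg.k_clusters)
    for k in range(cfg.k_clusters):
        idx = order[start : start + cfg.markers_per_cluster]
        start += cfg.markers_per_cluster
        profiles[idx, k] *= np.exp(cfg.marker_logfc)
        marker_mass[k] = profiles[idx, k].sum()
        markers[k] = np.sort(idx)
    target = marker_mass.mean()
    start = 0
    for k in range(cfg.k_clusters):
        idx = order[start : start + cfg.markers_per_cluster]
        start += cfg.markers_per_cluster
        profiles[idx, k] *= target / marker_mass[k]
    profiles /= profiles.sum(axis=0, keepdims=True)
    return profiles, markers


def _nb_counts(profile, depths, shape, rng):
    """Gamma-Poisson draws: genes x cells for one shared profile."""
    lam = profile[:, None] * depths[None, :]
    gamma = rng.gamma(shape, 1.0 / shape, size=lam.shape)
    return rng.poisson(lam * gamma)


def simulate_droplet_experiment(
    config: DropletSimConfig,
) -> tuple[CountMatrix, PlantedTruth]:
    """Generate a genes x barcodes UMI matrix with planted barcode classes.

    Cells follow negative-binomial expression with cluster marker up-shifts;
    empties draw the ambient (mean) profile at low depth; multiplets mix two
    parent cells' cluster profiles at an inflated capture depth; ambient
    genes receive an additive Poisson background in every barcode.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles, markers = _cluster_profiles(config, rng)

    n_multi = int(round(config.multiplet_fraction * config.n_cells))
    clusters = rng.integers(0, config.k_clusters, size=config.n_cells)
    cell_depths = np.maximum(
        np.round(
            10.0
            ** rng.normal(
                config.cell_depth_log10_mean,
                config.cell_depth_log10_sd,
                size=config.n_cells,
            )
        ),
        1,
    )
    blocks = []
    for k in range(config.k_clusters):
        in_k = clusters == k
        blocks.append((in_k, _nb_counts(profiles[:, k], cell_depths[in_k],
                                        config.nb_dispersion, rng)))
    cell_counts = np.zeros((config.n_genes, config.n_cells), dtype=np.int64)
    for in_k, block in blocks:
        cell_counts[:, in_k] = block

    ambient_profile = profiles.mean(axis=1)
    ambient_profile /= ambient_profile.sum()
    empty_depths = np.maximum(
        np.round(
            10.0
            ** rng.normal(
                config.empty_depth_log10_mean,
                config.empty_depth_log10_sd,
                size=config.n_empty,
            )
        ),
        1,
    )
    empty_counts = rng.poisson(ambient_profile[:, None] * empty_depths[None, :])

    if n_multi:
        parents = rng.integers(0, config.n_cells, size=(n_multi, 2))
        multi_profiles = 0.5 * (
            profiles[:, clusters[parents[:, 0]]] + profiles[:, clusters[parents[:, 1]]]
        )
        multi_depths = np.maximum(
            np.round(
                10.0
                ** rng.normal(
                    config.multiplet_mode_ratio * config.cell_depth_log10_mean,
                    config.multiplet_depth_log10_sd,
                    size=n_multi,
                )
            ),
            1,
        )
        multi_counts = rng.poisson(multi_profiles * multi_depths[None, :])
    else:
        multi_counts = np.zeros((config.n_genes, 0), dtype=np.int64)

    counts = np.concatenate([cell_counts, empty_counts, multi_counts], axis=1)
    # ambient contamination: additive Poisson background in all barcodes
    all_depths = np.concatenate(
        [cell_depths, empty_depths, np.full(n_multi, 10 ** config.cell_depth_log10_mean)]
    )
    for g, rate in config.ambient_genes.items():
        counts[g, :] += rng.poisson(rate * all_depths)

    n_total = counts.shape[1]
    barcodes = np.array([f"BC{i:06d}" for i in range(n_total)], dtype=object)
    genes = np.array([f"gene{g:04d}" for g in range(config.n_genes)], dtype=object)
    barcode_class = np.array(
        ["cell"] * config.n_cells + ["empty"] * config.n_empty + ["multiplet"] * n_multi,
        dtype=object,
    )
    cell_cluster = np.full(n_total, -1, dtype=int)
    cell_cluster[: config.n_cells] = clusters

    truth = PlantedTruth(
        barcode_class=barcode_class,
        cell_cluster=cell_cluster,
        marker_genes={k: genes[v] for k, v in markers.items()},
        depth_modes_log10={
            "cell": config.cell_depth_log10_mean,
            "empty": config.empty_depth_log10_mean,
            "multiplet": config.multiplet_mode_ratio * config.cell_depth_log10_mean,
        },
    )
    return CountMatrix(genes, barcodes, sp.csr_matrix(counts)), truth


def simulate_nested_experiment(
    n_cells: int = 2000,
    n_genes: int = 800,
    n_major: int = 3,
    n_sub: int = 2,
    markers_per_major: int = 30,
    markers_per_sub: int = 15,
    major_logfc: float = 2.5,
    sub_logfc: float = 1.6,
    depth_log10_mean: float = 3.3,
    depth_log10_sd: float = 0.2,
    nb_dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[CountMatrix, PlantedTruth]:
    """Hierarchically structured, QC-clean cells: ``n_major`` well-separated
    major clusters each split into ``n_sub`` more weakly separated
    subclusters.  Major markers get a large log fold up-shift, sub markers a
    smaller one, so the first clustering iteration should resolve the majors
    and per-cluster re-clustering the subclusters."""
    rng = np.random.default_rng(seed)
    n_types = n_major * n_sub
    need = n_major * markers_per_major + n_types * markers_per_sub
    if need > n_genes:
        raise InvalidConfigError("not enough genes for the requested markers")

    base = rng.lognormal(0.0, 1.0, size=n_genes)
    profiles = np.tile(base[:, None], (1, n_types))
    order = rng.permutation(n_genes)
    pos = 0
    for maj in range(n_major):
        idx = order[pos : pos + markers_per_major]
        pos += markers_per_major
        for s in range(n_sub):
            profiles[idx, maj * n_sub + s] *= np.exp(major_logfc)
    for t in range(n_types):
        idx = order[pos : pos + markers_per_sub]
        pos += markers_per_sub
        profiles[idx, t] *= np.exp(sub_logfc)
    profiles /= profiles.sum(axis=0, keepdims=True)

    types = rng.integers(0, n_types, size=n_cells)
    depths = np.maximum(
        np.round(10.0 ** rng.normal(depth_log10_mean, depth_log10_sd, size=n_cells)), 1
    )
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for t in range(n_types):
        in_t = types == t
        counts[:, in_t] = _nb_counts(profiles[:, t], depths[in_t], nb_dispersion, rng)

    genes = np.array([f"gene{g:04d}" for g in range(n_genes)], dtype=object)
    barcodes = np.array([f"BC{i:06d}" for i in range(n_cells)], dtype=object)
    truth = PlantedTruth(major_cluster=types // n_sub, sub_cluster=types)
    return CountMatrix(genes, barcodes, sp.csr_matrix(counts)), truth


# ---------------------------------------------------------------------------
# two-condition experiment (induction + level effects, sample intercepts)
# ---------------------------------------------------------------------------

def simulate_condition_effects(
    cond: ConditionSimConfig,
) -> tuple[dict[str, CountMatrix], pd.DataFrame, PlantedTruth]:
    """Two-condition expression with planted hurdle effects.

    Per gene, a cell expresses with probability
    ``logit^-1(logit(pi0) + delta * I(treated) + b_sample)`` and, if
    expressing, draws a gamma level with log-mean shifted by
    ``beta * I(treated) + b'_sample``, discretised to a positive count.
    Random intercepts are drawn independently per gene and sample.
    Returns one matrix per condition (``control`` / ``treated``), a
    metadata table (barcode, condition, sample), and the planted truth.
    """
    cond.validate()
    rng = np.random.default_rng(cond.seed)
    delta = cond.resolved("induction_effects")
    beta = cond.resolved("level_effects")
    pi0 = cond.resolved("baseline_induction")
    n_genes = cond.n_genes
    shape = cond.gamma_shape

    matrices: dict[str, CountMatrix] = {}
    meta_rows = []
    genes = np.array([f"gene{g:04d}" for g in range(n_genes)], dtype=object)
    for ci, condition in enumerate(("control", "treated")):
        n_cells = cond.cells_per_condition
        samples = np.repeat(
            np.arange(cond.n_samples_per_condition),
            int(np.ceil(n_cells / cond.n_samples_per_condition)),
        )[:n_cells]
        sample_names = np.array(
            [f"{condition}_s{j}" for j in samples], dtype=object
        )
        # per-gene, per-sample random intercepts on both scales
        b_ind = rng.normal(
            0, cond.sample_random_intercept_sd,
            size=(n_genes, cond.n_samples_per_condition),
        )
        b_lev = rng.normal(
            0, cond.sample_random_intercept_sd,
            size=(n_genes, cond.n_samples_per_condition),
        )
        eta = _logit(pi0)[:, None] + ci * delta[:, None] + b_ind[:, samples]
        expressed = rng.random((n_genes, n_cells)) < _expit(eta)
        log_mu = (
            cond.baseline_level_log_mean + ci * beta[:, None] + b_lev[:, samples]
        )
        levels = rng.gamma(shape, np.exp(log_mu) / shape, size=(n_genes, n_cells))
        counts = np.where(expressed, np.maximum(np.round(levels), 1), 0).astype(np.int64)
        barcodes = np.array(
            [f"{condition}_BC{i:05d}" for i in range(n_cells)], dtype=object
        )
        matrices[condition] = CountMatrix(genes, barcodes, sp.csr_matrix(counts))
        meta_rows.append(
            pd.DataFrame(
                {"barcode": barcodes, "condition": condition, "sample": sample_names}
            )
        )

    metadata = pd.concat(meta_rows, ignore_index=True)
    truth = PlantedTruth(
        induction_effects=delta, level_effects=beta, baseline_induction=pi0
    )
    return matrices, metadata, truth


# ---------------------------------------------------------------------------
# gene-count evolution along a tree
# ---------------------------------------------------------------------------

def simulate_gene_count_history(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_count: int,
    seed: int = 0,
) -> tuple[dict[str, int], dict[str, int]]:
    """Evolve a gene count along a tree by a birth-death jump process.

    Gains arrive at constant rate ``gain_rate`` (so empty families can be
    re-seeded); losses occur at ``loss_rate`` per extant gene.  Returns
    (tip counts, internal-node counts), keyed by taxon label for tips and by
    node label for internal nodes (labels are assigned when missing).
    """
    if gain_rate < 0 or loss_rate < 0:
        raise InvalidConfigError("rates must be non-negative")
    rng = np.random.default_rng(seed)

    def evolve(count: int, t: float) -> int:
        while t > 0:
            total = gain_rate + loss_rate * count
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait > t:
                break
            t -= wait
            if rng.random() < gain_rate / total:
                count += 1
            else:
                count -= 1
        return count

    tip_counts: dict[str, int] = {}
    internal_counts: dict[str, int] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            count = root_count
        else:
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise InvalidConfigError("branch lengths must be positive")
            count = evolve(node.parent_node._sim_count, bl)
        node._sim_count = count
        if node.is_leaf():
            tip_counts[node.taxon.label] = count
        else:
            if node.label is None:
                node.label = f"node{i}"
            internal_counts[node.label] = count
    return tip_counts, internal_counts


# ---------------------------------------------------------------------------
# ISH puncta tables
# ---------------------------------------------------------------------------

PUNCTA_BINS = [str(b) for b in range(1, 10)] + ["10+"]


def simulate_puncta_table(
    n_samples: int,
    cells_per_sample: int,
    probe_effects: dict[str, float],
    baseline: float = -1.0,
    species: tuple[str, str] = ("mouse", "naked_mole_rat"),
    geometric_p: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """ISH puncta-bin cell-count table with a planted species effect.

    Each cell is positive with probability ``logit^-1(baseline)`` in the
    baseline (first) species and ``logit^-1(baseline + effect)`` in the
    other; positive cells draw ``1 + Geometric(geometric_p)`` puncta, binned
    into 1..9 and 10+.  Output columns: species, sample, probe, puncta_bin,
    cell_count, total_cells.
    """
    if not probe_effects:
        raise InvalidConfigError("probes must be named")
    if not all(np.isfinite(list(probe_effects.values()))):
        raise InvalidConfigError("effects must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for probe, effect in probe_effects.items():
        for si, sp_name in enumerate(species):
            p_pos = _expit(baseline + (effect if si else 0.0))
            for sample in range(n_samples):
                n_pos = rng.binomial(cells_per_sample, p_pos)
                puncta = rng.geometric(geometric_p, size=n_pos)  # support >= 1
                binned = np.minimum(puncta, 10)
                bin_counts = np.bincount(binned, minlength=11)
                for b in range(1, 11):
                    rows.append(
                        {
                            "species": sp_name,
                            "sample": f"{sp_name}_s{sample}",
                            "probe": probe,
                            "puncta_bin": PUNCTA_BINS[b - 1],
                            "cell_count": int(bin_counts[b]),
                            "total_cells": cells_per_sample,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# homology tables
# ---------------------------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _hit_row(q, s, ident, evalue, qlen=500, sstart=1):
    return {
        "qseqid": q, "sseqid": s, "pident": round(float(ident), 2),
        "length": qlen, "mismatch": int(qlen * (1 - ident / 100)), "gapopen": 0,
        "qstart": 1, "qend": qlen, "sstart": sstart, "send": sstart + qlen - 1,
        "evalue": float(evalue), "bitscore": round(2 * qlen * ident / 100, 1),
    }


def simulate_homology_tables(
    families: dict[str, int],
    pseudogene_fraction: float = 0.2,
    identity_noise: float = 0.0,
    cross_family_hit_fraction: float = 0.0,
    n_decoy_intervals: int = 5,
    species: tuple[str, str] = ("mouse", "nmr"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Homology inputs with planted orthology, pseudogenes, and confusions.

    ``families`` maps family name -> number of protein-coding genes per
    species.  Each gene has one transcript form.  True orthologs are
    reciprocal best hits at high identity (95 +/- noise); each species also
    carries annotated pseudogenes (decayed copies at identity 82-94 hitting
    their family) and, on the second species' genome, intergenic decayed
    loci (true putative pseudogenes) at ~55% identity with a confirming
    domain hit.  A fraction ``cross_family_hit_fraction`` of the genomic
    hits that cover annotated genes is redirected to a gene of a different
    family, planting a known false-positive rate for benchmarking.

    Returns (hits A->B, hits B->A, genomic hit table with domain columns,
    annotation table, truth).
    """
    if not families:
        raise InvalidConfigError("families non-empty")
    rng = np.random.default_rng(seed)
    sp_a, sp_b = species

    ann_rows = []
    gene_ids: dict[str, list[tuple[str, str]]] = {sp_a: [], sp_b: []}
    pseudo_ids: list[str] = []
    coord = {sp_a: 1000, sp_b: 1000}
    for fam, n in families.items():
        scaffold = {sp_a: f"{sp_a}_scaf_{fam}", sp_b: f"{sp_b}_scaf_{fam}"}
        for sp_name in species:
            for i in range(n):
                gid = f"{sp_name}_{fam}_{i}"
                start = coord[sp_name]
                coord[sp_name] += 5000
                ann_rows.append(
                    {
                        "species": sp_name, "gene_id": gid, "symbol": f"{fam}{i}",
                        "family": fam, "biotype": "protein_coding",
                        "scaffold": scaffold[sp_name],
                        "start": start, "end": start + 1500,
                    }
                )
                gene_ids[sp_name].append((gid, fam))
            n_pseudo = int(round(pseudogene_fraction * n))
            for i in range(n_pseudo):
                gid = f"{sp_name}_{fam}_ps{i}"
                start = coord[sp_name]
                coord[sp_name] += 5000
                ann_rows.append(
                    {
                        "species": sp_name, "gene_id": gid, "symbol": f"{fam}-ps{i}",
                        "family": fam, "biotype": "annotated_pseudogene",
                        "scaffold": scaffold[sp_name],
                        "start": start, "end": start + 1200,
                    }
                )
                pseudo_ids.append(gid)
    annotations = pd.DataFrame(ann_rows)

    # pairwise transcript hits: orthologs are mutual best at high identity
    ortholog_map = {}
    hits_ab, hits_ba = [], []
    fam_list = list(families)
    for (gid_a, fam) in gene_ids[sp_a]:
        idx = int(gid_a.rsplit("_", 1)[1])
        gid_b = f"{sp_b}_{fam}_{idx}"
        ortholog_map[gid_a] = gid_b
        ident = 95.0 + rng.normal(0, identity_noise)
        hits_ab.append(_hit_row(f"{gid_a}.t1", f"{gid_b}.t1", ident, 1e-50))
        hits_ba.append(_hit_row(f"{gid_b}.t1", f"{gid_a}.t1", ident, 1e-50))
        # weaker off-target paralog hits
        others = [g for g, f in gene_ids[sp_b] if f == fam and g != gid_b]
        if others:
            other = others[rng.integers(len(others))]
            ident2 = 70.0 + rng.normal(0, identity_noise)
            hits_ab.append(_hit_row(f"{gid_a}.t1", f"{other}.t1", ident2, 1e-10))
    # annotated pseudogene transcript hits back into their family
    for gid in pseudo_ids:
        sp_name, fam = gid.split("_")[0], gid.split("_")[1]
        targets = [g for g, f in gene_ids[sp_name] if f == fam]
        if targets:
            t = targets[rng.integers(len(targets))]
            ident = rng.uniform(82, 94)
            row = _hit_row(f"{gid}.t1", f"{t}.t1", ident, 1e-20)
            (hits_ab if sp_name == sp_a else hits_ba).append(row)

    # genomic hits on species B: intergenic decayed loci (true putative
    # pseudogenes), plus hits covering annotated genes for FP benchmarking
    genomic_rows = []
    psi_rows = []
    for fam in fam_list:
        scaffold = f"{sp_b}_scaf_{fam}"
        n_psi = int(round(pseudogene_fraction * families[fam]))
        for i in range(n_psi):
            start = 1_000_000 + 10_000 * i  # far from annotated genes
            query = f"{sp_a}_{fam}_0.t1"
            genomic_rows.append(
                {
                    "qseqid": query, "family": fam, "scaffold": scaffold,
                    "start": start, "end": start + 900,
                    "pident": float(rng.uniform(50, 60)),
                    "domain_evalue": 1e-5, "domain_pident": 70.0,
                }
            )
            psi_rows.append(
                {"family": fam, "scaffold": scaffold, "start": start, "end": start + 900}
            )
    # hits covering annotated species-B genes
    b_genes = annotations[annotations.species == sp_b]
    n_confused = 0
    for _, rec in b_genes.iterrows():
        if rng.random() < cross_family_hit_fraction and len(fam_list) > 1:
            other = [f for f in fam_list if f != rec.family]
            qfam = other[rng.integers(len(other))]
            n_confused += 1
        else:
            qfam = rec.family
        genomic_rows.append(
            {
                "qseqid": f"{sp_a}_{qfam}_0.t1", "family": qfam,
                "scaffold": rec.scaffold, "start": rec.start, "end": rec.end,
                "pident": float(rng.uniform(60, 90)),
                "domain_evalue": 1e-5, "domain_pident": 75.0,
            }
        )

    truth = PlantedTruth(
        ortholog_map=ortholog_map,
        pseudogene_ids=pseudo_ids,
        putative_pseudogene_intervals=pd.DataFrame(
            psi_rows, columns=["family", "scaffold", "start", "end"]
        ),
        confusion_fraction=n_confused / max(len(b_genes), 1),
    )
    return (
        pd.DataFrame(hits_ab, columns=BLAST_COLUMNS),
        pd.DataFrame(hits_ba, columns=BLAST_COLUMNS),
        pd.DataFrame(genomic_rows),
        annotations,
        truth,
    )


# ---------------------------------------------------------------------------
# reference profiles
# ---------------------------------------------------------------------------

def make_reference_profiles(
    cell_types: list[str],
    genes: list[str],
    specificity_factor: float = 4.0,
    markers_per_type: int | None = None,
    type_markers: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Reference TPM matrix (genes x cell types) with planted type markers.

    Each type's markers exceed every other type by at least
    ``specificity_factor``; columns are normalised to sum to 1e6 (TPM).
    Markers are drawn at random unless ``type_markers`` pins an explicit
    cell type -> gene list map (e.g. to mirror planted cluster markers).
    """
    if len(cell_types) < 2:
        raise InvalidConfigError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    n_genes, n_types = len(genes), len(cell_types)
    gene_pos = {g: i for i, g in enumerate(genes)}
    tpm = np.full((n_genes, n_types), 50.0)
    if type_markers is None:
        if markers_per_type is None:
            markers_per_type = max(1, n_genes // (2 * n_types))
        if markers_per_type * n_types > n_genes:
            raise InvalidConfigError("not enough genes for the requested markers")
        order = rng.permutation(n_genes)
        type_markers = {}
        pos = 0
        for ct in cell_types:
            idx = order[pos : pos + markers_per_type]
            pos += markers_per_type
            type_markers[ct] = [genes[i] for i in np.sort(idx)]
    else:
        missing = set(type_markers) - set(cell_types)
        if missing:
            raise InvalidConfigError(f"markers given for unknown types: {missing}")
    for t, ct in enumerate(cell_types):
        idx = [gene_pos[g] for g in type_markers.get(ct, ())]
        tpm[idx, t] *= specificity_factor * 1.5  # margin over the exact factor
    tpm *= 1e6 / tpm.sum(axis=0, keepdims=True)
    ref = pd.DataFrame(tpm, index=list(genes), columns=list(cell_types))
    return ref, PlantedTruth(type_markers=type_markers)
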