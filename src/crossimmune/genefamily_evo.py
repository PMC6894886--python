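"""Gene-family phyletics: orthology, pseudogene discovery, and ancestral
gene-count reconstruction.

NK cell receptor gene families (the lectin-like KLRA..KLRK families of the
natural killer gene complex, the immunoglobulin-like KIR/LILR families of
the leukocyte receptor complex) and their MHC class I ligands expand and
contract rapidly across mammals.  This module compiles, per species and
family, the numbers of protein-coding genes (P), annotated pseudogenes
(Psi), and putative unannotated pseudogenes (psi) detected by genomic
homology with domain confirmation, and reconstructs ancestral family sizes
on a species phylogeny by Sankoff maximum parsimony with a cost linear in
the gene-count change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

PUTATIVE_EXCLUDED_FAMILIES = ("LILR", "KIR")  # shared Ig domain: psi unreliable


def _form_to_gene(form_id: str) -> str:
    """Default transcript/protein form -> gene mapping: strip the final
    dot-suffix (e.g. ``geneA.t1`` -> ``geneA``)."""
    return form_id.rsplit(".", 1)[0] if "." in form_id else form_id


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

def _best_hits(hits: pd.DataFrame, forms_map, e_max: float, id_min: float):
    """Gene-level best-hit sets after e-value/identity filtering.

    Per query *form* the best subject (lowest e-value, then highest
    bitscore) is taken; a gene's best-hit set is the union over its forms.
    """
    h = hits[(hits.evalue < e_max) & (hits.pident > id_min)].copy()
    if h.empty:
        return {}
    h["qgene"] = h.qseqid.map(forms_map)
    h["sgene"] = h.sseqid.map(forms_map)
    h = h.sort_values(["evalue", "bitscore"], ascending=[True, False])
    best_per_form = h.drop_duplicates(subset="qseqid", keep="first")
    out: dict[str, set] = {}
    for qg, sg in zip(best_per_form.qgene, best_per_form.sgene):
        out.setdefault(qg, set()).add(sg)
    return out


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    forms_map=None,
    e_max: float = 0.1,
    id_min: float = 80.0,
) -> pd.DataFrame:
    """One-to-one gene orthologs by reciprocal best hits.

    Both tables (BLAST tabular, outfmt 6 columns) are filtered to e-value
    < ``e_max`` and identity > ``id_min`` (strict); forms are aggregated to
    genes via ``forms_map`` (mapping or callable; default strips the final
    dot-suffix).  A gene pair is retained when any form of A best-hits B
    and any form of B best-hits A.
    """
    if forms_map is None:
        mapper = _form_to_gene
    elif callable(forms_map):
        mapper = forms_map
    else:
        mapper = lambda f: forms_map.get(f, f)  # noqa: E731
    best_ab = _best_hits(hits_ab, mapper, e_max, id_min)
    best_ba = _best_hits(hits_ba, mapper, e_max, id_min)
    pairs = sorted(
        (a, b)
        for a, targets in best_ab.items()
        for b in targets
        if a in best_ba.get(b, ())
    )
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def augment_orthogroups(
    orthogroups: pd.DataFrame,
    pseudo_hits: pd.DataFrame,
    forms_map=None,
    e_max: float = 0.1,
    id_min: float = 80.0,
) -> pd.DataFrame:
    """Attach annotated pseudogenes to family orthogroups.

    ``orthogroups`` maps protein-coding gene_id -> family.  Any pseudogene
    whose transcript hits any family member below ``e_max`` and above
    ``id_min`` joins that family; a pseudogene hitting several families is
    assigned by best e-value, ties broken by identity and flagged.
    """
    if forms_map is None:
        mapper = _form_to_gene
    elif callable(forms_map):
        mapper = forms_map
    else:
        mapper = lambda f: forms_map.get(f, f)  # noqa: E731
    fam_of = dict(zip(orthogroups.gene_id, orthogroups.family))
    h = pseudo_hits[(pseudo_hits.evalue < e_max) & (pseudo_hits.pident > id_min)].copy()
    if h.empty:
        return pd.DataFrame(columns=["gene_id", "family", "ambiguous"])
    h["qgene"] = h.qseqid.map(mapper)
    h["family"] = h.sseqid.map(mapper).map(fam_of)
    h = h.dropna(subset=["family"])
    rows = []
    for gid, sub in h.groupby("qgene"):
        best = sub.groupby("family").agg(
            evalue=("evalue", "min"), pident=("pident", "max")
        ).sort_values(["evalue", "pident"], ascending=[True, False])
        ambiguous = bool(
            len(best) > 1
            and best.evalue.iloc[0] == best.evalue.iloc[1]
            and best.pident.iloc[0] == best.pident.iloc[1]
        )
        rows.append(
            {"gene_id": gid, "family": best.index[0], "ambiguous": ambiguous}
        )
    return pd.DataFrame(rows, columns=["gene_id", "family", "ambiguous"])


# ---------------------------------------------------------------------------
# putative pseudogene detection
# ---------------------------------------------------------------------------

_GENOMIC_COLUMNS = {"family", "scaffold", "start", "end", "pident",
                    "domain_evalue", "domain_pident"}


def _check_genomic(hits: pd.DataFrame) -> pd.DataFrame:
    missing = _GENOMIC_COLUMNS - set(hits.columns)
    if missing:
        raise ValueError(f"genomic hit table missing columns: {sorted(missing)}")
    if hits[["start", "end"]].isna().any().any():
        raise ValueError("genomic hits lacking coordinates")
    if (hits.start > hits.end).any():
        raise ValueError("start must be <= end (1-based inclusive intervals)")
    return hits


def merge_family_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Union interval-overlapping hits whose queries share a family.

    Overlap means at least one shared base on the same scaffold (1-based
    inclusive coordinates).  Domain statistics of a merged hit are the best
    among its members (min e-value, max identity).  Idempotent.
    """
    _check_genomic(hits)
    rows = []
    for (fam, scaf), sub in hits.groupby(["family", "scaffold"], sort=True):
        sub = sub.sort_values(["start", "end"])
        cur = None
        for rec in sub.itertuples():
            if cur is not None and rec.start <= cur["end"]:
                cur["end"] = max(cur["end"], rec.end)
                cur["pident"] = max(cur["pident"], rec.pident)
                cur["domain_evalue"] = min(cur["domain_evalue"], rec.domain_evalue)
                cur["domain_pident"] = max(cur["domain_pident"], rec.domain_pident)
                cur["n_queries"] += 1
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "family": fam, "scaffold": scaf,
                    "start": int(rec.start), "end": int(rec.end),
                    "pident": float(rec.pident),
                    "domain_evalue": float(rec.domain_evalue),
                    "domain_pident": float(rec.domain_pident),
                    "n_queries": 1,
                }
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(
        rows,
        columns=["family", "scaffold", "start", "end", "pident",
                 "domain_evalue", "domain_pident", "n_queries"],
    )


def _overlaps_annotation(rec, ann: pd.DataFrame) -> pd.DataFrame:
    same = ann[ann.scaffold == rec.scaffold]
    return same[(same.start <= rec.end) & (same.end >= rec.start)]


def detect_putative_pseudogenes(
    genomic_hits: pd.DataFrame,
    annotations: pd.DataFrame,
    locus_scaffolds: dict[str, set] | None = None,
    species: str | None = None,
    id_min: float = 40.0,
    dom_e_max: float = 0.1,
    dom_id_min: float = 60.0,
    exclude_families: tuple = PUTATIVE_EXCLUDED_FAMILIES,
) -> pd.DataFrame:
    """Putative (unannotated) pseudogene discovery pipeline.

    Stages: (1) keep genomic hits with identity >= ``id_min``; (2) merge
    interval-overlapping hits of the same family; (3) require the merged
    hit's domain confirmation to pass e-value < ``dom_e_max`` AND identity
    > ``dom_id_min``; (4) restrict to the family's locus scaffolds (derived
    from the annotations when not given); (5) drop hits overlapping any
    annotated gene interval.  Families in ``exclude_families`` are never
    emitted (their defining domain is shared, making psi calls unreliable).
    Surviving intervals become putative_pseudogene gene records.
    """
    hits = _check_genomic(genomic_hits)
    hits = hits[hits.pident >= id_min]
    merged = merge_family_hits(hits)
    merged = merged[
        (merged.domain_evalue < dom_e_max) & (merged.domain_pident > dom_id_min)
    ]
    if locus_scaffolds is None:
        locus_scaffolds = {
            fam: set(sub.scaffold)
            for fam, sub in annotations.groupby("family")
        }
    rows = []
    counter = itertools.count()
    for rec in merged.itertuples():
        if rec.family in exclude_families:
            continue
        if rec.family in locus_scaffolds and rec.scaffold not in locus_scaffolds[rec.family]:
            continue
        if len(_overlaps_annotation(rec, annotations)):
            continue
        rows.append(
            {
                "species": species, "gene_id": f"psi_{rec.family}_{next(counter)}",
                "symbol": None, "family": rec.family,
                "biotype": "putative_pseudogene",
                "scaffold": rec.scaffold, "start": rec.start, "end": rec.end,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "gene_id", "symbol", "family", "biotype",
                 "scaffold", "start", "end"],
    )


def benchmark_false_positives(
    genomic_hits: pd.DataFrame,
    annotations: pd.DataFrame,
    id_min: float = 40.0,
    flag_threshold: float = 0.05,
) -> pd.DataFrame:
    """False-positive benchmark of the genomic homology search.

    Among merged hits that cover annotated genes, a hit is a false positive
    when the covered gene's family differs from the query family.  Reported
    per (query family, search-species genome); NA when a family has no
    annotated-gene-covering hits.  Families at or above ``flag_threshold``
    are flagged (their putative-pseudogene calls should be suppressed).
    """
    hits = _check_genomic(genomic_hits)
    merged = merge_family_hits(hits[hits.pident >= id_min])
    rows = []
    species_list = (
        list(pd.unique(annotations.species)) if "species" in annotations else [None]
    )
    for sp in species_list:
        ann = annotations if sp is None else annotations[annotations.species == sp]
        scafs = set(ann.scaffold)
        for fam, sub in merged.groupby("family"):
            n_cover = n_fp = 0
            for rec in sub.itertuples():
                if rec.scaffold not in scafs:
                    continue
                covered = _overlaps_annotation(rec, ann)
                if len(covered):
                    n_cover += 1
                    if not (covered.family == fam).any():
                        n_fp += 1
            frac = n_fp / n_cover if n_cover else np.nan
            rows.append(
                {
                    "family": fam, "search_species": sp,
                    "n_covering_hits": n_cover, "n_false_positive": n_fp,
                    "fp_fraction": frac,
                    "flagged": bool(n_cover and frac >= flag_threshold),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phyletic patterns
# ---------------------------------------------------------------------------

BIOTYPES = ("protein_coding", "annotated_pseudogene", "putative_pseudogene")


def compile_phyletic_pattern(
    annotations: pd.DataFrame,
    species: list[str],
    families: list[str],
    exclude_putative: tuple = PUTATIVE_EXCLUDED_FAMILIES,
) -> pd.DataFrame:
    """Species x family gene counts split by biotype.

    Returns a long table with columns species, family, P (protein-coding),
    Psi (annotated pseudogenes), psi (putative pseudogenes; forced to zero
    for ``exclude_putative`` families), and total = P + Psi + psi.  Species
    with no records get explicit zeros.
    """
    bad = set(annotations.biotype) - set(BIOTYPES)
    if bad:
        raise ValueError(f"unknown biotypes: {sorted(bad)}")
    rows = []
    for sp in species:
        for fam in families:
            sub = annotations[
                (annotations.species == sp) & (annotations.family == fam)
            ]
            p = int((sub.biotype == "protein_coding").sum())
            big_psi = int((sub.biotype == "annotated_pseudogene").sum())
            small_psi = (
                0 if fam in exclude_putative
                else int((sub.biotype == "putative_pseudogene").sum())
            )
            rows.append(
                {
                    "species": sp, "family": fam, "P": p, "Psi": big_psi,
                    "psi": small_psi, "total": p + big_psi + small_psi,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sankoff ancestral reconstruction
# ---------------------------------------------------------------------------

@dataclass
class AncestralStates:
    """Per-node minimal-cost vectors and co-optimal state probabilities."""

    min_cost: int
    states: pd.DataFrame  # node, state, cost, optimal, probability
    map_state: dict = field(default_factory=dict)

    def node_probabilities(self, node: str) -> pd.Series:
        sub = self.states[self.states.node == node]
        return pd.Series(sub.probability.to_numpy(), index=sub.state.to_numpy())


def _linear_cost(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    return np.abs(i - j)


def sankoff_ancestral(
    tree: dendropy.Tree,
    tip_counts: dict[str, int],
    s_max: int | None = None,
) -> AncestralStates:
    """Sankoff maximum-parsimony gene counts for internal nodes.

    Cost of changing from i to j genes along an edge is |i - j| (linear in
    the number of gains/losses; the proportionality constant does not
    affect the minimiser).  State probabilities put uniform measure on the
    globally minimum-cost full assignments and marginalise per node, via a
    bottom-up cost/count pass and a top-down outside pass; the MAP state is
    the most probable (ties resolved to the smallest count).  Branch
    lengths are ignored.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(leaves) - set(tip_counts)
    if missing:
        raise ValueError(f"leaves without counts: {sorted(missing)}")
    if s_max is None:
        s_max = max(tip_counts[l] for l in leaves)
    if any(tip_counts[l] > s_max for l in leaves):
        raise ValueError("a tip count exceeds s_max")
    n_states = s_max + 1
    states = np.arange(n_states)
    cost_matrix = _linear_cost(states[:, None], states[None, :])
    big = 10**9

    # label internal nodes for reporting
    idx = itertools.count()
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is None:
            node.label = f"anc{next(idx)}"

    # bottom-up: subtree min cost c_v(s) and optimal-assignment counts n_v(s)
    cost: dict = {}
    count: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = np.full(n_states, big, dtype=np.int64)
            c[tip_counts[node.taxon.label]] = 0
            cost[node] = c
            count[node] = [1 if s == tip_counts[node.taxon.label] else 0
                           for s in states]
            continue
        c = np.zeros(n_states, dtype=np.int64)
        n = [1] * n_states
        for child in node.child_nodes():
            # for each parent state: min over child states of edge + child cost
            through = cost_matrix + cost[child][None, :]
            best = through.min(axis=1)
            c += best
            n = [
                n[s] * sum(
                    count[child][t]
                    for t in states
                    if through[s, t] == best[s]
                )
                for s in states
            ]
        cost[node] = c
        count[node] = n

    root = tree.seed_node
    min_cost = int(cost[root].min())

    # top-down outside pass: cost/count of the rest of the tree given node state
    out_cost: dict = {root: np.zeros(n_states, dtype=np.int64)}
    out_count: dict = {root: [1] * n_states}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            sib_cost = np.zeros(n_states, dtype=np.int64)
            sib_count = [1] * n_states
            for sib in children:
                if sib is child:
                    continue
                through = cost_matrix + cost[sib][None, :]
                best = through.min(axis=1)
                sib_cost += best
                sib_count = [
                    sib_count[s] * sum(
                        count[sib][t] for t in states if through[s, t] == best[s]
                    )
                    for s in states
                ]
            # outside of child state t: min over node state s
            total_at_s = out_cost[node] + sib_cost  # indexed by node state s
            through = total_at_s[:, None] + cost_matrix  # s x t
            oc = through.min(axis=0)
            ocount = [
                sum(
                    out_count[node][s] * sib_count[s]
                    for s in states
                    if through[s, t] == oc[t]
                )
                for t in states
            ]
            out_cost[child] = oc
            out_count[child] = ocount

    rows = []
    map_state: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        total = cost[node] + out_cost[node]
        optimal = total == min_cost
        weights = [
            count[node][s] * out_count[node][s] if optimal[s] else 0
            for s in states
        ]
        denom = sum(weights)
        probs = [w / denom for w in weights]
        for s in states:
            rows.append(
                {
                    "node": node.label, "state": int(s), "cost": int(total[s]),
                    "optimal": bool(optimal[s]), "probability": probs[s],
                }
            )
        map_state[node.label] = int(np.argmax(probs))
    return AncestralStates(
        min_cost=min_cost,
        states=pd.DataFrame(rows),
        map_state=map_state,
    )


def brute_force_parsimony(
    tree: dendropy.Tree,
    tip_counts: dict[str, int],
    s_max: int | None = None,
) -> tuple[int, list[dict]]:
    """Exhaustive minimum-cost search over internal-state assignments.

    Test oracle only: refuses more than 8 internal nodes or s_max > 6.
    Returns (min cost, list of optimal assignments as node-label -> state).
    """
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    if s_max is None:
        s_max = max(tip_counts.values())
    if len(internals) > 8 or s_max > 6:
        raise ValueError("instance too large for brute force")
    idx = itertools.count()
    for node in internals:
        if node.label is None:
            node.label = f"anc{next(idx)}"

    def edge_cost(assign) -> int:
        total = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s_par = assign[node.parent_node.label]
            s_node = (
                tip_counts[node.taxon.label] if node.is_leaf() else assign[node.label]
            )
            total += abs(s_par - s_node)
        return total

    best_cost = None
    best: list[dict] = []
    labels = [n.label for n in internals]
    for combo in itertools.product(range(s_max + 1), repeat=len(internals)):
        assign = dict(zip(labels, combo))
        c = edge_cost(assign)
        if best_cost is None or c < best_cost:
            best_cost, best = c, [assign]
        elif c == best_cost:
            best.append(assign)
    return int(best_cost), best
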