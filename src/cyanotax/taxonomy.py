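"""Species and genus delimitation from genomic signature matrices.

Numeric cut-offs delimit taxa: two genomes belong to the same species when
AAI >= 95%, GGD >= 70% and (where a 16S gene exists for both) 16S identity
>= 98.8%; they belong to the same genus when AAI >= 70%.  All bounds are
inclusive.  Clusters are connected components of the pairwise verdict graph
(single-linkage), with non-transitive triples surfaced as warnings rather
than silently absorbed.  Genus components are additionally required to be
monophyletic in a reference tree: a non-monophyletic component is split into
its maximal monophyletic subclades, but a species cluster is never divided.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

from .signatures import SignatureMatrices

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Signature cut-offs for taxon delimitation (all inclusive bounds)."""

    aai_species: float = 95.0
    ggd_species: float = 70.0
    s16_species: float = 98.8
    aai_genus: float = 70.0


class Verdict(str, Enum):
    same_species = "same_species"
    same_genus = "same_genus"
    distinct = "distinct"


@dataclass(frozen=True)
class PairVerdict:
    genome_a: str
    genome_b: str
    verdict: Verdict
    evidence: dict[str, bool]
    missing: frozenset[str]


def _is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def classify_pair(aai: float, ggd: float | None, s16: float | None,
                  thresholds: Thresholds = Thresholds(),
                  genome_a: str = "a", genome_b: str = "b") -> PairVerdict:
    """Classify one genome pair from its three signatures.

    A missing GGD blocks a same-species call (and is flagged); a missing 16S
    is tolerated, the species call then resting on AAI and GGD alone.
    """
    if _is_missing(aai):
        raise ValueError("AAI must be present to classify a pair")
    missing = set()
    if _is_missing(ggd):
        missing.add("ggd")
    if _is_missing(s16):
        missing.add("s16")
    evidence = {
        "aai_species": aai >= thresholds.aai_species,
        "ggd_species": "ggd" not in missing and ggd >= thresholds.ggd_species,
        "s16_species": "s16" not in missing and s16 >= thresholds.s16_species,
        "aai_genus": aai >= thresholds.aai_genus,
    }
    same_species = (evidence["aai_species"] and evidence["ggd_species"]
                    and ("s16" in missing or evidence["s16_species"]))
    if same_species:
        verdict = Verdict.same_species
    elif evidence["aai_genus"]:
        verdict = Verdict.same_genus
    else:
        verdict = Verdict.distinct
    return PairVerdict(genome_a, genome_b, verdict, evidence,
                       frozenset(missing))


# ---------------------------------------------------------------------------
# Partitions


@dataclass
class TaxonPartition:
    """Genome-to-cluster assignments at species and genus rank."""

    species_of: dict[str, str]
    genus_of: dict[str, str]
    non_transitivity_warnings: list[tuple[str, str, str]] = field(
        default_factory=list)
    monophyly_splits: list[tuple[tuple[str, ...], tuple[tuple[str, ...], ...]]] \
        = field(default_factory=list)
    flags: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.species_of) != set(self.genus_of):
            raise ValueError("species and genus maps must cover same genomes")
        by_species: dict[str, set[str]] = {}
        for g, sp in self.species_of.items():
            by_species.setdefault(sp, set()).add(self.genus_of[g])
        for sp, genera in by_species.items():
            if len(genera) > 1:
                raise ValueError(
                    f"species cluster {sp} spans genus clusters {sorted(genera)}")

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.species_of)
        return pd.DataFrame({
            "species_cluster": [self.species_of[g] for g in ids],
            "genus_cluster": [self.genus_of[g] for g in ids],
            "flags": [";".join(sorted(self.flags.get(g, ()))) for g in ids],
        }, index=pd.Index(ids, name="genome_id"))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _label_clusters(components: Iterable[set[str]], prefix: str) -> dict[str, str]:
    ordered = sorted(components, key=min)
    out = {}
    for i, comp in enumerate(ordered, start=1):
        for g in comp:
            out[g] = f"{prefix}_{i:02d}"
    return out


def _nontransitivity_triples(graph: nx.Graph,
                             component: set[str]) -> list[tuple[str, str, str]]:
    """For each non-adjacent pair in a component, one witness triple."""
    triples = []
    for a, c in combinations(sorted(component), 2):
        if graph.has_edge(a, c):
            continue
        common = sorted(set(graph[a]) & set(graph[c]))
        if common:
            b = common[0]
        else:
            path = nx.shortest_path(graph, a, c)
            b = path[len(path) // 2]
        triples.append((a, b, c))
    return triples


def delimit_species(matrices: SignatureMatrices,
                    thresholds: Thresholds = Thresholds()
                    ) -> tuple[dict[str, str], list[tuple[str, str, str]]]:
    """Species partition: connected components of same-species verdicts.

    Components are kept whole even when an internal pair fails the species
    criteria, but every such failing triple is reported as a
    non-transitivity warning.
    """
    ids = matrices.genome_ids
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a, b in combinations(ids, 2):
        verdict = classify_pair(matrices.aai.loc[a, b], matrices.ggd.loc[a, b],
                                matrices.s16.loc[a, b], thresholds, a, b)
        if verdict.verdict is Verdict.same_species:
            graph.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(graph)]
    warnings: list[tuple[str, str, str]] = []
    for comp in components:
        warnings.extend(_nontransitivity_triples(graph, comp))
    return _label_clusters(components, "species"), warnings


# ---------------------------------------------------------------------------
# Trees and monophyly


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree, preserving underscores in labels."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup leaf {outgroup!r} not found in tree")
    tree.reroot_at_edge(node.edge, update_bipartitions=True)
    return tree


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


def check_monophyly(tree: dendropy.Tree, taxa: Iterable[str],
                    outgroup: str | None = None) -> bool:
    """True iff the smallest clade containing ``taxa`` holds no other leaf."""
    taxa = set(taxa)
    tree.is_rooted = True
    if outgroup is not None:
        root_on_outgroup(tree, outgroup)
    labels = {t.label for t in tree.taxon_namespace}
    unknown = taxa - labels
    if unknown:
        raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
    if len(taxa) == 1:
        return True
    mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t) for t in taxa])
    return _leaf_labels(mrca) == taxa


def _maximal_pure_clades(tree: dendropy.Tree,
                         members: set[str]) -> list[set[str]]:
    """Partition ``members`` into maximal clades containing only members."""
    blocks: list[set[str]] = []

    def visit(node: dendropy.Node) -> None:
        leaves = _leaf_labels(node)
        inside = leaves & members
        if not inside:
            return
        if leaves <= members:
            blocks.append(leaves)
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)
    return blocks


def delimit_genera(matrices: SignatureMatrices,
                   tree: dendropy.Tree | None = None,
                   thresholds: Thresholds = Thresholds(),
                   species_partition: dict[str, str] | None = None
                   ) -> TaxonPartition:
    """Genus partition: AAI components refined to monophyletic clades.

    Connected components at AAI >= ``thresholds.aai_genus`` are computed
    first; with a reference tree, any non-monophyletic component is split
    into its maximal monophyletic subclades.  A species cluster is never
    divided: if a split would divide one, the whole species cluster follows
    its majority subclade and the event is logged.  Genomes absent from the
    tree are assigned by AAI alone and flagged.
    """
    ids = matrices.genome_ids
    if species_partition is None:
        species_partition, warnings = delimit_species(matrices, thresholds)
    else:
        warnings = []
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a, b in combinations(ids, 2):
        if matrices.aai.loc[a, b] >= thresholds.aai_genus:
            graph.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(graph)]

    flags: dict[str, set[str]] = {}
    splits: list[tuple[tuple[str, ...], tuple[tuple[str, ...], ...]]] = []
    if tree is not None:
        tree.is_rooted = True
    tree_labels = ({t.label for t in tree.taxon_namespace}
                   if tree is not None else set())

    blocks: list[set[str]] = []
    for comp in components:
        in_tree = comp & tree_labels
        absent = comp - tree_labels
        for g in absent:
            if tree is not None:
                flags.setdefault(g, set()).add("not_in_tree")
        if tree is None or len(in_tree) <= 1:
            blocks.append(comp)
            continue
        pure = _maximal_pure_clades(tree, in_tree)
        if len(pure) <= 1:
            blocks.append(comp)
            continue
        # species clusters must not straddle subclades
        pure = [set(b) for b in sorted(pure, key=min)]
        by_species: dict[str, list[str]] = {}
        for g in in_tree:
            by_species.setdefault(species_partition[g], []).append(g)
        for sp, members in by_species.items():
            counts = [(len(set(members) & b), -i) for i, b in enumerate(pure)]
            target = -max(counts)[1]
            spread = {i for i, b in enumerate(pure) if set(members) & b}
            if len(spread) > 1:
                log.warning("species cluster %s straddles monophyletic "
                            "subclades; kept whole", sp)
            for i in spread - {target}:
                pure[i] -= set(members)
            pure[target] |= set(members)
        pure = [b for b in pure if b]
        if len(pure) == 1:
            blocks.append(pure[0] | absent)
            continue
        # absent genomes follow the largest subclade (tie: first by min id)
        if absent:
            largest = max(range(len(pure)), key=lambda i: (len(pure[i]),
                                                           min(pure[i])))
            pure[largest] |= absent
        splits.append((tuple(sorted(comp)),
                       tuple(tuple(sorted(b)) for b in sorted(pure, key=min))))
        blocks.extend(pure)

    genus_of = _label_clusters(blocks, "genus")
    for a, b in combinations(ids, 2):
        if _is_missing(matrices.ggd.loc[a, b]):
            flags.setdefault(a, set()).add("ggd_missing")
            flags.setdefault(b, set()).add("ggd_missing")
    if len(ids) > 1:
        for g in ids:
            if matrices.s16.loc[g].drop(g).isna().all():
                flags.setdefault(g, set()).add("s16_missing")
    partition = TaxonPartition(species_of=dict(species_partition),
                               genus_of=genus_of,
                               non_transitivity_warnings=warnings,
                               monophyly_splits=splits, flags=flags)
    partition.validate()
    return partition


# ---------------------------------------------------------------------------
# AAI dendrogram (heatmap ordering)


@dataclass(frozen=True)
class AaiDendrogram:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    genome_ids: list[str]

    def merge_order(self) -> list[tuple[frozenset[str], frozenset[str]]]:
        """Successive merges as pairs of leaf-label sets."""
        n = len(self.genome_ids)
        clusters: dict[int, frozenset[str]] = {
            i: frozenset({self.genome_ids[i]}) for i in range(n)}
        merges = []
        for step, (i, j, _, _) in enumerate(self.linkage_matrix):
            a, b = clusters[int(i)], clusters[int(j)]
            merges.append((a, b) if min(a) <= min(b) else (b, a))
            clusters[n + step] = a | b
        return merges

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def fmt(node) -> str:
            if node.is_leaf():
                return self.genome_ids[node.id]
            left, right = fmt(node.left), fmt(node.right)
            return f"({left}:{node.dist - node.left.dist:.6g}," \
                   f"{right}:{node.dist - node.right.dist:.6g})"

        return fmt(tree) + ";"


def aai_linkage(matrices: SignatureMatrices,
                method: str = "complete") -> AaiDendrogram:
    """Hierarchical clustering of genomes on Manhattan distances between
    their AAI row vectors (heatmap-ready ordering)."""
    aai = matrices.aai.to_numpy(dtype=float)
    if np.isnan(aai).any():
        raise ValueError("AAI matrix must be complete for linkage")
    dists = pdist(aai, metric="cityblock")
    z = linkage(dists, method=method)
    order = [matrices.genome_ids[i] for i in leaves_list(z)]
    return AaiDendrogram(linkage_matrix=z, leaf_order=order,
                         genome_ids=list(matrices.genome_ids))


# ---------------------------------------------------------------------------
# Reassignment report


_UNCLASSIFIED = {"", "sp.", "sp", "unclassified", "nan"}


@dataclass
class ReassignmentReport:
    per_genome: pd.DataFrame
    n_genera: int
    n_species: int
    n_reassigned: int

    def write(self, path: str | Path) -> None:
        self.per_genome.to_csv(path, sep="\t")


def _is_unclassified(label: object) -> bool:
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return True
    return str(label).strip().lower() in _UNCLASSIFIED


def reassignment_report(old_labels: pd.DataFrame,
                        partition: TaxonPartition) -> ReassignmentReport:
    """Compare an existing taxonomy against the inferred partition.

    ``old_labels`` is indexed by genome id with columns ``genus`` and
    ``species`` (species epithet; "sp." or blank means unclassified).  A
    genome needs reassignment at a rank if it is unclassified there, or if
    its old name groups it with genomes that fall outside its inferred
    cluster at that rank.
    """
    ids = sorted(partition.species_of)
    missing = set(ids) - set(old_labels.index.astype(str))
    if missing:
        raise ValueError(f"labels missing for genome(s) {sorted(missing)}")

    def rank_conflicts(rank: str, label_of: dict[str, object],
                       cluster_of: dict[str, str]) -> dict[str, bool]:
        groups: dict[object, set[str]] = {}
        for g in ids:
            if not _is_unclassified(label_of[g]):
                groups.setdefault(label_of[g], set()).add(g)
        needs = {}
        for g in ids:
            if _is_unclassified(label_of[g]):
                needs[g] = True
                continue
            mates = groups[label_of[g]]
            needs[g] = any(cluster_of[m] != cluster_of[g] for m in mates)
        return needs

    genus_label = {g: old_labels.loc[g, "genus"] for g in ids}
    species_label = {}
    for g in ids:
        sp = old_labels.loc[g, "species"]
        if _is_unclassified(sp) or _is_unclassified(genus_label[g]):
            species_label[g] = None
        else:
            species_label[g] = (str(genus_label[g]).strip(), str(sp).strip())
    needs_genus = rank_conflicts("genus", genus_label, partition.genus_of)
    needs_species = rank_conflicts("species", species_label,
                                   partition.species_of)
    frame = pd.DataFrame({
        "old_genus": [genus_label[g] for g in ids],
        "old_species": [old_labels.loc[g, "species"] for g in ids],
        "genus_cluster": [partition.genus_of[g] for g in ids],
        "species_cluster": [partition.species_of[g] for g in ids],
        "needs_genus_reassignment": [needs_genus[g] for g in ids],
        "needs_species_reassignment": [needs_species[g] for g in ids],
    }, index=pd.Index(ids, name="genome_id"))
    frame["needs_reassignment"] = (frame.needs_genus_reassignment
                                   | frame.needs_species_reassignment)
    return ReassignmentReport(
        per_genome=frame,
        n_genera=len(set(partition.genus_of.values())),
        n_species=len(set(partition.species_of.values())),
        n_reassigned=int(frame.needs_reassignment.sum()),
    )
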