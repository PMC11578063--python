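"""Homologous gene clustering, single-copy core genes and phylogenomics.

Translated CDS from all genomes are clustered by pairwise identity (>=50%
over >=80% coverage, single linkage), single-copy core clusters are scored
for alignment homogeneity, the best-ranked markers (42 by default, matching
common practice for a concatenated bacterial marker set) are concatenated,
and a neighbour-joining species tree is built with gene-resampling bootstrap.

Homogeneity indices:
  geometric  — per-column agreement of gap/non-gap state, averaged over
               columns (1 = identical gap structure);
  functional — per-column frequency of the modal residue among non-gap
               members, averaged over non-fully-gapped columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import networkx as nx
import numpy as np

from .genome_io import ProteinSeq
from .og_classification import (
    GeneTree,
    _bipartitions,  # shared tree plumbing
    _canon_side,
    _nj_from_percent_identity,
    align_proteins,
)

__all__ = [
    "GeneCluster",
    "HomogeneityScores",
    "MarkerSet",
    "protein_identity_fast",
    "cluster_genes",
    "single_copy_core",
    "homogeneity",
    "select_markers",
    "concat_tree",
]


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (genome_id, protein_id)
    alignment: dict[str, str] = field(default_factory=dict)  # protein_id -> row
    copy_number: dict[str, int] = field(default_factory=dict)

    def is_single_copy_core(self, genome_ids: Sequence[str]) -> bool:
        return all(self.copy_number.get(g, 0) == 1 for g in genome_ids)


@dataclass
class HomogeneityScores:
    geometric: float
    functional: float


@dataclass
class MarkerSet:
    clusters: list[GeneCluster]
    scores: dict[str, HomogeneityScores] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)


def protein_identity_fast(a: str, b: str) -> float:
    """Percent identity from a global edit-distance alignment (edlib)."""
    a, b = a.rstrip("*"), b.rstrip("*")
    r = edlib.align(a, b, mode="NW", task="path")
    match = cols = 0
    import re

    for num, op in re.findall(r"(\d+)([=XID])", r["cigar"] or ""):
        n = int(num)
        cols += n
        if op == "=":
            match += n
    return 100.0 * match / cols if cols else 0.0


def cluster_genes(
    proteins_by_genome: dict[str, list[ProteinSeq]],
    min_identity: float = 50.0,
    min_coverage: float = 80.0,
) -> list[GeneCluster]:
    """Single-linkage clustering of all proteins across genomes.

    Edges join proteins at >= min_identity% global identity whose length
    ratio satisfies the coverage bound (a global alignment covers the shorter
    sequence whenever the lengths are compatible).
    """
    if len(proteins_by_genome) < 2:
        raise ValueError("need >=2 genomes")
    entries: list[tuple[str, str, str]] = []  # (genome, id, residues)
    for gid, prots in proteins_by_genome.items():
        for p in prots:
            entries.append((gid, p.protein_id, p.residues.rstrip("*")))
    g = nx.Graph()
    for gid, pid, _seq in entries:
        g.add_node(pid, genome=gid)
    cov = min_coverage / 100.0
    for (ga, pa, sa), (gb, pb, sb) in itertools.combinations(entries, 2):
        la, lb = len(sa), len(sb)
        if min(la, lb) < cov * max(la, lb):
            continue
        if protein_identity_fast(sa, sb) >= min_identity:
            g.add_edge(pa, pb)
    seq_of = {pid: seq for _g, pid, seq in entries}
    genome_of = {pid: gid for gid, pid, _s in entries}
    clusters: list[GeneCluster] = []
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    for k, comp in enumerate(comps, start=1):
        members = sorted((genome_of[p], p) for p in comp)
        copy_number: dict[str, int] = {}
        for gid, _p in members:
            copy_number[gid] = copy_number.get(gid, 0) + 1
        aln: dict[str, str] = {}
        if len(comp) >= 2:
            aln = align_proteins(
                [ProteinSeq(protein_id=p, residues=seq_of[p]) for p in comp]
            )
        else:
            aln = {comp[0]: seq_of[comp[0]]}
        clusters.append(
            GeneCluster(
                cluster_id=f"GC{k:05d}",
                members=members,
                alignment=aln,
                copy_number=copy_number,
            )
        )
    return clusters


def single_copy_core(
    clusters: Sequence[GeneCluster], genome_ids: Sequence[str]
) -> list[GeneCluster]:
    """Clusters present exactly once in every genome."""
    return [c for c in clusters if c.is_single_copy_core(genome_ids)]


def homogeneity(cluster: GeneCluster) -> HomogeneityScores:
    if len(cluster.members) < 2:
        raise ValueError("homogeneity undefined for a single-member cluster")
    rows = [cluster.alignment[p] for _g, p in cluster.members]
    L = {len(r) for r in rows}
    if len(L) != 1:
        raise ValueError("alignment rows differ in length")
    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    gap = mat == ord("-")
    n = len(rows)
    npairs = n * (n - 1) / 2
    # geometric: gap-state pair disagreement per column
    ngap = gap.sum(axis=0)
    disagree = ngap * (n - ngap) / npairs
    geometric = float(np.mean(1.0 - disagree))
    # functional: modal-residue frequency among non-gap members
    fvals = []
    for j in range(mat.shape[1]):
        col = mat[~gap[:, j], j]
        if col.size == 0:
            continue
        _vals, counts = np.unique(col, return_counts=True)
        fvals.append(counts.max() / col.size)
    functional = float(np.mean(fvals)) if fvals else 0.0
    return HomogeneityScores(geometric=geometric, functional=functional)


def select_markers(candidates: Sequence[GeneCluster], n: int = 42) -> MarkerSet:
    """Rank by (geometric desc, functional asc), ties by cluster_id; take n."""
    scored = [(c, homogeneity(c)) for c in candidates]
    scored.sort(key=lambda cs: (-cs[1].geometric, cs[1].functional, cs[0].cluster_id))
    if len(scored) < n:
        import warnings

        warnings.warn(f"only {len(scored)} single-copy core candidates (< {n})")
    picked = scored[:n]
    return MarkerSet(
        clusters=[c for c, _s in picked],
        scores={c.cluster_id: s for c, s in picked},
    )


def concat_tree(
    markers: MarkerSet,
    genome_ids: Sequence[str],
    bootstrap: int = 100,
    seed: int = 0,
) -> GeneTree:
    """NJ species tree from per-genome concatenated marker alignments.

    Bootstrap resamples whole markers (genes) with replacement, respecting
    gene-level correlation of sites.
    """
    if len(genome_ids) < 3:
        raise ValueError("need >=3 genomes")
    gids = sorted(genome_ids)
    per_marker: list[dict[str, str]] = []
    for c in markers.clusters:
        row = {}
        for gid, pid in c.members:
            row[gid] = c.alignment[pid]
        if set(row) < set(gids):
            raise RuntimeError(f"marker {c.cluster_id} missing a genome")
        per_marker.append(row)
    if not per_marker:
        raise ValueError("no markers")

    def tree_from(marker_idx: Sequence[int]) -> tuple:
        cat = {g: "".join(per_marker[i][g] for i in marker_idx) for g in gids}
        mat = np.array(
            [np.frombuffer(cat[g].encode(), dtype=np.uint8) for g in gids]
        )
        gap = mat == ord("-")
        n = len(gids)
        p = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~gap[i] & ~gap[j]
                tot = int(ok.sum())
                p[i, j] = p[j, i] = (
                    float((mat[i, ok] != mat[j, ok]).sum() / tot) if tot else 0.0
                )
        return _nj_from_percent_identity(gids, 100.0 * (1.0 - p))

    main = tree_from(range(len(per_marker)))
    leaves = frozenset(gids)
    supports: dict[frozenset, int] = {b: 0 for b in _bipartitions(main, leaves)}
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x67656E65])
    for _ in range(bootstrap):
        pick = rng.integers(0, len(per_marker), size=len(per_marker))
        rep = tree_from(pick)
        for b in _bipartitions(rep, leaves):
            if b in supports:
                supports[b] += 1
    for node in main.non_tips(include_self=False):
        under = _canon_side(frozenset(t.name for t in node.tips()), leaves)
        if under in supports:
            node.name = str(supports[under])
    return GeneTree(tree=main, newick=str(main).strip(), supports=supports,
                    n_bootstrap=bootstrap)
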