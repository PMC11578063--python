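"""Orthologue-group (OG) classification of RdhA proteins.

RdhA sequences are grouped at a 90% amino-acid identity cutoff (single
linkage), singletons receive letter labels, overlapping OGs are merged with
support from a neighbour-joining gene tree, 75-90% "umbrella" groups are
detected one node rootward of each OG clade, and each multi-clade OG is
screened for clade concordance: an OG whose members cluster by genome clade is
consistent with vertical descent, while clade-discordant clustering marks an
HGT candidate.

Identity is defined over a global alignment with free end gaps (BLOSUM62,
gap open 11 / extend 1): matches divided by aligned columns, terminal-gap
columns excluded.
"""

from __future__ import annotations

import itertools
import shutil
import string
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .genome_io import ProteinSeq

__all__ = [
    "IdentityMatrix",
    "OGPartition",
    "GeneTree",
    "UmbrellaGroup",
    "ConcordanceReport",
    "pairwise_identity",
    "identity_matrix",
    "assign_ogs",
    "build_nj_tree",
    "curate_partition",
    "detect_umbrellas",
    "clade_concordance",
    "align_proteins",
    "singleton_label",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
MAX_CORRECTED_DISTANCE = 10.0


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    # free end gaps
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    return al


_ALIGNER = _aligner()


def pairwise_identity(a: ProteinSeq | str, b: ProteinSeq | str) -> float:
    """Percent identity over a free-end-gap global alignment, in [0, 100]."""
    sa = (a.residues if isinstance(a, ProteinSeq) else a).rstrip("*")
    sb = (b.residues if isinstance(b, ProteinSeq) else b).rstrip("*")
    if not sa or not sb:
        raise ValueError("pairwise_identity: empty sequence")
    if sa == sb:
        return 100.0
    aln = _ALIGNER.align(sa, sb)[0]
    c = aln.counts()
    denom = c.identities + c.mismatches + c.internal_gaps
    if denom == 0:
        return 0.0
    return 100.0 * c.identities / denom


@dataclass
class IdentityMatrix:
    ids: list[str]
    matrix: np.ndarray  # percent identity, symmetric, diagonal 100

    def __post_init__(self) -> None:
        self._index = {x: i for i, x in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> "IdentityMatrix":
        idx = [self._index[i] for i in ids]
        return IdentityMatrix(list(ids), self.matrix[np.ix_(idx, idx)])


def identity_matrix(proteins: Sequence[ProteinSeq]) -> IdentityMatrix:
    ids = [p.protein_id for p in proteins]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate protein ids")
    n = len(proteins)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_identity(proteins[i], proteins[j])
            m[i, j] = m[j, i] = v
    return IdentityMatrix(ids, m)


# ---------------------------------------------------------------------------
# OG assignment
# ---------------------------------------------------------------------------

def singleton_label(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-column style)."""
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


@dataclass
class OGPartition:
    assignment: dict[str, str]  # member id -> label
    merged_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == label)

    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m, lab in self.assignment.items():
            out.setdefault(lab, []).append(m)
        return {k: sorted(v) for k, v in out.items()}


def assign_ogs(identity: IdentityMatrix, threshold: float = 90.0) -> OGPartition:
    """Single-linkage components of the >= threshold identity graph.

    Components of size >= 2 are numbered OG1, OG2, ... in order of
    (size descending, lexicographically smallest member); singletons get
    letters A, B, ..., Z, AA, ... in lexicographic order of member id.
    """
    g = nx.Graph()
    g.add_nodes_from(identity.ids)
    n = len(identity.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if identity.matrix[i, j] >= threshold:
                g.add_edge(identity.ids[i], identity.ids[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    multi = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c[0]))
    singles = sorted((c[0] for c in comps if len(c) == 1))
    assignment: dict[str, str] = {}
    for k, comp in enumerate(multi, start=1):
        for m in comp:
            assignment[m] = f"OG{k}"
    for k, m in enumerate(singles):
        assignment[m] = singleton_label(k)
    return OGPartition(assignment=assignment)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    tree: TreeNode  # unrooted interpretation; skbio stores it rooted
    newick: str
    supports: dict[frozenset, int] = field(default_factory=dict)
    n_bootstrap: int = 0

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def _corrected_distance(p: np.ndarray) -> np.ndarray:
    """Poisson-family correction d = -(19/20) ln(1 - 20p/19), capped."""
    arg = 1.0 - (20.0 / 19.0) * p
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -(19.0 / 20.0) * np.log(arg)
    bad = ~np.isfinite(d) | (p >= 0.95)
    if bad.any() and (p > 0).any():
        if (p[bad] > 0).any():
            warnings.warn(
                "p-distance >= 0.95: correction undefined, capping distance"
            )
    d = np.where(bad, MAX_CORRECTED_DISTANCE, d)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _canon_side(under: frozenset, leaves: frozenset) -> frozenset:
    comp = frozenset(leaves - under)
    return min(under, comp, key=lambda s: (len(s), tuple(sorted(s))))


def _bipartitions(tree: TreeNode, leaves: frozenset) -> set[frozenset]:
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        under = frozenset(t.name for t in node.tips())
        if 2 <= len(under) <= len(leaves) - 2:
            out.add(_canon_side(under, leaves))
    return out


def _nj_from_percent_identity(ids: list[str], ident: np.ndarray) -> TreeNode:
    p = 1.0 - ident / 100.0
    d = _corrected_distance(p)
    d = (d + d.T) / 2.0
    dm = DistanceMatrix(d, ids)
    tree = nj(dm)
    # negative NJ branch lengths are a numerical artifact; clamp for display
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def align_proteins(proteins: Sequence[ProteinSeq]) -> dict[str, str]:
    """Multiple alignment of a protein set.

    Equal-length sequence sets (the substitution-only simulation regime) are
    already positionally aligned and are returned as-is; otherwise mafft is
    invoked.
    """
    seqs = {p.protein_id: p.residues.rstrip("*") for p in proteins}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return seqs
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH and sequences are not equal-length")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.faa"
        with open(fin, "w") as fh:
            for pid, s in seqs.items():
                fh.write(f">{pid}\n{s}\n")
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
    out: dict[str, str] = {}
    cur = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            out[cur] = ""
        elif cur is not None:
            out[cur] += line.strip().upper()
    return out


def _pdist_from_alignment(ids: list[str], cols: np.ndarray) -> np.ndarray:
    """Pairwise p-distance over columns where both rows are non-gap."""
    n = len(ids)
    p = np.zeros((n, n))
    gap = cols == ord("-")
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            tot = ok.sum()
            pij = float((cols[i, ok] != cols[j, ok]).sum() / tot) if tot else 0.0
            p[i, j] = p[j, i] = pij
    return p


def build_nj_tree(
    identity: IdentityMatrix,
    alignment: Optional[dict[str, str]] = None,
    bootstrap: int = 100,
    seed: int = 0,
) -> GeneTree:
    """Neighbour-joining tree on corrected distances, with optional bootstrap.

    Bootstrap resamples alignment columns (requires ``alignment``); supports
    are counted per internal bipartition of the point-estimate tree.
    """
    if len(identity.ids) < 3:
        raise ValueError("need >=3 sequences for a tree")
    tree = _nj_from_percent_identity(identity.ids, identity.matrix)
    supports: dict[frozenset, int] = {}
    nboot = 0
    if alignment is not None and bootstrap > 0:
        ids = identity.ids
        L = {len(alignment[i]) for i in ids}
        if len(L) != 1:
            raise ValueError("alignment rows must be equal length")
        ncol = L.pop()
        cols = np.array([np.frombuffer(alignment[i].encode(), dtype=np.uint8) for i in ids])
        leaves = frozenset(ids)
        main_bips = _bipartitions(tree, leaves)
        counts = {b: 0 for b in main_bips}
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x626F6F74])
        for _ in range(bootstrap):
            pick = rng.integers(0, ncol, size=ncol)
            p = _pdist_from_alignment(ids, cols[:, pick])
            rep = _nj_from_percent_identity(ids, 100.0 * (1.0 - p))
            for b in _bipartitions(rep, leaves):
                if b in counts:
                    counts[b] += 1
        supports = counts
        nboot = bootstrap
        for node in tree.non_tips(include_self=False):
            under = _canon_side(frozenset(t.name for t in node.tips()), leaves)
            if under in supports:
                node.name = str(supports[under])
    newick = str(tree).strip()
    return GeneTree(tree=tree, newick=newick, supports=supports, n_bootstrap=nboot)


# ---------------------------------------------------------------------------
# tree-based curation, umbrellas, concordance
# ---------------------------------------------------------------------------

def _rooted_copy(tree: TreeNode) -> TreeNode:
    t = tree.copy()
    try:
        return t.root_at_midpoint()
    except Exception:
        return t


def _min_cross_identity(
    identity: IdentityMatrix, a: Sequence[str], b: Sequence[str]
) -> float:
    return min(identity.get(x, y) for x in a for y in b)


def _edge_sides(tree: TreeNode) -> list[frozenset]:
    sides = []
    for node in tree.traverse(include_self=False):
        under = (
            frozenset(t.name for t in node.tips())
            if not node.is_tip()
            else frozenset({node.name})
        )
        sides.append(under)
    return sides


def _interleaved(
    sides: list[frozenset], all_leaves: frozenset, x: frozenset, y: frozenset
) -> bool:
    """True when X and Y cannot both form clean clades excluding each other.

    X/Y interleave when (at least one of them is non-monophyletic in the
    unrooted sense) and either no edge separates X from Y, or X union Y
    itself forms a clade (one label nested inside the other's clade).
    """
    candidates = sides + [all_leaves - s for s in sides] + [all_leaves]

    def mono(s: frozenset) -> bool:
        if len(s) <= 1 or s == all_leaves:
            return True
        return any(s == side for side in candidates)

    if mono(x) and mono(y):
        return False
    separable = any(
        (x <= side and y <= all_leaves - side)
        or (y <= side and x <= all_leaves - side)
        for side in sides
    )
    if not separable:
        return True

    def breakers(s: frozenset) -> frozenset:
        closure = min(
            (c for c in candidates if s <= c),
            key=lambda c: (len(c), tuple(sorted(c))),
        )
        return closure - s

    return y <= breakers(x) or x <= breakers(y)


def curate_partition(
    partition: OGPartition,
    gene_tree: GeneTree,
    identity: IdentityMatrix,
) -> OGPartition:
    """Merge labels whose members interleave on the gene tree.

    Two labels merge when neither forms a clean clade excluding the other:
    either their members mix on the tree, or one label (e.g. a singleton)
    nests inside the other's clade.  Each merge records the minimum
    cross-label identity; identities are recorded, not enforced.
    """
    groups = partition.groups()
    labels = sorted(groups)
    memsets = {lab: frozenset(groups[lab]) for lab in labels}
    sides = _edge_sides(gene_tree.tree)
    all_leaves = frozenset(t.name for t in gene_tree.tree.tips())

    parent = {lab: lab for lab in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges: list[tuple[str, str, float]] = []
    for la, lb in itertools.combinations(labels, 2):
        if _interleaved(sides, all_leaves, memsets[la], memsets[lb]):
            ra, rb = find(la), find(lb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
            merges.append(
                (la, lb, round(_min_cross_identity(identity, groups[la], groups[lb]), 2))
            )

    # representative label per merged component: the label of the largest
    # original group (ties to the lexicographically smallest label)
    comps: dict[str, list[str]] = {}
    for lab in labels:
        comps.setdefault(find(lab), []).append(lab)
    rep: dict[str, str] = {}
    for labs in comps.values():
        keep = sorted(labs, key=lambda l: (-len(groups[l]), l))[0]
        for l in labs:
            rep[l] = keep
    assignment = {m: rep[lab] for m, lab in partition.assignment.items()}
    return OGPartition(assignment=assignment, merged_pairs=sorted(merges))


@dataclass
class UmbrellaGroup:
    labels: frozenset
    min_identity: float  # min pairwise identity of all leaves under the node
    node_leaves: frozenset

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("umbrella needs >=2 labels")


def detect_umbrellas(
    gene_tree: GeneTree,
    identity: IdentityMatrix,
    partition: OGPartition,
    floor: float = 75.0,
) -> list[UmbrellaGroup]:
    """One-node-rootward umbrella search.

    For each label's clade, step to the parent node; if every leaf pair under
    the parent is > floor% identical and the parent covers >= 2 labels, that
    node defines an umbrella.  Only maximal nodes are emitted (no umbrella
    nested inside another emitted umbrella).
    """
    rooted = _rooted_copy(gene_tree.tree)
    groups = partition.groups()
    classified = set(partition.assignment)
    candidates: dict[frozenset, UmbrellaGroup] = {}
    for lab, members in groups.items():
        if len(members) == 1:
            node = next(t for t in rooted.tips() if t.name == members[0])
        else:
            node = rooted.lca(members)
        parent_node = node.parent
        if parent_node is None:
            continue
        leaves = frozenset(t.name for t in parent_node.tips()) & classified
        if len(leaves) < 2:
            continue
        min_id = min(
            identity.get(a, b) for a, b in itertools.combinations(sorted(leaves), 2)
        )
        if min_id <= floor:
            continue
        labs = frozenset(partition.assignment[l] for l in leaves)
        if len(labs) < 2:
            continue
        candidates[leaves] = UmbrellaGroup(labs, round(min_id, 2), leaves)
    # keep maximal leaf sets only
    out = []
    for leaves, umb in candidates.items():
        if any(leaves < other for other in candidates if other != leaves):
            continue
        out.append(umb)
    return sorted(out, key=lambda u: sorted(u.labels))


@dataclass
class ConcordanceReport:
    og_label: str
    per_clade: dict[str, bool]  # clade -> monophyletic in the restricted tree
    violations: int
    verdict: str  # vertical | hgt_candidate | not_applicable


def _is_monophyletic_unrooted(tree: TreeNode, group: set[str]) -> bool:
    """Bipartition test: some edge separates exactly `group` from the rest."""
    all_leaves = {t.name for t in tree.tips()}
    if group == all_leaves or len(group) == 1:
        return True
    for node in tree.traverse(include_self=False):
        under = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if under == group or (all_leaves - under) == group:
            return True
    return False


def clade_concordance(
    og_members: Sequence[tuple[str, str]],
    clades: dict[str, str],
    gene_tree: GeneTree,
    og_label: str = "",
) -> ConcordanceReport:
    """Screen one OG for vertical descent vs HGT.

    Restricts the gene tree to the OG's members and tests, for each genome
    clade contributing >= 2 members, whether those members are monophyletic.
    Zero violations -> vertical; otherwise hgt_candidate.  An OG confined to
    one clade, or with < 3 members, is not_applicable.
    """
    member_ids = [m for m, _g in og_members]
    member_clades = {m: clades[g] for m, g in og_members}
    n_clades = len(set(member_clades.values()))
    if len(member_ids) < 3 or n_clades < 2:
        return ConcordanceReport(og_label, {}, 0, "not_applicable")
    sub = gene_tree.tree.shear(member_ids)
    per_clade: dict[str, bool] = {}
    violations = 0
    for clade in sorted(set(member_clades.values())):
        members = {m for m, c in member_clades.items() if c == clade}
        if len(members) < 2:
            continue
        mono = _is_monophyletic_unrooted(sub, members)
        per_clade[clade] = mono
        if not mono:
            violations += 1
    verdict = "vertical" if violations == 0 else "hgt_candidate"
    return ConcordanceReport(og_label, per_clade, violations, verdict)
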