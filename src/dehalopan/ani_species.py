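"""Fragment-based average nucleotide identity (ANI) and species delineation.

ANIb-style scheme: the query genome is chopped into consecutive 1020 bp
fragments, each fragment is aligned to the reference (best hit over both
strands), fragments are retained at >=30% identity and >=70% coverage, and
the directional ANI is the mean identity of retained fragments.  The
symmetric per-pair summary is the mean of the two directions, and species are
single-linkage components at >=95% summary ANI.

Two alignment backends are provided: a fast infix aligner (edlib) that aligns
the whole fragment into the reference, and an exact local dynamic-programming
aligner (Biopython) used to validate the fast path on small inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner

from .genome_io import Genome, reverse_complement

__all__ = [
    "DirectionalANI",
    "ANIMatrix",
    "SpeciesPartition",
    "directional_ani",
    "ani_matrix",
    "delineate_species",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class DirectionalANI:
    query_id: str
    reference_id: str
    ani: Optional[float]  # percent; None when no fragment was retained
    aligned_fraction: float
    n_fragments: int = 0


@dataclass
class ANIMatrix:
    ids: list[str]
    directional: dict[tuple[str, str], DirectionalANI]
    summary: np.ndarray  # percent, symmetric, diagonal 100; NaN when missing

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.summary[i, j])


@dataclass
class SpeciesPartition:
    assignment: dict[str, str]
    threshold: float

    def n_species(self) -> int:
        return len(set(self.assignment.values()))


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """(identity fraction, aligned columns) from an edlib extended cigar."""
    match = cols = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            match += n
    return (match / cols if cols else 0.0), cols


def _best_fragment_hit_edlib(frag: str, targets: list[str]) -> tuple[float, float]:
    """Best (identity, coverage) of a fragment over targets (both strands)."""
    # banded edit-distance passes (escalating k, then capped by the best hit
    # so far) before a single traceback on the winning target
    kcap = max(1, int(0.7 * len(frag)))
    best_dist, best_t = None, None
    for t in targets:
        if best_dist is not None:
            k = best_dist - 1
            if k < 0:
                break
            r = edlib.align(frag, t, mode="HW", task="distance", k=k)
            if 0 <= r["editDistance"] < best_dist:
                best_dist, best_t = r["editDistance"], t
            continue
        k = 64
        while True:
            r = edlib.align(frag, t, mode="HW", task="distance", k=k)
            if r["editDistance"] >= 0:
                best_dist, best_t = r["editDistance"], t
                break
            if k >= kcap:
                break
            k = min(kcap, k * 4)
    if best_t is None:
        return 0.0, 0.0
    r = edlib.align(frag, best_t, mode="HW", task="path")
    ident, _cols = _cigar_identity(r["cigar"] or "")
    return ident, 1.0  # infix mode aligns the full fragment


_DP = PairwiseAligner()
_DP.mode = "local"
_DP.match_score = 1.0
_DP.mismatch_score = -1.0
_DP.open_gap_score = -2.0
_DP.extend_gap_score = -1.0


def _best_fragment_hit_dp(frag: str, targets: list[str]) -> tuple[float, float]:
    best = (0.0, 0.0)
    for t in targets:
        aln = _DP.align(frag, t)
        if len(aln) == 0:
            continue
        a = aln[0]
        c = a.counts()
        cols = c.identities + c.mismatches + c.internal_gaps
        if cols == 0:
            continue
        ident = c.identities / cols
        qspan = a.aligned[0][-1][1] - a.aligned[0][0][0] if len(a.aligned[0]) else 0
        cov = qspan / len(frag)
        if (ident * cov, ident) > (best[0] * best[1], best[0]):
            best = (ident, cov)
    return best


def _fragments(genome: Genome, frag_len: int) -> list[str]:
    frags: list[str] = []
    for contig in genome.contigs:
        seq = contig.sequence
        for i in range(0, len(seq), frag_len):
            frag = seq[i : i + frag_len]
            if len(frag) >= 100:  # skip trailing slivers too short to align
                frags.append(frag)
    return frags


def directional_ani(
    query: Genome,
    reference: Genome,
    frag_len: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_coverage: float = 70.0,
    backend: str = "edlib",
    reduction: str = "mean",
) -> DirectionalANI:
    """One-way fragment ANI of ``query`` against ``reference``."""
    if query.length == 0 or reference.length == 0:
        raise ValueError("empty genome")
    hit = _best_fragment_hit_edlib if backend == "edlib" else _best_fragment_hit_dp
    targets = [c.sequence for c in reference.contigs]
    targets += [reverse_complement(t) for t in targets]
    idents: list[float] = []
    frags = _fragments(query, frag_len)
    for frag in frags:
        ident, cov = hit(frag, targets)
        if ident * 100.0 >= min_frag_identity and cov * 100.0 >= min_frag_coverage:
            idents.append(ident)
    if not idents:
        return DirectionalANI(query.genome_id, reference.genome_id, None, 0.0, len(frags))
    agg = np.mean if reduction == "mean" else np.median
    return DirectionalANI(
        query.genome_id,
        reference.genome_id,
        float(agg(idents)) * 100.0,
        len(idents) / len(frags),
        len(frags),
    )


def ani_matrix(
    genomes: Sequence[Genome],
    frag_len: int = 1020,
    backend: str = "edlib",
    reduction: str = "mean",
) -> ANIMatrix:
    """All ordered pairs; symmetric summary = mean of the two directions."""
    if len(genomes) < 2:
        raise ValueError("need >=2 genomes")
    ids = [g.genome_id for g in sorted(genomes, key=lambda g: g.genome_id)]
    by_id = {g.genome_id: g for g in genomes}
    n = len(ids)
    directional: dict[tuple[str, str], DirectionalANI] = {}
    summary = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = directional_ani(
                by_id[ids[i]], by_id[ids[j]], frag_len=frag_len,
                backend=backend, reduction=reduction,
            )
            directional[(ids[i], ids[j])] = d
    for i in range(n):
        for j in range(i + 1, n):
            a = directional[(ids[i], ids[j])].ani
            b = directional[(ids[j], ids[i])].ani
            vals = [v for v in (a, b) if v is not None]
            summary[i, j] = summary[j, i] = float(np.mean(vals)) if vals else np.nan
    return ANIMatrix(ids=ids, directional=directional, summary=summary)


def delineate_species(matrix: ANIMatrix, threshold: float = 95.0) -> SpeciesPartition:
    """Single-linkage species clustering at the summary-ANI threshold."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.summary[i, j]
            if np.isfinite(v) and v >= threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j])
    assignment: dict[str, str] = {}
    for comp in nx.connected_components(g):
        label = f"sp_{min(comp)}"
        for m in comp:
            assignment[m] = label
    return SpeciesPartition(assignment=assignment, threshold=threshold)
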