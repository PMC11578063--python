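"""RDase cluster synteny and genomic-island delimitation.

Adjacent rdhA genes (inter-gene gap <= 10 kb, boundary to boundary) form
RDase clusters.  Clusters are compared across genomes through two link tiers:
solid links join members of the same OG (>90% aa identity) and umbrella links
join members of related OGs/singletons under one umbrella (75-90% identity).
Genomic islands around a query locus are delimited by the nearest single-copy
core gene on either side (inner-edge bounds), and the island's mobile-element
content is tallied from annotation keywords (a keyword-estimated surrogate
for model-based MGE classifiers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .genome_io import Feature, Genome, reverse_complement
from .og_classification import IdentityMatrix, OGPartition, UmbrellaGroup

__all__ = [
    "RdhCluster",
    "SyntenyLink",
    "GenomicIsland",
    "IslandComparison",
    "MGETally",
    "DEFAULT_KEYWORDS",
    "find_rdh_clusters",
    "link_clusters",
    "synteny_conservation",
    "delimit_island",
    "compare_islands",
    "mge_tally",
]


@dataclass
class RdhCluster:
    genome_id: str
    contig_id: str
    members: list[Feature]  # ordered 5'->3'
    gaps: list[int] = field(default_factory=list)
    isolated: bool = False
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def member_ids(self) -> list[str]:
        return [f.feature_id for f in self.members]


def find_rdh_clusters(
    features: Sequence[Feature],
    max_gap: int = 10000,
    contig_lengths: Optional[dict[str, int]] = None,
) -> list[RdhCluster]:
    """Maximal runs of rdhA features with inter-feature gaps <= max_gap.

    The gap is measured end-to-start, exclusive (bases strictly between the
    two features).  Single rdhA genes become size-1 clusters flagged
    isolated; truncation flags mark clusters whose outermost member lies
    within max_gap of a contig end.
    """
    clusters: list[RdhCluster] = []
    by_contig: dict[tuple[str, str], list[Feature]] = {}
    for f in features:
        by_contig.setdefault((f.genome_id, f.contig_id), []).append(f)
    for (gid, cid), feats in sorted(by_contig.items()):
        feats = sorted(feats, key=lambda f: (f.start, f.end))
        run: list[Feature] = [feats[0]]
        gaps: list[int] = []
        def flush() -> None:
            clen = (contig_lengths or {}).get(cid)
            clusters.append(
                RdhCluster(
                    genome_id=gid,
                    contig_id=cid,
                    members=list(run),
                    gaps=list(gaps),
                    isolated=len(run) == 1,
                    truncated_start=run[0].start - 1 <= max_gap,
                    truncated_end=(clen is not None and clen - run[-1].end <= max_gap),
                )
            )
        for f in feats[1:]:
            gap = f.start - run[-1].end - 1
            if gap <= max_gap:
                run.append(f)
                gaps.append(gap)
            else:
                flush()
                run, gaps = [f], []
        flush()
    return clusters


@dataclass
class SyntenyLink:
    a_index: int
    b_index: int
    a_id: str
    b_id: str
    tier: str  # solid | umbrella
    identity: float


def link_clusters(
    a: RdhCluster,
    b: RdhCluster,
    partition: OGPartition,
    umbrellas: Sequence[UmbrellaGroup],
    identity: IdentityMatrix,
) -> list[SyntenyLink]:
    """Cross-cluster homology links in two tiers (Fig.-6 style).

    Solid: same OG and >90% identity.  Umbrella: labels co-occur in an
    umbrella and identity in [75, 90].  Each member takes at most one
    counterpart per tier; best identity wins, ties to the smaller index.
    """
    umb_pairs: set[frozenset] = set()
    for u in umbrellas:
        for la in u.labels:
            for lb in u.labels:
                if la != lb:
                    umb_pairs.add(frozenset((la, lb)))
    candidates: dict[str, list[tuple[float, int, int]]] = {"solid": [], "umbrella": []}
    for i, fa in enumerate(a.members):
        for j, fb in enumerate(b.members):
            la = partition.assignment.get(fa.feature_id)
            lb = partition.assignment.get(fb.feature_id)
            if la is None or lb is None:
                continue
            ident = identity.get(fa.feature_id, fb.feature_id)
            if la == lb and ident > 90.0:
                candidates["solid"].append((ident, i, j))
            elif (
                la != lb
                and frozenset((la, lb)) in umb_pairs
                and 75.0 <= ident <= 90.0
            ):
                candidates["umbrella"].append((ident, i, j))
    links: list[SyntenyLink] = []
    for tier, cands in candidates.items():
        cands.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for ident, i, j in cands:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            links.append(
                SyntenyLink(
                    a_index=i,
                    b_index=j,
                    a_id=a.members[i].feature_id,
                    b_id=b.members[j].feature_id,
                    tier=tier,
                    identity=round(ident, 2),
                )
            )
    return sorted(links, key=lambda l: (l.a_index, l.tier))


def synteny_conservation(
    a: RdhCluster, b: RdhCluster, links: Sequence[SyntenyLink]
) -> Optional[float]:
    """Fraction of adjacent linked pairs in ``a`` that stay adjacent in ``b``.

    Orientation-aware: colinear and reverse-colinear adjacencies both count,
    scored under the better of the two global orientations.  Returns None
    (undefined) with fewer than 2 links.
    """
    mapping: dict[int, int] = {}
    for l in sorted(links, key=lambda l: -l.identity):
        if l.a_index not in mapping:
            mapping[l.a_index] = l.b_index
    if len(mapping) < 2:
        return None
    idx = sorted(mapping)
    pairs = [
        (mapping[i], mapping[j])
        for i, j in zip(idx, idx[1:])
        if j == i + 1
    ]
    if not pairs:
        return None
    fwd = sum(1 for x, y in pairs if y - x == 1)
    rev = sum(1 for x, y in pairs if y - x == -1)
    return max(fwd, rev) / len(pairs)


@dataclass
class GenomicIsland:
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    upstream_core: Optional[str]  # flanking core cluster id (None if open)
    downstream_core: Optional[str]
    enclosed: list[Feature] = field(default_factory=list)
    query: tuple[int, int] = (0, 0)
    open_start: bool = False
    open_end: bool = False
    sequence: str = ""


def delimit_island(
    query: tuple[str, int, int],
    genome: Genome,
    features: Sequence[Feature],
    scg_membership: dict[str, str],
    inclusive_flanks: bool = False,
) -> GenomicIsland:
    """Delimit the island around a query locus by the nearest core genes.

    ``query`` is (contig_id, start, end), 1-based inclusive.  The island runs
    from the inner boundary of the nearest upstream single-copy core gene to
    the inner boundary of the nearest downstream one; ``inclusive_flanks``
    switches to gene-inclusive bounds.  A missing flank extends the island to
    the contig end and sets the corresponding open flag.
    """
    if not scg_membership:
        raise ValueError("no single-copy-core membership map supplied")
    cid, qstart, qend = query
    contig = genome.contig(cid)
    local = [f for f in features if f.contig_id == cid]
    scgs = [f for f in local if f.feature_id in scg_membership]
    up = [f for f in scgs if f.end < qstart]
    down = [f for f in scgs if f.start > qend]
    open_start = not up
    open_end = not down
    up_f = max(up, key=lambda f: f.end) if up else None
    down_f = min(down, key=lambda f: f.start) if down else None
    if inclusive_flanks:
        start = up_f.start if up_f else 1
        end = down_f.end if down_f else len(contig)
    else:
        start = up_f.end + 1 if up_f else 1
        end = down_f.start - 1 if down_f else len(contig)
    enclosed = [f for f in local if f.start >= start and f.end <= end]
    return GenomicIsland(
        genome_id=genome.genome_id,
        contig_id=cid,
        start=start,
        end=end,
        upstream_core=scg_membership.get(up_f.feature_id) if up_f else None,
        downstream_core=scg_membership.get(down_f.feature_id) if down_f else None,
        enclosed=sorted(enclosed, key=lambda f: f.start),
        query=(qstart, qend),
        open_start=open_start,
        open_end=open_end,
        sequence=contig.sequence[start - 1 : end],
    )


@dataclass
class IslandComparison:
    blocks: list[tuple[int, int, float]]  # (a_start0, length, identity%)
    total_shared: int
    mean_identity: Optional[float]  # length-weighted percent


def compare_islands(
    a: GenomicIsland,
    b: GenomicIsland,
    window: int = 1000,
    min_block: int = 1000,
    min_identity: float = 90.0,
) -> IslandComparison:
    """Shared-block report between two islands.

    ``a`` is chopped into windows, each mapped into ``b`` (both strands,
    infix alignment); consecutive windows above the identity floor chain
    into blocks, and blocks shorter than ``min_block`` are dropped.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("islands carry no sequence")
    targets = [b.sequence, reverse_complement(b.sequence)]
    hits: list[Optional[float]] = []
    offs = list(range(0, max(1, len(a.sequence) - window // 2), window))
    for off in offs:
        frag = a.sequence[off : off + window]
        if len(frag) < window // 2:
            hits.append(None)
            continue
        best = None
        for t in targets:
            r = edlib.align(frag, t, mode="HW", task="path")
            if r["editDistance"] < 0:
                continue
            match = cols = 0
            for num, op in re.findall(r"(\d+)([=XID])", r["cigar"] or ""):
                cols += int(num)
                if op == "=":
                    match += int(num)
            ident = 100.0 * match / cols if cols else 0.0
            if best is None or ident > best:
                best = ident
        hits.append(best if best is not None and best >= min_identity else None)
    blocks: list[tuple[int, int, float]] = []
    i = 0
    while i < len(offs):
        if hits[i] is None:
            i += 1
            continue
        j = i
        while j + 1 < len(offs) and hits[j + 1] is not None:
            j += 1
        start0 = offs[i]
        end0 = min(offs[j] + window, len(a.sequence))
        length = end0 - start0
        idents = [hits[k] for k in range(i, j + 1)]
        if length >= min_block:
            blocks.append((start0, length, float(sum(idents) / len(idents))))
        i = j + 1
    total = sum(l for _s, l, _i in blocks)
    mean_ident = (
        sum(l * ident for _s, l, ident in blocks) / total if total else None
    )
    return IslandComparison(blocks=blocks, total_shared=total, mean_identity=mean_ident)


DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "transposon_is": ["transposase", "insertion sequence", "IS"],
    "conjugative_phage": [
        "integrase",
        "recombinase",
        "conjugal",
        "conjugative",
        "relaxase",
        "phage",
        "terminase",
    ],
    "other_recombinase": ["resolvase", "invertase", "excisionase"],
}
KEYWORD_TABLE_VERSION = "1"

_IS_FAMILY = re.compile(r"\bIS\d+")


@dataclass
class MGETally:
    counts: dict[str, int]
    keyword_table_version: str = KEYWORD_TABLE_VERSION
    n_cds: int = 0


def _keyword_hit(product: str, keyword: str) -> bool:
    if keyword == "IS":
        return bool(_IS_FAMILY.search(product))
    return keyword.lower() in product.lower()


def mge_tally(
    island: GenomicIsland,
    keyword_table: Optional[dict[str, list[str]]] = None,
) -> MGETally:
    """Keyword-estimated MGE gene tally over the island's CDS products.

    Categories are tested in table order; the first matching category wins
    per feature.
    """
    table = keyword_table or DEFAULT_KEYWORDS
    counts = {cat: 0 for cat in table}
    n_cds = 0
    for f in island.enclosed:
        if f.kind != "CDS":
            continue
        n_cds += 1
        for cat, keywords in table.items():
            if any(_keyword_hit(f.product, kw) for kw in keywords):
                counts[cat] += 1
                break
    return MGETally(counts=counts, n_cds=n_cds)
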