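"""Pangenome simulator with known ground truth.

Generates small bacterial pangenomes — a species tree with clades, core genes
evolving under Jukes-Cantor, reductive-dehalogenase (rdhA) gene clusters whose
members fall into orthologue groups at controlled amino-acid identities, an
optional mobile genomic island inserted at a shared hotspot, and gene
loss/duplication/transfer events — so that every analysis stage downstream has
a recovery test with exact truth.

Nucleotide material (core genes, spacers) evolves along the tree with the
Jukes-Cantor per-branch transition probability, so realized divergence over a
path matches the JC expectation.  rdhA genes evolve at the amino-acid level
(with a separate, slower clock) on top of a fixed ancestral codon backbone, so
within-OG and between-OG protein identities are controlled directly; iron-
sulphur motif positions and the start/stop are protected from substitution.

All randomness flows from one integer seed; per-genome and per-gene streams
are derived by hashing names, so output is independent of iteration order.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from skbio import TreeNode

from .genome_io import (
    Contig,
    Feature,
    Genome,
    ProteinSeq,
    reverse_complement,
    translate,
    write_genome,
    write_protein_fasta,
)

__all__ = [
    "SimConfig",
    "IslandSpec",
    "TruthTables",
    "SimulatedPangenome",
    "mutate_to_identity",
    "random_genome",
    "simulate_pangenome",
    "emit_fixture",
    "FIXTURES",
]

_AAS = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
# sense codons of the bacterial code, fixed order for determinism
_SENSE = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]
from Bio.Data import CodonTable as _CT

_T11 = _CT.unambiguous_dna_by_id[11]
_AA2CODONS: dict[str, list[str]] = {}
for _codon, _aa in _T11.forward_table.items():
    _AA2CODONS.setdefault(_aa, []).append(_codon)
for _v in _AA2CODONS.values():
    _v.sort()


def _crc(name: str) -> int:
    return zlib.crc32(name.encode())


def _rng(seed: int, *keys: object) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF] + [_crc(str(k)) for k in keys])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class IslandSpec:
    donor: str
    recipients: list[str]
    n_cargo_genes: int = 15
    identity: float = 0.985  # donor vs recipient nucleotide identity
    anchor_gene: Optional[str] = None  # defaults to the designated hotspot core gene


@dataclass
class SimConfig:
    seed: int = 0
    species_tree: str = (
        "((A1:0.005,A2:0.005,A3:0.005)cladeA:0.04,"
        "(B1:0.005,B2:0.005,B3:0.005)cladeB:0.04,"
        "(C1:0.005,C2:0.005,C3:0.005)cladeC:0.04);"
    )
    n_core_genes: int = 50
    core_gene_codons: int = 300
    n_rdh_clusters: int = 2
    rdh_cluster_sizes: list[int] = field(default_factory=lambda: [6, 4])
    rdha_codons: int = 350
    # within-OG target identity (>= threshold) and between-OG identity band
    og_within_identity: float = 0.95
    og_between_identity: tuple[float, float] = (0.60, 0.85)
    rdh_aa_scale: float = 0.5  # aa substitutions/site per unit nt branch length
    intergenic_length: float = 200.0  # mean bp, geometric
    max_cluster_gap: int = 9000  # internal spacers capped below the 10 kb rule
    island_spec: Optional[IslandSpec] = None
    loss_events: list[tuple[str, str]] = field(default_factory=list)
    dup_events: list[tuple[str, str]] = field(default_factory=list)
    # (donor leaf, recipient leaf, rdh family id): recipient's copy is
    # re-derived from the donor leaf's sequence (horizontal transfer)
    transfer_events: list[tuple[str, str, str]] = field(default_factory=list)
    with_decoys: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "island_spec" in raw and raw["island_spec"] is not None:
            raw["island_spec"] = IslandSpec(**raw["island_spec"])
        if "loss_events" in raw:
            raw["loss_events"] = [tuple(e) for e in raw["loss_events"]]
        if "dup_events" in raw:
            raw["dup_events"] = [tuple(e) for e in raw["dup_events"]]
        if "transfer_events" in raw:
            raw["transfer_events"] = [tuple(e) for e in raw["transfer_events"]]
        if "og_between_identity" in raw:
            raw["og_between_identity"] = tuple(raw["og_between_identity"])
        return cls(**raw)


@dataclass
class TruthTables:
    true_clades: dict[str, str]
    true_ogs: dict[str, str]  # rdhA protein id -> planted OG family
    true_island: list[tuple[str, int, int, bool]]  # (genome, start, end, is_donor)
    true_events: list[dict]
    true_decoys: dict[str, str]  # protein id -> decoy kind
    island_identity: Optional[float] = None


@dataclass
class SimulatedPangenome:
    genomes: dict[str, Genome]
    features: dict[str, list[Feature]]
    proteins: dict[str, list[ProteinSeq]]
    truth: TruthTables
    config: SimConfig

    def all_proteins(self) -> list[ProteinSeq]:
        return [p for ps in self.proteins.values() for p in ps]


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def mutate_to_identity(
    seq: str,
    target_identity: float,
    seed: int,
    protected: Sequence[int] = (),
) -> str:
    """Substitute exactly ``len - round(len*target)`` uniformly chosen sites.

    DNA substitutions draw from the other 3 bases, protein from the other 19
    residues; no indels.  Realized identity is round(len*target)/len exactly.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    n = len(seq)
    n_sub = n - round(n * target_identity)
    if n_sub == 0:
        return seq
    rng = _rng(seed, "mutate", seq[:32], n)
    is_dna = set(seq.upper()) <= set("ACGTN")
    alphabet = _BASES if is_dna else _AAS
    eligible = np.array([i for i in range(n) if i not in set(protected)])
    if n_sub > len(eligible):
        raise ValueError("too many substitutions for the unprotected sites")
    sites = rng.choice(eligible, size=n_sub, replace=False)
    out = list(seq)
    for i in sites:
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def random_genome(seed: int, length: int = 60000) -> str:
    """Uniform random DNA, for identity-calibration experiments."""
    rng = _rng(seed, "random_genome", length)
    return "".join(rng.choice(list(_BASES), size=length))


def _random_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    """ATG-initiated, stop-free random codon body (terminal TAA added later)."""
    body = [str(_SENSE[i]) for i in rng.integers(0, len(_SENSE), size=n_codons - 1)]
    return ["ATG"] + body


def _jc_evolve(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    """One Jukes-Cantor step: per-site substitution prob 3/4*(1-e^(-4b/3))."""
    if branch_length <= 0:
        return seq
    p = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in hits:
        cur = chr(arr[i])
        if cur not in _BASES:
            continue
        choices = [b for b in _BASES if b != cur]
        arr[i] = ord(choices[rng.integers(3)])
    return arr.tobytes().decode()


def _codons_to_protein(codons: list[str]) -> str:
    return "".join(_T11.forward_table.get(c, "X") if c not in _STOPS else "*" for c in codons)


def _evolve_protein_codons(
    codons: list[str],
    branch_length: float,
    scale: float,
    protected: set[int],
    rng: np.random.Generator,
) -> list[str]:
    """Amino-acid level evolution on a codon backbone.

    Each unprotected codon substitutes its amino acid with probability
    ``branch_length * scale``; the codon is rewritten to a codon of the new
    residue, leaving untouched codons byte-identical to the ancestor.
    """
    p = min(1.0, branch_length * scale)
    if p <= 0:
        return list(codons)
    out = list(codons)
    hits = np.nonzero(rng.random(len(out)) < p)[0]
    for i in hits:
        if i in protected or i == 0:
            continue
        cur_aa = _T11.forward_table.get(out[i])
        if cur_aa is None:
            continue
        new_aa = _AAS[rng.integers(20)]
        while new_aa == cur_aa:
            new_aa = _AAS[rng.integers(20)]
        cods = _AA2CODONS[new_aa]
        out[i] = cods[rng.integers(len(cods))]
    return out


def _mutate_codons_to_identity(
    codons: list[str], target: float, protected: set[int], rng: np.random.Generator
) -> list[str]:
    """Exact-count amino-acid substitutions on a codon backbone."""
    n = len(codons)
    n_sub = n - round(n * target)
    eligible = [i for i in range(1, n) if i not in protected]
    sites = rng.choice(eligible, size=n_sub, replace=False) if n_sub else []
    out = list(codons)
    for i in sites:
        cur_aa = _T11.forward_table.get(out[i], "X")
        new_aa = _AAS[rng.integers(20)]
        while new_aa == cur_aa:
            new_aa = _AAS[rng.integers(20)]
        cods = _AA2CODONS[new_aa]
        out[i] = cods[rng.integers(len(cods))]
    return out


# ---------------------------------------------------------------------------
# ancestral layout
# ---------------------------------------------------------------------------

_MOTIF_OFFSETS = (0, 3, 7)  # C..C...C


def _rdha_family(rng: np.random.Generator, n_codons: int) -> tuple[list[str], set[int]]:
    """An ancestral rdhA codon backbone with two protected Fe-S motifs."""
    codons = _random_codons(rng, n_codons)
    protected: set[int] = {0}
    for base in (40, max(60, n_codons - 60)):
        for off in _MOTIF_OFFSETS:
            pos = base + off
            codons[pos] = "TGC"  # Cys
            protected.add(pos)
    return codons, protected


@dataclass
class _Segment:
    kind: str  # core | rdha | rdhb | spacer | decoy | island_slot
    name: str
    payload: Optional[object] = None  # ancestral sequence / codons
    product: str = ""
    strand: str = "+"
    protected: set = field(default_factory=set)


def _build_layout(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[_Segment], str]:
    """Ancestral gene order; returns segments and the hotspot anchor gene id."""
    segs: list[_Segment] = []
    spacer_count = 0

    def spacer(cap: Optional[int] = None) -> None:
        nonlocal spacer_count
        ln = 1 + int(rng.geometric(1.0 / cfg.intergenic_length))
        if cap is not None:
            ln = min(ln, cap)
        seq = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=ln)])
        segs.append(_Segment("spacer", f"sp{spacer_count:04d}", seq))
        spacer_count += 1

    core_ids = [f"core{i:04d}" for i in range(cfg.n_core_genes)]

    def core(gid: str) -> None:
        codons = _random_codons(rng, cfg.core_gene_codons)
        strand = "-" if _crc(gid) % 4 == 0 else "+"
        segs.append(
            _Segment("core", gid, "".join(codons) + "TAA", "hypothetical protein", strand)
        )
        spacer()

    # rdhA family backbones: one per cluster slot, diverged from a base
    sizes = list(cfg.rdh_cluster_sizes)[: cfg.n_rdh_clusters]
    base_codons, base_protected = _rdha_family(rng, cfg.rdha_codons)
    families: list[tuple[str, list[str], set[int]]] = []
    lo, hi = cfg.og_between_identity
    fam_idx = 0
    # every family diverges from a virtual ancestor (the ancestor itself is
    # not emitted), so planted OGs radiate as clean clades on a gene tree
    for ci, size in enumerate(sizes):
        for _ in range(size):
            fam = f"rdhA{fam_idx:03d}"
            t = float(rng.uniform(lo, hi))
            cod = _mutate_codons_to_identity(base_codons, t, base_protected, rng)
            families.append((fam, cod, set(base_protected)))
            fam_idx += 1

    def rdh_cluster(ci: int, members: list[tuple[str, list[str], set[int]]]) -> None:
        for j, (fam, cod, prot) in enumerate(members):
            if j > 0:
                spacer(cap=min(cfg.max_cluster_gap - 400, 2000))
            segs.append(
                _Segment(
                    "rdha",
                    fam,
                    cod,
                    "reductive dehalogenase alpha subunit",
                    "+",
                    prot,
                )
            )
            spacer(cap=300)
            bcod = _random_codons(rng, 80)
            segs.append(
                _Segment(
                    "rdhb",
                    fam + "B",
                    "".join(bcod) + "TAA",
                    "reductive dehalogenase membrane anchor rdhB",
                    "+",
                )
            )
        spacer()

    third = max(1, cfg.n_core_genes // 3)
    pos = 0
    for gid in core_ids[:third]:
        core(gid)
        pos += 1
    offset = 0
    rdh_members = []
    for size in sizes:
        rdh_members.append(families[offset : offset + size])
        offset += size
    if rdh_members:
        rdh_cluster(0, rdh_members[0])
    for gid in core_ids[third : 2 * third]:
        core(gid)
    anchor_gene = core_ids[2 * third - 1]
    segs.append(_Segment("island_slot", "island"))
    spacer()
    mid2 = 2 * third + max(1, third // 2)
    for gid in core_ids[2 * third : mid2]:
        core(gid)
    if len(rdh_members) > 1:
        rdh_cluster(1, rdh_members[1])
    for gid in core_ids[mid2:]:
        core(gid)

    if cfg.with_decoys:
        # planted negatives for the mining filters
        # decoys evolve on codon backbones with the motif sites protected so
        # each one keeps failing its intended filter in every genome
        short = _random_codons(rng, 150)
        prot_short = {0}
        for off in _MOTIF_OFFSETS:
            short[40 + off] = "TGC"
            prot_short.add(40 + off)
        segs.append(
            _Segment("decoy", "decoy_short", short,
                     "reductive dehalogenase alpha subunit", "+", prot_short)
        )
        spacer()
        # cysteine-free body -> motif-free by construction
        aas_no_c = _AAS.replace("C", "")
        nomotif = ["ATG"] + [
            _AA2CODONS[aas_no_c[i]][0] for i in rng.integers(0, 19, size=299)
        ]
        segs.append(
            _Segment("decoy", "decoy_nomotif", nomotif,
                     "reductive dehalogenase alpha subunit", "+", {0})
        )
        spacer()
        pseudo = _random_codons(rng, 320)
        prot_pseudo = {0}
        for off in _MOTIF_OFFSETS:
            pseudo[40 + off] = "TGC"
            prot_pseudo.add(40 + off)
        segs.append(
            _Segment("decoy", "decoy_pseudo", pseudo,
                     "reductive dehalogenase alpha subunit", "+", prot_pseudo)
        )
        spacer()
    return segs, anchor_gene


_ISLAND_PRODUCTS = [
    "IS256 family transposase",
    "IS4 family transposase",
    "transposase",
    "insertion sequence protein",
    "phage integrase",
    "site-specific recombinase",
    "conjugal transfer protein TraG",
    "relaxase MobA",
    "phage terminase large subunit",
    "hypothetical protein",
]


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def _clades_from_tree(tree: TreeNode) -> dict[str, str]:
    clades: dict[str, str] = {}
    i = 0
    for child in tree.children:
        leaves = [t.name for t in child.tips()] if not child.is_tip() else [child.name]
        i += 1
        label = child.name or f"clade{i}"
        if child.is_tip():
            label = child.name
        for leaf in leaves:
            clades[leaf] = label
    return clades


def _leaves_under(tree: TreeNode, lineage: str) -> list[str]:
    for node in tree.traverse(include_self=True):
        if node.name == lineage:
            if node.is_tip():
                return [node.name]
            return [t.name for t in node.tips()]
    raise ValueError(f"lineage {lineage!r} not in the species tree")


def simulate_pangenome(config: SimConfig) -> SimulatedPangenome:
    """Run the simulator; same config (same seed) gives byte-identical output."""
    cfg = config
    tree = TreeNode.read(io.StringIO(cfg.species_tree))
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 2:
        raise ValueError("species tree needs >=2 leaves")
    clades = _clades_from_tree(tree)

    root_rng = _rng(cfg.seed, "ancestor")
    segments, anchor_gene = _build_layout(cfg, root_rng)

    if cfg.island_spec is not None:
        carriers = {cfg.island_spec.donor, *cfg.island_spec.recipients}
        missing = carriers - set(leaves)
        if missing:
            raise ValueError(f"island carriers not in tree: {sorted(missing)}")

    # --- evolve ancestral states down the tree -----------------------------
    # state: segment name -> nt string (nt segments) or codon list (rdha)
    def node_stream(node_name: str) -> np.random.Generator:
        return _rng(cfg.seed, "branch", node_name)

    root_state: dict[str, object] = {}
    for seg in segments:
        if seg.kind == "island_slot":
            continue
        root_state[seg.name] = seg.payload

    tree.name = tree.name or "root"
    states: dict[str, dict[str, object]] = {tree.name: root_state}
    for node in tree.preorder(include_self=False):
        nname = node.name or f"node{id(node)}"
        node.name = nname
        parent_state = states[node.parent.name]
        rng = node_stream(nname)
        b = node.length or 0.0
        st: dict[str, object] = {}
        for seg in segments:
            if seg.kind == "island_slot":
                continue
            parent_val = parent_state[seg.name]
            if isinstance(parent_val, list):  # codon backbone: aa-level clock
                st[seg.name] = _evolve_protein_codons(
                    parent_val, b, cfg.rdh_aa_scale, seg.protected, rng
                )
            else:
                st[seg.name] = _jc_evolve(parent_val, b, rng)
        states[nname] = st

    # --- horizontal transfers (leaf-level) ---------------------------------
    events: list[dict] = []
    for donor, recipient, fam in cfg.transfer_events:
        if fam not in states[donor]:
            raise ValueError(f"transfer gene {fam!r} unknown")
        rng = _rng(cfg.seed, "transfer", donor, recipient, fam)
        donor_codons = states[donor][fam]
        seg = next(s for s in segments if s.name == fam)
        states[recipient][fam] = _mutate_codons_to_identity(
            list(donor_codons), 0.99, seg.protected, rng
        )
        events.append(
            {"type": "transfer", "donor": donor, "recipient": recipient, "gene": fam}
        )

    # --- island cargo -------------------------------------------------------
    island_payloads: dict[str, str] = {}
    island_gene_specs: list[tuple[str, int, str]] = []  # (id, n_codons, product)
    if cfg.island_spec is not None:
        isp = cfg.island_spec
        irng = _rng(cfg.seed, "island")
        parts: list[str] = []
        bounds: list[tuple[str, int, int, str]] = []
        cursor = 0
        for i in range(isp.n_cargo_genes):
            gid = f"isl{i:03d}"
            prod = _ISLAND_PRODUCTS[i % len(_ISLAND_PRODUCTS)]
            n_cod = 250 + int(irng.integers(0, 150))
            gene = "".join(_random_codons(irng, n_cod)) + "TAA"
            sp_len = 1 + int(irng.geometric(1.0 / cfg.intergenic_length))
            sp = "".join(np.array(list(_BASES))[irng.integers(0, 4, size=sp_len)])
            parts.append(gene)
            bounds.append((gid, cursor, cursor + len(gene), prod))
            cursor += len(gene)
            parts.append(sp)
            cursor += len(sp)
        donor_island = "".join(parts)
        island_payloads[isp.donor] = donor_island
        for r in isp.recipients:
            island_payloads[r] = mutate_to_identity(
                donor_island, isp.identity, _crc(f"{cfg.seed}:{r}") & 0x7FFFFFFF
            )
        island_gene_specs = [(g, s, e, p) for (g, s, e, p) in bounds]

    # --- loss / duplication maps --------------------------------------------
    lost: dict[str, set[str]] = {leaf: set() for leaf in leaves}
    for lineage, gene in cfg.loss_events:
        for leaf in _leaves_under(tree, lineage):
            lost[leaf].add(gene)
            events.append({"type": "loss", "lineage": lineage, "leaf": leaf, "gene": gene})
    dup: dict[str, set[str]] = {leaf: set() for leaf in leaves}
    for lineage, gene in cfg.dup_events:
        for leaf in _leaves_under(tree, lineage):
            dup[leaf].add(gene)
            events.append({"type": "dup", "lineage": lineage, "leaf": leaf, "gene": gene})

    # --- assemble leaf genomes ----------------------------------------------
    genomes: dict[str, Genome] = {}
    features: dict[str, list[Feature]] = {}
    proteins: dict[str, list[ProteinSeq]] = {}
    true_ogs: dict[str, str] = {}
    true_decoys: dict[str, str] = {}
    true_island: list[tuple[str, int, int, bool]] = []

    anchor_index = next(
        i for i, s in enumerate(segments) if s.kind == "core" and s.name == anchor_gene
    )

    for leaf in leaves:
        st = states[leaf]
        seq_parts: list[str] = []
        feats: list[Feature] = []
        pos = 0  # 0-based running length
        island_here = cfg.island_spec is not None and leaf in island_payloads
        island_span: Optional[tuple[int, int]] = None

        def add_gene(seg: _Segment, copy_suffix: str = "") -> None:
            nonlocal pos
            val = st[seg.name]
            nt = "".join(val) + "TAA" if isinstance(val, list) else val
            fid = f"{leaf}|{seg.name}{copy_suffix}"
            insert = nt if seg.strand == "+" else reverse_complement(nt)
            seq_parts.append(insert)
            feats.append(
                Feature(
                    feature_id=fid,
                    genome_id=leaf,
                    contig_id=f"{leaf}_c1",
                    start=pos + 1,
                    end=pos + len(nt),
                    strand=seg.strand,
                    kind="CDS",
                    product=seg.product,
                    is_pseudo=(seg.name == "decoy_pseudo"),
                )
            )
            if seg.kind == "rdha":
                true_ogs[fid] = seg.name
            if seg.kind == "decoy":
                true_decoys[fid] = seg.name
            pos += len(nt)

        for i, seg in enumerate(segments):
            if seg.kind == "island_slot":
                if island_here:
                    isl_seq = island_payloads[leaf]
                    isl_start0 = pos
                    # the truth span runs from just after the anchor gene to
                    # just before the next core gene (spacers included): this
                    # is exactly what flanking-core-gene delimitation defines
                    for gid, s0, e0, prod in island_gene_specs:
                        feats.append(
                            Feature(
                                feature_id=f"{leaf}|{gid}",
                                genome_id=leaf,
                                contig_id=f"{leaf}_c1",
                                start=pos + s0 + 1,
                                end=pos + e0,
                                strand="+",
                                kind="CDS",
                                product=prod,
                            )
                        )
                    seq_parts.append(isl_seq)
                    pos += len(isl_seq)
                    island_span = (isl_start0, pos)
                continue
            if seg.kind == "spacer":
                nt = st[seg.name]
                seq_parts.append(nt)
                pos += len(nt)
                continue
            if seg.name in lost[leaf]:
                continue
            add_gene(seg)
            if seg.name in dup[leaf]:
                # tandem duplication with a short spacer
                sp = "".join(
                    np.array(list(_BASES))[
                        _rng(cfg.seed, "dupspacer", leaf, seg.name).integers(0, 4, size=50)
                    ]
                )
                seq_parts.append(sp)
                pos += len(sp)
                add_gene(seg, copy_suffix="_dup")

        genome = Genome(
            genome_id=leaf,
            contigs=[Contig(contig_id=f"{leaf}_c1", sequence="".join(seq_parts))],
            clade_label=clades.get(leaf),
        )
        genomes[leaf] = genome
        features[leaf] = feats
        prots = []
        for f in feats:
            if f.kind == "CDS":
                p = translate(f, genome)
                p.partial = p.partial or f.is_partial
                prots.append(p)
        proteins[leaf] = prots
        if island_here and island_span is not None:
            # report 1-based inclusive bounds of the inter-core-gene span:
            # starts right after the anchor gene, ends right before the next
            # core gene (the spacer following the slot belongs to the island
            # span as delimited by inner edges of the flanking core genes)
            anchor_feat = next(f for f in feats if f.feature_id == f"{leaf}|{anchor_gene}")
            next_core = min(
                (f for f in feats if f.start > island_span[1] and "core" in f.feature_id),
                key=lambda f: f.start,
            )
            true_island.append(
                (leaf, anchor_feat.end + 1, next_core.start - 1,
                 leaf == cfg.island_spec.donor)
            )

    truth = TruthTables(
        true_clades=clades,
        true_ogs=true_ogs,
        true_island=true_island,
        true_events=events,
        true_decoys=true_decoys,
        island_identity=(cfg.island_spec.identity if cfg.island_spec else None),
    )
    return SimulatedPangenome(genomes, features, proteins, truth, cfg)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def _fixture_small(seed: int = 11) -> SimConfig:
    return SimConfig(
        seed=seed,
        species_tree="((A1:0.005,A2:0.005)cladeA:0.04,(B1:0.005,B2:0.005)cladeB:0.04);",
        n_core_genes=40,
        rdh_cluster_sizes=[4, 3],
    )


def _fixture_medium(seed: int = 12) -> SimConfig:
    # 8 planted OGs across 5 genomes = 40 RdhA total
    return SimConfig(
        seed=seed,
        species_tree=(
            "((A1:0.004,A2:0.004)cladeA:0.03,"
            "(B1:0.004,B2:0.004)cladeB:0.03,C1:0.034);"
        ),
        n_core_genes=45,
        rdh_cluster_sizes=[5, 3],
        og_between_identity=(0.60, 0.85),
    )


def _fixture_island(seed: int = 13) -> SimConfig:
    return SimConfig(
        seed=seed,
        species_tree=(
            "((A1:0.005,A2:0.005,A3:0.005)cladeA:0.04,"
            "(B1:0.005,B2:0.005,B3:0.005)cladeB:0.04);"
        ),
        n_core_genes=45,
        rdh_cluster_sizes=[4, 3],
        island_spec=IslandSpec(donor="B1", recipients=["A1"], n_cargo_genes=17,
                               identity=0.985),
    )


def _fixture_hgt(seed: int = 14) -> SimConfig:
    return SimConfig(
        seed=seed,
        species_tree=(
            "((A1:0.005,A2:0.005,A3:0.005)cladeA:0.04,"
            "(B1:0.005,B2:0.005,B3:0.005)cladeB:0.04,"
            "(C1:0.005,C2:0.005,C3:0.005)cladeC:0.04);"
        ),
        n_core_genes=45,
        rdh_cluster_sizes=[5, 3],
        transfer_events=[("B1", "A1", "rdhA002")],
    )


FIXTURES = {
    "small": _fixture_small,
    "medium": _fixture_medium,
    "island": _fixture_island,
    "hgt-og": _fixture_hgt,
}


def emit_fixture(name: str, out_dir: str | Path, seed: Optional[int] = None) -> Path:
    """Write a named fixture (FASTA + GFF3 + protein FASTA + truth TSVs)."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; options: {sorted(FIXTURES)}")
    cfg = FIXTURES[name]() if seed is None else FIXTURES[name](seed)
    sim = simulate_pangenome(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gid, genome in sorted(sim.genomes.items()):
        write_genome(genome, sim.features[gid], out / f"{gid}.fasta", out / f"{gid}.gff3")
        write_protein_fasta(sim.proteins[gid], out / f"{gid}.faa")
    with open(out / "truth_clades.tsv", "w") as fh:
        fh.write("genome\tclade\n")
        for g, c in sorted(sim.truth.true_clades.items()):
            fh.write(f"{g}\t{c}\n")
    with open(out / "truth_ogs.tsv", "w") as fh:
        fh.write("protein\tog\n")
        for p, og in sorted(sim.truth.true_ogs.items()):
            fh.write(f"{p}\t{og}\n")
    with open(out / "truth_island.tsv", "w") as fh:
        fh.write("genome\tstart\tend\tis_donor\n")
        for g, s, e, d in sim.truth.true_island:
            fh.write(f"{g}\t{s}\t{e}\t{int(d)}\n")
    with open(out / "truth_events.tsv", "w") as fh:
        fh.write("record\n")
        for ev in sim.truth.true_events:
            fh.write(f"{ev}\n")
    return out
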