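"""Reductive-dehalogenase (RdhA) candidate mining.

RdhA catalytic subunits carry one or more twin iron-sulphur cluster binding
motifs (CXXCXXXC).  Candidates are screened by length (>=200 aa), presence of
at least one motif, pseudogene and truncation flags from the annotation, and
optionally by best identity against a reference RdhA panel (a stand-in for a
profile-domain search, with the panel supplied by the user).

Rejection reasons are assigned in a fixed priority order — too_short,
no_motif, pseudogene, truncated, no_domain — so tallies are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .genome_io import Feature, ProteinSeq

__all__ = [
    "MotifSpec",
    "RdhACandidate",
    "count_motifs",
    "screen_candidates",
    "select_rdha_features",
]

_AA_OK = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class MotifSpec:
    """C-x(2)-C-x(3)-C, the 8-residue iron-sulphur cluster binding motif."""

    offsets: tuple[int, ...] = (0, 3, 7)
    length: int = 8
    residue: str = "C"


DEFAULT_MOTIF = MotifSpec()


@dataclass
class RdhACandidate:
    protein: ProteinSeq
    genome_id: str
    length_aa: int
    motif_count: int
    domain_score: Optional[float]
    is_pseudo: bool
    verdict: str  # retained | rejected
    rejection_reason: Optional[str] = None


def count_motifs(protein: ProteinSeq | str, spec: MotifSpec = DEFAULT_MOTIF) -> int:
    """Number of motif start positions; overlapping occurrences all count."""
    seq = protein.residues if isinstance(protein, ProteinSeq) else protein
    n = len(seq)
    count = 0
    for i in range(n - spec.length + 1):
        if all(seq[i + off] == spec.residue for off in spec.offsets):
            count += 1
    return count


def _best_panel_identity(protein: ProteinSeq, panel: list[ProteinSeq]) -> float:
    # deferred import: og_classification owns the alignment parameters
    from .og_classification import pairwise_identity

    best = 0.0
    for ref in panel:
        ident = pairwise_identity(protein, ref) / 100.0
        best = max(best, ident)
    return best


def screen_candidates(
    proteins: Iterable[ProteinSeq],
    features: Iterable[Feature],
    reference_panel: Optional[list[ProteinSeq]] = None,
    min_len: int = 200,
    min_domain_identity: float = 0.25,
    motif: MotifSpec = DEFAULT_MOTIF,
) -> list[RdhACandidate]:
    """Apply the RdhA retention filters.

    A candidate is retained iff length >= ``min_len`` AND it carries at least
    one motif AND it is neither a pseudogene nor truncated AND (no panel was
    given OR its best panel identity >= ``min_domain_identity``).  The first
    failing check, in that order, becomes the rejection reason.
    """
    feat_by_id = {f.feature_id: f for f in features}
    out: list[RdhACandidate] = []
    for prot in proteins:
        bad = set(prot.residues) - _AA_OK
        if bad:
            raise ValueError(
                f"protein {prot.protein_id!r}: residues outside the alphabet {sorted(bad)}"
            )
        feat = feat_by_id.get(prot.source_feature or prot.protein_id)
        is_pseudo = bool(feat.is_pseudo) if feat else False
        is_partial = bool(feat.is_partial if feat else False) or prot.partial
        genome_id = feat.genome_id if feat else ""
        length = len(prot.residues.rstrip("*"))
        motifs = count_motifs(prot, motif)
        score: Optional[float] = None

        reason: Optional[str] = None
        if length < min_len:
            reason = "too_short"
        elif motifs < 1:
            reason = "no_motif"
        elif is_pseudo:
            reason = "pseudogene"
        elif is_partial:
            reason = "truncated"
        elif reference_panel is not None:
            score = _best_panel_identity(prot, reference_panel)
            if score < min_domain_identity:
                reason = "no_domain"

        out.append(
            RdhACandidate(
                protein=prot,
                genome_id=genome_id,
                length_aa=length,
                motif_count=motifs,
                domain_score=score,
                is_pseudo=is_pseudo,
                verdict="rejected" if reason else "retained",
                rejection_reason=reason,
            )
        )
    return out


def select_rdha_features(
    features: Iterable[Feature], keyword: str = "dehalogenase alpha"
) -> list[Feature]:
    """Annotation-based extraction of putative rdhA genes (product text)."""
    kw = keyword.lower()
    return [f for f in features if f.kind == "CDS" and kw in f.product.lower()]
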