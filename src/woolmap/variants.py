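"""Coisogenic deletion detection and gene-model overlap annotation.

Two coisogenic strains differ, by design, at a single mutated locus, so the
comparator assumes the mutant sequence is the wild type with exactly one
contiguous run of bases removed.  Under that contract an alignment-free
longest-common-prefix / longest-common-suffix comparison finds every
equivalent placement of the deletion; the call is normalized by left
alignment, the standard indel convention in repetitive context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from woolmap.errors import NotASimpleDeletionError, ValidationError
from woolmap.genes import GeneModel


@dataclass(frozen=True)
class DeletionCall:
    """A left-aligned contiguous deletion.

    ``ambiguity_span`` is the number of equivalent right-shifted placements
    that were absorbed by left alignment (0 when the placement is unique).
    """

    chrom: str
    start_bp: int
    length_bp: int
    ambiguity_span: int = 0

    def __post_init__(self):
        if self.start_bp < 0 or self.length_bp <= 0 or self.ambiguity_span < 0:
            raise ValidationError("invalid deletion call")

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.length_bp


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def find_deletion(wild: str, mutant: str, chrom: str = "chr") -> DeletionCall:
    """Call the single contiguous deletion separating two coisogenic sequences.

    Valid placements of the deletion are the starts ``s`` with
    ``len(mutant) - S <= s <= min(P, len(mutant))`` where P and S are the
    longest common prefix and suffix; the left-most placement is returned.
    Any other difference between the sequences raises
    :class:`NotASimpleDeletionError` naming the first conflicting position.
    """
    if not wild or not mutant:
        raise ValidationError("sequences must be non-empty")
    wild = wild.upper()
    mutant = mutant.upper()
    if len(mutant) >= len(wild):
        if wild == mutant:
            raise ValidationError("sequences are identical: no deletion to call")
        if len(mutant) == len(wild):
            raise NotASimpleDeletionError(
                f"equal-length sequences with a mismatch at position "
                f"{_common_prefix(wild, mutant)}: not a simple deletion",
                conflict_pos=_common_prefix(wild, mutant),
            )
        raise ValidationError("mutant sequence is longer than wild type")

    length = len(wild) - len(mutant)
    p = _common_prefix(wild, mutant)
    s = _common_suffix(wild, mutant)
    lo = max(0, len(mutant) - s)
    hi = min(p, len(mutant))
    if lo > hi:
        raise NotASimpleDeletionError(
            f"sequences differ by more than one contiguous deletion; first "
            f"conflict at position {p}",
            conflict_pos=p,
        )
    return DeletionCall(chrom=chrom, start_bp=lo, length_bp=length, ambiguity_span=hi - lo)


# ---------------------------------------------------------------------------
# overlap annotation


@dataclass
class OverlapAnnotation:
    """Per-gene classification of a deletion against gene models.

    ``features_hit`` maps gene name to (feature type, transcription-order
    ordinal, fraction of the feature removed); ``splice_sites_lost`` lists
    (gene, exon ordinal, "acceptor"/"donor").  Splice sites follow the
    3-base definition below; losing any base of a site counts as loss.
    """

    classification: dict[str, str] = field(default_factory=dict)
    features_hit: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    splice_sites_lost: list[tuple[str, int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def lost_sites_for(self, gene: str) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, ordinal, site in self.splice_sites_lost:
            if g == gene:
                out.setdefault(ordinal, set()).add(site)
        return out

    def to_dict(self) -> dict:
        return {
            "classification": dict(self.classification),
            "features_hit": {
                g: [list(t) for t in v] for g, v in self.features_hit.items()
            },
            "splice_sites_lost": [list(t) for t in self.splice_sites_lost],
            "warnings": list(self.warnings),
        }


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _acceptor_sites(model: GeneModel) -> dict[int, tuple[int, int]]:
    """Genomic [start, end) of each exon's acceptor: last 2 intronic nt + first exonic nt."""
    sites = {}
    for e in model.exons[1:]:  # first exon has no acceptor
        if model.strand == "+":
            sites[e.ordinal] = (e.start - 2, e.start + 1)
        else:
            sites[e.ordinal] = (e.end - 1, e.end + 2)
    return sites


def _donor_sites(model: GeneModel) -> dict[int, tuple[int, int]]:
    """Genomic [start, end) of each exon's donor: last exonic nt + first 2 intronic nt."""
    sites = {}
    for e in model.exons[:-1]:  # last exon has no donor
        if model.strand == "+":
            sites[e.ordinal] = (e.end - 1, e.end + 2)
        else:
            sites[e.ordinal] = (e.start - 2, e.start + 1)
    return sites


def annotate_deletion(call: DeletionCall, models: list[GeneModel]) -> OverlapAnnotation:
    """Classify a deletion's overlap with each gene model.

    Genes whose genomic span does not intersect the deletion are omitted;
    an empty annotation carries a warning.  Classification is strand-aware:
    ordinals and acceptor/donor identity are in transcription orientation.
    """
    ann = OverlapAnnotation()
    d0, d1 = call.start_bp, call.end_bp
    for m in models:
        g0, g1 = m.span
        if _overlap(d0, d1, g0, g1) == 0:
            continue
        hits: list[tuple[str, int, float]] = []
        exonic = False
        for e in m.exons:
            ov = _overlap(d0, d1, e.start, e.end)
            if ov:
                exonic = True
                hits.append(("exon", e.ordinal, ov / e.length))
        for ordinal, i0, i1 in m.introns():
            ov = _overlap(d0, d1, i0, i1)
            if ov:
                hits.append(("intron", ordinal, ov / (i1 - i0)))
        ann.classification[m.name] = (
            "removes_exonic_sequence" if exonic else "intronic_only"
        )
        ann.features_hit[m.name] = hits
        for ordinal, (s0, s1) in _acceptor_sites(m).items():
            if _overlap(d0, d1, s0, s1):
                ann.splice_sites_lost.append((m.name, ordinal, "acceptor"))
        for ordinal, (s0, s1) in _donor_sites(m).items():
            if _overlap(d0, d1, s0, s1):
                ann.splice_sites_lost.append((m.name, ordinal, "donor"))
    if not ann.classification:
        ann.warnings.append("deletion does not overlap any gene model")
    return ann
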