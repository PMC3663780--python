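"""Gene models on a genomic sequence and transcript splicing.

Coordinates are 0-based half-open on the genome internally; exon ordinals
are 1-based in transcription order (so for a minus-strand gene, exon 1 is
the genomically rightmost).  CDS coordinates are transcript offsets,
0-based half-open on the spliced mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from woolmap.errors import ValidationError


@dataclass(frozen=True)
class Exon:
    """One exon: genomic [start, end) plus its transcription-order ordinal."""

    ordinal: int
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(f"exon {self.ordinal}: bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Exon structure and CDS of one gene.

    ``exons`` are in transcription order.  A model produced by the mutant
    predictor keeps the wild-type ordinals of its surviving exons and sets
    ``mutant_of`` to the source gene name; only wild-type models must have a
    CDS length divisible by 3.
    """

    name: str
    chrom: str
    strand: str
    exons: list[Exon]
    cds_start: int
    cds_end: int
    domains: list[tuple[str, int, int]] = field(default_factory=list)
    mutant_of: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-': {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.name}: no exons")
        ordinals = [e.ordinal for e in self.exons]
        if len(set(ordinals)) != len(ordinals):
            raise ValidationError(f"gene {self.name}: duplicate exon ordinals")
        if ordinals != sorted(ordinals):
            raise ValidationError(f"gene {self.name}: exons not in transcription order")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValidationError(f"gene {self.name}: overlapping exons")
        if self.strand == "+":
            if [e.start for e in self.exons] != [e.start for e in genomic]:
                raise ValidationError(f"gene {self.name}: + strand exons out of order")
        else:
            if [e.start for e in self.exons] != [e.start for e in genomic[::-1]]:
                raise ValidationError(f"gene {self.name}: - strand exons out of order")
        tlen = self.transcript_length
        if not (0 <= self.cds_start < self.cds_end <= tlen):
            raise ValidationError(
                f"gene {self.name}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"transcript of length {tlen}"
            )
        if self.mutant_of is None and (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(
                f"gene {self.name}: wild-type CDS length not divisible by 3"
            )
        for name, aa_start, aa_end in self.domains:
            if not (1 <= aa_start <= aa_end):
                raise ValidationError(f"domain {name}: bad aa span {aa_start}-{aa_end}")

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) footprint of the gene."""
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def exon(self, ordinal: int) -> Exon:
        for e in self.exons:
            if e.ordinal == ordinal:
                return e
        raise KeyError(f"gene {self.name}: no exon {ordinal}")

    def exon_transcript_offsets(self) -> dict[int, int]:
        """Transcript offset of each exon's first (transcribed) base."""
        offsets = {}
        pos = 0
        for e in self.exons:
            offsets[e.ordinal] = pos
            pos += e.length
        return offsets

    def introns(self) -> list[tuple[int, int, int]]:
        """Introns as (ordinal, genomic start, genomic end) in transcription order.

        Intron ordinal k lies between exons k and k+1 (transcription order).
        """
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a.ordinal, a.end, b.start))
            else:
                out.append((a.ordinal, b.end, a.start))
        return out


@dataclass(frozen=True)
class PrimerPair:
    """Primer binding sites in transcript-strand exon coordinates.

    Each site is (exon ordinal, offset of the site's 5'-most transcript base
    within that exon, site length).  The forward site must lie upstream of
    the reverse site on the spliced transcript.
    """

    forward: tuple[int, int, int]
    reverse: tuple[int, int, int]
    name: str = ""

    def __post_init__(self):
        for label, (_, off, length) in (("forward", self.forward), ("reverse", self.reverse)):
            if off < 0 or length <= 0:
                raise ValidationError(f"{label} primer: bad offset/length ({off}, {length})")


def splice(model: GeneModel, genome: str) -> str:
    """Return the spliced transcript of ``model`` on ``genome``.

    Exon sequences are concatenated in transcription order; minus-strand
    genes are reverse-complemented, so the result always reads 5'->3' on the
    mRNA.
    """
    n = len(genome)
    parts = []
    for e in model.exons:
        if e.end > n:
            raise ValidationError(
                f"gene {model.name}: exon {e.ordinal} [{e.start}, {e.end}) exceeds "
                f"genome length {n}"
            )
        chunk = genome[e.start : e.end]
        if model.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        parts.append(chunk)
    return "".join(parts)
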