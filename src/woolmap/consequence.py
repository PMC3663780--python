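"""Mutant transcript prediction, RT-PCR amplicons, translation and truncation.

The skipping rule is purely structural: an exon whose acceptor or donor
splice site is (even partially) removed by the deletion is dropped from the
mutant transcript, joining its neighbours directly; an exon that loses
internal bases but keeps both sites keeps its remaining sequence; a
deletion strictly internal to an intron leaves splicing untouched.  No
splice-strength or branch-point modelling is attempted — the biological
inference this package reproduces rests on acceptor removal alone, and
donor loss is handled by the symmetric choice.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from woolmap.errors import ValidationError
from woolmap.genes import Exon, GeneModel, PrimerPair, splice
from woolmap.variants import DeletionCall, OverlapAnnotation, annotate_deletion

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ProteinComparison:
    """Common-prefix comparison of wild-type and mutant proteins."""

    wt_len: int
    mut_len: int
    last_identical_residue: int
    novel_residues: int
    frameshift_after_codon: int | None  # None = no frameshift signature

    @property
    def frameshift(self) -> str:
        if self.frameshift_after_codon is None:
            return "none"
        return f"after_codon_{self.frameshift_after_codon}"


@dataclass
class ConsequenceReport:
    """Full consequence summary for one gene and one deletion."""

    gene: str
    skipped_exons: list[int]
    wt_amplicon_bp: int | None
    mut_amplicon_bp: int | None
    frameshift: str
    last_identical_residue: int
    novel_residues: int
    wt_protein_aa: int
    mut_protein_aa: int
    truncated_domains: list[tuple[str, float]]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "skipped_exons": list(self.skipped_exons),
            "wt_amplicon_bp": self.wt_amplicon_bp,
            "mut_amplicon_bp": self.mut_amplicon_bp,
            "frameshift": self.frameshift,
            "last_identical_residue": self.last_identical_residue,
            "novel_residues": self.novel_residues,
            "wt_protein_aa": self.wt_protein_aa,
            "mut_protein_aa": self.mut_protein_aa,
            "truncated_domains": [list(t) for t in self.truncated_domains],
            "warnings": list(self.warnings),
        }


def _lift(pos: int, del_start: int, del_len: int) -> int:
    """Map a wild-type genomic coordinate onto the deleted genome."""
    return pos - max(0, min(del_len, pos - del_start))


def _exon_should_drop(lost_sites: set[str]) -> bool:
    """One rule function isolates the skipping decision: any lost splice
    site (acceptor or donor, symmetrically) drops the exon."""
    return bool(lost_sites)


def predict_mutant_model(
    model: GeneModel, call: DeletionCall, annotation: OverlapAnnotation | None = None
) -> GeneModel:
    """Predict the mutant gene model after a genomic deletion.

    Exons with a lost splice site are skipped; partially deleted exons with
    intact sites keep their remainder; intron-internal deletions leave the
    exon set unchanged.  All coordinates are lifted onto the deleted genome.
    Removing the CDS start codon is outside the skipping rule's domain and
    raises a "start lost" error.
    """
    if annotation is None:
        annotation = annotate_deletion(call, [model])
    lost = annotation.lost_sites_for(model.name)
    d0, d1 = call.start_bp, call.end_bp

    # genomic footprint of the CDS start codon (first 3 coding transcript bases)
    start_codon_genomic = _transcript_to_genomic(model)[model.cds_start : model.cds_start + 3]
    first_exon = model.exons[0]

    new_exons: list[Exon] = []
    for e in model.exons:
        if _exon_should_drop(lost.get(e.ordinal, set())):
            if any(e.start <= g < e.end for g in start_codon_genomic):
                raise ValidationError(
                    f"gene {model.name}: deletion removes the CDS start codon "
                    "(start lost)"
                )
            continue
        a, b = _lift(e.start, d0, call.length_bp), _lift(e.end, d0, call.length_bp)
        if b - a == 0:
            # whole exon deleted without touching either splice-site window is
            # geometrically impossible for exons >= 1 bp, but guard anyway
            continue
        if (b - a) < e.length and any(d0 <= g < d1 for g in start_codon_genomic):
            raise ValidationError(
                f"gene {model.name}: deletion removes the CDS start codon (start lost)"
            )
        new_exons.append(Exon(e.ordinal, a, b))
    if not new_exons:
        raise ValidationError(f"gene {model.name}: no exons survive the deletion")
    if first_exon.ordinal not in {e.ordinal for e in new_exons} or any(
        d0 <= g < d1 for g in start_codon_genomic
    ):
        raise ValidationError(
            f"gene {model.name}: deletion removes the CDS start codon (start lost)"
        )

    # transcript offset of the original start codon in the mutant transcript
    start_g_mut = _lift(start_codon_genomic[0], d0, call.length_bp)
    pos = 0
    new_cds_start = None
    for e in new_exons:
        if model.strand == "+":
            if e.start <= start_g_mut < e.end:
                new_cds_start = pos + (start_g_mut - e.start)
        else:
            if e.start <= start_g_mut < e.end:
                new_cds_start = pos + (e.end - 1 - start_g_mut)
        pos += e.length
    if new_cds_start is None:
        raise ValidationError(
            f"gene {model.name}: deletion removes the CDS start codon (start lost)"
        )

    return GeneModel(
        name=f"{model.name}_mut",
        chrom=model.chrom,
        strand=model.strand,
        exons=new_exons,
        cds_start=new_cds_start,
        cds_end=pos,  # open-ended: translation runs to the first stop
        domains=list(model.domains),
        mutant_of=model.name,
    )


def _transcript_to_genomic(model: GeneModel) -> list[int]:
    """Genomic index of each transcript base, in transcript order."""
    idx: list[int] = []
    for e in model.exons:
        if model.strand == "+":
            idx.extend(range(e.start, e.end))
        else:
            idx.extend(range(e.end - 1, e.start - 1, -1))
    return idx


def predict_amplicon(model: GeneModel, primers: PrimerPair) -> int:
    """Spliced RT-PCR product length for a primer pair on a gene model.

    Length runs from the first base of the forward site to the last base of
    the reverse site, inclusive — the size a band would show on a gel.
    Raises if either primer's exon was skipped ("primer site lost").
    """
    offsets = model.exon_transcript_offsets()
    sites = {}
    for label, (ordinal, off, length) in (
        ("forward", primers.forward),
        ("reverse", primers.reverse),
    ):
        if ordinal not in offsets:
            raise ValidationError(
                f"{label} primer site lost: exon {ordinal} absent from model "
                f"{model.name}"
            )
        exon = model.exon(ordinal)
        if off + length > exon.length:
            raise ValidationError(
                f"{label} primer site exceeds exon {ordinal} "
                f"({off}+{length} > {exon.length})"
            )
        sites[label] = offsets[ordinal] + off
    f_start = sites["forward"]
    r_last = sites["reverse"] + primers.reverse[2] - 1
    if r_last <= f_start:
        raise ValidationError("reverse primer site lies upstream of the forward site")
    return r_last - f_start + 1


def translate_cds(transcript: str, cds_start: int) -> str:
    """Translate from ``cds_start`` to the first stop (standard nuclear code).

    The stop residue is not included.  If the transcript ends before any
    in-frame stop, a "no in-frame stop" warning is emitted and the full
    translation is returned.
    """
    if cds_start < 0 or len(transcript) < cds_start + 3:
        raise ValidationError(
            f"transcript too short to translate from offset {cds_start}"
        )
    coding = transcript[cds_start:].upper()
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop = aa.find("*")
    if stop == -1:
        _warnings.warn("no in-frame stop codon before transcript end", UserWarning)
        return aa
    return aa[:stop]


def compare_proteins(wt: str, mut: str) -> ProteinComparison:
    """Common-prefix comparison: divergence point, novel residues, frameshift.

    A frameshift signature is reported when the mutant diverges before its
    own end (novel residues follow the divergence point); a pure truncation
    (mutant is a prefix of wild type) is not a frameshift.
    """
    n = min(len(wt), len(mut))
    prefix = n
    for i in range(n):
        if wt[i] != mut[i]:
            prefix = i
            break
    novel = len(mut) - prefix
    shift = prefix if novel > 0 else None
    return ProteinComparison(
        wt_len=len(wt),
        mut_len=len(mut),
        last_identical_residue=prefix,
        novel_residues=novel,
        frameshift_after_codon=shift,
    )


def domain_overlap(
    comparison: ProteinComparison, domains: list[tuple[str, int, int]]
) -> list[tuple[str, float]]:
    """Fraction of each protein domain retained identically in the mutant.

    Domain spans are 1-based inclusive amino-acid coordinates on the
    wild-type protein.  Retention is computed against the common prefix;
    domains with retention < 1 are listed as truncated.
    """
    prefix = comparison.last_identical_residue
    truncated = []
    for name, aa_start, aa_end in domains:
        span = aa_end - aa_start + 1
        retained = max(0, min(aa_end, prefix) - aa_start + 1)
        fraction = retained / span
        if fraction < 1.0:
            truncated.append((name, fraction))
    return truncated


def _removed_coding_bases(
    model: GeneModel, mut_model: GeneModel, call: DeletionCall
) -> int:
    """Count wild-type coding bases absent from the mutant transcript."""
    retained = {e.ordinal for e in mut_model.exons}
    d0, d1 = call.start_bp, call.end_bp
    exon_of = {}
    for e in model.exons:
        for g in range(e.start, e.end):
            exon_of[g] = e.ordinal
    coding_g = _transcript_to_genomic(model)[model.cds_start : model.cds_end]
    removed = 0
    for g in coding_g:
        if exon_of[g] not in retained or d0 <= g < d1:
            removed += 1
    return removed


def analyze_consequence(
    genome: str,
    model: GeneModel,
    call: DeletionCall,
    primers: PrimerPair | None = None,
    annotation: OverlapAnnotation | None = None,
) -> ConsequenceReport:
    """Run the full consequence pipeline for one gene.

    Splices the wild-type transcript, predicts the mutant model on the
    deleted genome, recomputes both amplicons, translates both CDSs and
    summarizes frameshift, truncation and domain loss.
    """
    if annotation is None:
        annotation = annotate_deletion(call, [model])
    report_warnings: list[str] = []

    wt_tx = splice(model, genome)
    mut_genome = genome[: call.start_bp] + genome[call.end_bp :]
    mut_model = predict_mutant_model(model, call, annotation)
    mut_tx = splice(mut_model, mut_genome)

    skipped = sorted(
        {e.ordinal for e in model.exons} - {e.ordinal for e in mut_model.exons}
    )

    wt_amp = mut_amp = None
    if primers is not None:
        wt_amp = predict_amplicon(model, primers)
        try:
            mut_amp = predict_amplicon(mut_model, primers)
        except ValidationError as exc:
            report_warnings.append(str(exc))

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        wt_prot = translate_cds(wt_tx, model.cds_start)
        mut_prot = translate_cds(mut_tx, mut_model.cds_start)
    report_warnings.extend(str(w.message) for w in caught)

    cmp = compare_proteins(wt_prot, mut_prot)
    truncated = domain_overlap(cmp, model.domains)

    # the frame rule: a frameshift occurs iff the count of removed coding
    # nucleotides (skipped or directly deleted) is not a multiple of 3 —
    # an in-frame skip diverges in sequence but keeps the reading frame
    removed_coding = _removed_coding_bases(model, mut_model, call)
    if removed_coding % 3 == 0:
        frameshift = "none"
    else:
        frameshift = f"after_codon_{cmp.last_identical_residue}"

    return ConsequenceReport(
        gene=model.name,
        skipped_exons=skipped,
        wt_amplicon_bp=wt_amp,
        mut_amplicon_bp=mut_amp,
        frameshift=frameshift,
        last_identical_residue=cmp.last_identical_residue,
        novel_residues=cmp.novel_residues,
        wt_protein_aa=len(wt_prot),
        mut_protein_aa=len(mut_prot),
        truncated_domains=truncated,
        warnings=report_warnings,
    )
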