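"""Synthetic genomic/genetic fixtures with the properties the analysis assumes.

Two kinds of fixture are produced here:

* locus fixtures — a random-background genomic sequence carrying two
  (possibly overlapping) engineered genes, a known injected deletion, and
  primer sets, emitted as FASTA + GFF3 + TSV/JSON so every downstream stage
  can be exercised without any download; and

* mapping fixtures — a deterministic replica of the published backcross
  panel (1,679 N2 progeny, six microsatellites, 11 proximal and 19 distal
  trait-flanking recombinants) plus the SNP typing of its 30 interval
  recombinants, and the annotated interval gene table used for triage.

The locus generator engineers only what the downstream contracts require:
canonical GT..AG splice sites, an open reading frame with a single terminal
stop, optionally a controlled out-of-frame stop so that skipping one exon
yields a chosen number of novel residues, and deletion boundaries free of
left/right-shift ambiguity.  Everything else is uniform random background,
so fixtures share none of the repeat structure, codon bias or GC profile of
real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from woolmap import io as wio
from woolmap.consequence import STOP_CODONS, translate_cds
from woolmap.errors import ValidationError
from woolmap.genes import Exon, GeneModel, PrimerPair, splice
from woolmap.genetics import BackcrossPanel, GeneticMap, Marker, Progeny, TraitLocus
from woolmap.triage import AnnotatedGene
from woolmap.variants import DeletionCall, annotate_deletion

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def apply_deletion(sequence: str, start: int, length: int) -> str:
    """Remove ``[start, start + length)`` from a sequence (0-based)."""
    if start < 0 or length < 0 or start + length > len(sequence):
        raise ValidationError(
            f"deletion [{start}, {start + length}) outside sequence of length "
            f"{len(sequence)}"
        )
    return sequence[:start] + sequence[start + length :]


# ---------------------------------------------------------------------------
# locus fixture specification


@dataclass
class GeneSpec:
    """Structural recipe for one gene: exon/intron lengths in transcription order.

    ``offset_bp`` is the genomic start (leftmost coordinate) of the gene's
    footprint regardless of strand.  CDS start/end are transcript
    coordinates, 0-based half-open.
    """

    name: str
    strand: str
    offset_bp: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    cds_start: int
    cds_end: int
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValidationError(
                f"gene {self.name}: need one fewer intron than exons"
            )
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValidationError(f"gene {self.name}: non-positive feature length")
        total = sum(self.exon_lengths)
        if not (0 <= self.cds_start < self.cds_end <= total):
            raise ValidationError(f"gene {self.name}: CDS outside transcript")

    @property
    def span_bp(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def exons(self) -> list[Exon]:
        """Genomic exons in transcription order."""
        out = []
        if self.strand == "+":
            cursor = self.offset_bp
            for i, el in enumerate(self.exon_lengths):
                out.append(Exon(i + 1, cursor, cursor + el))
                cursor += el
                if i < len(self.intron_lengths):
                    cursor += self.intron_lengths[i]
        else:
            cursor = self.offset_bp + self.span_bp
            for i, el in enumerate(self.exon_lengths):
                out.append(Exon(i + 1, cursor - el, cursor))
                cursor -= el
                if i < len(self.intron_lengths):
                    cursor -= self.intron_lengths[i]
        return out

    def model(self, chrom: str) -> GeneModel:
        return GeneModel(
            name=self.name, chrom=chrom, strand=self.strand, exons=self.exons(),
            cds_start=self.cds_start, cds_end=self.cds_end,
            domains=list(self.domains),
        )


@dataclass
class LocusFixtureSpec:
    """Recipe for a two-gene locus fixture with an injected deletion.

    ``frameshift_stop`` = (gene, skipped exon ordinal, novel aa count)
    engineers the out-of-frame reading entered when that exon is skipped to
    meet its first stop codon after exactly that many novel residues.
    ``anchor_deletion`` pins the deletion boundaries so the injected
    placement is the unique left-aligned call.
    """

    chrom: str
    length_bp: int
    genes: list[GeneSpec]
    deletion: tuple[int, int]  # (start_bp 0-based, length_bp)
    primers: list[tuple[str, PrimerPair]] = field(default_factory=list)
    frameshift_stop: tuple[str, int, int] | None = None
    anchor_deletion: bool = False
    seed: int = 0

    def __post_init__(self):
        s, length = self.deletion
        if s < 0 or length <= 0 or s + length > self.length_bp:
            raise ValidationError("deletion outside fixture sequence")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene names")
        for g in self.genes:
            if g.offset_bp < 0 or g.offset_bp + g.span_bp > self.length_bp:
                raise ValidationError(f"gene {g.name} outside fixture sequence")

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class LocusFixture:
    """An instantiated locus fixture: sequences, models, call and primers."""

    spec: LocusFixtureSpec
    wild_genome: str
    mutant_genome: str
    models: list[GeneModel]
    deletion: DeletionCall
    primers: list[tuple[str, PrimerPair]]
    flags: list[str] = field(default_factory=list)

    def model(self, name: str) -> GeneModel:
        for m in self.models:
            if m.name == name:
                return m
        raise KeyError(name)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit FASTA (wild + mutant), GFF3, primer TSV and a JSON descriptor."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "wild_fasta": out / "wild.fa",
            "mutant_fasta": out / "mutant.fa",
            "gff3": out / "genes.gff3",
            "primers": out / "primers.tsv",
            "descriptor": out / "fixture.json",
        }
        wio.write_fasta(paths["wild_fasta"], {self.spec.chrom: self.wild_genome})
        wio.write_fasta(paths["mutant_fasta"], {self.spec.chrom: self.mutant_genome})
        wio.write_gff3(paths["gff3"], self.models, {self.spec.chrom: self.spec.length_bp})
        wio.write_primers(paths["primers"], self.primers)
        descriptor = {
            "chrom": self.spec.chrom,
            "length_bp": self.spec.length_bp,
            "deletion": {
                "start_bp": self.deletion.start_bp,
                "length_bp": self.deletion.length_bp,
            },
            "genes": [
                {
                    "name": g.name,
                    "strand": g.strand,
                    "offset_bp": g.offset_bp,
                    "exon_lengths": g.exon_lengths,
                    "intron_lengths": g.intron_lengths,
                    "cds_start": g.cds_start,
                    "cds_end": g.cds_end,
                }
                for g in self.spec.genes
            ],
            "flags": self.flags,
            "seed": self.spec.seed,
        }
        paths["descriptor"].write_text(json.dumps(descriptor, indent=2) + "\n")
        return paths


# ---------------------------------------------------------------------------
# sequence engineering


def _transcript_index(model: GeneModel) -> list[int]:
    idx: list[int] = []
    for e in model.exons:
        if model.strand == "+":
            idx.extend(range(e.start, e.end))
        else:
            idx.extend(range(e.end - 1, e.start - 1, -1))
    return idx


class _Editor:
    """Mutable genome with strand-aware transcript-coordinate access."""

    def __init__(self, seq: list[str]):
        self.seq = seq

    def get_t(self, model: GeneModel, idx: list[int], t: int) -> str:
        base = self.seq[idx[t]]
        return base if model.strand == "+" else base.translate(_COMPLEMENT)

    def set_t(self, model: GeneModel, idx: list[int], t: int, base: str) -> None:
        self.seq[idx[t]] = base if model.strand == "+" else base.translate(_COMPLEMENT)

    def codon(self, model: GeneModel, idx: list[int], t: int) -> str:
        return "".join(self.get_t(model, idx, t + k) for k in range(3))


def _write_splice_sites(ed: _Editor, model: GeneModel) -> None:
    """Canonical GT..AG sites in transcription orientation for every intron."""
    for _, i0, i1 in model.introns():
        if model.strand == "+":
            ed.seq[i0], ed.seq[i0 + 1] = "G", "T"
            ed.seq[i1 - 2], ed.seq[i1 - 1] = "A", "G"
        else:
            # transcript-orientation donor/acceptor on the complement strand
            ed.seq[i1 - 2], ed.seq[i1 - 1] = "A", "C"
            ed.seq[i0], ed.seq[i0 + 1] = "C", "T"


def _clean_orf(ed: _Editor, model: GeneModel, idx: list[int]) -> None:
    """Remove internal stops from the wild-type frame and write a final TAA.

    A stop codon is destroyed by setting its middle base to C (no stop codon
    contains a C, so this can never create a stop elsewhere).
    """
    for t in range(model.cds_start, model.cds_end - 3, 3):
        if ed.codon(model, idx, t) in STOP_CODONS:
            ed.set_t(model, idx, t + 1, "C")
    for k, base in enumerate("TAA"):
        ed.set_t(model, idx, model.cds_end - 3 + k, base)


def _engineer_frameshift_stop(
    ed: _Editor, model: GeneModel, idx: list[int], skip_ordinal: int, novel: int
) -> None:
    """Shape the out-of-frame reading entered when ``skip_ordinal`` is skipped.

    After skipping, translation stays in frame up to the exon junction and
    then reads the next exon shifted by the skipped length mod 3.  This
    routine (run after :func:`_clean_orf`) makes the junction codon a serine
    (AGC) in the wild type and a different, non-stop codon (ACC) in the
    skipped transcript, removes stop codons from the shifted frame for
    ``novel - 1`` codons, and writes TAA as the ``novel``-th, so the skipped
    product carries exactly ``novel`` novel residues.  Only the carry-1
    geometry (coding length before the junction = 1 mod 3) is supported.
    """
    offsets = model.exon_transcript_offsets()
    ordinals = [e.ordinal for e in model.exons]
    pos = ordinals.index(skip_ordinal)
    if pos == 0 or pos == len(ordinals) - 1:
        raise ValidationError("cannot engineer a skip of the first or last exon")
    next_ord = ordinals[pos + 1]
    t_skip = offsets[skip_ordinal]
    t_next = offsets[next_ord]
    c = t_skip - model.cds_start
    if c <= 0:
        raise ValidationError("skipped exon must lie downstream of the CDS start")
    phase = c % 3
    skip_len = model.exon(skip_ordinal).length
    if skip_len % 3 == 0:
        raise ValidationError("skipped exon length must not be a multiple of 3")
    if phase != 1:
        raise ValidationError(
            "frameshift-stop engineering supports only junctions with a "
            "1-base codon carry"
        )
    # wild-type junction codon: A + GC = AGC (Ser), spanning the junction
    ed.set_t(model, idx, t_skip - 1, "A")
    ed.set_t(model, idx, t_skip, "G")
    ed.set_t(model, idx, t_skip + 1, "C")
    # skipped-transcript junction codon: A + CC = ACC (Thr) — diverges, not a stop
    ed.set_t(model, idx, t_next, "C")
    ed.set_t(model, idx, t_next + 1, "C")
    # shifted-frame codons live at next-exon local offsets 2, 5, 8, ...
    base0 = 3 - phase
    next_len = model.exon(next_ord).length
    if base0 + 3 * novel > next_len:
        raise ValidationError(
            f"exon {next_ord} too short to host {novel} shifted-frame codons"
        )
    for k in range(1, novel):
        lo = t_next + base0 + 3 * (k - 1)
        if ed.codon(model, idx, lo) in STOP_CODONS:
            ed.set_t(model, idx, lo + 1, "C")
    lo = t_next + base0 + 3 * (novel - 1)
    for k, base in enumerate("TAA"):
        ed.set_t(model, idx, lo + k, base)


def _anchor_deletion(ed: _Editor, start: int, length: int) -> None:
    """Make the injected deletion placement unique under left alignment."""
    seq = ed.seq
    end = start + length
    if start > 0 and seq[start - 1] == seq[end - 1]:
        seq[start - 1] = "C" if seq[end - 1] != "C" else "A"
    if end < len(seq) and seq[start] == seq[end]:
        seq[start] = "C" if seq[end] != "C" else "A"


def make_locus_fixture(spec: LocusFixtureSpec) -> LocusFixture:
    """Instantiate a locus fixture from its structural spec.

    Raises a validation error if the deletion does not overlap any declared
    gene; a fixture whose deletion is strictly intronic for every
    overlapped gene is flagged ``"no splice site removed"``.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(rng.choice(list("ACGT"), size=spec.length_bp))
    ed = _Editor(seq)

    models = [g.model(spec.chrom) for g in spec.genes]
    indices = {m.name: _transcript_index(m) for m in models}

    for m in models:
        _write_splice_sites(ed, m)
    for m in models:
        _clean_orf(ed, m, indices[m.name])
    if spec.frameshift_stop is not None:
        # every base this writes sits in a codon that can never be a stop in
        # the wild-type frame, so it cannot undo the ORF cleaning above
        gene_name, skip_ord, novel = spec.frameshift_stop
        m = next(m for m in models if m.name == gene_name)
        _engineer_frameshift_stop(ed, m, indices[m.name], skip_ord, novel)
    if spec.anchor_deletion:
        _anchor_deletion(ed, *spec.deletion)

    wild = "".join(seq)

    s, length = spec.deletion
    call = DeletionCall(chrom=spec.chrom, start_bp=s, length_bp=length)
    ann = annotate_deletion(call, models)
    if not ann.classification:
        raise ValidationError(
            "deletion does not overlap the declared gene features"
        )
    flags = []
    if not ann.splice_sites_lost and all(
        c == "intronic_only" for c in ann.classification.values()
    ):
        flags.append("no splice site removed")

    mutant = apply_deletion(wild, s, length)

    # verify each wild-type ORF translates cleanly to its declared length
    for m in models:
        tx = splice(m, wild)
        prot = translate_cds(tx, m.cds_start)
        expected = (m.cds_end - m.cds_start) // 3 - 1
        if len(prot) != expected:
            raise ValidationError(
                f"fixture engineering conflict: gene {m.name} translates to "
                f"{len(prot)} aa, expected {expected}"
            )

    return LocusFixture(
        spec=spec,
        wild_genome=wild,
        mutant_genome=mutant,
        models=models,
        deletion=call,
        primers=list(spec.primers),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# the replica locus preset

#: structural constants of the replica locus (see docs for their provenance)
REPLICA_CHROM = "chr11_fix"
REPLICA_EXON3_LEN = 125
REPLICA_DELETION_LEN = 955


def replica_locus_spec(seed: int = 0) -> LocusFixtureSpec:
    """The two-gene replica locus.

    Gene B (Fam83g-like): five exons (700/214/125/1000/700 nt), CDS of
    2,439 nt (812 codons + stop) starting 100 nt into exon 1; 600 + 214
    coding nt precede exon 3, so the codon for Ser-272 spans the exon 2/3
    junction and the 125-nt exon 3 shifts frame when skipped.  The nested
    primer pair (exon 1 / exon 4) spans 484 bp on the wild-type spliced
    transcript and 359 bp after the skip.  Gene A (Slc5a10-like): thirteen
    100-nt exons whose intron 10–11 contains gene B's deleted region
    entirely.  The 955-bp deletion removes the last 830 nt of gene B's
    intron 2–3 (including the exon-3 acceptor) plus all of exon 3.
    """
    gene_b = GeneSpec(
        name="FamB",
        strand="+",
        offset_bp=4150,
        exon_lengths=[700, 214, REPLICA_EXON3_LEN, 1000, 700],
        intron_lengths=[400, 1200, 600, 500],
        cds_start=100,
        cds_end=100 + 2439,
        domains=[
            ("DUF1669", 30, 300),
            ("PLD_N_like", 50, 230),
            ("PLD_superfamily", 280, 460),
            ("Pro_rich", 470, 511),
        ],
    )
    gene_a = GeneSpec(
        name="SlcA",
        strand="+",
        offset_bp=1000,
        exon_lengths=[100] * 13,
        intron_lengths=[150] * 9 + [7000, 150, 150],
        cds_start=50,
        cds_end=50 + 1200,
    )
    # exon 3 of gene B occupies [6664, 6789); the deletion removes the last
    # 830 nt of intron 2-3 plus the whole exon: [5834, 6789)
    exon3 = gene_b.exons()[2]
    del_start = exon3.start - 830
    primers = [
        # nested pair: wild-type spliced product 484 bp, exon-3 skip 359 bp
        ("FamB", PrimerPair(forward=(1, 600, 28), reverse=(4, 17, 28), name="4F/4R")),
        # outer pair used for the first amplification round
        ("FamB", PrimerPair(forward=(1, 560, 28), reverse=(4, 60, 28), name="3F/3R")),
        # gene A pair flanking its intron 10-11 (splicing unaffected)
        ("SlcA", PrimerPair(forward=(10, 10, 28), reverse=(11, 60, 30), name="2F/2R")),
    ]
    return LocusFixtureSpec(
        chrom=REPLICA_CHROM,
        length_bp=12000,
        genes=[gene_a, gene_b],
        deletion=(del_start, REPLICA_DELETION_LEN),
        primers=primers,
        frameshift_stop=("FamB", 3, 24),
        anchor_deletion=True,
        seed=seed,
    )


def replica_locus(seed: int = 0) -> LocusFixture:
    """Convenience: the instantiated replica locus fixture."""
    fix = make_locus_fixture(replica_locus_spec(seed))
    exon3 = fix.model("FamB").exon(3)
    assert exon3.length == REPLICA_EXON3_LEN
    return fix


# ---------------------------------------------------------------------------
# the replica backcross panel

_REPLICA_MARKERS = [
    ("D11Mit313", 0),
    ("D11Mit208", 3_000_000),
    ("D11Mit260", 5_400_000),
    ("D11Mit242", 7_800_000),
    ("D11Mit216", 9_500_000),
    ("D11Mit261", 11_000_000),
]
_REPLICA_CM_PER_MB = 0.5
REPLICA_TRAIT_POS_BP = 5_350_000

_REPLICA_SNPS = [
    ("SNP1", 3_600_000),
    ("SNP2", 4_900_000),
    ("SNP3", 5_450_000),
    ("SNP4", 5_550_000),
    ("SNP5", 5_600_000),
    ("SNP6", 5_650_000),
]


def replica_map() -> GeneticMap:
    markers = [
        Marker(name, "chr11", bp, bp * _REPLICA_CM_PER_MB / 1e6)
        for name, bp in _REPLICA_MARKERS
    ]
    return GeneticMap(chrom="chr11", markers=markers, cm_per_mb=_REPLICA_CM_PER_MB)


def replica_trait() -> TraitLocus:
    return TraitLocus(
        name="wly",
        pos_bp=REPLICA_TRAIT_POS_BP,
        pos_cM=REPLICA_TRAIT_POS_BP * _REPLICA_CM_PER_MB / 1e6,
    )


def _progeny_block(
    prefix: str, count: int, alleles: list[str], trait_allele: str, marker_names: list[str]
) -> list[Progeny]:
    genos = {
        name: ("H" if a == "A" else "N") for name, a in zip(marker_names, alleles)
    }
    phenotype = "mutant" if trait_allele == "N" else "normal"
    return [
        Progeny(id=f"{prefix}{i + 1:02d}", phenotype=phenotype, genotypes=dict(genos))
        for i in range(count)
    ]


def replica_panel() -> BackcrossPanel:
    """The deterministic 1,679-progeny replica testcross panel.

    Encodes the published totals: 11 recombinants with a crossover between
    the proximal flank and the trait, 19 between the trait and the distal
    flank, no recombination between the trait and the cosegregating middle
    marker, and an overall 840 mutant : 839 normal segregation.  Crossover
    counts in the outer intervals are plausible filler consistent with the
    map distances, not published values.
    """
    gmap = replica_map()
    names = gmap.names  # 313, 208, 260, 242, 216, 261
    blocks: list[Progeny] = []

    def add(prefix, count, alleles, trait_allele):
        blocks.extend(_progeny_block(prefix, count, alleles, trait_allele, names))

    # crossover between D11Mit208 and the trait (11 total)
    add("RP-AN-", 6, ["A", "A", "N", "N", "N", "N"], "N")
    add("RP-NA-", 5, ["N", "N", "A", "A", "A", "A"], "A")
    # crossover between the trait and D11Mit242 (19 total)
    add("RD-AN-", 10, ["A", "A", "A", "N", "N", "N"], "A")
    add("RD-NA-", 9, ["N", "N", "N", "A", "A", "A"], "N")
    # outer-interval crossovers (filler counts)
    add("RO1-AN-", 12, ["A", "N", "N", "N", "N", "N"], "N")
    add("RO1-NA-", 12, ["N", "A", "A", "A", "A", "A"], "A")
    add("RO2-AN-", 9, ["A", "A", "A", "A", "N", "N"], "A")
    add("RO2-NA-", 8, ["N", "N", "N", "N", "A", "A"], "N")
    add("RO3-AN-", 8, ["A", "A", "A", "A", "A", "N"], "A")
    add("RO3-NA-", 7, ["N", "N", "N", "N", "N", "A"], "N")
    # parental classes fill to 1,679 with an 840:839 mutant:normal split
    n_rec_mut = 6 + 9 + 12 + 8 + 7
    n_parental = 1679 - len(blocks)
    n_par_mut = 840 - n_rec_mut
    add("PN-", n_par_mut, ["N"] * 6, "N")
    add("PA-", n_parental - n_par_mut, ["A"] * 6, "A")

    panel = BackcrossPanel(map=gmap, trait="wly", progeny=blocks)
    assert panel.n == 1679
    return panel


def replica_snp_markers() -> list[Marker]:
    return [
        Marker(name, "chr11", bp, bp * _REPLICA_CM_PER_MB / 1e6)
        for name, bp in _REPLICA_SNPS
    ]


def replica_snp_typing() -> dict[str, dict[str, str]]:
    """SNP1-6 genotypes for the 30 interval recombinants of the replica panel.

    Among the 11 proximal recombinants, two carry their crossover between
    SNP2 and the trait; among the 19 distal ones, one carries it between
    the trait and SNP6.  No crossover separates the trait from SNP3, SNP4
    or SNP5.
    """
    snp_names = [n for n, _ in _REPLICA_SNPS]

    def genos(alleles: list[str]) -> dict[str, str]:
        return {n: ("H" if a == "A" else "N") for n, a in zip(snp_names, alleles)}

    typing: dict[str, dict[str, str]] = {}
    # proximal recombinants, A-proximal orientation (trait allele N):
    # RP-AN-01..02: crossover between SNP2 and the trait  -> define SNP2 flank
    # RP-AN-03..04: crossover between SNP1 and SNP2
    # RP-AN-05..06: crossover between D11Mit208 and SNP1
    typing["RP-AN-01"] = genos(["A", "A", "N", "N", "N", "N"])
    typing["RP-AN-02"] = genos(["A", "A", "N", "N", "N", "N"])
    typing["RP-AN-03"] = genos(["A", "N", "N", "N", "N", "N"])
    typing["RP-AN-04"] = genos(["A", "N", "N", "N", "N", "N"])
    typing["RP-AN-05"] = genos(["N", "N", "N", "N", "N", "N"])
    typing["RP-AN-06"] = genos(["N", "N", "N", "N", "N", "N"])
    # proximal recombinants, mirrored orientation (trait allele A)
    typing["RP-NA-01"] = genos(["N", "A", "A", "A", "A", "A"])
    typing["RP-NA-02"] = genos(["A", "A", "A", "A", "A", "A"])
    typing["RP-NA-03"] = genos(["A", "A", "A", "A", "A", "A"])
    typing["RP-NA-04"] = genos(["A", "A", "A", "A", "A", "A"])
    typing["RP-NA-05"] = genos(["A", "A", "A", "A", "A", "A"])
    # distal recombinants: one crossover between SNP5 and SNP6 (defines the
    # SNP6 flank); the rest lie between SNP6 and D11Mit242
    typing["RD-AN-01"] = genos(["A", "A", "A", "A", "A", "N"])
    for i in range(2, 11):
        typing[f"RD-AN-{i:02d}"] = genos(["A", "A", "A", "A", "A", "A"])
    for i in range(1, 10):
        typing[f"RD-NA-{i:02d}"] = genos(["N", "N", "N", "N", "N", "N"])
    return typing


# ---------------------------------------------------------------------------
# the replica interval gene table


def replica_interval_genes() -> tuple[list[AnnotatedGene], tuple[int, int]]:
    """Annotated genes of the refined critical interval, and the interval.

    Six genes with engineered null alleles and normal coats, four predicted
    genes without skin-expression evidence (named generically), and the two
    overlapping skin-cDNA-library genes.  Coordinates are placements within
    the interval, not genome-database positions.
    """
    lo, hi = 4_900_000, 5_650_000  # SNP2..SNP6
    genes = [
        AnnotatedGene("Slc47a1", 4_940_000, 4_980_000, True, "other"),
        AnnotatedGene("Epn2", 5_000_000, 5_060_000, True, "unknown"),
        AnnotatedGene("Grap", 5_080_000, 5_110_000, True, "other"),
        AnnotatedGene("Ulk2", 5_130_000, 5_190_000, True, "unknown"),
        AnnotatedGene("Mapk7", 5_210_000, 5_230_000, True, "other"),
        AnnotatedGene("Akap10", 5_250_000, 5_310_000, True, "unknown"),
        AnnotatedGene("PredictedGene1", 5_330_000, 5_340_000, None, "none"),
        AnnotatedGene("PredictedGene2", 5_350_000, 5_360_000, None, "none"),
        AnnotatedGene("PredictedGene3", 5_470_000, 5_480_000, None, "none"),
        AnnotatedGene("PredictedGene4", 5_500_000, 5_510_000, None, "none"),
        # the overlapping primary candidates, both from skin cDNA libraries
        AnnotatedGene("Slc5a10", 5_370_000, 5_430_000, False, "cdna_library"),
        AnnotatedGene("Fam83g", 5_400_000, 5_420_000, None, "cdna_library"),
    ]
    return genes, (lo, hi)
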