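"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA is read through pyfaidx; GFF3 is parsed through gffutils.  Tables
(marker maps, genotype panels, primers, gene annotations) are TSV via
pandas.  GFF3 coordinates are 1-based inclusive on disk and 0-based
half-open in memory.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from woolmap.errors import ValidationError
from woolmap.genes import Exon, GeneModel, PrimerPair
from woolmap.genetics import (
    GENOTYPE_CODES,
    BackcrossPanel,
    GeneticMap,
    Marker,
    Progeny,
)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for line in textwrap.wrap(seq, width):
                fh.write(line + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------------------
# GFF3 gene models

def _cds_genomic_intervals(model: GeneModel) -> list[tuple[int, int]]:
    """Genomic [start, end) slices of the CDS, one per coding exon."""
    out = []
    pos = 0
    for e in model.exons:
        lo = max(model.cds_start, pos)
        hi = min(model.cds_end, pos + e.length)
        if lo < hi:
            if model.strand == "+":
                out.append((e.start + (lo - pos), e.start + (hi - pos)))
            else:
                out.append((e.end - (hi - pos), e.end - (lo - pos)))
        pos += e.length
    return out


def write_gff3(path: str | Path, models: list[GeneModel], chrom_lengths: dict[str, int]) -> None:
    lines = ["##gff-version 3"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for m in models:
        lo, hi = m.span
        attrs = f"ID=gene:{m.name};Name={m.name}"
        if m.domains:
            dom = ",".join(f"{n}|{a}|{b}" for n, a, b in m.domains)
            attrs += f";domains={dom}"
        lines.append(
            f"{m.chrom}\twoolmap\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{m.chrom}\twoolmap\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
            f"ID=tx:{m.name};Parent=gene:{m.name}"
        )
        for e in m.exons:
            lines.append(
                f"{m.chrom}\twoolmap\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t"
                f"ID=exon:{m.name}.{e.ordinal};Parent=tx:{m.name}"
            )
        # phase of each CDS piece, walking in transcription order
        remaining = 0
        pieces = _cds_genomic_intervals(model=m)
        if m.strand == "-":
            ordered = pieces  # already transcription order; genomic coords inside
        else:
            ordered = pieces
        for i, (a, b) in enumerate(ordered):
            phase = (3 - remaining % 3) % 3
            remaining += b - a
            lines.append(
                f"{m.chrom}\twoolmap\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t{phase}\t"
                f"ID=cds:{m.name}.{i + 1};Parent=tx:{m.name}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Reconstruct gene models (exons + transcript-coordinate CDS) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", [gene.id.split(":")[-1]])[0]
        domains = []
        for spec in gene.attributes.get("domains", []):
            for item in spec.split(","):
                dn, a, b = item.split("|")
                domains.append((dn, int(a), int(b)))
        exon_iv = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds_iv = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")
        )
        if not exon_iv:
            raise ValidationError(f"gene {name}: no exon features in GFF3")
        if not cds_iv:
            raise ValidationError(f"gene {name}: no CDS features in GFF3")
        if gene.strand == "-":
            exon_iv = exon_iv[::-1]
        exons = [Exon(i + 1, a, b) for i, (a, b) in enumerate(exon_iv)]
        # transcript coordinates of the CDS from its genomic extent
        cds_lo = min(a for a, _ in cds_iv)
        cds_hi = max(b for _, b in cds_iv)
        pos = 0
        cds_start = cds_end = None
        for e in exons:
            if gene.strand == "+":
                if e.start <= cds_lo < e.end:
                    cds_start = pos + (cds_lo - e.start)
                if e.start < cds_hi <= e.end:
                    cds_end = pos + (cds_hi - e.start)
            else:
                if e.start < cds_hi <= e.end:
                    cds_start = pos + (e.end - cds_hi)
                if e.start <= cds_lo < e.end:
                    cds_end = pos + (e.end - cds_lo)
            pos += e.end - e.start
        if cds_start is None or cds_end is None:
            raise ValidationError(f"gene {name}: CDS bounds not inside exons")
        models.append(
            GeneModel(
                name=name, chrom=gene.seqid, strand=gene.strand,
                exons=exons, cds_start=cds_start, cds_end=cds_end,
                domains=domains,
            )
        )
    return models


# ---------------------------------------------------------------------------
# TSV tables

def write_marker_map(path: str | Path, gmap: GeneticMap) -> None:
    df = pd.DataFrame(
        {
            "name": [m.name for m in gmap.markers],
            "chrom": [m.chrom for m in gmap.markers],
            "pos_bp": [m.pos_bp for m in gmap.markers],
            "pos_cM": [m.pos_cM for m in gmap.markers],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path, cm_per_mb: float = 0.5) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chrom", "pos_bp", "pos_cM"}
    if not required.issubset(df.columns):
        raise ValidationError(f"marker map must have columns {sorted(required)}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValidationError(
            f"multi-chromosome marker maps are not supported (got {list(chroms)})"
        )
    markers = [
        Marker(str(r["name"]), str(r["chrom"]), int(r["pos_bp"]), float(r["pos_cM"]))
        for _, r in df.iterrows()
    ]
    return GeneticMap(chrom=str(chroms[0]), markers=markers, cm_per_mb=cm_per_mb)


def write_genotypes(path: str | Path, panel: BackcrossPanel) -> None:
    names = panel.map.names
    rows = []
    for p in panel.progeny:
        row = {"id": p.id, "phenotype": p.phenotype}
        for n in names:
            row[n] = p.genotypes.get(n, "-")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, gmap: GeneticMap, trait: str = "wly") -> BackcrossPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "phenotype" not in df.columns:
        raise ValidationError("genotype table must have 'id' and 'phenotype' columns")
    marker_cols = [c for c in df.columns if c not in ("id", "phenotype")]
    unknown = set(marker_cols) - set(gmap.names)
    if unknown:
        raise ValidationError(f"genotype columns not in marker map: {sorted(unknown)}")
    progeny = []
    for _, r in df.iterrows():
        genos = {}
        for c in marker_cols:
            code = r[c] if pd.notna(r[c]) else "-"
            if code not in GENOTYPE_CODES:
                raise ValidationError(f"progeny {r['id']}: unknown genotype code {code!r}")
            genos[c] = code
        progeny.append(Progeny(id=str(r["id"]), phenotype=str(r["phenotype"]), genotypes=genos))
    return BackcrossPanel(map=gmap, trait=trait, progeny=progeny)


def write_primers(path: str | Path, primers: list[tuple[str, PrimerPair]]) -> None:
    rows = []
    for gene, p in primers:
        rows.append(
            {
                "name": p.name, "gene": gene,
                "fwd_exon": p.forward[0], "fwd_offset": p.forward[1], "fwd_len": p.forward[2],
                "rev_exon": p.reverse[0], "rev_offset": p.reverse[1], "rev_len": p.reverse[2],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_primers(path: str | Path) -> list[tuple[str, PrimerPair]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            (
                str(r["gene"]),
                PrimerPair(
                    forward=(int(r["fwd_exon"]), int(r["fwd_offset"]), int(r["fwd_len"])),
                    reverse=(int(r["rev_exon"]), int(r["rev_offset"]), int(r["rev_len"])),
                    name=str(r["name"]),
                ),
            )
        )
    return out


def write_vcf(path: str | Path, chrom: str, start: int, length: int, wild: str) -> None:
    """Write one deletion as a minimal VCF 4.2 record.

    Uses the anchor-base convention: POS is the 1-based position of the base
    preceding the deleted run, REF includes that base plus the deleted bases.
    """
    if start < 1:
        raise ValidationError("VCF anchor-base convention requires start >= 1")
    pos = start  # 1-based coordinate of wild[start - 1]
    ref = wild[start - 1 : start + length]
    alt = wild[start - 1]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(wild)}>",
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deletion length">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tSVLEN=-{length}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
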