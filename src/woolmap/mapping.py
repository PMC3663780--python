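"""Testcross linkage mapping by recombinant counting.

In a testcross the phenotype of each N2 animal reads out the allele the
heterozygous F1 dam transmitted at the trait locus, so the trait can be
treated as one more locus on the transmitted haplotype.  Mapping then
reduces to counting: the recombination fraction between two loci is the
proportion of informative meioses in which the dam-derived alleles differ,
and the trait interval is bounded by the nearest markers that show at
least one trait–marker recombinant on each side.  No likelihood machinery
(LOD scores, multipoint estimation) is used — with ~1,700 meioses, direct
recombinant counting is the estimator of record for this design.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from scipy.stats import chi2 as _chi2

from woolmap.errors import ValidationError
from woolmap.genetics import (
    GENO_HET,
    GENO_HOM,
    GENO_MISSING,
    BackcrossPanel,
    GeneticMap,
    Marker,
    Progeny,
)

ALLELE_A = "A"  # dam transmitted the A-strain allele
ALLELE_N = "N"  # dam transmitted the mutant-stock allele


@dataclass(frozen=True)
class SegregationTest:
    """Goodness of fit of the phenotype counts to the expected 1:1 ratio."""

    n_mutant: int
    n_normal: int
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n_mutant": self.n_mutant,
            "n_normal": self.n_normal,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


@dataclass
class TransmittedHaplotype:
    """Dam-derived alleles for one progeny, with the trait as a pseudo-locus.

    Marker alleles are 'A', 'N' or None (unknown); the trait allele is 'N'
    for a mutant phenotype (the dam transmitted the mutant allele) and 'A'
    for a normal one.
    """

    progeny_id: str
    alleles: dict[str, str | None]
    trait: str
    trait_allele: str | None

    def allele(self, locus: str) -> str | None:
        if locus == self.trait:
            return self.trait_allele
        return self.alleles[locus]


@dataclass(frozen=True)
class HaplotypeClassCount:
    """One distinct transmitted-haplotype pattern and its frequency."""

    loci: tuple[str, ...]
    pattern: tuple[str | None, ...]
    count: int


@dataclass(frozen=True)
class IntervalEstimate:
    """Recombination fraction between two loci with its binomial SE."""

    locus_a: str
    locus_b: str
    n_recombinant: int
    n_informative: int
    r: float
    se: float

    def to_dict(self) -> dict:
        return {
            "locus_a": self.locus_a,
            "locus_b": self.locus_b,
            "n_recombinant": self.n_recombinant,
            "n_informative": self.n_informative,
            "r": self.r,
            "se": self.se,
        }


@dataclass
class TraitLocalization:
    """Flanking-marker interval for the trait with its defining recombinants."""

    proximal_flank: str
    distal_flank: str
    n_proximal_recombinants: int
    n_distal_recombinants: int
    proximal_recombinant_ids: list[str]
    distal_recombinant_ids: list[str]
    interval_bp: int | None
    flagged_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "proximal_flank": self.proximal_flank,
            "distal_flank": self.distal_flank,
            "n_proximal_recombinants": self.n_proximal_recombinants,
            "n_distal_recombinants": self.n_distal_recombinants,
            "proximal_recombinant_ids": list(self.proximal_recombinant_ids),
            "distal_recombinant_ids": list(self.distal_recombinant_ids),
            "interval_bp": self.interval_bp,
            "flagged_ids": list(self.flagged_ids),
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------


def test_segregation(panel: BackcrossPanel) -> SegregationTest:
    """Chi-square goodness of fit to the 1 mutant : 1 normal testcross ratio.

    Raw chi-square with df = 1 and no continuity correction; p is the
    upper-tail probability.
    """
    if panel.n == 0:
        raise ValidationError("empty panel")
    n_mut, n_norm = panel.phenotype_counts()
    expected = (n_mut + n_norm) / 2.0
    stat = (n_mut - expected) ** 2 / expected + (n_norm - expected) ** 2 / expected
    p = float(_chi2.sf(stat, df=1))
    return SegregationTest(n_mutant=n_mut, n_normal=n_norm, chi2=stat, df=1, p_value=p)


def infer_transmitted_haplotypes(panel: BackcrossPanel) -> list[TransmittedHaplotype]:
    """Decode genotypes into dam-derived alleles, adding the trait pseudo-locus.

    H (heterozygous) means the dam transmitted the A allele, N (homozygous)
    the mutant-stock allele; missing genotypes propagate as unknown.
    """
    out = []
    for p in panel.progeny:
        alleles: dict[str, str | None] = {}
        for name in panel.map.names:
            code = p.genotypes.get(name, GENO_MISSING)
            if code == GENO_HET:
                alleles[name] = ALLELE_A
            elif code == GENO_HOM:
                alleles[name] = ALLELE_N
            elif code == GENO_MISSING:
                alleles[name] = None
            else:
                raise ValidationError(
                    f"progeny {p.id}: unknown genotype code {code!r} at {name}"
                )
        trait_allele = ALLELE_N if p.phenotype == "mutant" else ALLELE_A
        out.append(
            TransmittedHaplotype(
                progeny_id=p.id, alleles=alleles, trait=panel.trait,
                trait_allele=trait_allele,
            )
        )
    return out


def count_haplotype_classes(
    haplotypes: list[TransmittedHaplotype], loci: list[str] | None = None
) -> list[HaplotypeClassCount]:
    """Partition haplotypes by identical allele pattern (unknowns distinct).

    ``loci`` defaults to the marker loci of the first haplotype (map order)
    followed by the trait pseudo-locus.  Classes are returned sorted by
    descending count.
    """
    if not haplotypes:
        return []
    if loci is None:
        loci = list(haplotypes[0].alleles.keys()) + [haplotypes[0].trait]
    counts = Counter(tuple(h.allele(l) for l in loci) for h in haplotypes)
    loci_t = tuple(loci)
    return [
        HaplotypeClassCount(loci=loci_t, pattern=pat, count=c)
        for pat, c in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    ]


def estimate_recombination(
    haplotypes: list[TransmittedHaplotype], locus_a: str, locus_b: str
) -> IntervalEstimate:
    """Recombination fraction between two loci from transmitted haplotypes.

    Informative progeny have known dam alleles at both loci; recombinants
    are those whose alleles differ.  SE is the binomial sqrt(r(1-r)/n).
    """
    rec = inf = 0
    for h in haplotypes:
        a, b = h.allele(locus_a), h.allele(locus_b)
        if a is None or b is None:
            continue
        inf += 1
        if a != b:
            rec += 1
    if inf == 0:
        raise ValidationError(
            f"no progeny informative for both {locus_a} and {locus_b}"
        )
    r = rec / inf
    se = math.sqrt(r * (1 - r) / inf)
    return IntervalEstimate(
        locus_a=locus_a, locus_b=locus_b, n_recombinant=rec, n_informative=inf,
        r=r, se=se,
    )


# ---------------------------------------------------------------------------
# trait localization


def _side_candidates(
    haplotypes: list[TransmittedHaplotype], marker_order: list[str]
) -> tuple[dict[str, list[str]], dict[str, list[str]], list[str]]:
    """Per-progeny flank candidates from the concordance pattern.

    For each progeny the markers concordant with the trait allele must form
    one contiguous block; the nearest discordant marker on each side is
    that progeny's flank candidate (the crossover between it and the block
    must separate it from the trait).  Progeny with no concordant marker or
    more than one concordant block would require a double crossover within
    a single interval around the trait and are flagged instead of
    constraining the interval.
    """
    prox: dict[str, list[str]] = {}
    dist: dict[str, list[str]] = {}
    flagged: list[str] = []
    for h in haplotypes:
        if h.trait_allele is None:
            continue
        known = [
            (j, h.alleles[name])
            for j, name in enumerate(marker_order)
            if h.alleles[name] is not None
        ]
        if not known:
            continue
        conc = [j for j, a in known if a == h.trait_allele]
        if len(conc) == len(known):
            continue  # non-recombinant with the trait
        if not conc:
            flagged.append(h.progeny_id)
            continue
        # contiguity within the sequence of known markers
        known_idx = [j for j, _ in known]
        first, last = conc[0], conc[-1]
        inner = [j for j in known_idx if first <= j <= last]
        if inner != conc:
            flagged.append(h.progeny_id)
            continue
        below = [j for j in known_idx if j < first]
        above = [j for j in known_idx if j > last]
        if below:
            prox.setdefault(marker_order[max(below)], []).append(h.progeny_id)
        if above:
            dist.setdefault(marker_order[min(above)], []).append(h.progeny_id)
    return prox, dist, flagged


def localize_trait(
    haplotypes: list[TransmittedHaplotype], gmap: GeneticMap
) -> TraitLocalization:
    """Bound the trait locus by its nearest recombinant-bearing markers.

    The proximal flank is the marker closest to the trait from below that
    carries at least one recombinant whose crossover places the trait
    distal of it; symmetrically for the distal flank.  Markers showing no
    recombination with the trait fall inside the reported interval.  A side
    with no recombinant at all falls back to the outermost typed marker and
    records a warning.
    """
    if not haplotypes:
        raise ValidationError("no haplotypes")
    if all(h.trait_allele is None for h in haplotypes):
        raise ValidationError("trait pseudo-locus absent from every haplotype")
    order = gmap.names
    prox, dist, flagged = _side_candidates(haplotypes, order)
    warnings: list[str] = []
    if flagged:
        warnings.append(
            f"{len(flagged)} progeny require a double crossover within one "
            "interval (possible genotyping error or incomplete penetrance)"
        )

    pos = {m.name: m.pos_bp for m in gmap.markers}
    if prox:
        proximal = max(prox, key=lambda n: pos[n])
        prox_ids = sorted(prox[proximal])
    else:
        proximal = order[0]
        prox_ids = []
        warnings.append(
            "no proximal recombinant: flank set to the outermost proximal marker"
        )
    if dist:
        distal = min(dist, key=lambda n: pos[n])
        dist_ids = sorted(dist[distal])
    else:
        distal = order[-1]
        dist_ids = []
        warnings.append(
            "no distal recombinant: flank set to the outermost distal marker"
        )
    if pos[proximal] >= pos[distal]:
        raise ValidationError(
            f"inconsistent localization: proximal flank {proximal} is not "
            f"proximal of distal flank {distal}"
        )
    return TraitLocalization(
        proximal_flank=proximal,
        distal_flank=distal,
        n_proximal_recombinants=len(prox_ids),
        n_distal_recombinants=len(dist_ids),
        proximal_recombinant_ids=prox_ids,
        distal_recombinant_ids=dist_ids,
        interval_bp=pos[distal] - pos[proximal],
        flagged_ids=flagged,
        warnings=warnings,
    )


def refine_interval(
    localization: TraitLocalization,
    panel: BackcrossPanel,
    extra_markers: list[Marker],
    extra_genotypes: dict[str, dict[str, str]],
    drop_flagged: bool = False,
) -> TraitLocalization:
    """Refine a localization with markers typed only on its recombinants.

    ``extra_markers`` must lie strictly inside the current interval;
    ``extra_genotypes`` maps progeny id to genotype codes for every
    recombinant listed in the localization.  Progeny that are not interval
    recombinants are treated as implicitly parental across the interval
    (their flank alleles agree, so every internal locus is filled with that
    allele).  The refined interval is never wider than the input one.
    """
    if not extra_markers:
        return localization
    gmap = panel.map
    p_lo = gmap.marker(localization.proximal_flank)
    p_hi = gmap.marker(localization.distal_flank)
    for m in extra_markers:
        if not (p_lo.pos_bp < m.pos_bp < p_hi.pos_bp):
            raise ValidationError(
                f"extra marker {m.name} at {m.pos_bp} lies outside the current "
                f"interval ({p_lo.pos_bp}, {p_hi.pos_bp})"
            )
    recombinants = set(localization.proximal_recombinant_ids) | set(
        localization.distal_recombinant_ids
    )
    missing = recombinants - set(extra_genotypes)
    if missing:
        raise ValidationError(
            f"extra genotypes missing for recombinants: {sorted(missing)}"
        )

    all_markers = sorted(gmap.markers + list(extra_markers), key=lambda m: m.pos_bp)
    union_map = GeneticMap(chrom=gmap.chrom, markers=all_markers, cm_per_mb=gmap.cm_per_mb)

    flagged = set(localization.flagged_ids)
    new_progeny = []
    for p in panel.progeny:
        if drop_flagged and p.id in flagged:
            continue
        genos = dict(p.genotypes)
        if p.id in extra_genotypes:
            for m in extra_markers:
                genos[m.name] = extra_genotypes[p.id].get(m.name, GENO_MISSING)
        else:
            a = genos.get(localization.proximal_flank, GENO_MISSING)
            b = genos.get(localization.distal_flank, GENO_MISSING)
            fill = a if (a == b and a != GENO_MISSING) else GENO_MISSING
            for m in extra_markers:
                genos[m.name] = fill
        new_progeny.append(Progeny(id=p.id, phenotype=p.phenotype, genotypes=genos))

    union_panel = BackcrossPanel(
        map=union_map, trait=panel.trait, progeny=new_progeny, seed=panel.seed
    )
    refined = localize_trait(infer_transmitted_haplotypes(union_panel), union_map)

    # guarantee the interval never widens
    pos = {m.name: m.pos_bp for m in union_map.markers}
    if pos[refined.proximal_flank] < p_lo.pos_bp:
        refined.proximal_flank = p_lo.name
        refined.n_proximal_recombinants = localization.n_proximal_recombinants
        refined.proximal_recombinant_ids = list(localization.proximal_recombinant_ids)
        refined.warnings.append("proximal flank clipped to the previous interval")
    if pos[refined.distal_flank] > p_hi.pos_bp:
        refined.distal_flank = p_hi.name
        refined.n_distal_recombinants = localization.n_distal_recombinants
        refined.distal_recombinant_ids = list(localization.distal_recombinant_ids)
        refined.warnings.append("distal flank clipped to the previous interval")
    refined.interval_bp = pos[refined.distal_flank] - pos[refined.proximal_flank]
    return refined


def interval_estimates(
    haplotypes: list[TransmittedHaplotype], gmap: GeneticMap
) -> list[IntervalEstimate]:
    """Recombination fraction ± SE for each adjacent marker interval."""
    return [
        estimate_recombination(haplotypes, a, b)
        for a, b in zip(gmap.names, gmap.names[1:])
    ]


def format_class_table(classes: list[HaplotypeClassCount]) -> str:
    """Plain-text haplotype-class table: one locus per row, classes as columns."""
    if not classes:
        return "(no haplotypes)\n"
    loci = classes[0].loci
    width = max(len(l) for l in loci) + 2
    lines = []
    for i, locus in enumerate(loci):
        cells = "".join(
            f"{(c.pattern[i] or '?'):>6}" for c in classes
        )
        lines.append(f"{locus:<{width}}{cells}")
    lines.append(f"{'count':<{width}}" + "".join(f"{c.count:>6}" for c in classes))
    return "\n".join(lines) + "\n"
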