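"""Genetic maps, testcross panels and the meiosis simulator.

The simulated design is an (A x N)F1 female bred back to homozygous
mutant males of strain N, so that every progeny's phenotype reads out the
allele transmitted by the dam at the trait locus.  Only the dam's meiosis
is stochastic; the sire always contributes the N haplotype carrying the
mutant allele.  Crossovers follow the Haldane model: the crossover count
in an interval is Poisson with mean equal to the interval's length in
Morgans, with no interference, so the dam-derived allele switches between
adjacent loci with probability ``haldane(d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from woolmap.errors import ValidationError

# genotype codes used in TSV tables: H = heterozygous A/N, N = homozygous N,
# "-" = missing
GENO_HET = "H"
GENO_HOM = "N"
GENO_MISSING = "-"
GENOTYPE_CODES = frozenset({GENO_HET, GENO_HOM, GENO_MISSING})

PHENOTYPES = ("mutant", "normal")


def haldane(d_morgans: float) -> float:
    """Map a genetic distance in Morgans to a recombination fraction.

    r = (1 - exp(-2 d)) / 2, the no-interference (Poisson crossover) map
    function; r -> 0.5 as d -> infinity.
    """
    if d_morgans < 0:
        raise ValidationError(f"negative genetic distance: {d_morgans}")
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def haldane_inverse(r: float) -> float:
    """Recombination fraction back to Morgans (inverse of :func:`haldane`)."""
    if not 0 <= r < 0.5:
        raise ValidationError(f"recombination fraction must be in [0, 0.5): {r}")
    return -0.5 * np.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class Marker:
    """A mapped locus with physical (bp, 0-based) and genetic (cM) positions."""

    name: str
    chrom: str
    pos_bp: int
    pos_cM: float

    def __post_init__(self):
        if self.pos_bp < 0:
            raise ValidationError(f"marker {self.name}: pos_bp must be >= 0")
        if self.pos_cM < 0:
            raise ValidationError(f"marker {self.name}: pos_cM must be >= 0")


@dataclass
class GeneticMap:
    """An ordered single-chromosome marker panel.

    Markers must be strictly increasing in both bp and cM (monotone
    co-linear).  Multi-chromosome maps are rejected; mapping a trait
    against markers on several chromosomes is out of scope.
    """

    chrom: str
    markers: list[Marker]
    cm_per_mb: float = 0.5

    def __post_init__(self):
        if len(self.markers) < 2:
            raise ValidationError("a genetic map needs at least 2 markers")
        if self.cm_per_mb <= 0:
            raise ValidationError("cm_per_mb must be positive")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate marker names in map")
        chroms = {m.chrom for m in self.markers}
        if chroms != {self.chrom}:
            raise ValidationError(
                f"all markers must lie on chromosome {self.chrom!r}; got {sorted(chroms)}"
            )
        for a, b in zip(self.markers, self.markers[1:]):
            if not (a.pos_bp < b.pos_bp and a.pos_cM < b.pos_cM):
                raise ValidationError(
                    f"markers {a.name} and {b.name} are not strictly increasing "
                    "in both bp and cM"
                )

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def span_bp(self) -> tuple[int, int]:
        return (self.markers[0].pos_bp, self.markers[-1].pos_bp)

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class TraitLocus:
    """The trait locus under mapping (a fully penetrant recessive by default)."""

    name: str
    pos_bp: int
    pos_cM: float
    mode: str = "recessive"
    penetrance: float = 1.0

    def __post_init__(self):
        if self.mode != "recessive":
            raise ValidationError("only recessive trait loci are supported")
        if not 0 < self.penetrance <= 1:
            raise ValidationError(f"penetrance must be in (0, 1]: {self.penetrance}")


@dataclass
class Progeny:
    """One N2 animal: phenotype plus per-marker genotype codes."""

    id: str
    phenotype: str
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype {self.phenotype!r}")
        bad = {g for g in self.genotypes.values()} - GENOTYPE_CODES
        if bad:
            raise ValidationError(f"unknown genotype codes {sorted(bad)}")


@dataclass
class BackcrossPanel:
    """A testcross family: map, trait name, and the typed progeny."""

    map: GeneticMap
    trait: str
    progeny: list[Progeny]
    seed: int | None = None

    def __post_init__(self):
        names = set(self.map.names)
        for p in self.progeny:
            extra = set(p.genotypes) - names
            if extra:
                raise ValidationError(
                    f"progeny {p.id} typed at markers not in map: {sorted(extra)}"
                )

    @property
    def n(self) -> int:
        return len(self.progeny)

    def phenotype_counts(self) -> tuple[int, int]:
        mut = sum(1 for p in self.progeny if p.phenotype == "mutant")
        return mut, len(self.progeny) - mut


def make_marker_map(
    n_markers: int,
    span_bp: int,
    cm_per_mb: float = 0.5,
    positions_bp: Sequence[int] | None = None,
    chrom: str = "chr11",
    names: Sequence[str] | None = None,
) -> GeneticMap:
    """Build a single-chromosome map with pos_cM = pos_bp * cm_per_mb / 1e6.

    Markers are evenly spaced over ``[0, span_bp]`` unless explicit
    ``positions_bp`` are supplied (which must be strictly increasing).
    """
    if n_markers < 2:
        raise ValidationError("need at least 2 markers")
    if span_bp <= 0:
        raise ValidationError("span_bp must be positive")
    if cm_per_mb <= 0:
        raise ValidationError("cm_per_mb must be positive")
    if positions_bp is None:
        positions_bp = [round(i * span_bp / (n_markers - 1)) for i in range(n_markers)]
    else:
        positions_bp = list(positions_bp)
        if len(positions_bp) != n_markers:
            raise ValidationError("positions_bp length must equal n_markers")
        if any(b <= a for a, b in zip(positions_bp, positions_bp[1:])):
            raise ValidationError("positions_bp must be strictly increasing")
        if positions_bp[0] < 0 or positions_bp[-1] > span_bp:
            raise ValidationError("positions_bp must lie within [0, span_bp]")
    if names is None:
        names = [f"M{i + 1}" for i in range(n_markers)]
    markers = [
        Marker(name, chrom, int(bp), bp * cm_per_mb / 1e6)
        for name, bp in zip(names, positions_bp)
    ]
    return GeneticMap(chrom=chrom, markers=markers, cm_per_mb=cm_per_mb)


def _transmitted_alleles(
    positions_cm: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate dam-derived alleles at ordered loci for n meioses.

    Returns a boolean (n, L) matrix, True where the dam transmitted the A
    allele.  The first locus is A or N with probability 1/2; the allele then
    switches across each interval with the Haldane probability for the
    interval's cM length.
    """
    L = len(positions_cm)
    is_a = np.empty((n, L), dtype=bool)
    is_a[:, 0] = rng.random(n) < 0.5
    d_morgans = np.diff(positions_cm) / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    if L > 1:
        switches = rng.random((n, L - 1)) < r[None, :]
        for j in range(1, L):
            is_a[:, j] = is_a[:, j - 1] ^ switches[:, j - 1]
    return is_a


def simulate_backcross(
    gmap: GeneticMap,
    trait: TraitLocus,
    n: int,
    genotyping_error: float = 0.0,
    seed: int = 0,
) -> BackcrossPanel:
    """Simulate a testcross panel of ``n`` progeny.

    Phenotype is mutant iff the dam transmitted the mutant (N-derived)
    allele at the trait locus, masked by penetrance.  Genotype is H iff the
    dam transmitted the A allele at the marker, else N; ``genotyping_error``
    flips each genotype call independently.  The same seed yields an
    identical panel.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if genotyping_error < 0 or genotyping_error >= 1:
        raise ValidationError("genotyping_error must be in [0, 1)")
    lo, hi = gmap.span_bp
    if not lo <= trait.pos_bp <= hi:
        raise ValidationError(
            f"trait position {trait.pos_bp} outside map span [{lo}, {hi}]"
        )

    rng = np.random.default_rng(seed)
    # insert the trait as a pseudo-locus in cM order
    loci_cm = [m.pos_cM for m in gmap.markers]
    trait_idx = int(np.searchsorted(loci_cm, trait.pos_cM))
    positions = np.asarray(loci_cm[:trait_idx] + [trait.pos_cM] + loci_cm[trait_idx:])
    is_a = _transmitted_alleles(positions, n, rng)

    dam_a_at_trait = is_a[:, trait_idx]
    marker_a = np.delete(is_a, trait_idx, axis=1)

    # recessive trait: mutant phenotype requires the dam's mutant (N) allele,
    # expressed with probability = penetrance
    expressed = rng.random(n) < trait.penetrance
    mutant = (~dam_a_at_trait) & expressed

    if genotyping_error > 0:
        flips = rng.random(marker_a.shape) < genotyping_error
        marker_a = marker_a ^ flips

    width = max(4, len(str(n)))
    names = gmap.names
    progeny = []
    for i in range(n):
        genos = {
            name: (GENO_HET if marker_a[i, j] else GENO_HOM)
            for j, name in enumerate(names)
        }
        progeny.append(
            Progeny(
                id=f"N2-{i + 1:0{width}d}",
                phenotype="mutant" if mutant[i] else "normal",
                genotypes=genos,
            )
        )
    return BackcrossPanel(map=gmap, trait=trait.name, progeny=progeny, seed=seed)
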