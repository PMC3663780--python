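"""Rule-based candidate-gene triage for a critical interval.

The rules mirror how positional-cloning studies prune an interval gene
list on published evidence alone: a gene whose engineered null allele
leaves the coat normal cannot explain a fully penetrant coat phenotype; a
gene with no evidence of skin expression is deprioritized; genes isolated
from skin cDNA libraries are the primary candidates.  Exclusion is only
ever on positive evidence — genes with unknown annotations are kept as
weak candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from woolmap.errors import ValidationError

EVIDENCE_LEVELS = ("cdna_library", "other", "none", "unknown")

# fixed precedence of exclusion reasons, applied regardless of input order
REASON_PRECEDENCE = ("outside_interval", "knockout_normal_coat", "no_skin_role")


@dataclass(frozen=True)
class AnnotatedGene:
    """One interval gene with the two annotations the rules consume.

    ``null_allele_coat_normal`` is True/False/None (None = unknown);
    ``skin_expression_evidence`` is one of ``EVIDENCE_LEVELS``.
    """

    name: str
    start_bp: int
    end_bp: int
    null_allele_coat_normal: bool | None = None
    skin_expression_evidence: str = "unknown"

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValidationError(f"gene {self.name}: start must precede end")
        if self.skin_expression_evidence not in EVIDENCE_LEVELS:
            raise ValidationError(
                f"gene {self.name}: unknown evidence level "
                f"{self.skin_expression_evidence!r}"
            )


@dataclass
class TriageResult:
    """Partition of the input genes into excluded and primary candidates."""

    excluded: list[tuple[str, str]] = field(default_factory=list)
    primary: list[str] = field(default_factory=list)
    weak_evidence: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded": [list(t) for t in self.excluded],
            "primary": list(self.primary),
            "weak_evidence": list(self.weak_evidence),
            "warnings": list(self.warnings),
        }


def triage(genes: list[AnnotatedGene], interval: tuple[int, int]) -> TriageResult:
    """Apply the exclusion rules to ``genes`` against a critical interval.

    Interval membership uses any-overlap, half-open coordinates.  Exclusion
    reasons follow the fixed precedence ``outside_interval >
    knockout_normal_coat > no_skin_role``; results are sorted by gene start
    so input order is irrelevant.
    """
    lo, hi = interval
    if lo >= hi:
        raise ValidationError(f"invalid interval ({lo}, {hi})")
    result = TriageResult()
    if not genes:
        result.warnings.append("empty gene list")
        return result
    for g in sorted(genes, key=lambda g: (g.start_bp, g.name)):
        if g.end_bp <= lo or g.start_bp >= hi:
            result.excluded.append((g.name, "outside_interval"))
        elif g.null_allele_coat_normal is True:
            result.excluded.append((g.name, "knockout_normal_coat"))
        elif g.skin_expression_evidence == "none":
            result.excluded.append((g.name, "no_skin_role"))
        else:
            result.primary.append(g.name)
            if g.skin_expression_evidence != "cdna_library":
                result.weak_evidence.append(g.name)
    return result
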