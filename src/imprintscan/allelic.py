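"""Parent-of-origin validation logic for candidate imprinted regions.

Given a mother-child pair heterozygous in the child and homozygous in the
mother at a nearby SNP, each child allele can be assigned to a parent; the
allelic ratio of a methylation or expression readout then tests whether the
region behaves monoallelically and whether the silenced allele matches the
parental origin predicted by the DMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    ConfigError,
    MendelianInconsistencyError,
    UndefinedValueError,
    ValidationError,
)

_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class MotherChildGenotype:
    snp_id: str
    maternal_genotype: tuple[str, str]
    child_genotype: tuple[str, str]
    allele_measure: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for g in (self.maternal_genotype, self.child_genotype):
            if not set(g) <= _ALLELES:
                raise ValidationError(f"alleles must be A/C/G/T, got {g}")
        if any(v < 0 for v in self.allele_measure.values()):
            raise ValidationError("allele measures must be non-negative")


@dataclass(frozen=True)
class BisulphiteClone:
    clone_id: str
    cpg_states: tuple[bool, ...]  # True = methylated
    conversion_rate: float

    def __post_init__(self):
        if not 0 <= self.conversion_rate <= 1:
            raise ValidationError("conversion_rate must lie in [0, 1]")


def _check_mendelian(g: MotherChildGenotype) -> None:
    if not set(g.maternal_genotype) & set(g.child_genotype):
        raise MendelianInconsistencyError(
            f"{g.snp_id}: child {g.child_genotype} shares no allele with "
            f"mother {g.maternal_genotype}"
        )


def is_informative(g: MotherChildGenotype) -> bool:
    """Informative for parental origin: child heterozygous, mother homozygous."""
    _check_mendelian(g)
    child_het = g.child_genotype[0] != g.child_genotype[1]
    mother_hom = g.maternal_genotype[0] == g.maternal_genotype[1]
    return child_het and mother_hom


def infer_parental_alleles(g: MotherChildGenotype) -> tuple[str, str]:
    """(maternal allele, paternal allele) for an informative pair: the child
    allele carried by the homozygous mother is maternal, the other paternal."""
    if not is_informative(g):
        raise ValidationError(f"{g.snp_id}: pair is not informative")
    maternal = g.maternal_genotype[0]
    paternal = next(a for a in g.child_genotype if a != maternal)
    return maternal, paternal


def allelic_ratio(measure_a: float, measure_b: float) -> float:
    """Minor-allele fraction min(a, b) / (a + b), in [0, 0.5]; symmetric."""
    if measure_a < 0 or measure_b < 0:
        raise ValidationError("measures must be non-negative")
    total = measure_a + measure_b
    if total == 0:
        raise UndefinedValueError("allelic ratio undefined: both measures zero")
    return min(measure_a, measure_b) / total


def call_monoallelic(ratio: float, threshold: float = 0.3) -> bool:
    """Monoallelic iff the minor-allele fraction is strictly below threshold."""
    if not 0 <= ratio <= 0.5:
        raise ValidationError("ratio must lie in [0, 0.5]")
    return ratio < threshold


def expression_concordance(expressed_allele_parent: str, dmr_origin: str) -> str:
    """'matched' iff the expressed parent differs from the DMR-methylated
    parent (promoter methylation is assumed silencing), else 'opposite'."""
    for label in (expressed_allele_parent, dmr_origin):
        if label not in ("maternal", "paternal"):
            raise ConfigError(f"label must be maternal/paternal, got {label!r}")
    return "matched" if expressed_allele_parent != dmr_origin else "opposite"


def filter_clones(
    clones: list[BisulphiteClone], min_conversion: float = 0.8
) -> list[BisulphiteClone]:
    """Keep clones with bisulphite conversion rate >= min_conversion
    (inclusive boundary: a clone at exactly the cutoff survives)."""
    if not 0 <= min_conversion <= 1:
        raise ConfigError("min_conversion must lie in [0, 1]")
    return [c for c in clones if c.conversion_rate >= min_conversion]
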