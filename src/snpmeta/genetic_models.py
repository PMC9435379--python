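"""Genetic-model contrasts: collapse genotype counts to 2x2 tables.

Four contrasts are supported for a biallelic SNP with coded allele A:

* ``allele``    — A vs G, counting two alleles per person (A = 2*AA + AG);
* ``recessive`` — AA vs AG+GG;
* ``dominant``  — AA+AG vs GG;
* ``additive``  — AA vs GG, the genotypic extreme contrast that discards
  heterozygotes.  This follows the source analysis's usage of the label;
  it is not a Cochran-Armitage trend test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io_studies import StudyRecord


class GeneticModel(str, enum.Enum):
    ALLELE = "allele"
    RECESSIVE = "recessive"
    DOMINANT = "dominant"
    ADDITIVE = "additive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CountsUnavailableError(ValueError):
    """Raised when a contrast is requested for a record without genotype
    counts; callers should use the reported effect directly instead."""


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 exposure-by-status count table for one study under one model.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.  Under the allele model the units are alleles (two per
    person); under the additive contrast heterozygous individuals are absent
    from both margins.
    """

    model: GeneticModel
    a: int
    b: int
    c: int
    d: int
    study_id: str = ""
    snp_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contrast table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def allele_counts(genotypes: tuple[int, int, int]) -> tuple[int, int]:
    """Collapse an (AA, AG, GG) genotype triple to (A, G) allele counts."""
    aa, ag, gg = genotypes
    if min(aa, ag, gg) < 0:
        raise ValueError("genotype counts must be non-negative")
    return (2 * aa + ag, 2 * gg + ag)


def _collapse(genotypes: tuple[int, int, int], model: GeneticModel
              ) -> tuple[int, int]:
    aa, ag, gg = genotypes
    if model is GeneticModel.ALLELE:
        return allele_counts(genotypes)
    if model is GeneticModel.RECESSIVE:
        return (aa, ag + gg)
    if model is GeneticModel.DOMINANT:
        return (aa + ag, gg)
    if model is GeneticModel.ADDITIVE:
        return (aa, gg)
    raise ValueError(f"unknown genetic model: {model!r}")


def build_contrast(record: StudyRecord, model: GeneticModel | str) -> ContrastTable:
    """Build the 2x2 contrast table for one study under one genetic model."""
    model = GeneticModel(model)
    if not record.has_counts:
        raise CountsUnavailableError(
            f"{record.study_id}/{record.snp_id}: genotype counts unavailable; "
            "use the reported effect directly"
        )
    a, b = _collapse(record.case_counts, model)
    c, d = _collapse(record.control_counts, model)
    return ContrastTable(model=model, a=a, b=b, c=c, d=d,
                         study_id=record.study_id, snp_id=record.snp_id)
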