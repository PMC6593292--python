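"""Genotype call containers shared by the parser and the caller.

A :class:`GenotypeCall` is the unit of output of both the genotype-string
parser (for tabulated genotypes) and the qPCR allele caller.  SNP loci
take one of ``hom_ref`` / ``het`` / ``hom_alt``; the gene-deletion locus
is only observable as ``present`` / ``absent``; ``no_call`` covers every
QC failure and always carries at least one flag or a free-text reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, FrozenSet

if TYPE_CHECKING:  # pragma: no cover
    from .panel import MiHALocus


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    PRESENT = "present"
    ABSENT = "absent"
    NO_CALL = "no_call"


class Flag(enum.Enum):
    LOW_RFU = "low_rfu"
    CONTROL_FAIL = "control_fail"
    REPLICATE_DISCORDANT = "replicate_discordant"
    PARSED_WARNING = "parsed_warning"


@dataclass(frozen=True)
class GenotypeCall:
    """One per-locus genotype with QC annotations."""

    locus: "MiHALocus"
    genotype: Genotype
    flags: FrozenSet[Flag] = field(default_factory=frozenset)
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.genotype in (Genotype.PRESENT, Genotype.ABSENT):
            if self.locus.locus_kind.value != "gene_deletion":
                raise ValueError(
                    f"{self.genotype.value} is only valid for the gene-deletion "
                    f"locus, not {self.locus.name}"
                )
        if self.genotype is Genotype.NO_CALL and not self.flags and not self.reason:
            raise ValueError("no_call requires at least one flag or a reason")

    @property
    def is_no_call(self) -> bool:
        return self.genotype is Genotype.NO_CALL

    def alleles(self) -> frozenset[str]:
        """Set of nucleotide alleles carried (SNP loci only).

        For the deletion locus ``present`` maps to {Im} and ``absent``
        to {No}, mirroring the tabulated notation.
        """
        g = self.genotype
        loc = self.locus
        if g is Genotype.HOM_REF:
            return frozenset({loc.ref_allele})
        if g is Genotype.HOM_ALT:
            return frozenset({loc.alt_allele})
        if g is Genotype.HET:
            return frozenset({loc.ref_allele, loc.alt_allele})
        if g is Genotype.PRESENT:
            return frozenset({loc.ref_allele})
        if g is Genotype.ABSENT:
            return frozenset({loc.alt_allele})
        raise ValueError("no_call has no allele set")

    def carries(self, allele: str) -> bool:
        return allele in self.alleles()

    def is_homozygous_for(self, allele: str) -> bool:
        return self.alleles() == frozenset({allele})

    def with_flags(self, *flags: Flag) -> "GenotypeCall":
        return GenotypeCall(
            self.locus, self.genotype, self.flags | frozenset(flags), self.reason
        )
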