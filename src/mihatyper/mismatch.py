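"""Graft-versus-host MiHA mismatch imputation for donor-recipient pairs.

A locus is mismatched in the GvH direction when the recipient carries at
least one copy of the allele known to be immunogenic in vivo while the
donor is homozygous for the alternative allele — then donor T cells meet
a recipient peptide they were never tolerized against.  For the
gene-deletion locus the same logic reads: recipient gene-present, donor
homozygous deleted.  Mismatches are unidirectional; potentially
co-dominant loci where the donor-only allele might be immunogenic in the
reverse (rejection) direction are annotated but never counted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from .calls import Genotype, GenotypeCall
from .errors import InputError
from .panel import MiHALocus, PanelDefinition


class Verdict(enum.Enum):
    MISMATCH = "mismatch"
    NO_MISMATCH = "no_mismatch"
    INDETERMINATE = "indeterminate"


class PairType(enum.Enum):
    RELATED = "related"
    UNRELATED = "unrelated"


def is_gvh_mismatch(
    locus: MiHALocus, recipient: GenotypeCall, donor: GenotypeCall
) -> Verdict:
    """Apply the GvH mismatch rule to one locus.

    Mismatch iff the recipient carries the immunogenic allele and the
    donor is homozygous for the non-immunogenic allele (deletion locus:
    recipient present, donor absent).  Any ``no_call`` on either side
    makes the locus indeterminate.
    """
    if recipient.locus.name != locus.name or donor.locus.name != locus.name:
        raise InputError(
            f"calls for {recipient.locus.name}/{donor.locus.name} "
            f"do not belong to locus {locus.name}"
        )
    if recipient.is_no_call or donor.is_no_call:
        return Verdict.INDETERMINATE
    if recipient.carries(locus.immunogenic_allele) and donor.is_homozygous_for(
        locus.nonimmunogenic_allele
    ):
        return Verdict.MISMATCH
    return Verdict.NO_MISMATCH


@dataclass(frozen=True)
class PairReport:
    """Per-locus GvH verdicts and the mismatch total for one pair."""

    pair_id: str
    pair_type: PairType
    recipient_id: str
    donor_id: str
    per_locus: Mapping[str, Verdict]
    recipient_calls: Mapping[str, GenotypeCall]
    donor_calls: Mapping[str, GenotypeCall]
    reverse_annotations: tuple[str, ...] = ()

    @property
    def total_mm(self) -> int:
        """Number of loci with a GvH mismatch verdict (indeterminate
        loci are never counted)."""
        return sum(1 for v in self.per_locus.values() if v is Verdict.MISMATCH)

    @property
    def n_indeterminate(self) -> int:
        return sum(1 for v in self.per_locus.values() if v is Verdict.INDETERMINATE)

    @property
    def n_evaluable(self) -> int:
        return len(self.per_locus) - self.n_indeterminate

    @property
    def indeterminate_loci(self) -> tuple[str, ...]:
        return tuple(
            n for n, v in self.per_locus.items() if v is Verdict.INDETERMINATE
        )

    def rows(self):
        """Iterate (locus, (recipient call, donor call, verdict)) in order."""
        for name, verdict in self.per_locus.items():
            yield name, (self.recipient_calls[name], self.donor_calls[name], verdict)


def build_pair_report(
    recipient_calls: Sequence[GenotypeCall],
    donor_calls: Sequence[GenotypeCall],
    pair_type: PairType | str = PairType.UNRELATED,
    pair_id: str = "",
    recipient_id: str = "recipient",
    donor_id: str = "donor",
    panel: PanelDefinition | None = None,
) -> PairReport:
    """Evaluate the GvH rule across a panel for one donor-recipient pair.

    Both call sets must cover the same loci (the full panel when
    ``panel`` is given).  The reverse direction — donor carries an
    allele the recipient lacks at a locus whose alternative peptide may
    also be presented — is recorded as annotations only.
    """
    if isinstance(pair_type, str):
        pair_type = PairType(pair_type.lower())
    rec = {c.locus.name: c for c in recipient_calls}
    don = {c.locus.name: c for c in donor_calls}
    if set(rec) != set(don):
        raise InputError(
            "recipient and donor call sets cover different loci",
            sorted(set(rec) ^ set(don)),
        )
    if panel is not None:
        missing = [n for n in panel.locus_names if n not in rec]
        if missing:
            raise InputError("call sets do not cover the panel", missing)
        order = panel.locus_names
    else:
        order = tuple(c.locus.name for c in recipient_calls)

    per_locus: dict[str, Verdict] = {}
    reverse: list[str] = []
    for name in order:
        locus = rec[name].locus
        per_locus[name] = is_gvh_mismatch(locus, rec[name], don[name])
        # reverse (rejection-direction) annotation: donor carries the
        # non-immunogenic allele's peptide the recipient entirely lacks
        if not rec[name].is_no_call and not don[name].is_no_call:
            if don[name].carries(locus.nonimmunogenic_allele) and rec[
                name
            ].is_homozygous_for(locus.immunogenic_allele):
                reverse.append(name)
    return PairReport(
        pair_id=pair_id or f"{recipient_id}/{donor_id}",
        pair_type=pair_type,
        recipient_id=recipient_id,
        donor_id=donor_id,
        per_locus=per_locus,
        recipient_calls=rec,
        donor_calls=don,
        reverse_annotations=tuple(reverse),
    )
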