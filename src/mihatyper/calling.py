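"""Allele calling from paired REF/ALT allele-specific qPCR reactions.

Each SNP locus is interrogated in two wells of the same multiplex panel:
one carrying the allele-specific primer (ASP) for the reference allele,
one for the alternative allele.  A reaction is *positive* when it
crosses the detection threshold before 30 cycles with an end-point
signal of at least 300 RFU.  Calling then proceeds per locus:

* both reactions positive and within 2 cycles of each other -> het;
* both positive but one leads by >= 2 cycles -> homozygous for the
  earlier allele (the lagging signal is ASP cross-reaction on the
  mismatched template);
* exactly one positive -> homozygous for that allele;
* both negative -> no call (assay failure, not a genotype).

The B2M internal control in channel 5 gates each panel: its Cq values
in the two wells must agree within 1.5 cycles, otherwise all four loci
of that panel are voided for the sample.  The gene-deletion locus
(UGT2B17) uses identical primers in both wells, so double-negative is
the informative homozygous-deletion state rather than a failure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .calls import Flag, Genotype, GenotypeCall
from .errors import InputError
from .panel import MiHALocus, PanelDefinition
from .qpcr_io import DEFAULT_MAX_CYCLES, MixGroup, WellRecord


@dataclass(frozen=True)
class CallingConfig:
    """Decision thresholds for reaction classification and calling.

    positivity_cq
        Cq below which a reaction counts as positive (cycles).
    hom_delta_cq
        Lead in cycles at which the earlier of two positive reactions
        overrides a heterozygous call.
    control_delta_cq
        Maximum allowed disagreement between the two B2M control Cqs.
    min_rfu
        End-point fluorescence floor; weaker wells are discarded.
    max_cycles
        Length of the run; Cq values beyond it are input errors.
    """

    positivity_cq: float = 30.0
    hom_delta_cq: float = 2.0
    control_delta_cq: float = 1.5
    min_rfu: float = 300.0
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        if min(self.positivity_cq, self.hom_delta_cq, self.control_delta_cq,
               self.min_rfu, self.max_cycles) <= 0:
            raise ValueError("all calling thresholds must be positive")
        if self.positivity_cq > self.max_cycles:
            raise ValueError("positivity_cq cannot exceed max_cycles")


class ReactionStatus(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INVALID = "invalid"


@dataclass(frozen=True)
class ReactionResult:
    """Classified outcome of one allele-specific reaction."""

    status: ReactionStatus
    cq: float | None = None
    end_rfu: float = 0.0

    @property
    def is_positive(self) -> bool:
        return self.status is ReactionStatus.POSITIVE

    @property
    def is_invalid(self) -> bool:
        return self.status is ReactionStatus.INVALID


def classify_reaction(
    cq: float | None, end_rfu: float, cfg: CallingConfig | None = None
) -> ReactionResult:
    """Classify a single reaction as positive, negative, or invalid.

    The RFU floor is checked first: a well below ``min_rfu`` is invalid
    regardless of Cq.  Otherwise the reaction is positive iff it crossed
    the threshold before ``positivity_cq`` cycles; an absent Cq (no
    crossing within the run) is negative.
    """
    cfg = cfg or CallingConfig()
    if end_rfu < 0:
        raise InputError(f"negative end-point RFU {end_rfu}")
    if cq is not None and cq > cfg.max_cycles:
        raise InputError(f"Cq {cq} exceeds run length {cfg.max_cycles}")
    if end_rfu < cfg.min_rfu:
        return ReactionResult(ReactionStatus.INVALID, cq, end_rfu)
    if cq is None or cq >= cfg.positivity_cq:
        return ReactionResult(ReactionStatus.NEGATIVE, cq, end_rfu)
    return ReactionResult(ReactionStatus.POSITIVE, cq, end_rfu)


def check_internal_control(
    b2m_ref: ReactionResult, b2m_alt: ReactionResult, cfg: CallingConfig | None = None
) -> bool:
    """Gate a panel on its B2M control wells.

    Passes iff both control reactions recorded a Cq, neither failed the
    RFU floor, and the Cqs agree to within ``control_delta_cq`` cycles
    (a larger gap suggests evaporation or pipetting failure in one well).
    Exactly at the limit counts as a failure.
    """
    cfg = cfg or CallingConfig()
    if b2m_ref.is_invalid or b2m_alt.is_invalid:
        return False
    if b2m_ref.cq is None or b2m_alt.cq is None:
        return False
    return abs(b2m_ref.cq - b2m_alt.cq) < cfg.control_delta_cq


def call_snp_locus(
    locus: MiHALocus,
    ref_rx: ReactionResult,
    alt_rx: ReactionResult,
    control_ok: bool,
    cfg: CallingConfig | None = None,
) -> GenotypeCall:
    """Call one SNP locus from its REF-well and ALT-well reactions."""
    cfg = cfg or CallingConfig()
    if locus.is_deletion:
        raise ValueError(f"{locus.name} is a deletion locus; use call_deletion_locus")
    if not control_ok:
        return GenotypeCall(locus, Genotype.NO_CALL, frozenset({Flag.CONTROL_FAIL}))
    if ref_rx.is_invalid or alt_rx.is_invalid:
        return GenotypeCall(locus, Genotype.NO_CALL, frozenset({Flag.LOW_RFU}))
    ref_pos, alt_pos = ref_rx.is_positive, alt_rx.is_positive
    if ref_pos and alt_pos:
        delta = ref_rx.cq - alt_rx.cq
        if abs(delta) >= cfg.hom_delta_cq:
            geno = Genotype.HOM_REF if delta < 0 else Genotype.HOM_ALT
        else:
            geno = Genotype.HET
        return GenotypeCall(locus, geno)
    if ref_pos:
        return GenotypeCall(locus, Genotype.HOM_REF)
    if alt_pos:
        return GenotypeCall(locus, Genotype.HOM_ALT)
    return GenotypeCall(
        locus, Genotype.NO_CALL, reason="no amplification in either well"
    )


def call_deletion_locus(
    locus: MiHALocus,
    rx1: ReactionResult,
    rx2: ReactionResult,
    control_ok: bool,
    cfg: CallingConfig | None = None,
) -> GenotypeCall:
    """Call the gene-deletion locus from its duplicate reactions.

    Both wells run the same primers, so the two reactions are technical
    replicates: double-negative means homozygous deletion, any positive
    means the gene is present.  A positive/negative split is still
    called present (one specific amplification is positive evidence) but
    flagged ``replicate_discordant``.
    """
    if not locus.is_deletion:
        raise ValueError(f"{locus.name} is a SNP locus; use call_snp_locus")
    if not control_ok:
        return GenotypeCall(locus, Genotype.NO_CALL, frozenset({Flag.CONTROL_FAIL}))
    if rx1.is_invalid or rx2.is_invalid:
        return GenotypeCall(locus, Genotype.NO_CALL, frozenset({Flag.LOW_RFU}))
    pos = rx1.is_positive + rx2.is_positive
    if pos == 0:
        return GenotypeCall(locus, Genotype.ABSENT)
    if pos == 2:
        return GenotypeCall(locus, Genotype.PRESENT)
    return GenotypeCall(
        locus, Genotype.PRESENT, frozenset({Flag.REPLICATE_DISCORDANT})
    )


def _index_wells(
    wells: Iterable[WellRecord],
) -> dict[tuple[int, MixGroup, int], WellRecord]:
    indexed: dict[tuple[int, MixGroup, int], WellRecord] = {}
    dupes = []
    for w in wells:
        key = (w.panel_index, w.mix_group, w.channel)
        if key in indexed:
            dupes.append(f"panel {key[0]} {key[1].value} channel {key[2]}")
        indexed[key] = w
    if dupes:
        raise InputError("duplicate readouts for sample", dupes)
    return indexed


def call_sample(
    wells: Sequence[WellRecord],
    panel: PanelDefinition,
    cfg: CallingConfig | None = None,
) -> list[GenotypeCall]:
    """Call all panel loci for one sample from its well records.

    Wells are grouped per multiplex panel; the B2M control gate is
    evaluated once per panel and scopes only that panel's four loci.
    A missing well or missing control readout voids the affected panel
    (``control_fail``) rather than the whole sample.  Output is one
    call per locus in panel order, deterministically.
    """
    cfg = cfg or CallingConfig()
    samples = {w.sample_id for w in wells}
    if len(samples) > 1:
        raise InputError("call_sample got wells from multiple samples", sorted(samples))
    indexed = _index_wells(wells)

    calls: list[GenotypeCall] = []
    for panel_index in panel.panel_indices:
        loci = panel.loci_in_panel(panel_index)

        def rx_at(mix: MixGroup, channel: int) -> ReactionResult | None:
            well = indexed.get((panel_index, mix, channel))
            if well is None:
                return None
            return classify_reaction(well.cq, well.end_rfu, cfg)

        ctrl_ref = rx_at(MixGroup.REF, panel.control_channel)
        ctrl_alt = rx_at(MixGroup.ALT, panel.control_channel)
        missing_control = ctrl_ref is None or ctrl_alt is None
        control_ok = (
            False
            if missing_control
            else check_internal_control(ctrl_ref, ctrl_alt, cfg)
        )
        for locus in loci:
            rx_ref = rx_at(MixGroup.REF, locus.channel)
            rx_alt = rx_at(MixGroup.ALT, locus.channel)
            if rx_ref is None or rx_alt is None:
                calls.append(
                    GenotypeCall(
                        locus,
                        Genotype.NO_CALL,
                        frozenset({Flag.CONTROL_FAIL}),
                        reason=f"missing well in panel {panel_index}",
                    )
                )
                continue
            if locus.is_deletion:
                calls.append(call_deletion_locus(locus, rx_ref, rx_alt, control_ok, cfg))
            else:
                calls.append(call_snp_locus(locus, rx_ref, rx_alt, control_ok, cfg))
    order = {name: i for i, name in enumerate(panel.locus_names)}
    calls.sort(key=lambda c: order[c.locus.name])
    return calls


@dataclass(frozen=True)
class ConcordanceSummary:
    """Comparison of two call sets over the same (sample, locus) points."""

    n_total: int
    n_compared: int
    n_excluded: int
    discordances: tuple[tuple[str, str, str], ...] = ()  # (key, call_a, call_b)

    @property
    def n_discordant(self) -> int:
        return len(self.discordances)


def concordance(
    calls_a: Sequence[GenotypeCall],
    calls_b: Sequence[GenotypeCall],
    keys: Sequence[str] | None = None,
) -> ConcordanceSummary:
    """Compare two aligned call sets point by point.

    Points where either side is ``no_call`` are excluded from the
    comparison (``n_compared + n_excluded = n_total``); every remaining
    disagreement is listed with both calls.  ``keys`` optionally labels
    the points (defaults to ``index:locus``).
    """
    if len(calls_a) != len(calls_b):
        raise InputError(
            f"call sets differ in length ({len(calls_a)} vs {len(calls_b)})"
        )
    mism = [
        f"position {i}: {a.locus.name} vs {b.locus.name}"
        for i, (a, b) in enumerate(zip(calls_a, calls_b))
        if a.locus.name != b.locus.name
    ]
    if mism:
        raise InputError("call sets cover different loci", mism)
    if keys is None:
        keys = [f"{i}:{a.locus.name}" for i, a in enumerate(calls_a)]

    compared = 0
    excluded = 0
    discordances = []
    for key, a, b in zip(keys, calls_a, calls_b):
        if a.is_no_call or b.is_no_call:
            excluded += 1
            continue
        compared += 1
        if a.genotype is not b.genotype:
            discordances.append((key, a.genotype.value, b.genotype.value))
    return ConcordanceSummary(
        n_total=len(calls_a),
        n_compared=compared,
        n_excluded=excluded,
        discordances=tuple(discordances),
    )
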