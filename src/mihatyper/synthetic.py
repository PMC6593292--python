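"""Ground-truthed synthetic genotypes, pairs, and qPCR plates.

The generator emulates the signal structure of multiplex allele-specific
qPCR wells well enough to exercise every branch of the caller:

* a specific reaction crosses around ``base_cq`` cycles;
* the mismatched-primer (non-specific) reaction of a homozygote trails
  the specific one by ``nonspecific_delta_cq`` cycles — the allele
  discrimination margin of a well-designed allele-specific primer — and
  is dropped entirely if that pushes it past the run length;
* heterozygotes present half the template per allele, so both wells
  shift later by ``het_shift`` (one template doubling ~ one cycle);
* the deletion locus amplifies in both wells when the gene is present
  and in neither when it is absent;
* the B2M control amplifies in every well near ``b2m_cq``.

Failure artifacts are injected at configurable rates: *evaporation*
delays one whole well (control and targets) past the control-agreement
gate, *low RFU* crushes a readout's plateau below the calling floor,
and *dropout* removes a readout's threshold crossing altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .calls import Genotype, GenotypeCall
from .errors import InputError
from .panel import FrequencyTable, PanelDefinition
from .qpcr_io import DEFAULT_MAX_CYCLES, MixGroup, PlateLayout, WellRecord

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


@dataclass(frozen=True)
class NoiseConfig:
    """Signal and artifact model for synthetic plates.

    All Cq quantities are in cycles, fluorescence in RFU.  Defaults are
    a clean assay: tight replicate scatter (sd 0.3), a 4.9-cycle
    allele-discrimination margin, bright plateaus, and no artifacts.
    """

    base_cq: float = 24.0
    cq_sd: float = 0.3
    het_shift: float = 1.0
    nonspecific_delta_cq: float = 4.9
    plateau_rfu_mean: float = 1500.0
    plateau_rfu_sd: float = 200.0
    b2m_cq: float = 21.0
    evaporation_rate: float = 0.0
    low_rfu_rate: float = 0.0
    dropout_rate: float = 0.0
    max_cycles: float = DEFAULT_MAX_CYCLES
    evaporation_shift: float = 3.0  # cycles added to an evaporated well

    def __post_init__(self) -> None:
        if self.nonspecific_delta_cq < 0:
            raise InputError("nonspecific_delta_cq must be >= 0")
        for rate in (self.evaporation_rate, self.low_rfu_rate, self.dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise InputError(f"artifact rate {rate} outside [0, 1]")
        if self.cq_sd < 0 or self.plateau_rfu_sd < 0:
            raise InputError("standard deviations must be >= 0")


def _draw_genotype(p_imm: float, rng: np.random.Generator) -> int:
    """Immunogenic-allele dosage of one HWE individual."""
    return int(rng.binomial(2, p_imm))


def _dosage_to_call(locus, dosage: int) -> GenotypeCall:
    if locus.is_deletion:
        geno = Genotype.PRESENT if dosage >= 1 else Genotype.ABSENT
    else:
        imm_is_ref = locus.immunogenic_allele == locus.ref_allele
        if dosage == 1:
            geno = Genotype.HET
        elif dosage == 2:
            geno = Genotype.HOM_REF if imm_is_ref else Genotype.HOM_ALT
        else:
            geno = Genotype.HOM_ALT if imm_is_ref else Genotype.HOM_REF
    return GenotypeCall(locus, geno)


def simulate_genotype_vector(
    freqs: FrequencyTable,
    panel: PanelDefinition,
    seed: int | np.random.Generator,
) -> list[GenotypeCall]:
    """Draw one individual's panel genotypes under HWE.

    The deletion locus is drawn as a biallelic presence/deletion marker
    but reported only as present/absent, matching what the assay can
    observe.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    probs = freqs.for_panel(panel)
    return [
        _dosage_to_call(locus, _draw_genotype(p, rng))
        for locus, p in zip(panel.loci, probs)
    ]


def simulate_pair(
    freqs: FrequencyTable,
    panel: PanelDefinition,
    pair_type: str,
    seed: int | np.random.Generator,
) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
    """Draw a (recipient, donor) genotype pair.

    ``related`` pairs are siblings: per locus two HWE parents are drawn
    and each child receives one Mendelian allele from each parent.
    ``unrelated`` pairs are two independent HWE draws.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    probs = freqs.for_panel(panel)
    rec, don = [], []
    for locus, p in zip(panel.loci, probs):
        if pair_type == "related":
            g1, g2 = rng.binomial(2, p), rng.binomial(2, p)
            d_rec = int(rng.binomial(1, g1 / 2.0) + rng.binomial(1, g2 / 2.0))
            d_don = int(rng.binomial(1, g1 / 2.0) + rng.binomial(1, g2 / 2.0))
        elif pair_type == "unrelated":
            d_rec, d_don = _draw_genotype(p, rng), _draw_genotype(p, rng)
        else:
            raise InputError(f"unknown pair type {pair_type!r}")
        rec.append(_dosage_to_call(locus, d_rec))
        don.append(_dosage_to_call(locus, d_don))
    return rec, don


def _well_name(index: int) -> str:
    row, col = divmod(index, PLATE_COLS)
    if row >= len(PLATE_ROWS):
        # spill onto virtual extra plates rather than fail
        plate, row = divmod(row, len(PLATE_ROWS))
        return f"P{plate + 1}-{PLATE_ROWS[row]}{col + 1}"
    return f"{PLATE_ROWS[row]}{col + 1}"


def render_plate(
    genotypes: Mapping[str, Sequence[GenotypeCall]],
    panel: PanelDefinition,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[WellRecord], PlateLayout]:
    """Render genotypes into per-well records plus a matching layout.

    ``genotypes`` maps sample id -> panel-ordered genotype calls (the
    ground truth).  Each sample occupies two wells per multiplex panel
    (REF-mix and ALT-mix); channel 5 carries the B2M control.  Artifact
    injection happens after the clean signal model, per configured
    rates, with all randomness drawn from ``seed``.
    """
    noise = noise or NoiseConfig()
    if seed is None:
        raise InputError("render_plate requires a seed or Generator")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed

    records: list[WellRecord] = []
    layout: dict[str, tuple[str, int, MixGroup]] = {}
    well_counter = 0

    def normal(mean: float, sd: float) -> float:
        return float(rng.normal(mean, sd)) if sd > 0 else mean

    def plateau() -> float:
        return max(0.0, normal(noise.plateau_rfu_mean, noise.plateau_rfu_sd))

    def clip_cq(cq: float) -> float | None:
        """Crossings later than the run length never register a Cq."""
        return None if cq > noise.max_cycles else max(cq, 0.01)

    for sample_id, calls in genotypes.items():
        by_name = {c.locus.name: c for c in calls}
        missing = [n for n in panel.locus_names if n not in by_name]
        if missing:
            raise InputError(f"sample {sample_id}: genotypes missing loci", missing)
        for panel_index in panel.panel_indices:
            well_of = {}
            for mix in (MixGroup.REF, MixGroup.ALT):
                wid = _well_name(well_counter)
                well_counter += 1
                layout[wid] = (sample_id, panel_index, mix)
                well_of[mix] = wid

            evaporated = (
                rng.random() < noise.evaporation_rate
            )  # one well of the pair delays
            evap_mix = MixGroup.REF if rng.random() < 0.5 else MixGroup.ALT
            # dropout is a whole-well failure (no mix, bad seal): every
            # channel of the well, B2M included, loses its crossing, so
            # the control gate voids the panel instead of the lone
            # surviving non-specific signal flipping a genotype
            dropped = {
                mix: rng.random() < noise.dropout_rate
                for mix in (MixGroup.REF, MixGroup.ALT)
            }

            pending: list[tuple[MixGroup, int, str, float | None]] = []
            for locus in panel.loci_in_panel(panel_index):
                geno = by_name[locus.name].genotype
                if locus.is_deletion:
                    if geno is Genotype.PRESENT:
                        cqs = {
                            MixGroup.REF: normal(noise.base_cq, noise.cq_sd),
                            MixGroup.ALT: normal(noise.base_cq, noise.cq_sd),
                        }
                    else:
                        cqs = {MixGroup.REF: None, MixGroup.ALT: None}
                else:
                    if geno is Genotype.HET:
                        cqs = {
                            MixGroup.REF: normal(noise.base_cq + noise.het_shift, noise.cq_sd),
                            MixGroup.ALT: normal(noise.base_cq + noise.het_shift, noise.cq_sd),
                        }
                    elif geno in (Genotype.HOM_REF, Genotype.HOM_ALT):
                        matching = MixGroup.REF if geno is Genotype.HOM_REF else MixGroup.ALT
                        other = MixGroup.ALT if matching is MixGroup.REF else MixGroup.REF
                        specific = normal(noise.base_cq, noise.cq_sd)
                        cqs = {
                            matching: specific,
                            other: specific + noise.nonspecific_delta_cq,
                        }
                    else:
                        raise InputError(
                            f"sample {sample_id}: cannot render {geno.value} "
                            f"at {locus.name}"
                        )
                for mix in (MixGroup.REF, MixGroup.ALT):
                    pending.append((mix, locus.channel, locus.name, cqs[mix]))
            for mix in (MixGroup.REF, MixGroup.ALT):
                pending.append(
                    (mix, panel.control_channel, panel.control_target,
                     normal(noise.b2m_cq, noise.cq_sd))
                )

            for mix, channel, target, cq in pending:
                if evaporated and mix is evap_mix and cq is not None:
                    cq = cq + noise.evaporation_shift
                rfu = plateau()
                if rng.random() < noise.low_rfu_rate:
                    rfu = float(rng.uniform(10.0, 250.0))  # below the 300 floor
                if dropped[mix]:
                    cq = None
                records.append(
                    WellRecord(
                        well_id=well_of[mix],
                        sample_id=sample_id,
                        panel_index=panel_index,
                        mix_group=mix,
                        channel=channel,
                        target=target,
                        cq=clip_cq(cq) if cq is not None else None,
                        end_rfu=rfu,
                    )
                )
    return records, PlateLayout(wells=layout)
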