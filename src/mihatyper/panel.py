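"""The 20-locus MiHA genotyping panel and genotype-string notation.

The default panel covers the 20 known HLA-A*02:01-restricted minor
histocompatibility antigens (MiHAs).  Nineteen loci are non-synonymous
SNPs; the twentieth (UGT2B17/A2) is a whole-gene deletion polymorphism
that the assay observes only as gene presence or absence.  Loci are
multiplexed into 5 panels of 4, one hydrolysis-probe color channel per
locus, with a beta-2-microglobulin (B2M) amplification control on
channel 5 of every panel.

Genotypes are written in the compact notation used for tabulated
results: ``"A/G"`` for a heterozygote, a single letter for a homozygote,
and ``"Im"`` / ``"No"`` for the deletion locus (gene present / absent).
Calls are unphased and order-normalized with the reference allele first.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .calls import Flag, Genotype, GenotypeCall
from .errors import GenotypeParseError, InputError, PanelError

HLA_RESTRICTION = "HLA-A*02:01"

#: Deletion-locus state labels: gene present (the immunogenic state) and
#: homozygous deletion.  "N/O" is accepted as a typographic variant of "No".
PRESENT_LABEL = "Im"
ABSENT_LABEL = "No"


class LocusKind(enum.Enum):
    SNP = "snp"
    GENE_DELETION = "gene_deletion"


@dataclass(frozen=True)
class MiHALocus:
    """One locus of the genotyping panel.

    ``ref_allele``/``alt_allele`` are the genomic SNP alleles in
    reference-genome orientation; for the deletion locus they are the
    presence/absence state labels.  ``immunogenic_allele`` is the variant
    whose peptide is known to elicit an in vivo T-cell response.
    ``pmm_unrelated_published`` is the published per-locus probability
    that a random unrelated donor-recipient pair is mismatched.
    """

    name: str
    gene: str
    chromosome: str
    variant_id: str
    ref_allele: str
    alt_allele: str
    immunogenic_allele: str
    locus_kind: LocusKind = LocusKind.SNP
    panel_index: int = 0
    channel: int = 0
    hla_restriction: str = HLA_RESTRICTION
    pmm_unrelated_published: float | None = None

    def __post_init__(self) -> None:
        if self.immunogenic_allele not in (self.ref_allele, self.alt_allele):
            raise PanelError(
                f"{self.name}: immunogenic allele {self.immunogenic_allele!r} "
                f"is neither ref {self.ref_allele!r} nor alt {self.alt_allele!r}"
            )
        if self.pmm_unrelated_published is not None and not (
            0.0 < self.pmm_unrelated_published <= 0.25
        ):
            # q^2(1-q^2) has analytic maximum 1/4
            raise PanelError(
                f"{self.name}: published mismatch probability "
                f"{self.pmm_unrelated_published} outside (0, 0.25]"
            )

    @property
    def nonimmunogenic_allele(self) -> str:
        return (
            self.alt_allele
            if self.immunogenic_allele == self.ref_allele
            else self.ref_allele
        )

    @property
    def is_deletion(self) -> bool:
        return self.locus_kind is LocusKind.GENE_DELETION


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered multiplex panel: loci plus the internal-control target."""

    loci: tuple[MiHALocus, ...]
    control_target: str = "B2M"
    control_channel: int = 5

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], str] = {}
        for loc in self.loci:
            key = (loc.panel_index, loc.channel)
            if loc.channel == self.control_channel:
                raise PanelError(
                    f"{loc.name}: channel {loc.channel} is reserved for "
                    f"{self.control_target}"
                )
            if key in seen:
                raise PanelError(
                    f"panel {key[0]} channel {key[1]} assigned to both "
                    f"{seen[key]} and {loc.name}"
                )
            seen[key] = loc.name
        deletions = [l for l in self.loci if l.is_deletion]
        if len(deletions) != 1:
            raise PanelError(
                f"expected exactly one gene-deletion locus, found "
                f"{[l.name for l in deletions]}"
            )
        panels = self.panel_indices
        for p in panels:
            chans = sorted(l.channel for l in self.loci if l.panel_index == p)
            if chans != list(range(1, len(chans) + 1)):
                raise PanelError(f"panel {p} channels {chans} are not 1..{len(chans)}")

    @property
    def panel_indices(self) -> tuple[int, ...]:
        return tuple(sorted({l.panel_index for l in self.loci}))

    @property
    def deletion_locus(self) -> MiHALocus:
        return next(l for l in self.loci if l.is_deletion)

    def locus(self, name: str) -> MiHALocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"no locus named {name!r} in panel")

    def locus_at(self, panel_index: int, channel: int) -> MiHALocus:
        for l in self.loci:
            if l.panel_index == panel_index and l.channel == channel:
                return l
        raise KeyError(f"no locus at panel {panel_index}, channel {channel}")

    def loci_in_panel(self, panel_index: int) -> tuple[MiHALocus, ...]:
        return tuple(
            sorted(
                (l for l in self.loci if l.panel_index == panel_index),
                key=lambda l: l.channel,
            )
        )

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)


# name, gene, chromosome, variant id, ref, alt, immunogenic, panel, channel,
# published unrelated mismatch probability
_DEFAULT_PANEL_ROWS = [
    ("HER-2/NEU", "ERBB2", "17", "rs1058808", "C", "G", "C", 1, 1, 0.247),
    ("HA-1/A2", "ARHGAP45", "19", "rs1801284", "G", "A", "A", 1, 2, 0.246),
    ("HA-2", "MYO1G", "7", "rs61739531", "C", "T", "C", 1, 3, 0.050),
    ("UTA2-1", "KIAA1551", "12", "rs2166807", "T", "C", "T", 1, 4, 0.234),
    ("LB-ADIR-1F", "TOR3A", "1", "rs2296377", "T", "C", "T", 2, 1, 0.250),
    ("LB-CLYBL-1Y", "CLYBL", "13", "rs17577293", "G", "T", "T", 2, 2, 0.056),
    ("C19ORF48", "C19ORF48", "19", "rs3745526", "T", "A", "A", 2, 3, 0.082),
    ("TRIM22", "TRIM22", "11", "rs187416296", "C", "T", "T", 2, 4, 0.019),
    ("LB-PRCP-1D", "PRCP", "11", "rs2229437", "T", "G", "G", 3, 1, 0.226),
    ("LB-SSR1-1S", "SSR1", "6", "rs10004", "A", "G", "G", 3, 2, 0.246),
    ("LB-WNK1-1I", "WNK1", "12", "rs12828016", "G", "T", "T", 3, 3, 0.237),
    ("T4A1", "TRIM42", "3", "rs9876490", "C", "A", "C", 3, 4, 0.202),
    ("HA-8", "PUM3", "9", "rs2173904", "C", "G", "C", 4, 1, 0.206),
    ("LB-HIVEP1-1S", "HIVEP1", "6", "rs2228220", "A", "G", "G", 4, 2, 0.175),
    ("LB-NISCH-1A", "NISCH", "3", "rs887515", "C", "T", "C", 4, 3, 0.220),
    ("UGT2B17/A2", "UGT2B17", "4", "esv3600873,4", "Im", "No", "Im", 4, 4, 0.123),
    ("LB-CCL4-1T", "CCL4", "17", "rs1719152", "T", "A", "A", 5, 1, 0.246),
    ("LB-NCAPD3-1Q", "NCAPD3", "11", "rs12292394", "C", "T", "T", 5, 2, 0.130),
    ("LB-NDC80-1P", "NDC80", "18", "rs9051", "G", "C", "C", 5, 3, 0.241),
    ("WDR27-1L", "WDR27", "6", "rs4236176", "A", "G", "A", 5, 4, 0.205),
]


def load_default_panel() -> PanelDefinition:
    """Build the packaged 20-MiHA HLA-A*02:01 panel.

    Raises :class:`PanelError` if the packaged table is internally
    inconsistent (which would indicate a corrupted installation).
    """
    loci = tuple(
        MiHALocus(
            name=name,
            gene=gene,
            chromosome=chrom,
            variant_id=var,
            ref_allele=ref,
            alt_allele=alt,
            immunogenic_allele=imm,
            locus_kind=(
                LocusKind.GENE_DELETION if ref == PRESENT_LABEL else LocusKind.SNP
            ),
            panel_index=panel,
            channel=channel,
            pmm_unrelated_published=pmm,
        )
        for name, gene, chrom, var, ref, alt, imm, panel, channel, pmm in _DEFAULT_PANEL_ROWS
    )
    if len(loci) != 20:
        raise PanelError(f"packaged panel has {len(loci)} loci, expected 20")
    return PanelDefinition(loci=loci)


def load_panel_config(path: str | Path) -> PanelDefinition:
    """Load a panel from a user-editable JSON or YAML config.

    The config mirrors the fields of :class:`MiHALocus`::

        control_target: B2M
        control_channel: 5
        loci:
          - name: HA-1/A2
            gene: ARHGAP45
            ...

    so other MiHA panels (for other HLA restrictions) can be supplied
    without code changes.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        import yaml

        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "loci" not in doc:
        raise InputError(f"panel config {path} has no 'loci' section")
    loci = []
    for entry in doc["loci"]:
        try:
            loci.append(
                MiHALocus(
                    name=entry["name"],
                    gene=entry.get("gene", ""),
                    chromosome=str(entry.get("chromosome", "")),
                    variant_id=entry.get("variant_id", ""),
                    ref_allele=entry["ref_allele"],
                    alt_allele=entry["alt_allele"],
                    immunogenic_allele=entry["immunogenic_allele"],
                    locus_kind=LocusKind(entry.get("locus_kind", "snp")),
                    panel_index=int(entry["panel_index"]),
                    channel=int(entry["channel"]),
                    hla_restriction=entry.get("hla_restriction", HLA_RESTRICTION),
                    pmm_unrelated_published=entry.get("pmm_unrelated_published"),
                )
            )
        except KeyError as exc:
            raise InputError(
                f"panel config {path}: locus entry missing field {exc}"
            ) from exc
    return PanelDefinition(
        loci=tuple(loci),
        control_target=doc.get("control_target", "B2M"),
        control_channel=int(doc.get("control_channel", 5)),
    )


def panel_to_config(panel: PanelDefinition) -> dict:
    """Inverse of :func:`load_panel_config` (dict form, JSON/YAML-dumpable)."""
    return {
        "control_target": panel.control_target,
        "control_channel": panel.control_channel,
        "loci": [
            {
                "name": l.name,
                "gene": l.gene,
                "chromosome": l.chromosome,
                "variant_id": l.variant_id,
                "ref_allele": l.ref_allele,
                "alt_allele": l.alt_allele,
                "immunogenic_allele": l.immunogenic_allele,
                "locus_kind": l.locus_kind.value,
                "panel_index": l.panel_index,
                "channel": l.channel,
                "hla_restriction": l.hla_restriction,
                "pmm_unrelated_published": l.pmm_unrelated_published,
            }
            for l in panel.loci
        ],
    }


def parse_genotype_string(text: str, locus: MiHALocus) -> GenotypeCall:
    """Parse a tabulated genotype string into a :class:`GenotypeCall`.

    SNP loci: ``"X/Y"`` (heterozygous when X != Y, homozygous when equal)
    or a single letter (homozygous).  Deletion locus: ``"Im"`` for gene
    present, ``"No"`` for homozygous deletion; the typographic variant
    ``"N/O"`` is accepted as ``"No"`` but flagged ``parsed_warning``.
    Calls are order-normalized (reference allele first), so ``"G/A"`` and
    ``"A/G"`` yield identical heterozygous calls.
    """
    raw = text.strip()
    if not raw:
        raise GenotypeParseError(f"{locus.name}: empty genotype string")

    if locus.is_deletion:
        norm = raw.replace("/", "").upper()
        if norm == PRESENT_LABEL.upper():
            return GenotypeCall(locus, Genotype.PRESENT)
        if norm == ABSENT_LABEL.upper():
            flags = frozenset({Flag.PARSED_WARNING}) if "/" in raw else frozenset()
            return GenotypeCall(locus, Genotype.ABSENT, flags=flags)
        raise GenotypeParseError(
            f"{locus.name}: {raw!r} is not a deletion-locus state "
            f"({PRESENT_LABEL!r} or {ABSENT_LABEL!r})"
        )

    parts = raw.split("/") if "/" in raw else [raw]
    valid = {locus.ref_allele, locus.alt_allele}
    for a in parts:
        if a not in valid:
            raise GenotypeParseError(
                f"{locus.name}: allele {a!r} not in {{{locus.ref_allele}, "
                f"{locus.alt_allele}}}"
            )
    if len(parts) == 1 or parts[0] == parts[1]:
        geno = (
            Genotype.HOM_REF if parts[0] == locus.ref_allele else Genotype.HOM_ALT
        )
        return GenotypeCall(locus, geno)
    if len(parts) != 2:
        raise GenotypeParseError(f"{locus.name}: malformed genotype {raw!r}")
    return GenotypeCall(locus, Genotype.HET)


def format_genotype(call: GenotypeCall) -> str:
    """Render a call back into the tabulated notation.

    Homozygotes collapse to a single letter, heterozygotes are written
    reference-allele first.  ``no_call`` renders as ``"-"``.
    """
    g = call.genotype
    loc = call.locus
    if g is Genotype.NO_CALL:
        return "-"
    if g is Genotype.PRESENT:
        return PRESENT_LABEL
    if g is Genotype.ABSENT:
        return ABSENT_LABEL
    if g is Genotype.HOM_REF:
        return loc.ref_allele
    if g is Genotype.HOM_ALT:
        return loc.alt_allele
    return f"{loc.ref_allele}/{loc.alt_allele}"


@dataclass(frozen=True)
class FrequencyTable:
    """Per-locus immunogenic-allele frequencies in a reference population."""

    p_imm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [n for n, p in self.p_imm.items() if not (0.0 <= p <= 1.0)]
        if bad:
            raise InputError("allele frequencies outside [0, 1]", bad)

    def __getitem__(self, locus_name: str) -> float:
        try:
            return self.p_imm[locus_name]
        except KeyError:
            raise InputError(f"no frequency for locus {locus_name!r}") from None

    def validate_against(self, panel: PanelDefinition) -> None:
        missing = [n for n in panel.locus_names if n not in self.p_imm]
        if missing:
            raise InputError("frequency table missing panel loci", missing)

    def for_panel(self, panel: PanelDefinition) -> list[float]:
        """Frequencies in panel locus order (raises if any are missing)."""
        self.validate_against(panel)
        return [self.p_imm[n] for n in panel.locus_names]


def load_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a two-column TSV (locus <TAB> immunogenic-allele frequency).

    Lines starting with ``#`` are comments; a ``locus``/``p_imm`` header
    row is optional.
    """
    freqs: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated fields")
        name, value = fields
        if name.lower() in ("locus", "miha", "name"):
            continue
        try:
            freqs[name] = float(value)
        except ValueError:
            raise InputError(
                f"{path}:{lineno}: {value!r} is not a frequency"
            ) from None
    return FrequencyTable(p_imm=freqs)


def default_frequency_fixture() -> FrequencyTable:
    """Illustrative immunogenic-allele frequencies for the default panel.

    Synthetic reconstruction: the frequencies are back-calculated from the
    panel's published per-locus unrelated mismatch probabilities by
    inverting p_mm = (1 - q^2) q^2 and taking the minor-immunogenic root.
    They are for demonstrations and smoke tests, not an authoritative
    population reference; supply a real lookup via
    :func:`load_frequency_table` for production use.
    """
    from importlib.resources import files

    from importlib.resources import as_file

    resource = files("mihatyper").joinpath("data/european_freqs_synthetic.tsv")
    with as_file(resource) as path:
        return load_frequency_table(path)
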