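"""Reading and writing plate-level qPCR data and genotype tables.

The on-disk formats are deliberately plain: a comma-separated, UTF-8,
dot-decimal "Quantification Cq Results"-style export for per-well data;
a JSON/YAML plate layout mapping wells to (sample, panel, mix group);
and tab-separated genotype / pair-report tables.  An empty or ``NaN``
Cq field encodes a reaction that never crossed the detection threshold.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .calls import GenotypeCall
from .errors import InputError
from .panel import (
    MiHALocus,
    PanelDefinition,
    format_genotype,
    parse_genotype_string,
)

if TYPE_CHECKING:  # pragma: no cover
    from .mismatch import PairReport

#: Hydrolysis-probe dye -> color channel, matching the FAM, HEX, ROX,
#: Cy5, Cy5.5 assignment to channels 1-5.  "Cy5,5" is accepted as a
#: spelling variant of "Cy5.5".
DEFAULT_DYE_MAP: dict[str, int] = {
    "FAM": 1,
    "HEX": 2,
    "ROX": 3,
    "CY5": 4,
    "CY5.5": 5,
    "CY5,5": 5,
}

CQ_CSV_COLUMNS = ["Well", "Fluor", "Target", "Sample", "Cq", "EndRFU"]
DEFAULT_MAX_CYCLES = 40


class MixGroup(enum.Enum):
    """Which allele-specific-primer mix a well carries.

    Every panel is run in two wells per sample: one with the primers for
    the reference SNP alleles (REF) and one for the alternative alleles
    (ALT).  The deletion locus and the B2M control use identical oligos
    in both wells.
    """

    REF = "REF"
    ALT = "ALT"


@dataclass(frozen=True)
class WellRecord:
    """One fluorescence readout: a (well, channel) measurement."""

    well_id: str
    sample_id: str
    panel_index: int
    mix_group: MixGroup
    channel: int
    target: str
    cq: float | None
    end_rfu: float

    def __post_init__(self) -> None:
        if self.cq is not None and not self.cq > 0:
            raise InputError(f"well {self.well_id}: Cq {self.cq} must be positive")
        if self.end_rfu < 0:
            raise InputError(f"well {self.well_id}: negative RFU {self.end_rfu}")


@dataclass(frozen=True)
class PlateLayout:
    """Maps plate wells to (sample, panel, mix group) triples."""

    wells: Mapping[str, tuple[str, int, MixGroup]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int, MixGroup], str] = {}
        dupes = []
        for well, key in self.wells.items():
            if key in seen:
                dupes.append(f"{key[0]}/panel{key[1]}/{key[2].value} in both {seen[key]} and {well}")
            seen[key] = well
        if dupes:
            raise InputError("duplicate (sample, panel, mix group) assignments", dupes)
        halves = []
        for sample, panel in {(s, p) for s, p, _ in seen}:
            groups = {g for s, p, g in seen if s == sample and p == panel}
            if groups != {MixGroup.REF, MixGroup.ALT}:
                halves.append(f"{sample}/panel{panel} has only {sorted(g.value for g in groups)}")
        if halves:
            raise InputError("each (sample, panel) needs one REF and one ALT well", halves)

    def __getitem__(self, well_id: str) -> tuple[str, int, MixGroup]:
        return self.wells[well_id]

    def __contains__(self, well_id: str) -> bool:
        return well_id in self.wells

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _, _ in self.wells.values()}))


def load_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from JSON or YAML: well -> {sample, panel, mix}."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        import yaml

        doc = yaml.safe_load(text)
    wells = {}
    for well, entry in doc.items():
        try:
            wells[well] = (
                str(entry["sample"]),
                int(entry["panel"]),
                MixGroup(entry["mix"].upper()),
            )
        except (KeyError, ValueError) as exc:
            raise InputError(f"layout {path}: bad entry for well {well}: {exc}") from exc
    return PlateLayout(wells=wells)


def save_layout(layout: PlateLayout, path: str | Path) -> None:
    doc = {
        well: {"sample": s, "panel": p, "mix": g.value}
        for well, (s, p, g) in sorted(layout.wells.items())
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def _parse_cq(raw: object) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return None
    return float(text)


def read_cq_csv(
    path: str | Path,
    layout: PlateLayout,
    dye_map: Mapping[str, int] | None = None,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> list[WellRecord]:
    """Read a per-well Cq CSV export and join it to the plate layout.

    Expected header: ``Well,Fluor,Target,Sample,Cq,EndRFU``.  The color
    channel is derived from the dye name via ``dye_map`` (case-insensitive;
    defaults to :data:`DEFAULT_DYE_MAP`).  All well/dye/duplicate problems
    are collected and reported together in one :class:`InputError`.
    """
    dye_map = {k.upper(): v for k, v in (dye_map or DEFAULT_DYE_MAP).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CQ_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"{path}: missing columns", missing_cols)

    records: list[WellRecord] = []
    offenders: list[str] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        well = row["Well"].strip()
        if well not in layout:
            offenders.append(f"row {idx + 2}: well {well!r} not in layout")
            continue
        dye = row["Fluor"].strip().upper()
        if dye not in dye_map:
            offenders.append(f"row {idx + 2}: unknown dye {row['Fluor']!r}")
            continue
        channel = dye_map[dye]
        if (well, channel) in seen:
            offenders.append(f"row {idx + 2}: duplicate readout for well {well}, channel {channel}")
            continue
        seen.add((well, channel))
        sample, panel, mix = layout[well]
        try:
            cq = _parse_cq(row["Cq"])
        except ValueError:
            offenders.append(f"row {idx + 2}: unreadable Cq {row['Cq']!r}")
            continue
        if cq is not None and cq > max_cycles:
            offenders.append(f"row {idx + 2}: Cq {cq} exceeds {max_cycles} cycles")
            continue
        try:
            records.append(
                WellRecord(
                    well_id=well,
                    sample_id=sample,
                    panel_index=panel,
                    mix_group=mix,
                    channel=channel,
                    target=row["Target"].strip(),
                    cq=cq,
                    end_rfu=float(row["EndRFU"]),
                )
            )
        except (InputError, ValueError) as exc:
            offenders.append(f"row {idx + 2}: {exc}")
    if offenders:
        raise InputError(f"{path}: invalid rows", offenders)
    return records


def write_cq_csv(records: Sequence[WellRecord], path: str | Path) -> None:
    """Write well records back to the Cq CSV schema (lossless round-trip)."""
    inv_dyes = {1: "FAM", 2: "HEX", 3: "ROX", 4: "Cy5", 5: "Cy5.5"}
    rows = [
        {
            "Well": r.well_id,
            "Fluor": inv_dyes[r.channel],
            "Target": r.target,
            "Sample": r.sample_id,
            "Cq": "" if r.cq is None else f"{r.cq:.4f}",
            "EndRFU": f"{r.end_rfu:.1f}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CQ_CSV_COLUMNS).to_csv(path, index=False)


def _write_with_header(path: str | Path, header_lines: Iterable[str], body: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(body)


def write_genotypes_tsv(
    calls: Mapping[str, Sequence[GenotypeCall]] | Sequence[GenotypeCall],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    """Write per-locus genotype calls as TSV.

    ``calls`` is either one sample's call list or a mapping sample ->
    calls.  Columns: sample, locus, genotype (tabulated notation), flags.
    """
    if not isinstance(calls, Mapping):
        calls = {"": calls}
    lines = ["sample\tlocus\tgenotype\tflags"]
    for sample, sample_calls in calls.items():
        for call in sample_calls:
            flags = ",".join(sorted(f.value for f in call.flags))
            lines.append(
                f"{sample}\t{call.locus.name}\t{format_genotype(call)}\t{flags}"
            )
    _write_with_header(path, header_lines, "\n".join(lines) + "\n")


def read_genotypes_tsv(
    path: str | Path, panel: PanelDefinition
) -> dict[str, list[GenotypeCall]]:
    """Read a genotype TSV written by :func:`write_genotypes_tsv`.

    ``no_call`` rows (genotype ``-``) are skipped: they carry no genotype
    to re-import.
    """
    out: dict[str, list[GenotypeCall]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "sample":
            continue
        if len(fields) < 3:
            raise InputError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        sample, locus_name, geno = fields[0], fields[1], fields[2]
        if geno == "-":
            continue
        locus = panel.locus(locus_name)
        out.setdefault(sample, []).append(parse_genotype_string(geno, locus))
    return out


def write_pair_report_tsv(
    report: "PairReport", path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write a donor-recipient pair report as TSV.

    One locus per row with both genotypes and the mismatch verdict, then
    a ``Total MM`` footer counting mismatch verdicts only; indeterminate
    loci trigger an "evaluable loci" warning footer.
    """
    lines = ["locus\trecipient\tdonor\tverdict"]
    for locus_name, (rec, don, verdict) in report.rows():
        lines.append(
            f"{locus_name}\t{format_genotype(rec)}\t{format_genotype(don)}\t{verdict.value}"
        )
    lines.append(f"Total MM\t\t\t{report.total_mm}")
    if report.n_indeterminate:
        lines.append(
            f"# warning: total over {report.n_evaluable} evaluable loci "
            f"({report.n_indeterminate} indeterminate)"
        )
    _write_with_header(path, header_lines, "\n".join(lines) + "\n")


def read_pair_table_tsv(
    path: str | Path, panel: PanelDefinition
) -> list[dict]:
    """Read a combined multi-pair genotype table.

    Expected columns: ``pair_id, pair_type, role, sample_id`` followed by
    one column per panel locus holding genotype strings in tabulated
    notation.  Returns one dict per pair with parsed recipient and donor
    call lists in panel order.
    """
    rows: list[dict] = []
    header: list[str] | None = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            missing = [c for c in ("pair_id", "pair_type", "role", "sample_id") if c not in header]
            if missing:
                raise InputError(f"{path}: missing columns", missing)
            absent = [n for n in panel.locus_names if n not in header]
            if absent:
                raise InputError(f"{path}: missing locus columns", absent)
            continue
        rows.append(dict(zip(header, fields)))

    pairs: dict[str, dict] = {}
    for row in rows:
        pid = row["pair_id"]
        entry = pairs.setdefault(
            pid, {"pair_id": pid, "pair_type": row["pair_type"], "recipient": None, "donor": None}
        )
        calls = [
            parse_genotype_string(row[locus.name], locus) for locus in panel.loci
        ]
        role = row["role"].strip().lower()
        if role not in ("recipient", "donor"):
            raise InputError(f"{path}: pair {pid}: unknown role {row['role']!r}")
        entry[role] = calls
        entry[f"{role}_id"] = row["sample_id"]
    incomplete = [p for p, e in pairs.items() if e["recipient"] is None or e["donor"] is None]
    if incomplete:
        raise InputError(f"{path}: pairs missing a recipient or donor row", incomplete)
    return list(pairs.values())


def packaged_validation_pairs(panel: PanelDefinition | None = None) -> list[dict]:
    """The packaged 13-pair validation genotype table, parsed."""
    from importlib.resources import as_file, files

    from .panel import load_default_panel

    panel = panel or load_default_panel()
    resource = files("mihatyper").joinpath("data/validation_pairs.tsv")
    with as_file(resource) as p:
        return read_pair_table_tsv(p, panel)
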