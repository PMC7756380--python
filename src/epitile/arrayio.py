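"""Spot-level fluorescence tables and patient metadata I/O.

Spot tables are tab-separated UTF-8 with header::

    patient_id  probe_id  replicate  channel  total_fluorescence  background_fluorescence

``BLANK`` is a reserved probe_id for peptide-free spots; for BLANK rows the
``replicate`` column indexes the blank *position* on the array
(1..blank_count) — blanks are individual spots with no probe identity to
aggregate over.

Patient metadata is CSV with fixed columns ``patient_id, group,
symptom_class, challenge`` followed by any number of immunoblot intensity
columns ``<component>_ige_ru`` / ``<component>_igg4_ru`` (EUROLINE response
units) and extract titre columns ``<extract>_kul`` (ImmunoCAP kU/L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .tiling import ArrayLayout

logger = logging.getLogger(__name__)

BLANK = "BLANK"

SPOT_COLUMNS = [
    "patient_id",
    "probe_id",
    "replicate",
    "channel",
    "total_fluorescence",
    "background_fluorescence",
]

GROUPS = ("allergic", "tolerant")
SYMPTOM_CLASSES = ("objective", "subjective", "none")


@dataclass(frozen=True)
class SpotMeasurement:
    """One quantified fluorescence spot (arbitrary fluorescence units)."""

    patient_id: str
    probe_id: str
    replicate: int
    channel: str
    total_fluorescence: float
    background_fluorescence: float

    @property
    def is_blank(self) -> bool:
        return self.probe_id == BLANK


@dataclass
class PatientRecord:
    """Clinical metadata for one patient.

    ``el_ige`` / ``el_igg4`` map component name -> EUROLINE intensity (RU);
    ``immunocap`` maps extract name -> sIgE titre (kU/L).
    """

    patient_id: str
    group: str
    symptom_class: str
    challenge: bool
    el_ige: dict[str, float] = field(default_factory=dict)
    el_igg4: dict[str, float] = field(default_factory=dict)
    immunocap: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.patient_id}: unknown group {self.group!r}")
        if self.symptom_class not in SYMPTOM_CLASSES:
            raise ValueError(
                f"{self.patient_id}: unknown symptom_class {self.symptom_class!r}"
            )
        if self.group == "tolerant" and self.symptom_class != "none":
            raise ValueError(
                f"{self.patient_id}: tolerant patients must have symptom_class "
                f"'none', got {self.symptom_class!r}"
            )
        if self.group == "allergic" and self.symptom_class == "none":
            raise ValueError(
                f"{self.patient_id}: allergic patients must have objective or "
                "subjective symptoms"
            )
        for name, m in (("el_ige", self.el_ige), ("el_igg4", self.el_igg4),
                        ("immunocap", self.immunocap)):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(
                        f"{self.patient_id}: negative {name}[{k}] = {v}"
                    )


def _validate_spot_row(
    row: pd.Series, i: int, layout: ArrayLayout
) -> SpotMeasurement:
    probe_id = str(row["probe_id"])
    replicate = int(row["replicate"])
    channel = str(row["channel"])
    total = float(row["total_fluorescence"])
    background = float(row["background_fluorescence"])
    if total < 0:
        raise ValueError(f"row {i}: negative total_fluorescence {total}")
    if channel not in layout.channels:
        raise ValueError(
            f"row {i}: channel {channel!r} not in layout channels "
            f"{layout.channels}"
        )
    if probe_id == BLANK:
        if not 1 <= replicate <= layout.blank_count:
            raise ValueError(
                f"row {i}: blank position {replicate} outside "
                f"1..{layout.blank_count}"
            )
    else:
        if probe_id not in layout.probe_ids:
            raise ValueError(f"row {i}: probe_id {probe_id!r} not in layout")
        if not 1 <= replicate <= layout.replicate_count:
            raise ValueError(
                f"row {i}: replicate {replicate} outside "
                f"1..{layout.replicate_count}"
            )
    return SpotMeasurement(
        patient_id=str(row["patient_id"]),
        probe_id=probe_id,
        replicate=replicate,
        channel=channel,
        total_fluorescence=total,
        background_fluorescence=background,
    )


def read_spot_table(path: str | Path, layout: ArrayLayout) -> list[SpotMeasurement]:
    """Read and validate a spot TSV against a layout.

    Row order is preserved. Any invalid row aborts the read with a message
    naming the row; rows are never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: spot table has no data rows", path)
        return []
    return spots_from_frame(df, layout)


def spots_from_frame(df: pd.DataFrame, layout: ArrayLayout) -> list[SpotMeasurement]:
    """Validate an in-memory spot table (same dialect as the TSV)."""
    return [
        _validate_spot_row(row, i, layout)
        for i, (_, row) in enumerate(df.iterrows(), start=2)
    ]


def spots_to_frame(spots: Sequence[SpotMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.patient_id,
                s.probe_id,
                s.replicate,
                s.channel,
                s.total_fluorescence,
                s.background_fluorescence,
            )
            for s in spots
        ],
        columns=SPOT_COLUMNS,
    )


def write_spot_table(spots: Sequence[SpotMeasurement], path: str | Path) -> None:
    spots_to_frame(spots).to_csv(path, sep="\t", index=False)


def read_gpr(
    path: str | Path,
    patient_id: str,
    channel_map: dict[str, str],
    layout: ArrayLayout,
) -> list[SpotMeasurement]:
    """Convenience import of a GenePix GPR results file.

    ``channel_map`` maps a wavelength tag (e.g. ``"635"``) to a layout
    channel; the corresponding ``F<tag> Median`` and ``B<tag> Median``
    columns become total and background fluorescence. GPR files are ATF:
    two count lines, header block, then a tab table.
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        first = fh.readline()
        if not first.startswith("ATF"):
            raise ValueError(f"{path}: not an ATF/GPR file")
        n_header = int(fh.readline().split()[0])
        for _ in range(n_header):
            fh.readline()
        df = pd.read_csv(fh, sep="\t")
    df.columns = [c.strip().strip('"') for c in df.columns]
    name_col = "Name" if "Name" in df.columns else "ID"
    spots: list[SpotMeasurement] = []
    counters: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        probe_id = str(row[name_col]).strip()
        for tag, channel in channel_map.items():
            key = (probe_id, channel)
            counters[key] = counters.get(key, 0) + 1
            spots.append(
                SpotMeasurement(
                    patient_id=patient_id,
                    probe_id=probe_id,
                    replicate=counters[key],
                    channel=channel,
                    total_fluorescence=float(row[f"F{tag} Median"]),
                    background_fluorescence=float(row[f"B{tag} Median"]),
                )
            )
    return [
        s
        for s in spots
        if s.probe_id == BLANK or s.probe_id in layout.probe_ids
    ]


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read and validate the patient metadata CSV."""
    df = pd.read_csv(path)
    required = ["patient_id", "group", "symptom_class", "challenge"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated patient_id(s) {sorted(set(dup))}")
    ige_cols = [c for c in df.columns if c.endswith("_ige_ru")]
    igg4_cols = [c for c in df.columns if c.endswith("_igg4_ru")]
    cap_cols = [c for c in df.columns if c.endswith("_kul")]
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                group=str(row["group"]),
                symptom_class=str(row["symptom_class"]),
                challenge=_parse_bool(row["challenge"]),
                el_ige={
                    c[: -len("_ige_ru")]: float(row[c])
                    for c in ige_cols
                    if pd.notna(row[c])
                },
                el_igg4={
                    c[: -len("_igg4_ru")]: float(row[c])
                    for c in igg4_cols
                    if pd.notna(row[c])
                },
                immunocap={
                    c[: -len("_kul")]: float(row[c])
                    for c in cap_cols
                    if pd.notna(row[c])
                },
            )
        )
    return records


def write_patient_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    components_ige = sorted({k for p in patients for k in p.el_ige})
    components_igg4 = sorted({k for p in patients for k in p.el_igg4})
    extracts = sorted({k for p in patients for k in p.immunocap})
    rows = []
    for p in patients:
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "group": p.group,
            "symptom_class": p.symptom_class,
            "challenge": p.challenge,
        }
        for c in components_ige:
            row[f"{c}_ige_ru"] = p.el_ige.get(c)
        for c in components_igg4:
            row[f"{c}_igg4_ru"] = p.el_igg4.get(c)
        for e in extracts:
            row[f"{e}_kul"] = p.immunocap.get(e)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")
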