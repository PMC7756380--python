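"""Per-spot signal statistics and blank-spot z-score normalization.

Each spot yields a log2 signal-to-noise ratio

    S = log2(total_fluorescence / background_fluorescence),

replicates are aggregated to a per-probe S by the median, and probe
S-values are normalized per patient x channel against the blank spots of
the same array:

    z = (S - median(S_blank)) / MAD(S_blank),

where MAD is the *unscaled* median absolute deviation about the median
(``mad_scale=1.0``). Setting ``mad_scale=1.4826`` gives the
Gaussian-consistent variant; it rescales all z uniformly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arrayio import BLANK, SpotMeasurement, spots_to_frame
from .tiling import ArrayLayout

logger = logging.getLogger(__name__)


def compute_snr(total_fluorescence: float, background_fluorescence: float) -> float:
    """log2 signal-to-noise ratio of a single spot."""
    if background_fluorescence <= 0:
        raise ValueError(
            f"background must be positive, got {background_fluorescence}"
        )
    if total_fluorescence <= 0:
        raise ValueError(f"total must be positive, got {total_fluorescence}")
    return math.log2(total_fluorescence / background_fluorescence)


def aggregate_replicates(values: Sequence[float]) -> float:
    """Median of the replicate S-values of one probe/patient/channel."""
    if len(values) == 0:
        raise ValueError("no valid replicates to aggregate")
    return float(np.median(values))


def median_deviation(values: Sequence[float], scale: float = 1.0) -> float:
    """Median absolute deviation about the median, times ``scale``."""
    arr = np.asarray(values, dtype=float)
    return scale * float(np.median(np.abs(arr - np.median(arr))))


@dataclass
class SignalTable:
    """Aggregated per-probe S-values plus the blank S-values per array.

    ``probe_s`` is indexed by (patient_id, channel) with one column per
    probe_id (NaN where a probe had no valid spot); ``blank_s`` maps
    (patient_id, channel) to the array's blank S-values.
    """

    probe_s: pd.DataFrame
    blank_s: dict[tuple[str, str], np.ndarray]


@dataclass
class ZScoreTable:
    """Blank-normalized reactivity per probe per patient x channel.

    ``normalization_stats`` records (median(S_blank), MAD(S_blank)) per
    array for audit.
    """

    z: pd.DataFrame
    normalization_stats: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def for_array(self, patient_id: str, channel: str) -> pd.Series:
        return self.z.loc[(patient_id, channel)]

    @property
    def arrays(self) -> list[tuple[str, str]]:
        return list(self.z.index)


def build_signal_table(
    spots: Iterable[SpotMeasurement] | pd.DataFrame, layout: ArrayLayout
) -> SignalTable:
    """Compute per-spot S, drop invalid spots, aggregate replicates.

    Spots with non-positive background or total are flagged invalid and
    excluded (never imputed); a probe with zero valid replicates is left
    missing (NaN) for that patient x channel.
    """
    df = spots if isinstance(spots, pd.DataFrame) else spots_to_frame(list(spots))
    df = df.copy()
    for col in ("total_fluorescence", "background_fluorescence"):
        df[col] = df[col].astype(float)
    df["replicate"] = df["replicate"].astype(int)

    invalid = (df["total_fluorescence"] <= 0) | (df["background_fluorescence"] <= 0)
    if invalid.any():
        logger.warning(
            "%d spot(s) with non-positive total or background excluded",
            int(invalid.sum()),
        )
        df = df[~invalid]

    df["S"] = np.log2(df["total_fluorescence"] / df["background_fluorescence"])

    probes = df[df["probe_id"] != BLANK]
    agg = (
        probes.groupby(["patient_id", "channel", "probe_id"], sort=False)["S"]
        .median()
        .unstack("probe_id")
    )
    # keep layout column order; probes never measured appear as NaN columns
    agg = agg.reindex(columns=layout.probe_ids)

    blanks = df[df["probe_id"] == BLANK]
    blank_s = {
        key: grp["S"].to_numpy()
        for key, grp in blanks.groupby(["patient_id", "channel"], sort=False)
    }
    return SignalTable(probe_s=agg, blank_s=blank_s)


def compute_zscores(signal: SignalTable, mad_scale: float = 1.0) -> ZScoreTable:
    """Normalize probe S-values against the blanks of the same array."""
    rows = []
    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for key in signal.probe_s.index:
        blanks = signal.blank_s.get(key)
        if blanks is None or len(blanks) < 2:
            raise ValueError(
                f"array {key}: need >= 2 blank S-values for normalization"
            )
        med = float(np.median(blanks))
        mad = median_deviation(blanks, scale=mad_scale)
        if mad == 0:
            raise ValueError(
                f"array {key}: blank MAD is zero (all blanks identical); "
                "inspect the blank spots before normalizing"
            )
        stats[key] = (med, mad)
        rows.append((signal.probe_s.loc[key] - med) / mad)
    z = pd.DataFrame(rows, index=signal.probe_s.index)
    return ZScoreTable(z=z, normalization_stats=stats)


def write_zscore_table(
    z: ZScoreTable, layout: ArrayLayout, path: str | Path
) -> None:
    """Write z-scores as long TSV with probe coordinates."""
    coords = {p.probe_id: (p.start, p.end) for p in layout.probes}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tchannel\tprobe_id\tstart\tend\tz\n")
        for (patient, channel), row in z.z.iterrows():
            for probe_id, val in row.items():
                s, e = coords[probe_id]
                zval = "NA" if pd.isna(val) else f"{val:.6g}"
                fh.write(f"{patient}\t{channel}\t{probe_id}\t{s}\t{e}\t{zval}\n")


def write_normalization_stats(z: ZScoreTable, path: str | Path) -> None:
    """Emit per-array blank median/MAD to a JSON sidecar for audit."""
    payload = {
        f"{patient}|{channel}": {"blank_median": med, "blank_mad": mad}
        for (patient, channel), (med, mad) in z.normalization_stats.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
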