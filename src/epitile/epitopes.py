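"""Contiguity-based linear epitope calling.

An epitope is a run of 2-4 contiguous reactive peptides (median z >= 3.0
by default). The consensus amino-acid region of a run is the intersection
of its peptide intervals — for 15-mers at offset 3 a two-peptide run names
a 12-residue epitope, three peptides 9, four peptides 6. Runs longer than
four reactive peptides exceed the definition and are split left-to-right
into windows of at most four (the final two windows rebalanced so no
window has length 1), each flagged ``split-from-long-run``.

Reactivity of a *run* requires every peptide in it to pass the threshold
(``run_rule="all_above"``); the weaker reading where only the run median
must pass is available as ``run_rule="median_only"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .signal import ZScoreTable
from .tiling import ArrayLayout, PeptideProbe


@dataclass(frozen=True)
class EpitopeCall:
    """One called epitope: a contiguous probe run and its consensus region."""

    patient_id: str
    channel: str
    antigen_id: str
    run_probe_ids: tuple[str, ...]
    region_start: int
    region_end: int
    median_z: float
    flag: str = ""

    @property
    def region(self) -> tuple[int, int]:
        return (self.region_start, self.region_end)

    @property
    def name(self) -> str:
        return f"aa{self.region_start}-{self.region_end}"

    def overlaps(self, start: int, end: int) -> bool:
        return self.region_start <= end and start <= self.region_end


def consensus_region(run_probes: Sequence[PeptideProbe]) -> tuple[int, int]:
    """Intersection of the run's peptide intervals (the epitope name)."""
    if not run_probes:
        raise ValueError("empty probe run")
    start = max(p.start for p in run_probes)
    end = min(p.end for p in run_probes)
    if start > end:
        raise ValueError(
            "probe run has empty intersection; run too long for this tiling "
            "geometry"
        )
    return start, end


def split_run(n: int, max_len: int = 4, min_len: int = 2) -> list[int]:
    """Window lengths for a reactive run of ``n`` probes.

    Left-to-right windows of ``max_len``; a remainder of 1 is avoided by
    rebalancing the final two windows (e.g. 5 -> 3+2, 9 -> 4+3+2).
    """
    if n < min_len:
        raise ValueError(f"run of {n} cannot be windowed (min {min_len})")
    if n <= max_len:
        return [n]
    q, r = divmod(n, max_len)
    sizes = [max_len] * q + ([r] if r else [])
    if 0 < sizes[-1] < min_len:
        deficit = min_len - sizes[-1]
        sizes[-2] -= deficit
        sizes[-1] += deficit
    return sizes


def call_epitopes(
    z: ZScoreTable,
    layout: ArrayLayout,
    threshold: float = 3.0,
    run_rule: str = "all_above",
) -> list[EpitopeCall]:
    """Call epitopes on every patient x channel array of a z-score table.

    Missing z-values break contiguity (conservative); isolated reactive
    peptides never yield a call.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if run_rule not in ("all_above", "median_only"):
        raise ValueError(f"unknown run_rule {run_rule!r}")
    calls: list[EpitopeCall] = []
    for patient_id, channel in z.arrays:
        row = z.z.loc[(patient_id, channel)]
        for antigen_id in layout.antigen_ids:
            probes = layout.probes_for(antigen_id)
            zvals = np.array(
                [row.get(p.probe_id, np.nan) for p in probes], dtype=float
            )
            calls.extend(
                _call_antigen(
                    patient_id, channel, antigen_id, probes, zvals,
                    layout.offset, threshold, run_rule,
                )
            )
    return calls


def _call_antigen(
    patient_id: str,
    channel: str,
    antigen_id: str,
    probes: Sequence[PeptideProbe],
    zvals: np.ndarray,
    offset: int,
    threshold: float,
    run_rule: str,
) -> list[EpitopeCall]:
    if run_rule == "all_above":
        runs = _maximal_reactive_runs(probes, zvals, offset, threshold)
    else:
        runs = _median_only_runs(probes, zvals, offset, threshold)
    calls = []
    for run in runs:
        sizes = split_run(len(run))
        flag = "split-from-long-run" if len(sizes) > 1 else ""
        pos = 0
        for size in sizes:
            idx = run[pos : pos + size]
            pos += size
            window = [probes[i] for i in idx]
            med = float(np.median(zvals[idx]))
            if med < threshold:  # cannot occur under all_above; kept explicit
                continue
            start, end = consensus_region(window)
            calls.append(
                EpitopeCall(
                    patient_id=patient_id,
                    channel=channel,
                    antigen_id=antigen_id,
                    run_probe_ids=tuple(p.probe_id for p in window),
                    region_start=start,
                    region_end=end,
                    median_z=med,
                    flag=flag,
                )
            )
    return calls


def _maximal_reactive_runs(
    probes: Sequence[PeptideProbe],
    zvals: np.ndarray,
    offset: int,
    threshold: float,
) -> list[list[int]]:
    """Maximal runs (length >= 2) of grid-contiguous reactive probes."""
    reactive = np.nan_to_num(zvals, nan=-np.inf) >= threshold
    runs: list[list[int]] = []
    current: list[int] = []
    for i, p in enumerate(probes):
        contiguous = (
            bool(current)
            and p.start - probes[current[-1]].start == offset
        )
        if reactive[i]:
            if contiguous:
                current.append(i)
            else:
                if len(current) >= 2:
                    runs.append(current)
                current = [i]
        else:
            if len(current) >= 2:
                runs.append(current)
            current = []
    if len(current) >= 2:
        runs.append(current)
    return runs


def _median_only_runs(
    probes: Sequence[PeptideProbe],
    zvals: np.ndarray,
    offset: int,
    threshold: float,
) -> list[list[int]]:
    """Greedy left-to-right windows of 2-4 whose median z passes.

    Exploratory weaker reading; windows never overlap and larger windows
    are preferred.
    """
    n = len(probes)
    runs: list[list[int]] = []
    i = 0
    while i < n - 1:
        best: list[int] | None = None
        for k in (4, 3, 2):
            if i + k > n:
                continue
            idx = list(range(i, i + k))
            if any(
                probes[j + 1].start - probes[j].start != offset
                for j in idx[:-1]
            ):
                continue
            window = zvals[idx]
            if np.isnan(window).any():
                continue
            if float(np.median(window)) >= threshold:
                best = idx
                break
        if best is None:
            i += 1
        else:
            runs.append(best)
            i = best[-1] + 1
    return runs


def cross_reference_channels(
    calls_ige: Sequence[EpitopeCall], calls_igg4: Sequence[EpitopeCall]
) -> pd.DataFrame:
    """Label each call IgE-only / IgG4-only / both per patient.

    Two calls pair ("both") when their consensus regions on the same
    antigen of the same patient share at least one residue.
    """
    rows = []
    for call in calls_ige:
        partner = any(
            c.patient_id == call.patient_id
            and c.antigen_id == call.antigen_id
            and c.overlaps(*call.region)
            for c in calls_igg4
        )
        rows.append(_xref_row(call, "both" if partner else "IgE-only"))
    for call in calls_igg4:
        partner = any(
            c.patient_id == call.patient_id
            and c.antigen_id == call.antigen_id
            and c.overlaps(*call.region)
            for c in calls_ige
        )
        rows.append(_xref_row(call, "both" if partner else "IgG4-only"))
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "channel", "antigen_id", "region", "median_z", "label",
        ],
    )


def _xref_row(call: EpitopeCall, label: str) -> tuple:
    return (
        call.patient_id, call.channel, call.antigen_id, call.name,
        call.median_z, label,
    )


def epitope_patient_matrix(
    calls: Sequence[EpitopeCall],
    patient_ids: Sequence[str],
    channel: str | None = None,
) -> pd.DataFrame:
    """Binary patient x epitope-region matrix for heatmaps and PCA.

    Columns are the distinct consensus regions observed in ``calls``
    (ordered by position); a cell is 1 when the patient has a call with
    exactly that region in the requested channel (all channels if None).
    """
    selected = [c for c in calls if channel is None or c.channel == channel]
    regions = sorted(
        {(c.antigen_id, c.region_start, c.region_end) for c in selected}
    )
    columns = [f"{a}:aa{s}-{e}" for a, s, e in regions]
    mat = pd.DataFrame(0, index=list(patient_ids), columns=columns, dtype=int)
    for c in selected:
        col = f"{c.antigen_id}:aa{c.region_start}-{c.region_end}"
        if c.patient_id in mat.index:
            mat.loc[c.patient_id, col] = 1
    return mat


def write_calls(calls: Sequence[EpitopeCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "patient_id\tchannel\tantigen_id\tregion\tprobe_run\tmedian_z\tflag\n"
        )
        for c in calls:
            fh.write(
                f"{c.patient_id}\t{c.channel}\t{c.antigen_id}\t{c.name}\t"
                f"{','.join(c.run_probe_ids)}\t{c.median_z:.4g}\t{c.flag}\n"
            )
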