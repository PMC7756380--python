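"""End-to-end orchestration: tiling -> z-scores -> calls -> diagnostics.

``run_pipeline`` drives the stages from a :class:`RunConfig`, writes every
stage output to the output directory and records a machine-readable
manifest (parameters, input digests, package version) so every reported
number is recomputable from the on-disk stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .arrayio import read_patient_table, read_spot_table
from .diagnostics import (
    DEFAULT_DISCRIMINATIVE_REGIONS,
    diagnostic_performance,
    el_to_east_class,
    epitope_classifier,
    ige_igg4_ratio,
    ratio_median,
    threshold_classifier,
)
from .epitopes import (
    call_epitopes,
    cross_reference_channels,
    epitope_patient_matrix,
    write_calls,
)
from .signal import (
    build_signal_table,
    compute_zscores,
    write_normalization_stats,
    write_zscore_table,
)
from .surface import (
    classify_epitope_exposure,
    compute_residue_accessibility,
    write_exposure_table,
)
from .tiling import build_layout, read_fasta, tile_sequence, write_layout

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults: 15-mer probes at offset 3, triplicate spots, z threshold
    3.0 with unscaled blank MAD, exposure cuts 0.5 (residue) / 0.25
    (epitope), discriminative regions aa30-41/aa39-50/aa84-95, extract
    titre cutoff 5 kU/L.
    """

    fasta: str
    spots: str
    patients: str
    outdir: str
    structure: str | None = None
    structure_antigen: str | None = None
    peptide_length: int = 15
    offset: int = 3
    replicate_count: int = 3
    blank_count: int = 30
    z_threshold: float = 3.0
    mad_scale: float = 1.0
    run_rule: str = "all_above"
    exposure_ratio_cut: float = 0.5
    exposure_fraction: float = 0.25
    discriminative_regions: tuple[tuple[int, int], ...] = (
        DEFAULT_DISCRIMINATIVE_REGIONS
    )
    titre_cutoff: float = 5.0
    titre_extract: str = "egg_white"
    ratio_component: str = "gal_d_1"


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure keep a ``.partial`` suffix.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("fasta", "spots", "patients", "structure", "outdir")
        },
        "inputs": {},
        "outputs": {},
    }
    stage = "design"
    try:
        for key in ("fasta", "spots", "patients", "structure"):
            path = getattr(config, key)
            if path is None:
                continue
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input file: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _digest(path)}

        sequences = read_fasta(config.fasta)
        probes = [
            p
            for seq in sequences
            for p in tile_sequence(seq, config.peptide_length, config.offset)
        ]
        layout = build_layout(
            probes,
            replicate_count=config.replicate_count,
            blank_count=config.blank_count,
        )
        write_layout(layout, out("layout.tsv"))

        stage = "signal"
        spots = read_spot_table(config.spots, layout)
        patients = read_patient_table(config.patients)
        signal = build_signal_table(spots, layout)
        z = compute_zscores(signal, mad_scale=config.mad_scale)
        write_zscore_table(z, layout, out("zscores.tsv"))
        write_normalization_stats(z, out("normalization_stats.json"))

        stage = "call"
        calls = call_epitopes(
            z, layout, threshold=config.z_threshold, run_rule=config.run_rule
        )
        write_calls(calls, out("epitope_calls.tsv"))
        patient_ids = [p.patient_id for p in patients]
        matrix = epitope_patient_matrix(
            calls, patient_ids, channel="IgE"
        )
        matrix.to_csv(out("epitope_matrix_ige.csv"))
        xref = cross_reference_channels(
            [c for c in calls if c.channel == "IgE"],
            [c for c in calls if c.channel == "IgG4"],
        )
        xref.to_csv(out("channel_crossref.csv"), index=False)

        stage = "surface"
        exposure_verdicts = []
        if config.structure is not None:
            target = config.structure_antigen or sequences[0].antigen_id
            mature = next(
                s.residues for s in sequences if s.antigen_id == target
            )
            exposures = compute_residue_accessibility(
                config.structure, mature_sequence=mature
            )
            write_exposure_table(exposures, out("residue_exposure.tsv"))
            regions = sorted(
                {
                    (c.region_start, c.region_end)
                    for c in calls
                    if c.antigen_id == target
                }
            )
            for region in regions:
                v = classify_epitope_exposure(
                    region, exposures, min_fraction=config.exposure_fraction
                )
                exposure_verdicts.append(
                    {
                        "region": f"aa{v.region_start}-{v.region_end}",
                        "n_residues": v.n_residues,
                        "n_exposed": v.n_exposed,
                        "surface_exposed": v.surface_exposed,
                    }
                )
            out("exposure_verdicts.json").write_text(
                json.dumps(exposure_verdicts, indent=1)
            )

        stage = "diagnose"
        truth = {p.patient_id: p.group for p in patients}
        report: dict = {"n_patients": len(patients)}
        epi_pred = epitope_classifier(
            calls, patient_ids, regions=config.discriminative_regions
        )
        report["epitope_rule"] = diagnostic_performance(epi_pred, truth).summary()
        titres = {
            p.patient_id: p.immunocap.get(config.titre_extract, 0.0)
            for p in patients
        }
        titre_pred = threshold_classifier(titres, config.titre_cutoff)
        report["titre_rule"] = diagnostic_performance(titre_pred, truth).summary()
        ratios = [
            ige_igg4_ratio(
                p.el_ige.get(config.ratio_component, 0.0),
                p.el_igg4.get(config.ratio_component, 0.0),
                p.patient_id,
                config.ratio_component,
            )
            for p in patients
        ]
        for group in ("allergic", "tolerant"):
            grp = [
                r for r, p in zip(ratios, patients) if p.group == group
            ]
            defined = [r for r in grp if r.ratio is not None]
            report[f"median_ratio_{group}"] = (
                ratio_median(defined) if defined else None
            )
            els = [
                p.el_ige.get(config.ratio_component)
                for p in patients
                if p.group == group
                and p.el_ige.get(config.ratio_component) is not None
            ]
            if els:
                med = float(sorted(els)[len(els) // 2])
                report[f"median_el_ige_{group}"] = med
                report[f"east_class_{group}"] = el_to_east_class(med)
        report["surface_verdicts"] = exposure_verdicts
        out("diagnostics.json").write_text(json.dumps(report, indent=1))

        manifest["outputs"] = {
            p.name: {"sha256": _digest(p)} for p in written if p.exists()
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        return manifest
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineError(stage, exc) from exc
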