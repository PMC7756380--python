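"""Synthetic cohorts: spot-level fluorescence, metadata, toy structures.

The generator emulates the statistical structure the analysis assumes: a
tiled antigen printed in triplicate with blank spots, lognormal
backgrounds, null probes whose log2 signal-to-noise fluctuates around 0,
and planted epitope regions that multiply the signal of every probe
*containing* the region by ``2^(effect_size_z * MAD_nominal)``, where
``MAD_nominal = 0.6745 * sigma_null`` is the expected blank MAD — so
``effect_size_z`` maps directly onto the z-score scale and the detection
threshold is analytically predictable.

Recognition is group-structured: each planted epitope is recognized per
patient with a group-specific probability (or by an exact per-group count
when given), IgE recognition is co-copied to IgG4 with a clonal-overlap
probability, and serology metadata (immunoblot intensities, extract
titres) is drawn around group-specific medians.

All randomness flows from one seed through per-patient substreams, so
growing the cohort never perturbs earlier patients. Default cohort
conditions: 13 allergic and 15 tolerant patients on a 186-residue
antigen with three rarely-tolerated discriminative regions and one
broadly recognized region, all aligned to the tiling grid so planted
regions are recoverable exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arrayio import BLANK, PatientRecord, SPOT_COLUMNS
from .tiling import ArrayLayout, MatureSequence, build_layout, tile_sequence

#: Gaussian consistency: MAD of N(0, sigma) is 0.6745 sigma.
MAD_PER_SIGMA = 0.674489750196082

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedEpitope:
    """A ground-truth reactive region planted into synthetic arrays."""

    start: int
    end: int
    channel: str = "IgE"
    recognition_prob_allergic: float = 0.2
    recognition_prob_tolerant: float = 0.03
    effect_size_z: float = 8.0
    #: exact per-group recognizer counts override the Bernoulli draws
    n_recognizers_allergic: int | None = None
    n_recognizers_tolerant: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid region ({self.start}, {self.end})")
        for p in (self.recognition_prob_allergic, self.recognition_prob_tolerant):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"recognition probability {p} outside [0, 1]")
        if self.effect_size_z <= 0:
            raise ValueError("effect_size_z must be positive")

    @property
    def region(self) -> tuple[int, int]:
        return (self.start, self.end)


def default_planted_epitopes() -> list[PlantedEpitope]:
    """Three discriminative regions plus one broadly recognized region.

    The regions are two-probe consensus intervals realizable on the
    default tiling grid (probe starts 1, 4, 7, ...), so a planted region
    is recovered as exactly that region by the epitope caller. Per-region
    recognition probabilities give allergic patients roughly even odds of
    recognizing at least one discriminative region, against rare tolerant
    recognition — the recognition structure of a component-discriminating
    cohort.
    """
    return [
        PlantedEpitope(31, 42, "IgE", 0.2, 0.03),
        PlantedEpitope(40, 51, "IgE", 0.2, 0.03),
        PlantedEpitope(85, 96, "IgE", 0.2, 0.03),
        PlantedEpitope(46, 57, "IgE", 0.38, 0.27),
    ]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_allergic: int = 13
    n_tolerant: int = 15
    antigen_length: int = 186
    planted_epitopes: list[PlantedEpitope] = field(
        default_factory=default_planted_epitopes
    )
    igg4_coclonal_prob: float = 0.8
    background_meanlog: float = math.log(1000.0)  # fluorescence units
    background_sdlog: float = 0.4
    sigma_null: float = 0.3  # log2 units, null spot-to-spot noise
    replicate_cv: float = 0.08
    blank_count: int = 30
    peptide_length: int = 15
    offset: int = 3
    replicate_count: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: no implicit randomness")
        if not 0.0 <= self.igg4_coclonal_prob <= 1.0:
            raise ValueError("igg4_coclonal_prob outside [0, 1]")
        for ep in self.planted_epitopes:
            if ep.end > self.antigen_length:
                raise ValueError(
                    f"planted region ({ep.start}, {ep.end}) outside antigen "
                    f"of length {self.antigen_length}"
                )

    @property
    def mad_nominal(self) -> float:
        return MAD_PER_SIGMA * self.sigma_null


@dataclass
class SimulatedCohort:
    """Spot table (array_io dialect), metadata, layout and ground truth."""

    spots: pd.DataFrame
    patients: list[PatientRecord]
    truth: list[dict]
    layout: ArrayLayout
    antigen: MatureSequence
    config: SyntheticCohortConfig | None = None


def _synthetic_antigen(length: int, rng: np.random.Generator) -> MatureSequence:
    residues = "".join(rng.choice(list(AA_ALPHABET), size=length))
    return MatureSequence(antigen_id="SYN_1", accession="SYNTH", residues=residues)


def simulate_cohort(
    config: SyntheticCohortConfig, layout: ArrayLayout | None = None
) -> SimulatedCohort:
    """Generate one cohort of synthetic arrays plus ground truth.

    Returns the spot table in the exact spot-TSV dialect of
    :mod:`epitile.arrayio`, validated patient records, and a truth table
    with one row per planted recognition event.
    """
    root = np.random.SeedSequence(config.seed)
    rng_seq = np.random.default_rng(root.spawn(1)[0])
    antigen = _synthetic_antigen(config.antigen_length, rng_seq)
    if layout is None:
        probes = tile_sequence(antigen, config.peptide_length, config.offset)
        layout = build_layout(
            probes,
            replicate_count=config.replicate_count,
            blank_count=config.blank_count,
        )

    patient_ids = [f"A{i + 1:02d}" for i in range(config.n_allergic)] + [
        f"T{i + 1:02d}" for i in range(config.n_tolerant)
    ]
    groups = ["allergic"] * config.n_allergic + ["tolerant"] * config.n_tolerant

    forced = _forced_recognizers(config, patient_ids, groups, root)

    rows: list[tuple] = []
    truth: list[dict] = []
    patients: list[PatientRecord] = []
    n_objective = round(8 / 13 * config.n_allergic)
    allergic_seen = 0
    for pidx, (pid, group) in enumerate(zip(patient_ids, groups)):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, pidx))
        )
        recognized = _patient_recognition(config, pid, group, forced, rng)
        for event in recognized:
            truth.append(dict(patient_id=pid, group=group, **event))
        rows.extend(
            _patient_spots(config, layout, pid, recognized, rng)
        )
        if group == "allergic":
            symptom = "objective" if allergic_seen < n_objective else "subjective"
            allergic_seen += 1
        else:
            symptom = "none"
        patients.append(_patient_metadata(pid, group, symptom, rng))

    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    return SimulatedCohort(
        spots=spots, patients=patients, truth=truth, layout=layout,
        antigen=antigen, config=config,
    )


def _forced_recognizers(
    config: SyntheticCohortConfig,
    patient_ids: list[str],
    groups: list[str],
    root: np.random.SeedSequence,
) -> dict[tuple[int, int, int], set[str]]:
    """Exact-count recognizer sets, drawn from a cohort-level substream."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2,))
    )
    out: dict[tuple[int, int, int], set[str]] = {}
    for ei, ep in enumerate(config.planted_epitopes):
        for grp, count in (
            ("allergic", ep.n_recognizers_allergic),
            ("tolerant", ep.n_recognizers_tolerant),
        ):
            if count is None:
                continue
            pool = [p for p, g in zip(patient_ids, groups) if g == grp]
            if count > len(pool):
                raise ValueError(
                    f"cannot pick {count} recognizers from {len(pool)} "
                    f"{grp} patients"
                )
            chosen = rng.choice(pool, size=count, replace=False)
            out.setdefault((ei, ep.start, ep.end), set()).update(chosen)
    return out


def _patient_recognition(
    config: SyntheticCohortConfig,
    pid: str,
    group: str,
    forced: dict[tuple[int, int, int], set[str]],
    rng: np.random.Generator,
) -> list[dict]:
    events = []
    for ei, ep in enumerate(config.planted_epitopes):
        key = (ei, ep.start, ep.end)
        exact = (
            ep.n_recognizers_allergic if group == "allergic"
            else ep.n_recognizers_tolerant
        )
        # a Bernoulli draw is consumed either way, keeping the patient's
        # stream identical whether or not exact counts are requested
        prob = (
            ep.recognition_prob_allergic if group == "allergic"
            else ep.recognition_prob_tolerant
        )
        bernoulli = rng.random() < prob
        hit = (pid in forced.get(key, set())) if exact is not None else bernoulli
        coclonal = rng.random() < config.igg4_coclonal_prob
        if not hit:
            continue
        events.append(
            dict(
                channel=ep.channel, region_start=ep.start, region_end=ep.end,
                effect_size_z=ep.effect_size_z,
            )
        )
        if ep.channel == "IgE" and coclonal:
            events.append(
                dict(
                    channel="IgG4", region_start=ep.start, region_end=ep.end,
                    effect_size_z=ep.effect_size_z,
                )
            )
    return events


def _patient_spots(
    config: SyntheticCohortConfig,
    layout: ArrayLayout,
    pid: str,
    recognized: list[dict],
    rng: np.random.Generator,
) -> list[tuple]:
    rows = []
    for channel in layout.channels:
        deltas = {}
        for probe in layout.probes:
            effects = [
                ev["effect_size_z"]
                for ev in recognized
                if ev["channel"] == channel
                and probe.contains(ev["region_start"], ev["region_end"])
            ]
            deltas[probe.probe_id] = (
                max(effects) * config.mad_nominal if effects else 0.0
            )
        for probe in layout.probes:
            for rep in range(1, layout.replicate_count + 1):
                background = rng.lognormal(
                    config.background_meanlog, config.background_sdlog
                )
                eps = rng.normal(0.0, config.sigma_null)
                jitter = math.exp(rng.normal(0.0, config.replicate_cv))
                total = background * 2 ** (deltas[probe.probe_id] + eps) * jitter
                rows.append(
                    (pid, probe.probe_id, rep, channel, total, background)
                )
        for pos in range(1, layout.blank_count + 1):
            background = rng.lognormal(
                config.background_meanlog, config.background_sdlog
            )
            eps = rng.normal(0.0, config.sigma_null)
            rows.append(
                (pid, BLANK, pos, channel, background * 2**eps, background)
            )
    return rows


#: Group medians the serology metadata is drawn around (lognormal, median
#: = exp(meanlog)): immunoblot RU for the main component and extract
#: titres in kU/L.
SEROLOGY_MEDIANS = {
    "allergic": {"ige_ru": 67.0, "igg4_ru": 46.0,
                 "egg_white": 7.0, "egg_yolk": 0.9},
    "tolerant": {"ige_ru": 33.0, "igg4_ru": 71.0,
                 "egg_white": 4.6, "egg_yolk": 3.3},
}


def _patient_metadata(
    pid: str, group: str, symptom: str, rng: np.random.Generator
) -> PatientRecord:
    med = SEROLOGY_MEDIANS[group]
    draw = lambda m, sd: float(rng.lognormal(math.log(m), sd))
    return PatientRecord(
        patient_id=pid,
        group=group,
        symptom_class=symptom,
        challenge=bool(rng.random() < 0.4),
        el_ige={"gal_d_1": draw(med["ige_ru"], 0.5)},
        el_igg4={"gal_d_1": draw(med["igg4_ru"], 0.5)},
        immunocap={
            "egg_white": draw(med["egg_white"], 0.8),
            "egg_yolk": draw(med["egg_yolk"], 0.8),
        },
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write spot TSV, patient CSV, truth JSON and config YAML; returns
    the paths."""
    import dataclasses

    import yaml

    from .arrayio import write_patient_table
    from .tiling import write_layout

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": outdir / "spots.tsv",
        "patients": outdir / "patients.csv",
        "truth": outdir / "truth.json",
        "layout": outdir / "layout.tsv",
        "fasta": outdir / "antigen.fasta",
    }
    if cohort.config is not None:
        paths["config"] = outdir / "config.yaml"
        paths["config"].write_text(
            yaml.safe_dump(dataclasses.asdict(cohort.config), sort_keys=False)
        )
    cohort.spots.to_csv(paths["spots"], sep="\t", index=False)
    write_patient_table(cohort.patients, paths["patients"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1))
    write_layout(cohort.layout, paths["layout"])
    paths["fasta"].write_text(
        f">{cohort.antigen.antigen_id} {cohort.antigen.accession}\n"
        f"{cohort.antigen.residues}\n"
    )
    return paths


# ---------------------------------------------------------------------------
# toy structures


_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF atom placement: position d with |cd|=bond, angle(b,c,d),
    torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _extended_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry extended chain (phi = psi = omega = 180 deg)."""
    coords: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    C = CA + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n_res):
        prev = coords[-1]
        N = _place(prev["N"], prev["CA"], prev["C"],
                   _BOND["C-N"], _ANGLE["CA-C-N"], 180.0)  # psi
        CA = _place(prev["CA"], prev["C"], N,
                    _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # omega
        C = _place(prev["C"], N, CA,
                   _BOND["CA-C"], _ANGLE["N-CA-C"], 180.0)  # phi
        coords.append({"N": N, "CA": CA, "C": C})
    for i, res in enumerate(coords):
        res["O"] = _place(res["N"], res["CA"], res["C"],
                          _BOND["C-O"], _ANGLE["CA-C-O"], 0.0)
    return coords


def _sleeve_points(
    atoms: Sequence[np.ndarray],
    axis: np.ndarray,
    radius: float,
    ring_spacing: float,
    ring_size: int,
    shrink: float,
    cap_radii: Sequence[float],
) -> np.ndarray:
    """Dummy positions on an open-ended cylinder around the chain axis.

    The cylinder covers the axial span of ``atoms`` shortened by
    ``shrink`` on each side (limits occlusion of the bonded neighbors);
    annular end-cap rings narrow the axial escape cones while leaving a
    tube for the chain itself.
    """
    u = np.asarray(axis, dtype=float)
    u /= np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    center = np.mean(atoms, axis=0)
    proj = [(a - center) @ u for a in atoms]
    t0, t1 = min(proj) + shrink, max(proj) - shrink
    if t1 <= t0:
        t0 = t1 = 0.5 * (t0 + t1)
    n_rings = max(2, int(round((t1 - t0) / ring_spacing)) + 1)

    def ring(t: float, r: float, n: int) -> list[np.ndarray]:
        angles = 2 * np.pi * np.arange(n) / n
        return [
            center + t * u + r * (math.cos(a) * v + math.sin(a) * w)
            for a in angles
        ]

    pts: list[np.ndarray] = []
    for t in np.linspace(t0, t1, n_rings):
        pts.extend(ring(t, radius, ring_size))
    for t in (t0, t1):
        for cap_radius in cap_radii:
            n_cap = max(8, int(round(ring_size * cap_radius / radius)))
            pts.extend(ring(t, cap_radius, n_cap))
    return np.array(pts)


def make_toy_structure(
    spec: Sequence[tuple[str, bool]],
    path: str | Path | None = None,
    sleeve_radius: float = 3.0,
    ring_spacing: float = 0.5,
    ring_size: int = 48,
    shrink: float = 1.25,
    cap_radii: Sequence[float] = (2.0, 2.7),
) -> str:
    """PDB text for an extended chain with optionally buried residues.

    ``spec`` lists (one-letter residue, buried flag). A buried residue is
    wrapped in a capped cylinder ("sleeve") of dummy hydrogen HETATMs
    around the chain axis: its relative accessibility drops well below
    the 0.5 exposure cut while the bonded neighbors stay exposed (the
    sleeve is axially shortened and its end caps leave a tube for the
    chain). Geometry defaults were chosen on this construction so that
    flagged residues score < 0.05 and unflagged neighbors > 0.55.
    """
    for aa, _ in spec:
        if aa not in AA3:
            raise ValueError(f"unknown residue letter {aa!r}")
    backbone = _extended_backbone(len(spec))
    lines = []
    serial = 1
    for i, ((aa, _), res) in enumerate(zip(spec, backbone), start=1):
        for name in ("N", "CA", "C", "O"):
            x, y, z = res[name]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<4s}{AA3[aa]:>3s} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    hetserial = serial
    if len(backbone) > 1:
        axis = backbone[-1]["CA"] - backbone[0]["CA"]
    else:
        axis = np.array([1.0, 0.0, 0.0])
    for i, ((aa, buried), res) in enumerate(zip(spec, backbone), start=1):
        if not buried:
            continue
        atoms = [res[name] for name in ("N", "CA", "C", "O")]
        for pt in _sleeve_points(
            atoms, axis, sleeve_radius, ring_spacing, ring_size,
            shrink, cap_radii,
        ):
            x, y, z = pt
            # one residue per dummy: PDB readers collapse duplicate atom
            # names within a residue
            lines.append(
                f"HETATM{hetserial:5d}  H   {'DUM':>3s} B{hetserial % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           H"
            )
            hetserial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
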