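"""Surface exposure of epitopes from per-residue solvent accessibility.

Accessible surface area (ASA) is computed by the Shrake-Rupley method:
each atom is inflated by the water-probe radius (1.4 Å), a deterministic
quasi-uniform point set is placed on the inflated sphere, and the
accessible fraction is the fraction of points not inside any neighboring
inflated sphere. A residue's *relative* accessibility is its summed ASA
divided by a residue-type-specific reference maximum (theoretical
Gly-X-Gly values of Tien et al. 2013 by default).

Decision rules: a residue is *exposed* when its relative accessibility is
strictly greater than 0.5; an epitope is *surface-exposed* when at least
25% of its residues are exposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

#: Van der Waals radii (Å) by element; fallback 1.70 for unknowns.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

#: Theoretical maximum ASA (Å^2) per residue type in an extended
#: Gly-X-Gly context (Tien et al. 2013, theoretical column).
MAX_ASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResidueExposure:
    """Relative solvent accessibility of one residue."""

    chain: str
    residue_index: int  # 1-based, aligned to the mature sequence
    amino_acid: str  # one-letter code
    accessibility_ratio: float
    exposed: bool
    flag: str = ""


@dataclass(frozen=True)
class ExposureVerdict:
    """Surface-exposure classification of one epitope region."""

    region_start: int
    region_end: int
    n_residues: int
    n_exposed: int
    surface_exposed: bool
    flag: str = ""

    @property
    def exposed_fraction(self) -> float:
        return self.n_exposed / self.n_residues


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden spiral).

    Deterministic; the discretization error of the accessible fraction
    scales as 1/n.
    """
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface area (Å^2).

    ``coords`` is (n_atoms, 3); ``radii`` the van der Waals radii. Returns
    one ASA value per atom. Adding atoms can only shrink existing atoms'
    ASA (monotone burial).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    n = len(coords)
    unit = sphere_points(n_points)
    inflated = radii + probe_radius
    asa = np.empty(n)
    for i in range(n):
        ri = inflated[i]
        # neighbors whose inflated spheres can intersect atom i's surface
        d = np.linalg.norm(coords - coords[i], axis=1)
        nbr = (d < ri + inflated) & (d > 0)
        pts = coords[i] + ri * unit
        if nbr.any():
            diff = pts[:, None, :] - coords[nbr][None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = (dist2 < (inflated[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        asa[i] = frac * 4.0 * np.pi * ri * ri
    return asa


def _chain_residues(structure, chain: str | None):
    model = next(structure.get_models())  # first model only
    residues = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if res.id[0] != " ":  # het/water: occluders, not residues
                continue
            residues.append((ch.id, res))
    return model, residues


def compute_residue_accessibility(
    structure: str | Path,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chain: str | None = None,
    mature_sequence: str | None = None,
    sidechain_only: bool = False,
    max_asa: dict[str, float] | None = None,
) -> list[ResidueExposure]:
    """Relative accessibility of every standard residue of a PDB structure.

    All atoms of the first model (including heteroatoms) occlude; only
    standard amino-acid residues are reported. With ``mature_sequence``
    the chain sequence is aligned to it and residues are reported in
    mature coordinates (author numbering is never trusted); otherwise
    residues are numbered 1..n in chain order. ``sidechain_only``
    restricts the residue ASA to non-backbone atoms (Gly falls back to
    its Cα).
    """
    max_asa = max_asa or MAX_ASA_TIEN
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("s", str(structure))
    model, residues = _chain_residues(struct, chain)
    if not residues:
        raise ValueError(f"{structure}: no protein residues found")

    atoms = [a for a in model.get_atoms()]
    coords = np.array([a.coord for a in atoms], dtype=float)
    radii = np.array(
        [VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS) for a in atoms]
    )
    asa = shrake_rupley(coords, radii, probe_radius=probe_radius, n_points=n_points)
    atom_asa = dict(zip((id(a) for a in atoms), asa))

    indices = _mature_indices(residues, mature_sequence)

    exposures = []
    for (chain_id, res), idx in zip(residues, indices):
        if idx is None:
            continue  # unaligned to the mature sequence
        resname = res.get_resname()
        names = {a.get_name() for a in res}
        flag = ""
        if sidechain_only:
            sel = [a for a in res if a.get_name() not in BACKBONE_ATOMS]
            if not sel:  # glycine: no side chain beyond Cα
                sel = [a for a in res if a.get_name() == "CA"]
        else:
            sel = list(res)
        if resname == "GLY":
            expected = {"N", "CA", "C", "O"}
        else:
            expected = {"N", "CA", "C", "O", "CB"}
        if not expected <= names:
            flag = "missing-atoms"
            logger.warning(
                "%s %s%s: missing atoms, ratio from present atoms only",
                chain_id, resname, res.id[1],
            )
        total = float(sum(atom_asa[id(a)] for a in sel))
        ref = max_asa.get(resname)
        if ref is None:
            flag = (flag + ";" if flag else "") + "no-reference-max"
            ratio = 0.0
        else:
            ratio = total / ref
        exposures.append(
            ResidueExposure(
                chain=chain_id,
                residue_index=idx,
                amino_acid=seq1(resname),
                accessibility_ratio=ratio,
                exposed=ratio > 0.5,
                flag=flag,
            )
        )
    return exposures


def _mature_indices(
    residues, mature_sequence: str | None
) -> list[int | None]:
    """Map structure residues to 1-based mature coordinates.

    Without a mature sequence, residues are numbered sequentially. With
    one, a global pairwise alignment of the chain sequence against the
    mature sequence defines the mapping; unaligned residues map to None.
    """
    if mature_sequence is None:
        return list(range(1, len(residues) + 1))
    chain_seq = "".join(seq1(res.get_resname()) for _, res in residues)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aln = aligner.align(chain_seq, mature_sequence)[0]
    mapping: list[int | None] = [None] * len(chain_seq)
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for off in range(qe - qs):
            mapping[qs + off] = ts + off + 1
    return mapping


def classify_epitope_exposure(
    region: tuple[int, int],
    exposures: Sequence[ResidueExposure],
    min_fraction: float = 0.25,
) -> ExposureVerdict:
    """Apply the >=25%-of-residues-exposed rule to one epitope region.

    Region residues absent from the structure (e.g. unresolved loops)
    count as not exposed and the verdict is flagged.
    """
    start, end = region
    if start > end:
        raise ValueError(f"invalid region ({start}, {end})")
    by_index = {e.residue_index: e for e in exposures}
    n_residues = end - start + 1
    n_exposed = 0
    missing = []
    for idx in range(start, end + 1):
        exp = by_index.get(idx)
        if exp is None:
            missing.append(idx)
        elif exp.exposed:
            n_exposed += 1
    flag = ""
    if missing:
        flag = f"unresolved-residues:{len(missing)}"
        warnings.warn(
            f"region aa{start}-{end}: {len(missing)} residue(s) absent from "
            "the structure counted as not exposed",
            stacklevel=2,
        )
    return ExposureVerdict(
        region_start=start,
        region_end=end,
        n_residues=n_residues,
        n_exposed=n_exposed,
        surface_exposed=(n_exposed / n_residues) >= min_fraction,
        flag=flag,
    )


def write_exposure_table(
    exposures: Sequence[ResidueExposure], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chain\tresidue_index\taa\tratio\texposed\n")
        for e in exposures:
            fh.write(
                f"{e.chain}\t{e.residue_index}\t{e.amino_acid}\t"
                f"{e.accessibility_ratio:.4f}\t{int(e.exposed)}\n"
            )
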