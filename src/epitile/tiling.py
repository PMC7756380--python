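"""Peptide probe design: overlapping tiling of mature antigen sequences.

A tiling microarray covers an antigen with short overlapping peptides
("probes") printed at a fixed offset along the mature sequence (signal
peptide removed; all coordinates are 1-based and inclusive on that
sequence). The default geometry is 15-mer peptides at offset 3, i.e.
consecutive probes share 12 residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Linker printed between peptide and slide surface (two beta-alanines and
#: one aspartic acid); metadata only, never enters coordinates or scoring.
DEFAULT_LINKER = "βAβAD"

DEFAULT_CHANNELS = ("IgE", "IgG4")


@dataclass(frozen=True)
class MatureSequence:
    """An antigen sequence in mature (signal-peptide-free) coordinates."""

    antigen_id: str
    accession: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(
                f"{self.antigen_id}: non-standard residue letters {sorted(bad)}; "
                "only the 20 standard one-letter codes are allowed"
            )
        if not self.residues:
            raise ValueError(f"{self.antigen_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PeptideProbe:
    """One printed peptide, an inclusive interval on the mature sequence."""

    probe_id: str
    antigen_id: str
    start: int
    end: int
    sequence: str
    linker: str = DEFAULT_LINKER

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.probe_id}: interval [{self.start},{self.end}] does not "
                f"match sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class ArrayLayout:
    """The probe set plus print geometry (replicates, blanks, channels).

    ``offset`` is the tiling grid step; probes whose starts differ by
    exactly this value are *contiguous* for epitope calling.
    """

    probes: list[PeptideProbe]
    replicate_count: int = 3
    blank_count: int = 30
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    offset: int | None = None

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("layout needs at least one probe")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.blank_count < 2:
            raise ValueError(
                "blank_count must be >= 2 (median deviation of blanks is "
                "degenerate otherwise)"
            )
        ids = [p.probe_id for p in self.probes]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate probe_id(s): {sorted(dup)}")
        for antigen in self.antigen_ids:
            starts = [p.start for p in self.probes_for(antigen)]
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError(
                    f"{antigen}: probe starts must be strictly increasing"
                )
            self._check_coverage(antigen)
        if self.offset is None:
            self.offset = self._infer_offset()

    def _infer_offset(self) -> int:
        diffs: list[int] = []
        for antigen in self.antigen_ids:
            starts = [p.start for p in self.probes_for(antigen)]
            diffs.extend(b - a for a, b in zip(starts, starts[1:]))
        if not diffs:  # single-probe layout
            return 1
        return max(set(diffs), key=diffs.count)

    def _check_coverage(self, antigen_id: str) -> None:
        """Probes must cover their span without gaps.

        Layouts produced by :func:`tile_sequence` span [1, L]; hand-built
        partial layouts may start later but must still be gap-free.
        """
        probes = self.probes_for(antigen_id)
        first = min(p.start for p in probes)
        last = max(p.end for p in probes)
        covered = set()
        for p in probes:
            covered.update(range(p.start, p.end + 1))
        missing = set(range(first, last + 1)) - covered
        if missing:
            raise ValueError(
                f"{antigen_id}: residues not covered by any probe: "
                f"{sorted(missing)[:10]}..."
            )

    @property
    def antigen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.probes:
            seen.setdefault(p.antigen_id, None)
        return list(seen)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def probes_for(self, antigen_id: str) -> list[PeptideProbe]:
        return [p for p in self.probes if p.antigen_id == antigen_id]

    def probe(self, probe_id: str) -> PeptideProbe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def spot_counts(self) -> dict[str, int]:
        """Expected spot counts per patient (all channels combined)."""
        n_ch = len(self.channels)
        return {
            "antigen_spots": len(self.probes) * self.replicate_count * n_ch,
            "blank_spots": self.blank_count * n_ch,
        }


def tile_sequence(
    seq: MatureSequence, peptide_length: int = 15, offset: int = 3
) -> list[PeptideProbe]:
    """Tile a mature sequence into overlapping peptide probes.

    Probes start at 1, 1+offset, 1+2*offset, ...; if the last regular
    probe does not reach the final residue, one extra probe ending exactly
    at the C-terminus is appended so that every residue is covered.
    """
    L = len(seq)
    if peptide_length > L:
        raise ValueError(
            f"{seq.antigen_id}: sequence length {L} is shorter than the "
            f"peptide length {peptide_length}"
        )
    if not 1 <= offset <= peptide_length:
        raise ValueError(f"offset must be in [1, {peptide_length}], got {offset}")

    pad = max(3, len(str(L)))
    starts = list(range(1, L - peptide_length + 2, offset))
    if starts[-1] + peptide_length - 1 < L:
        starts.append(L - peptide_length + 1)

    probes = []
    for s in starts:
        e = s + peptide_length - 1
        probes.append(
            PeptideProbe(
                probe_id=f"{seq.antigen_id}_{s:0{pad}d}",
                antigen_id=seq.antigen_id,
                start=s,
                end=e,
                sequence=seq.residues[s - 1 : e],
            )
        )
    return probes


def build_layout(
    probes: Sequence[PeptideProbe],
    replicate_count: int = 3,
    blank_count: int = 30,
    channels: Iterable[str] = DEFAULT_CHANNELS,
    offset: int | None = None,
) -> ArrayLayout:
    """Validate probes and assemble an :class:`ArrayLayout`."""
    return ArrayLayout(
        probes=list(probes),
        replicate_count=replicate_count,
        blank_count=blank_count,
        channels=tuple(channels),
        offset=offset,
    )


def read_fasta(path: str | Path) -> list[MatureSequence]:
    """Read mature antigen sequences from FASTA.

    The description line is parsed as ``>antigen_id accession ...``;
    a missing second token leaves the accession empty.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        accession = parts[1] if len(parts) > 1 else ""
        records.append(
            MatureSequence(
                antigen_id=rec.id,
                accession=accession,
                residues=str(rec.seq).upper(),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


LAYOUT_COLUMNS = ["probe_id", "antigen_id", "start", "end", "sequence", "linker"]


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    """Write the probe table as TSV (one row per probe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(LAYOUT_COLUMNS) + "\n")
        for p in layout.probes:
            fh.write(
                f"{p.probe_id}\t{p.antigen_id}\t{p.start}\t{p.end}\t"
                f"{p.sequence}\t{p.linker}\n"
            )


def read_layout(
    path: str | Path,
    replicate_count: int = 3,
    blank_count: int = 30,
    channels: Iterable[str] = DEFAULT_CHANNELS,
) -> ArrayLayout:
    """Read a probe TSV written by :func:`write_layout` back into a layout."""
    probes = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LAYOUT_COLUMNS:
            raise ValueError(f"unexpected layout header: {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, antigen, start, end, seq, linker = line.rstrip("\n").split("\t")
            probes.append(
                PeptideProbe(pid, antigen, int(start), int(end), seq, linker)
            )
    return build_layout(
        probes,
        replicate_count=replicate_count,
        blank_count=blank_count,
        channels=channels,
    )
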