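"""FG-motif valence accounting for fusion-protein sequences.

Nucleoporin-derived intrinsically disordered regions carry phenylalanine–
glycine (FG) dipeptide motifs, a subset of which occur in the GLFG
tetrapeptide context; their count per region is the motif "valence" that
governs phase-separation propensity.  This module counts FG/GLFG motifs
over whole sequences or annotated regions, applies F→A and FG→AA mutation
specifications, and computes residue-composition fractions.

Coordinates in the public interface are 1-based inclusive, matching
protein-literature convention; internally slices are half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ProteinSequence", "MutationSpec", "count_fg", "count_glfg",
           "fg_motif_positions", "apply_mutations", "composition_fraction",
           "read_fasta", "write_fasta"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_FG = re.compile(r"(?=FG)")
_GLFG = re.compile(r"(?=GLFG)")


@dataclass
class ProteinSequence:
    """One-letter residue string with named region annotations.

    ``regions`` maps a name to a 1-based inclusive ``(start, end)`` residue
    interval.
    """

    id: str
    residues: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.residues = str(self.residues).upper()
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in {self.id}: {sorted(bad)}")
        for name, (start, end) in self.regions.items():
            if not (1 <= start <= end <= len(self.residues)):
                raise ValueError(
                    f"region {name!r} ({start},{end}) outside sequence of "
                    f"length {len(self.residues)}"
                )

    def __len__(self):
        return len(self.residues)

    def region_slice(self, region: str | tuple[int, int] | None) -> tuple[int, str]:
        """Return (0-based offset, subsequence) for a region name/interval."""
        if region is None:
            return 0, self.residues
        if isinstance(region, str):
            region = self.regions[region]
        start, end = region
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(f"region ({start},{end}) out of bounds")
        return start - 1, self.residues[start - 1 : end]


@dataclass
class MutationSpec:
    """F→A ("FA") or FG→AA ("FGAA") substitutions.

    ``positions`` are the 1-based indices of the F residue of each targeted
    motif in the parent sequence.
    """

    kind: str
    positions: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("FA", "FGAA"):
            raise ValueError(f"kind must be 'FA' or 'FGAA', got {self.kind!r}")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based and must be >= 1")


def count_fg(seq: ProteinSequence, region: str | tuple[int, int] | None = None) -> int:
    """Number of FG dipeptide occurrences (GLFG occurrences count once)."""
    _, sub = seq.region_slice(region)
    if len(sub) == 0:
        logger.warning("counting FG motifs in an empty sequence/region")
        return 0
    return len(_FG.findall(sub))


def count_glfg(seq: ProteinSequence, region: str | tuple[int, int] | None = None) -> int:
    """Number of GLFG tetrapeptide occurrences."""
    _, sub = seq.region_slice(region)
    return len(_GLFG.findall(sub))


def fg_motif_positions(
    seq: ProteinSequence, region: str | tuple[int, int] | None = None
) -> list[int]:
    """1-based positions (of the F) of every FG motif, whole-sequence frame."""
    offset, sub = seq.region_slice(region)
    return [offset + m.start() + 1 for m in _FG.finditer(sub)]


def apply_mutations(seq: ProteinSequence, spec: MutationSpec) -> ProteinSequence:
    """Apply F→A or FG→AA substitutions; length is preserved.

    Every position must hold F (and G at the next residue for FG→AA) in the
    parent sequence; a mismatch raises ``ValueError`` naming the position.
    """
    res = list(seq.residues)
    for pos in spec.positions:
        i = pos - 1
        if i >= len(res) or res[i] != "F":
            raise ValueError(f"position {pos} is not F in {seq.id}")
        if spec.kind == "FGAA":
            if i + 1 >= len(res) or res[i + 1] != "G":
                raise ValueError(f"position {pos} is not the F of an FG motif in {seq.id}")
            res[i], res[i + 1] = "A", "A"
        else:
            res[i] = "A"
    suffix = f"_{len(spec.positions)}{spec.kind}" if spec.positions else ""
    return ProteinSequence(id=seq.id + suffix, residues="".join(res),
                           regions=dict(seq.regions))


def composition_fraction(
    seq: ProteinSequence,
    residue_set: set[str] | str,
    region: str | tuple[int, int] | None = None,
    window: int | None = None,
) -> float | np.ndarray:
    """Fraction of residues from ``residue_set`` in a region.

    With ``window`` set, returns the stride-1 sliding-window profile (one
    value per window); otherwise a single whole-region fraction.
    """
    residue_set = set(str(r).upper() for r in residue_set)
    if not residue_set:
        raise ValueError("residue_set must be non-empty")
    _, sub = seq.region_slice(region)
    ind = np.array([r in residue_set for r in sub], float)
    if window is None:
        return float(ind.mean()) if ind.size else 0.0
    if window < 1 or window > ind.size:
        raise ValueError(f"window {window} invalid for region of length {ind.size}")
    kernel = np.ones(window) / window
    return np.convolve(ind, kernel, mode="valid")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Minimal FASTA reader (no region annotations in the format)."""
    seqs: list[ProteinSequence] = []
    name, chunks = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs.append(ProteinSequence(name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line)
    if name is not None:
        seqs.append(ProteinSequence(name, "".join(chunks)))
    return seqs


def write_fasta(seqs: list[ProteinSequence], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
    return path
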