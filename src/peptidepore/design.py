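"""Design grammar for amphipathic beta-hairpin pore peptides.

The grammar assembles a 28-residue hairpin from five segments::

    N-cap (RG) | strand 1 (10 aa) | turn (DSDG) | strand 2 (10 aa) | C-cap (GR)

Strands alternate hydrophilic (Ser) and hydrophobic (Val) residues so the
assembled barrel presents a polar lumen and an apolar lipid-facing surface.
Tyrosines at positions 4, 12, 18 and 26 anchor the membrane interface
(snorkelling effect); the anionic turn (two Asp) and cationic termini (two
Arg) let an applied voltage orient the monomer.  An optional glycine kink
in a strand increases sheet curvature and favors a single barrel size
(the SVG28-style monodisperse redesign); its position is a user choice.

The default sequence is rule-derived from this grammar, not transcribed
from any published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HairpinDesignSpec",
    "DesignReport",
    "build_hairpin_sequence",
    "validate_design",
    "write_fasta",
    "HYDROPHOBIC",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: binary hydrophobicity table used for the alternation check
HYDROPHOBIC = set("AVLIMFWYC")
CATIONIC = set("RK")
ANIONIC = set("DE")


@dataclass
class HairpinDesignSpec:
    """Parameters of the hairpin grammar (positions are 1-based)."""

    strand_length: int = 10
    turn: str = "DSDG"
    n_cap: str = "RG"
    c_cap: str = "GR"
    hydrophilic: str = "S"
    hydrophobic: str = "V"
    snorkel: str = "Y"
    snorkel_positions: tuple[int, ...] = (4, 12, 18, 26)
    kink_position: int | None = None
    kink_residue: str = "G"

    @property
    def total_length(self) -> int:
        return len(self.n_cap) + len(self.c_cap) + 2 * self.strand_length + len(self.turn)

    def strand_ranges(self) -> tuple[range, range]:
        """1-based residue ranges of the two strands."""
        s1 = range(len(self.n_cap) + 1, len(self.n_cap) + self.strand_length + 1)
        s2_start = len(self.n_cap) + self.strand_length + len(self.turn) + 1
        return s1, range(s2_start, s2_start + self.strand_length)

    def turn_range(self) -> range:
        start = len(self.n_cap) + self.strand_length + 1
        return range(start, start + len(self.turn))

    def __post_init__(self) -> None:
        if self.strand_length < 2:
            raise ValueError("strands need at least two residues")
        s1, s2 = self.strand_ranges()
        in_strands = set(s1) | set(s2)
        for p in self.snorkel_positions:
            if p in self.turn_range():
                raise ValueError(f"snorkel position {p} collides with the turn")
            if p not in in_strands:
                raise ValueError(f"snorkel position {p} lies outside the strands")
        if self.kink_position is not None and self.kink_position not in in_strands:
            raise ValueError(
                f"kink position {self.kink_position} must lie inside a strand segment"
            )


def build_hairpin_sequence(spec: HairpinDesignSpec | None = None) -> str:
    """Assemble the peptide sequence from the grammar, deterministically.

    Within each strand, even offsets from the strand start are hydrophilic
    and odd offsets hydrophobic; snorkel residues then replace the listed
    positions, and the optional kink replaces one strand residue with Gly.
    """
    if spec is None:
        spec = HairpinDesignSpec()
    residues: dict[int, str] = {}
    pos = 1
    for ch in spec.n_cap:
        residues[pos] = ch
        pos += 1
    for rng in spec.strand_ranges():
        for i, p in enumerate(rng):
            residues[p] = spec.hydrophilic if i % 2 == 0 else spec.hydrophobic
    for i, ch in enumerate(spec.turn):
        residues[spec.turn_range()[i]] = ch
    c_start = spec.total_length - len(spec.c_cap) + 1
    for i, ch in enumerate(spec.c_cap):
        residues[c_start + i] = ch
    for p in spec.snorkel_positions:
        residues[p] = spec.snorkel
    if spec.kink_position is not None:
        residues[spec.kink_position] = spec.kink_residue
    return "".join(residues[p] for p in range(1, spec.total_length + 1))


@dataclass
class DesignReport:
    """Rule-compliance report for one candidate sequence."""

    sequence: str
    flags: dict = field(default_factory=dict)
    net_charge: int = 0

    @property
    def passed(self) -> bool:
        return all(self.flags.values())


def net_formal_charge(sequence: str) -> int:
    """Formal charge at neutral pH by residue counting (R,K = +1; D,E = -1)."""
    return sum(+1 for r in sequence if r in CATIONIC) - sum(
        1 for r in sequence if r in ANIONIC
    )


def validate_design(
    sequence: str, spec: HairpinDesignSpec | None = None
) -> DesignReport:
    """Check a sequence against the hairpin grammar.

    Flags: ``length``; ``alternation`` of hydrophilic/hydrophobic residues
    within the strand segments (snorkel and kink positions exempt);
    ``turn_charges`` (at least two anionic residues in the turn);
    ``terminal_charges`` (a cationic residue in each cap); and
    ``snorkel`` placement.  The net formal charge is always reported.
    """
    if spec is None:
        spec = HairpinDesignSpec()
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")

    flags: dict[str, bool] = {}
    flags["length"] = len(sequence) == spec.total_length

    exempt = set(spec.snorkel_positions)
    if spec.kink_position is not None:
        exempt.add(spec.kink_position)

    alternation = True
    if flags["length"]:
        for rng in spec.strand_ranges():
            for i, p in enumerate(rng):
                if p in exempt:
                    continue
                res = sequence[p - 1]
                want_philic = i % 2 == 0
                if want_philic == (res in HYDROPHOBIC):
                    alternation = False
    else:
        alternation = False
    flags["alternation"] = alternation

    if flags["length"]:
        turn_seq = "".join(sequence[p - 1] for p in spec.turn_range())
        flags["turn_charges"] = sum(r in ANIONIC for r in turn_seq) >= 2
        n_cap = sequence[: len(spec.n_cap)]
        c_cap = sequence[len(sequence) - len(spec.c_cap) :]
        flags["terminal_charges"] = any(r in CATIONIC for r in n_cap) and any(
            r in CATIONIC for r in c_cap
        )
        flags["snorkel"] = all(
            sequence[p - 1] == spec.snorkel for p in spec.snorkel_positions
        )
    else:
        flags["turn_charges"] = flags["terminal_charges"] = flags["snorkel"] = False

    return DesignReport(
        sequence=sequence, flags=flags, net_charge=net_formal_charge(sequence)
    )


def write_fasta(designs: list[tuple[str, str]], path) -> Path:
    """Write ``(name, sequence)`` designs to a FASTA file."""
    if not designs:
        raise ValueError("no designs to write")
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="rule-derived beta-hairpin design")
        for name, seq in designs
    ]
    try:
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    except OSError as exc:
        raise OSError(f"could not write FASTA to {path}: {exc}") from exc
    return path
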