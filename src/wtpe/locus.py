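"""Reference loci and SpCas9 protospacer/PAM/cut-site geometry.

Coordinate conventions used throughout the package:

* all coordinates are 0-based, half-open intervals on the + strand of a
  :class:`Locus` sequence;
* a protospacer is 20 nt followed by an NGG PAM on its own strand;
* the blunt double-strand break sits 3 bp 5' of the PAM on the protospacer
  strand, i.e. between protospacer positions 17 and 18.  For a + strand
  protospacer occupying ``[s, s+20)`` the cut coordinate is ``s + 17``;
  for a - strand protospacer occupying the same + strand interval it is
  ``s + 3``.

The *non-target strand* (NTS) of a site is the strand that carries the
protospacer sequence; the *residue spacer* is the 17-nt protospacer portion
retained on the PAM-distal side of the cut, which remains visible at edited
junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import CoordinateError, InvalidAlphabetError

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SPACER_LEN = 20
PAM_LEN = 3
#: distance from the PAM-proximal protospacer end to the blunt cut
CUT_OFFSET = 3
#: length of the protospacer remnant on the PAM-distal side of the cut
RESIDUE_SPACER_LEN = SPACER_LEN - CUT_OFFSET


def _check_dna(seq: str) -> str:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise InvalidAlphabetError(f"non-DNA characters in sequence: {bad}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def format_interval(name: str, start: int, end: int, strand: str = "+") -> str:
    """Render an interval as ``name:start-end(strand)``, half-open."""
    return f"{name}:{start}-{end}({strand})"


@dataclass(frozen=True)
class Locus:
    """A reference sequence with a name and an informational genomic offset."""

    name: str
    sequence: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidAlphabetError("locus sequence must be non-empty")
        _check_dna(self.sequence)
        if self.sequence != self.sequence.upper():
            object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpacerSite:
    """A 20-nt protospacer with its PAM, strand and blunt-cut coordinate.

    ``protospacer_interval`` is always given on the + strand; ``protospacer``
    and ``pam`` are given 5'->3' on the site's own strand.
    """

    locus_name: str
    protospacer: str
    pam: str
    strand: str
    protospacer_interval: tuple[int, int]
    cut_position: int = field(default=-1)

    def __post_init__(self) -> None:
        _check_dna(self.protospacer)
        _check_dna(self.pam)
        if len(self.protospacer) != SPACER_LEN:
            raise ValueError(f"protospacer must be {SPACER_LEN} nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        s, e = self.protospacer_interval
        if e - s != SPACER_LEN:
            raise ValueError("protospacer interval must span 20 nt")
        if self.cut_position < 0:
            object.__setattr__(self, "cut_position", cut_position_of_interval(s, self.strand))

    @property
    def interval_str(self) -> str:
        s, e = self.protospacer_interval
        return format_interval(self.locus_name, s, e, self.strand)


def cut_position_of_interval(start: int, strand: str) -> int:
    """Blunt-cut coordinate for a protospacer starting at ``start`` on + strand."""
    if strand == "+":
        return start + RESIDUE_SPACER_LEN
    return start + CUT_OFFSET


def cut_position_of(site: SpacerSite) -> int:
    """The blunt DSB coordinate of a site (3 bp 5' of the PAM on its strand)."""
    return cut_position_of_interval(site.protospacer_interval[0], site.strand)


def find_spacer_sites(locus: Locus, region: tuple[int, int] | None = None) -> list[SpacerSite]:
    """Enumerate every SpCas9 site (20-mer + NGG) on both strands of a region.

    N in the genome never matches a protospacer or PAM position, so any
    candidate window containing N is skipped.  Sites are sorted by cut
    position, then strand.
    """
    seq = locus.sequence
    n = len(seq)
    if region is None:
        region = (0, n)
    start, end = region
    if start < 0 or end > n or start > end:
        raise CoordinateError(f"region {region} outside locus of length {n}")
    if end - start < SPACER_LEN + PAM_LEN:
        raise CoordinateError("region shorter than a protospacer + PAM (23 nt)")

    sites: list[SpacerSite] = []
    # + strand: protospacer [s, s+20), PAM [s+20, s+23) == NGG
    for s in range(start, end - (SPACER_LEN + PAM_LEN) + 1):
        window = seq[s : s + SPACER_LEN + PAM_LEN]
        if "N" in window:
            continue
        if window[SPACER_LEN + 1] == "G" and window[SPACER_LEN + 2] == "G":
            sites.append(
                SpacerSite(
                    locus_name=locus.name,
                    protospacer=window[:SPACER_LEN],
                    pam=window[SPACER_LEN:],
                    strand="+",
                    protospacer_interval=(s, s + SPACER_LEN),
                )
            )
    # - strand: protospacer occupies [s, s+20) on +, PAM [s-3, s) reads CCN on +
    for s in range(max(start, 0) + PAM_LEN, end - SPACER_LEN + 1):
        window = seq[s - PAM_LEN : s + SPACER_LEN]
        if "N" in window:
            continue
        if window[0] == "C" and window[1] == "C":
            sites.append(
                SpacerSite(
                    locus_name=locus.name,
                    protospacer=reverse_complement(window[PAM_LEN:]),
                    pam=reverse_complement(window[:PAM_LEN]),
                    strand="-",
                    protospacer_interval=(s, s + SPACER_LEN),
                )
            )
    sites.sort(key=lambda x: (x.cut_position, x.strand))
    return sites


def read_loci(path: str | Path) -> dict[str, Locus]:
    """Load loci from a (multi-)FASTA file; record id becomes the locus name."""
    loci: dict[str, Locus] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        loci[rec.id] = Locus(name=rec.id, sequence=str(rec.seq).upper())
    return loci


def write_loci(loci: Iterable[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f">{locus.name}\n{locus.sequence}\n")
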