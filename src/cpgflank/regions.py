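"""Reference regions with indexed CpG and Dcm sites.

A region is a plain DNA string over {A,C,G,T} plus the coordinates needed by
every downstream stage: the 0-based top-strand positions of the C of each CG
dinucleotide, and the positions of the internal cytosine of each CCWGG
(W in {A,T}) Dcm recognition site, per strand.  CG is its own reverse
complement, so one index serves both strands; CCWGG occurrences likewise come
in strand pairs over the same window (the reverse complement of CCAGG is
CCTGG), with the bottom-strand internal C sitting opposite the top-strand G
at offset +3 of the match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DCM_RE = re.compile(r"(?=CC[AT]GG)")
_VALID_RE = re.compile(r"^[ACGT]+$")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_cpg_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CG dinucleotide on the top strand."""
    return [m.start() for m in re.finditer(r"(?=CG)", seq)]


def find_dcm_sites(seq: str) -> tuple[list[int], list[int]]:
    """Dcm (CCWGG) internal-cytosine positions, in top-strand coordinates.

    Returns ``(top, bottom)``: ``top`` holds the internal C (match offset +1)
    of each top-strand CCWGG; ``bottom`` holds the top-strand position of the
    G (match offset +3) complementary to the bottom-strand internal C.
    """
    starts = [m.start() for m in _DCM_RE.finditer(seq)]
    return [s + 1 for s in starts], [s + 3 for s in starts]


@dataclass
class ReferenceRegion:
    """A named DNA region with indexed CpG and Dcm sites.

    Coordinates are 0-based, half-open throughout; a CpG site is identified
    by its top-strand C position.
    """

    name: str
    sequence: str
    cpg_sites: list[int] = field(default_factory=list)
    dcm_sites_top: list[int] = field(default_factory=list)
    dcm_sites_bottom: list[int] = field(default_factory=list)

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "ReferenceRegion":
        sequence = sequence.upper()
        if not _VALID_RE.match(sequence):
            raise ValueError(f"region {name!r}: sequence must be non-empty over ACGT")
        top, bottom = find_dcm_sites(sequence)
        return cls(
            name=name,
            sequence=sequence,
            cpg_sites=find_cpg_sites(sequence),
            dcm_sites_top=top,
            dcm_sites_bottom=bottom,
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_sites)

    def has_full_flank(self, site: int, k: int) -> bool:
        """True if the CpG at top-strand position ``site`` has k bases on each side."""
        return site - k >= 0 and site + 2 + k <= len(self.sequence)

    def flank_window(self, site: int, strand: str, k: int) -> str:
        """5'->3' context of length 2k+2 around a CpG on the requested strand.

        The middle dinucleotide is CG in the reported orientation; the bottom
        strand window is the reverse complement of the top-strand window.
        """
        if site not in set(self.cpg_sites):
            raise ValueError(f"{site} is not a CpG site of region {self.name!r}")
        if not self.has_full_flank(site, k):
            raise ValueError(
                f"CpG at {site} lacks {k} flanking bases on each side (edge site)"
            )
        window = self.sequence[site - k : site + 2 + k]
        if strand == "top":
            return window
        if strand == "bottom":
            return reverse_complement(window)
        raise ValueError(f"unknown strand {strand!r}")
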