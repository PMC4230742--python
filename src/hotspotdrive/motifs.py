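"""Degenerate 13-bp motif scanning.

The hotspot motif (HM, ``CCTCCCTNNCCAC``) is the binding target of the
major human PRDM9 allele; the control motif (CM, ``CTTCCCTNNCCAC``) differs
only at the second position and has no effect on recombination, making it a
mutational control.  The two N positions are never compared across
lineages, and the discriminating second position is excluded as well when
contrasting HM and CM, leaving 10 comparison-informative positions; 11
non-N positions define the disruption opportunity (k = 11).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["MotifPattern", "MotifHit", "HM", "CM", "scan_motifs", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif over {A,C,G,T,N} with its informative-site map."""

    pattern: str
    motif_id: str
    comparison_informative_positions: frozenset[int]
    disruption_length: int

    def __post_init__(self) -> None:
        if not set(self.pattern) <= set("ACGTN"):
            raise ValueError(f"invalid motif alphabet: {self.pattern!r}")
        non_n = sum(1 for c in self.pattern if c != "N")
        if self.disruption_length != non_n:
            raise ValueError("disruption_length must equal the non-N count")
        for p in self.comparison_informative_positions:
            if not 0 <= p < len(self.pattern) or self.pattern[p] == "N":
                raise ValueError("informative positions must index non-N sites")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def regex(self) -> re.Pattern:
        return re.compile("(?=(" + self.pattern.replace("N", "[ACGT]") + "))")


def _motif(pattern: str, motif_id: str) -> MotifPattern:
    informative = frozenset(
        i for i, c in enumerate(pattern) if c != "N" and i != 1
    )
    return MotifPattern(
        pattern=pattern,
        motif_id=motif_id,
        comparison_informative_positions=informative,
        disruption_length=sum(1 for c in pattern if c != "N"),
    )


#: Hotspot motif of PRDM9 allele A.
HM = _motif("CCTCCCTNNCCAC", "HM")
#: Control motif (second position differs; not recombinogenic).
CM = _motif("CTTCCCTNNCCAC", "CM")

PATTERNS = {"HM": HM, "CM": CM}


@dataclass(frozen=True, order=True)
class MotifHit:
    """A located motif occurrence (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str = field(compare=False, default="+")
    motif_id: str = field(compare=False, default="")
    matched_sequence: str = field(compare=False, default="")

    def informative_positions(self, pattern: MotifPattern) -> list[int]:
        """Genomic positions of the comparison-informative sites, taking
        strand into account (offset o on '-' maps to end-1-o)."""
        offsets = sorted(pattern.comparison_informative_positions)
        if self.strand == "+":
            return [self.start + o for o in offsets]
        return sorted(self.end - 1 - o for o in offsets)


def scan_motifs(
    sequence: str,
    pattern: MotifPattern,
    strands: str = "both",
    chrom: str = "seq",
) -> list[MotifHit]:
    """Report every window of ``sequence`` matching ``pattern``.

    N in the pattern matches any base; N or gaps in the subject never
    match.  Overlapping matches are all reported; duplicates at the same
    (chrom, start, end) are collapsed (keeping the + strand orientation);
    hits come back sorted by position.
    """
    if strands not in ("both", "plus"):
        raise ValueError("strands must be 'both' or 'plus'")
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    hits: dict[tuple[str, int, int], MotifHit] = {}
    for m in pattern.regex.finditer(seq):
        s = m.start()
        hits[(chrom, s, s + len(pattern))] = MotifHit(
            chrom, s, s + len(pattern), "+", pattern.motif_id, m.group(1)
        )
    if strands == "both":
        rc = revcomp(seq)
        L = len(seq)
        for m in pattern.regex.finditer(rc):
            end = L - m.start()
            start = end - len(pattern)
            key = (chrom, start, end)
            if key not in hits:
                hits[key] = MotifHit(
                    chrom, start, end, "-", pattern.motif_id, m.group(1)
                )
    return sorted(hits.values())
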