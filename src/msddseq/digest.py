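"""In-silico restriction digestion.

Scans sequences for enzyme recognition sites, performs methylation-aware
double digestion, and supports fragment size selection as used when
designing a reduced-representation methylation library: a methylation-
insensitive cutter (MseI) is paired with one methylation-sensitive enzyme
whose cutting reports the methylation status of a single base in its
recognition site (AciI for CG, PstI for CHG, EcoT22I for CHH, DpnII for
adenine methylation at GATC).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

VALID_CONTEXTS = ("CG", "CHG", "CHH", "6mA", "none")

# context -> regex over the expanded recognition site identifying the
# reporting base (the base whose methylation blocks cutting)
_CONTEXT_PATTERNS = {
    "CG": r"C(?=G)",
    "CHG": r"C(?=[ACT]G)",
    "CHH": r"C(?=[ACT][ACT])",
    "6mA": r"A",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> str:
    try:
        return "".join(
            c if len(IUPAC[c]) == 1 else "[%s]" % IUPAC[c] for c in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol in recognition site: {exc}") from exc


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme and the methylation context it reports.

    ``cut_offset`` is the cut position within the recognition site on the
    forward strand (double-stranded overhangs are not modelled; one cut
    coordinate per site is enough for fragment accounting).
    ``reporting_offset`` marks the base whose methylation blocks cutting;
    when ``None`` it defaults to the first base of the recognition site
    matching the enzyme's context.
    """

    name: str
    recognition: str
    cut_offset: int
    methylation_sensitive: bool = False
    context: str = "none"
    reporting_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition site must be non-empty")
        _iupac_regex(self.recognition)  # validates alphabet
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition site")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.context == "6mA" and "A" not in self.recognition.upper():
            raise ValueError("6mA context requires an adenine in the recognition site")
        if self.reporting_offset is None and self.methylation_sensitive:
            object.__setattr__(
                self, "reporting_offset", self._default_reporting_offset()
            )

    def _default_reporting_offset(self) -> int:
        pat = _CONTEXT_PATTERNS.get(self.context)
        if pat is None:
            raise ValueError(
                f"enzyme {self.name}: sensitive enzyme needs a methylation context"
            )
        m = re.search(pat, self.recognition.upper())
        if m is None:
            raise ValueError(
                f"enzyme {self.name}: no {self.context}-context base in "
                f"{self.recognition}"
            )
        return m.start()

    @property
    def is_palindromic(self) -> bool:
        return self.recognition.upper() == reverse_complement(self.recognition.upper())


def default_registry() -> dict[str, Enzyme]:
    """The four context-reporting enzymes plus the insensitive MseI partner."""
    return {
        e.name: e
        for e in (
            Enzyme("MseI", "TTAA", 1),
            Enzyme("AciI", "CCGC", 1, methylation_sensitive=True, context="CG"),
            Enzyme("PstI", "CTGCAG", 5, methylation_sensitive=True, context="CHG"),
            Enzyme("EcoT22I", "ATGCAT", 5, methylation_sensitive=True, context="CHH"),
            Enzyme("DpnII", "GATC", 0, methylation_sensitive=True, context="6mA"),
        )
    }


ENZYME_PAIRS = {
    "CG": ("AciI", "MseI"),
    "CHG": ("PstI", "MseI"),
    "CHH": ("EcoT22I", "MseI"),
    "6mA": ("DpnII", "MseI"),
}


@dataclass(frozen=True)
class RestrictionSite:
    chrom: str
    pos: int  # 0-based start of the recognition match on the forward strand
    strand: str
    enzyme: Enzyme

    def cut_position(self) -> int:
        if self.strand == "+":
            return self.pos + self.enzyme.cut_offset
        return self.pos + len(self.enzyme.recognition) - self.enzyme.cut_offset

    def reporting_position(self) -> int:
        """Forward-strand coordinate of the base that governs sensitivity."""
        off = self.enzyme.reporting_offset
        if off is None:
            raise ValueError(f"{self.enzyme.name} has no reporting base")
        if self.strand == "+":
            return self.pos + off
        return self.pos + len(self.enzyme.recognition) - 1 - off


# chromosome-end sentinel used to label terminal fragments
CHROM_END = Enzyme("chrom_end", "N", 0)


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    left_enzyme: Enzyme = CHROM_END
    right_enzyme: Enzyme = CHROM_END

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must precede end")

    def __len__(self) -> int:
        return self.end - self.start


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if seq.strip("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN symbols: {bad}")
    return seq


def find_sites(
    sequence: str, enzyme: Enzyme, chrom: str = "chr"
) -> list[RestrictionSite]:
    """All recognition-site matches, forward strand and (for non-palindromic
    enzymes) reverse complement; N never matches; sorted by position."""
    seq = _validate_sequence(sequence)
    sites: list[RestrictionSite] = []
    fwd = re.compile(f"(?={_iupac_regex(enzyme.recognition)})")
    for m in fwd.finditer(seq):
        sites.append(RestrictionSite(chrom, m.start(), "+", enzyme))
    if not enzyme.is_palindromic:
        rev = re.compile(f"(?={_iupac_regex(reverse_complement(enzyme.recognition))})")
        for m in rev.finditer(seq):
            sites.append(RestrictionSite(chrom, m.start(), "-", enzyme))
    sites.sort(key=lambda s: (s.pos, s.strand))
    return sites


def effective_sites(
    sites: Iterable[RestrictionSite],
    methylome: Mapping[int, bool] | set[int] | None = None,
) -> list[RestrictionSite]:
    """Sites that actually cut: a methylation-sensitive enzyme is blocked at
    sites whose reporting base is methylated."""
    if methylome is None:
        return list(sites)
    methylated = (
        methylome if isinstance(methylome, (set, frozenset)) else
        {pos for pos, state in methylome.items() if state}
    )
    out = []
    for s in sites:
        if s.enzyme.methylation_sensitive and s.reporting_position() in methylated:
            continue
        out.append(s)
    return out


def double_digest(
    sequence: str,
    enzyme_a: Enzyme,
    enzyme_b: Enzyme,
    methylome: Mapping[int, bool] | set[int] | None = None,
    chrom: str = "chr",
) -> list[Fragment]:
    """Fragments from cutting with both enzymes; the fragments tile the
    sequence exactly and carry their flanking enzymes."""
    if enzyme_a.name == enzyme_b.name:
        raise ValueError("double digestion requires two distinct enzymes")
    seq = _validate_sequence(sequence)
    if not seq:
        return []
    sites = find_sites(seq, enzyme_a, chrom) + find_sites(seq, enzyme_b, chrom)
    cuts: dict[int, Enzyme] = {}
    for s in effective_sites(sites, methylome):
        cp = s.cut_position()
        if 0 < cp < len(seq):
            cuts.setdefault(cp, s.enzyme)
    boundaries = [0] + sorted(cuts) + [len(seq)]
    fragments = []
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        fragments.append(
            Fragment(
                chrom,
                left,
                right,
                cuts.get(left, CHROM_END),
                cuts.get(right, CHROM_END),
            )
        )
    return fragments


def fragment_size_distribution(fragments: Sequence[Fragment]) -> Counter:
    """Histogram of fragment lengths; counts sum to the number of fragments."""
    return Counter(len(f) for f in fragments)


def size_select(
    fragments: Sequence[Fragment], min_len: int = 250, max_len: int = 600
) -> list[Fragment]:
    """Fragments with min_len <= length <= max_len (inclusive bounds, the
    gel-selection default being 250-600 bp), order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [f for f in fragments if min_len <= len(f) <= max_len]


def write_fragments_bed(fragments: Sequence[Fragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t"
                f"{f.left_enzyme.name}|{f.right_enzyme.name}\n"
            )


def write_sites_bed(sites: Sequence[RestrictionSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            end = s.pos + len(s.enzyme.recognition)
            fh.write(f"{s.chrom}\t{s.pos}\t{end}\t{s.enzyme.name}\t0\t{s.strand}\n")
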