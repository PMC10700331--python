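"""In-silico PCR-RFLP genotyping.

Models the wet-lab assay used to type the bovine osteopontin c.495C>T SNP:
a primer pair defines an amplicon on a template sequence, a type IIS
restriction enzyme (MnlI, recognition CCTC, cutting downstream of its site)
digests the amplicon, and the genotype is read off the electrophoretic band
pattern — homozygotes show one allele's fragment ladder, heterozygotes the
union of both ladders (co-migrating fragments collapse into a single band).

Coordinates are 0-based half-open on the amplicon's top strand throughout;
fragment lengths are what a gel reads out, so only top-strand cut positions
are modeled. Complete digestion is assumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .exceptions import (
    AmbiguousPrimingError,
    NoAmplificationError,
    ParameterError,
    UncallableGenotypeError,
)

_DNA = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> None:
    if not seq or not _DNA.match(seq):
        raise ParameterError(f"{what} must be a nonempty string over A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        _check_dna(self.forward, "forward primer")
        _check_dna(self.reverse, "reverse primer")


@dataclass(frozen=True)
class EnzymeDef:
    """A type IIS restriction enzyme.

    ``cut_offset_top``/``cut_offset_bottom`` count bases downstream of the
    recognition site's 3' end, in the site's own reading orientation. MnlI
    is CCTC(7/6): the top strand is cut 7 nt past the site.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        _check_dna(self.recognition, f"recognition sequence of {self.name}")
        if self.cut_offset_top < 0 or self.cut_offset_bottom < 0:
            raise ParameterError("cut offsets must be >= 0")


#: The enzyme of the assay: MnlI, recognition CCTC, cuts N7 (top) / N6 (bottom).
MNLI = EnzymeDef("MnlI", "CCTC", 7, 6)


@dataclass(frozen=True)
class FragmentLadder:
    """Multiset of digest fragment lengths (bp), optionally tagged by allele."""

    fragments: tuple[int, ...]
    allele_label: str | None = None

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.fragments):
            raise ParameterError("fragment lengths must be >= 1 bp")
        object.__setattr__(self, "fragments", tuple(sorted(self.fragments)))

    @property
    def total_length(self) -> int:
        return sum(self.fragments)

    @property
    def distinct_bands(self) -> tuple[int, ...]:
        """Distinct fragment lengths — what a gel lane resolves into bands."""
        return tuple(sorted(set(self.fragments)))


@dataclass(frozen=True)
class GenotypeCall:
    """A diallelic genotype call with the band evidence that supports it."""

    genotype: str  # one of CC, CT, TT
    evidence: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.genotype not in ("CC", "CT", "TT"):
            raise ParameterError(f"genotype must be CC, CT or TT, got {self.genotype!r}")


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start offsets of needle in haystack."""
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def extract_amplicon(template: str, primers: PrimerPair) -> str:
    """Extract the PCR product defined by ``primers`` on ``template``.

    The amplicon runs from the unique exact top-strand match of the forward
    primer through the unique exact top-strand match of the reverse
    complement of the reverse primer, inclusive of both primer sites, and is
    returned 5'->3' on the top strand.

    Raises
    ------
    NoAmplificationError
        If either primer site is absent, or the sites are ordered so that no
        product spans them.
    AmbiguousPrimingError
        If either primer site occurs more than once.
    """
    template = template.upper()
    _check_dna(template, "template")
    fwd_hits = _find_all(template, primers.forward)
    rev_site = revcomp(primers.reverse)
    rev_hits = _find_all(template, rev_site)
    for hits, name in ((fwd_hits, "forward"), (rev_hits, "reverse")):
        if not hits:
            raise NoAmplificationError(f"{name} primer has no exact match on the template")
        if len(hits) > 1:
            raise AmbiguousPrimingError(
                f"{name} primer matches the template {len(hits)} times"
            )
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_site)
    if end <= start:
        raise NoAmplificationError(
            "primer sites are convergent on no interval: reverse site lies "
            "upstream of the forward site"
        )
    return template[start:end]


def cut_positions(amplicon: str, enzyme: EnzymeDef) -> list[int]:
    """Sorted distinct top-strand cut coordinates of ``enzyme`` on ``amplicon``.

    Sites are found in both orientations (recognition on the top strand and
    its reverse complement, i.e. the site reading off the bottom strand).
    For a top-strand site starting at i the cut falls at
    ``i + len(recognition) + cut_offset_top``; for a bottom-strand site the
    enzyme reads leftward along the top strand, so the cut falls at
    ``i - cut_offset_top``. Coordinates outside the open interval
    (0, len) are discarded — a cut at either end releases no fragment.
    """
    _check_dna(amplicon, "amplicon")
    site_len = len(enzyme.recognition)
    cuts: set[int] = set()
    for i in _find_all(amplicon, enzyme.recognition):
        cuts.add(i + site_len + enzyme.cut_offset_top)
    rc_site = revcomp(enzyme.recognition)
    for i in _find_all(amplicon, rc_site):
        cuts.add(i - enzyme.cut_offset_top)
    return sorted(c for c in cuts if 0 < c < len(amplicon))


def digest(amplicon: str, enzyme: EnzymeDef, allele_label: str | None = None) -> FragmentLadder:
    """Predict the complete-digestion fragment ladder of ``amplicon``.

    Zero sites yield a single full-length fragment; fragment lengths always
    sum to the amplicon length.
    """
    cuts = cut_positions(amplicon, enzyme)
    bounds = [0, *cuts, len(amplicon)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentLadder(fragments=fragments, allele_label=allele_label)


def _bands_match(observed: Sequence[int], predicted: Sequence[int], tolerance: int) -> bool:
    """Do two distinct-band sets agree, each band pairing within +/- tolerance?"""
    obs = sorted(set(observed))
    pred = sorted(set(predicted))
    if tolerance == 0:
        return obs == pred
    return all(any(abs(o - p) <= tolerance for p in pred) for o in obs) and all(
        any(abs(o - p) <= tolerance for o in obs) for p in pred
    )


def call_genotype(
    observed: Iterable[int],
    ladder_C: FragmentLadder,
    ladder_T: FragmentLadder,
    tolerance: int = 0,
) -> GenotypeCall:
    """Call CC/CT/TT from an observed band multiset.

    Matching is on distinct band lengths (co-migrating fragments collapse):
    CC if the bands match the C-allele ladder, TT for the T-allele ladder,
    CT for the union of both ladders' distinct lengths. ``tolerance`` is the
    gel resolution in bp (0 for in-silico bands).

    Raises
    ------
    UncallableGenotypeError
        If the observed pattern matches none of the three predictions.
    ParameterError
        If the two allele ladders do not differ, or tolerance < 0.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    if ladder_C.distinct_bands == ladder_T.distinct_bands:
        raise ParameterError("allele ladders are indistinguishable; the assay cannot type")
    observed = tuple(sorted(observed))
    bands_C = ladder_C.distinct_bands
    bands_T = ladder_T.distinct_bands
    union = tuple(sorted(set(bands_C) | set(bands_T)))
    if _bands_match(observed, bands_C, tolerance):
        return GenotypeCall("CC", evidence=observed)
    if _bands_match(observed, bands_T, tolerance):
        return GenotypeCall("TT", evidence=observed)
    if _bands_match(observed, union, tolerance):
        return GenotypeCall("CT", evidence=observed)
    raise UncallableGenotypeError(
        f"observed bands {observed} match neither allele ladder nor their union"
    )


def load_enzyme_catalogue(path=None) -> dict[str, EnzymeDef]:
    """Load the enzyme table (name, recognition, offset_top, offset_bottom).

    Without ``path`` the packaged catalogue is used; the file is a plain
    tab-separated table so users can add enzymes by editing a copy.
    """
    if path is None:
        text = resources.files("ketogene").joinpath("data/enzymes.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    catalogue: dict[str, EnzymeDef] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, recognition, off_top, off_bottom = line.split("\t")
        catalogue[name] = EnzymeDef(name, recognition, int(off_top), int(off_bottom))
    return catalogue
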