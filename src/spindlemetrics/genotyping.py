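"""In-silico CAPS genotyping.

A CAPS (cleaved amplified polymorphic sequence) assay genotypes a SNP by
amplifying the surrounding region and digesting the product with a
restriction enzyme whose recognition site is created or destroyed by the
polymorphism.  One allele is cleaved into a characteristic fragment pattern,
the other is left intact; a heterozygote shows the union of both patterns.

The two assays bundled here mirror the maize *dv1* allele assays:

* ``dv1-1``: a 235 bp amplicon digested with MseI (TTAA).  The mutant allele
  is cleaved into 152 + 83 bp; the wild-type allele remains uncut.
* ``dv1-IG``: a 533 bp amplicon digested with NsiI (ATGCAT).  The wild-type
  allele is cleaved into 272 + 261 bp; the mutant allele remains uncut.

Cut positions are 0-based offsets on the top strand of a linear amplicon;
fragment lengths are reported 5'→3'.  Both bundled enzymes recognise
palindromic sites, so scanning the top strand suffices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError

_DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int  # bp from the site start to the top-strand cut

    def __post_init__(self) -> None:
        if not self.site or set(self.site) - _DNA_ALPHABET:
            raise ValidationError(f"recognition site must be non-empty ACGT: {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValidationError("cut offset must lie within the recognition site")


#: MseI: T^TAA — cuts after the first base of its palindromic site.
MSEI = EnzymeSpec("MseI", "TTAA", 1)
#: NsiI: ATGCA^T — cuts after the fifth base of its palindromic site.
NSII = EnzymeSpec("NsiI", "ATGCAT", 5)

ENZYMES = {e.name: e for e in (MSEI, NSII)}


@dataclass(frozen=True)
class DigestResult:
    """Fragment pattern from digesting a linear molecule."""

    fragment_lengths: tuple[int, ...]  # 5'→3' order
    cut_positions: tuple[int, ...]     # sorted, 0-based top-strand offsets

    @property
    def fragments(self) -> Counter:
        """Fragment lengths as a multiset."""
        return Counter(self.fragment_lengths)


@dataclass(frozen=True)
class Assay:
    """A CAPS assay: enzyme, amplicon size, and the two expected patterns."""

    name: str
    enzyme: EnzymeSpec
    amplicon_length: int
    cut_fragments: tuple[int, ...]
    uncut_fragments: tuple[int, ...]
    cut_allele_label: str
    uncut_allele_label: str


DV1_1_ASSAY = Assay(
    name="dv1-1",
    enzyme=MSEI,
    amplicon_length=235,
    cut_fragments=(152, 83),
    uncut_fragments=(235,),
    cut_allele_label="dv1-1",
    uncut_allele_label="wild type",
)

DV1_IG_ASSAY = Assay(
    name="dv1-IG",
    enzyme=NSII,
    amplicon_length=533,
    cut_fragments=(272, 261),
    uncut_fragments=(533,),
    cut_allele_label="wild type",
    uncut_allele_label="dv1-IG",
)

ASSAYS = {a.name: a for a in (DV1_1_ASSAY, DV1_IG_ASSAY)}


@dataclass(frozen=True)
class AlleleCall:
    """Genotype implied by an observed fragment pattern."""

    assay: str
    call: str  # "cut-allele" | "uncut-allele" | "heterozygous" | "unknown"
    genotype_label: str
    matched_pattern: tuple[int, ...] = field(default=())


def _validate_sequence(sequence: str) -> str:
    seq = str(sequence).upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        # IUPAC ambiguity codes are deliberately rejected: a CAPS call on an
        # ambiguous template is not meaningful.
        raise ValidationError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return seq


def find_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Return sorted top-strand cut positions for every site occurrence.

    Overlapping occurrences are all reported.  Only the forward strand is
    scanned; the bundled enzymes have palindromic sites, for which the
    reverse-strand scan is redundant.
    """
    seq = _validate_sequence(sequence)
    cuts = []
    start = seq.find(enzyme.site)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = seq.find(enzyme.site, start + 1)
    return cuts


def digest(sequence: str, enzyme: EnzymeSpec) -> DigestResult:
    """Digest a linear molecule, returning fragments between consecutive cuts.

    Invariants: fragment lengths sum to the sequence length and a molecule
    with k cut sites yields k + 1 fragments.
    """
    seq = _validate_sequence(sequence)
    cuts = find_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds[:-1], bounds[1:]))
    return DigestResult(fragment_lengths=fragments, cut_positions=tuple(cuts))


def _pattern_matches(observed: list[int], expected: tuple[int, ...], tol: int) -> bool:
    if len(observed) != len(expected):
        return False
    obs = sorted(observed)
    exp = sorted(expected)
    return all(abs(o - e) <= tol for o, e in zip(obs, exp))


def call_allele(
    observed_fragments,
    assay: Assay,
    size_tolerance: int = 5,
) -> AlleleCall:
    """Match an observed fragment multiset against an assay's expected patterns.

    The union of the cut and uncut patterns is called heterozygous (the study
    genotypes segregating F2 material, so both alleles co-occur on a gel).
    A pattern matching nothing is ``unknown`` — a value, not an error.
    """
    observed = sorted(int(x) for x in observed_fragments)
    if not observed:
        raise ValidationError("observed fragment list is empty")
    het_pattern = tuple(sorted(assay.cut_fragments + assay.uncut_fragments))
    if _pattern_matches(observed, assay.cut_fragments, size_tolerance):
        return AlleleCall(assay.name, "cut-allele", assay.cut_allele_label,
                          assay.cut_fragments)
    if _pattern_matches(observed, assay.uncut_fragments, size_tolerance):
        return AlleleCall(assay.name, "uncut-allele", assay.uncut_allele_label,
                          assay.uncut_fragments)
    if _pattern_matches(observed, het_pattern, size_tolerance):
        label = f"{assay.cut_allele_label}/{assay.uncut_allele_label}"
        return AlleleCall(assay.name, "heterozygous", label, het_pattern)
    return AlleleCall(assay.name, "unknown", "unknown", ())
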