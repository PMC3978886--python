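"""Core domain types for SNP-profile sample tracking.

A *panel* is an ordered list of biallelic SNPs chosen so that every
commonly used exome capture kit genotypes them reliably.  A *profile*
is one sample's ordered dosage vector over that panel and acts as an
intrinsic identifier of the DNA sample.

Dosage convention
-----------------
Dosage counts copies of ``allele_b`` (the second-listed allele of the
panel file), so 0 = hom ``allele_a``, 1 = het, 2 = hom ``allele_b``.
The packaged allele frequencies refer to ``allele_b``; every downstream
statistic (match probability, mismatch distance) is invariant under
relabelling p <-> 1-p, so the convention only affects labelling.

Missing calls are the explicit sentinel :data:`MISSING` (-1) and are
never silently dropped; consumers decide policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

VALID_BASES = frozenset("ACGT")

#: Strand-ambiguous allele pairs: identical on the complementary strand,
#: excluded from any valid panel so calls can never be strand-confused.
COMPLEMENTARY_PAIRS = (frozenset("AT"), frozenset("CG"))

POPULATIONS = ("CEU", "CHB", "JPT", "YRI")


class SnptraceError(Exception):
    """Base class for all package errors."""


class IncompatibleAlleleError(SnptraceError):
    """An observed allele is not one of the panel SNP's two alleles."""


class IncompatibleSiteError(SnptraceError):
    """A variant site's REF/ALT pair does not match the panel SNP."""


class PanelIntegrityError(SnptraceError):
    """The panel file violates a panel invariant."""


class AlignmentError(SnptraceError):
    """Two profiles are not aligned to the same panel."""


@dataclass(frozen=True)
class PanelSNP:
    """One identifying marker of a panel.

    Parameters
    ----------
    chrom : str
        Chromosome label (GRCh37).
    pos : int
        1-based position.
    rsid : str
        dbSNP identifier.
    gene : str
        Gene symbol the SNP falls in.
    allele_a, allele_b : str
        The two alleles; dosage counts ``allele_b``.
    afs : mapping
        Population code -> frequency of ``allele_b`` in [0, 1].
    """

    chrom: str
    pos: int
    rsid: str
    gene: str
    allele_a: str
    allele_b: str
    afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelIntegrityError(f"{self.rsid}: position must be >= 1")
        for a in (self.allele_a, self.allele_b):
            if a not in VALID_BASES:
                raise PanelIntegrityError(f"{self.rsid}: invalid allele {a!r}")
        if self.allele_a == self.allele_b:
            raise PanelIntegrityError(f"{self.rsid}: alleles must differ")
        pair = frozenset((self.allele_a, self.allele_b))
        if pair in COMPLEMENTARY_PAIRS:
            raise PanelIntegrityError(
                f"{self.rsid}: strand-ambiguous allele pair "
                f"{self.allele_a}/{self.allele_b} is not allowed in a panel"
            )
        for pop, af in self.afs.items():
            if not 0.0 <= af <= 1.0:
                raise PanelIntegrityError(
                    f"{self.rsid}: AF for {pop} out of [0,1]: {af}"
                )

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_a, self.allele_b))


@dataclass
class Profile:
    """One sample's ordered dosage vector over a panel.

    ``calls`` is an int8 array aligned index-for-index with the panel;
    entries are 0/1/2 dosages of ``allele_b`` or :data:`MISSING`.
    """

    sample_id: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"{self.sample_id}: invalid dosage values {self.calls[bad]}"
            )

    def __len__(self) -> int:
        return self.calls.size

    @property
    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    @property
    def n_called(self) -> int:
        return int(self.called_mask.sum())

    @property
    def n_missing(self) -> int:
        return int(self.calls.size - self.n_called)


def encode_dosage(observed_alleles: Iterable[str] | None, snp: PanelSNP) -> int:
    """Encode an unordered allele pair as a dosage of ``snp.allele_b``.

    ``observed_alleles`` may be any iterable of two A/C/G/T symbols
    (e.g. the string ``"AC"``) or ``None`` / an empty or ``"--"``-style
    marker for a missing call.

    Raises
    ------
    IncompatibleAlleleError
        If any observed allele is not one of the SNP's two alleles.
    """
    if observed_alleles is None:
        return MISSING
    alleles = [a.upper() for a in observed_alleles]
    if not alleles or set(alleles) <= {"-", ".", "N", "0"}:
        return MISSING
    if len(alleles) != 2:
        raise IncompatibleAlleleError(
            f"{snp.rsid}: expected a diploid allele pair, got {alleles!r}"
        )
    dosage = 0
    for a in alleles:
        if a == snp.allele_b:
            dosage += 1
        elif a != snp.allele_a:
            raise IncompatibleAlleleError(
                f"{snp.rsid}: observed allele {a!r} is not in "
                f"{snp.allele_a}/{snp.allele_b}"
            )
    return dosage


def harmonize_site(vcf_ref: str, vcf_alt: str, snp: PanelSNP) -> str:
    """Resolve the allele orientation of a VCF site against a panel SNP.

    Returns ``"same"`` when (REF, ALT) equals (allele_a, allele_b) and
    ``"swapped"`` when reversed.  A dosage read from a swapped site is
    ``2 - raw_dosage``.  Because panels exclude complementary (A/T, C/G)
    pairs, allele-order swaps are always resolvable without strand
    information.

    Raises
    ------
    IncompatibleSiteError
        If the site's allele set differs from the SNP's.
    """
    ref, alt = vcf_ref.upper(), vcf_alt.upper()
    if ref == alt:
        raise IncompatibleSiteError(f"{snp.rsid}: REF equals ALT ({ref})")
    if (ref, alt) == (snp.allele_a, snp.allele_b):
        return "same"
    if (ref, alt) == (snp.allele_b, snp.allele_a):
        return "swapped"
    raise IncompatibleSiteError(
        f"{snp.rsid}: site alleles {ref}/{alt} do not match panel pair "
        f"{snp.allele_a}/{snp.allele_b}"
    )


def profiles_to_matrix(profiles: Sequence[Profile]) -> np.ndarray:
    """Stack profiles into an (n_samples, n_snps) int8 dosage matrix."""
    if not profiles:
        return np.empty((0, 0), dtype=np.int8)
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise AlignmentError(f"profiles have differing lengths: {sorted(lengths)}")
    return np.vstack([p.calls for p in profiles])
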