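"""Core domain types: variants, zygosity, samples, cohorts and filter results.

Variant identity is the exact 4-tuple ``(chrom, pos, ref, alt)``.  No
normalisation or left-alignment of indels is attempted: inputs are filtered
as called, so all VCFs entering one analysis must have been normalised
consistently upstream.  Chromosome names are compared as opaque strings
("chr1" != "1"); see :func:`normalize_chrom` for optional harmonisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple


class VcfSieveError(Exception):
    """Base class for all errors raised by this package."""


class MalformedRecordError(VcfSieveError):
    """A VCF/TSV/BED/GTF record violates its format contract."""


class RoleError(VcfSieveError):
    """Sample roles are mixed or missing in a way a filter cannot accept."""


class UnannotatedVariantError(VcfSieveError):
    """A unit-level filter received a variant with no unit assignment."""


class Zygosity(Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


class Role(Enum):
    CASE = "case"
    CONTROL = "control"
    CHILD = "child"
    MOTHER = "mother"
    FATHER = "father"


FAMILY_ROLES = frozenset({Role.CHILD, Role.MOTHER, Role.FATHER})


@dataclass(frozen=True, order=True)
class Variant:
    """One called variant: chromosome, 1-based position, ref and ONE alt allele.

    Multi-allelic VCF records are decomposed upstream (see
    :func:`decompose_record`), so a ``Variant`` always carries exactly one
    alternate allele.  Two variants are the same variant iff all four fields
    are equal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref == self.alt:
            raise ValueError(
                f"ref and alt must differ at {self.chrom}:{self.pos} ({self.ref})"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class SampleVariantSet:
    """One individual's decomposed variant observations plus its cohort role."""

    sample_id: str
    role: Role
    observations: Dict[Variant, Zygosity] = field(default_factory=dict)

    def replace_observations(self, obs: Dict[Variant, Zygosity]) -> "SampleVariantSet":
        return SampleVariantSet(self.sample_id, self.role, dict(obs))


@dataclass
class Cohort:
    """Unrelated cases and controls for the dominant/recessive filters.

    Family (trio) analyses never go through a ``Cohort``; they use the
    dedicated family filter with CHILD/MOTHER/FATHER roles.
    """

    cases: List[SampleVariantSet]
    controls: List[SampleVariantSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cases:
            raise RoleError("a cohort needs at least one case")
        for s in self.cases:
            if s.role is not Role.CASE:
                raise RoleError(
                    f"sample {s.sample_id!r} has role {s.role.value!r}; "
                    "cohort cases must all have role CASE (family samples are "
                    "analysed with the family filter, not a cohort)"
                )
        for s in self.controls:
            if s.role is not Role.CONTROL:
                raise RoleError(
                    f"sample {s.sample_id!r} has role {s.role.value!r}; "
                    "cohort controls must all have role CONTROL"
                )
        ids = [s.sample_id for s in self.cases + self.controls]
        if len(set(ids)) != len(ids):
            raise RoleError(f"sample ids must be unique across the cohort: {ids}")

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)


class ResultLevel(Enum):
    NUCLEOTIDE = "nucleotide"
    UNIT = "unit"


@dataclass(frozen=True)
class ResultRow:
    variant: Variant
    case_count: int
    control_count: int
    unit_id: Optional[Tuple[str, str]] = None  # (source, unit_id) at UNIT level


@dataclass
class FilterResult:
    """Variants (or units with their supporting variants) retained by a filter.

    ``case_count`` / ``control_count`` are counted under the producing
    filter's own matching rule (e.g. homozygous-only for the recessive
    nucleotide filter), so every retained row satisfies that filter's
    thresholds by construction.
    """

    rows: List[ResultRow]
    level: ResultLevel
    retained_units: Optional[List[Tuple[Tuple[str, str], int]]] = None

    @property
    def variants(self) -> List[Variant]:
        return [r.variant for r in self.rows]

    def variant_set(self) -> set:
        return {r.variant for r in self.rows}


_CHUNK_RE = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str):
    """Natural chromosome order: chr1 < chr2 < chr10 < chrX, with a
    lexicographic fallback for non-numeric names."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    parts = [p for p in _CHUNK_RE.split(name) if p != ""]
    key = tuple((0, int(p), "") if p.isdigit() else (1, 0, p) for p in parts)
    return (key, chrom)


def variant_sort_key(v: Variant):
    return (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)


def normalize_chrom(chrom: str, mode: Optional[str]) -> str:
    """Optionally harmonise a 'chr' prefix: mode 'add', 'strip' or None."""
    if mode is None:
        return chrom
    has = chrom.lower().startswith("chr")
    if mode == "add":
        return chrom if has else "chr" + chrom
    if mode == "strip":
        return chrom[3:] if has else chrom
    raise ValueError(f"unknown chrom harmonisation mode {mode!r}")


def decompose_record(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotype: Sequence[Optional[int]],
    *,
    lenient_ploidy: bool = False,
) -> List[Tuple[Variant, Zygosity]]:
    """Split one (possibly multi-allelic) genotyped record into per-alt observations.

    Each distinct alternate allele carried by the genotype yields one
    ``(Variant, Zygosity)`` pair: a diploid genotype with both alleles equal
    to the same alt is HOM_ALT; anything else carrying that alt is HET, so a
    1/2 genotype produces two HET observations.  Reference-only and fully
    missing genotypes yield nothing.  A partially missing genotype (./1) is
    conservatively HET.

    Non-diploid genotypes raise :class:`MalformedRecordError` unless
    ``lenient_ploidy`` is set, in which case "all present alleles are this
    alt and none missing" maps to HOM_ALT and any other carriage to HET.
    """
    present = [a for a in genotype if a is not None]
    if not present:
        return []
    n_alleles = len([a for a in genotype])
    if n_alleles != 2 and not lenient_ploidy:
        raise MalformedRecordError(
            f"non-diploid genotype ({n_alleles} alleles) at {chrom}:{pos}; "
            "pass lenient_ploidy=True to accept"
        )
    for a in present:
        if a < 0 or a > len(alts):
            raise MalformedRecordError(
                f"allele index {a} out of range for {len(alts)} alt allele(s) "
                f"at {chrom}:{pos}"
            )
    carried = sorted({a for a in present if a > 0})
    out: List[Tuple[Variant, Zygosity]] = []
    any_missing = len(present) != n_alleles
    for idx in carried:
        alt = alts[idx - 1]
        if not any_missing and all(a == idx for a in present):
            zyg = Zygosity.HOM_ALT
        else:
            zyg = Zygosity.HET
        out.append((Variant(chrom, pos, ref, alt), zyg))
    return out
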