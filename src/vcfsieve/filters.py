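"""The heuristic inheritance filters.

Four cohort filters (dominant/recessive x nucleotide/unit level) plus the
trio "family" mode.  All four cohort filters are parameterised by
:class:`~vcfsieve.pendet.PenDetThresholds`: a candidate must be present in
at least ``n_c`` cases and be matched by at most ``c_g`` controls under the
filter's own control rule.

Nucleotide level
    dominant: any zygosity counts, in cases and in controls.
    recessive: only homozygous-alternate observations count — case HETs
    never support a candidate and control HETs never filter one.

Unit level (requires annotated variants)
    A unit "qualifies" in a sample when, recessively, the sample has a
    homozygous variant or is compound heterozygous (>= 2 distinct HET
    variants) in the unit, or, dominantly, has any variant in the unit.
    Sharing is counted over units, not nucleotides, which is what admits
    allelic heterogeneity.  Control filtering removes individual case
    variants first (recessively in two steps: control homozygotes, then all
    variants of controls that are compound heterozygous in the unit), and
    qualification is recomputed on the survivors.

Compound heterozygosity ignores phase: two HETs in one unit qualify even if
truly in cis, and two HET observations decomposed from one multi-allelic
site are two distinct variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .annotation import AnnotatedVariant, AnnotationUnit, UnitIndex, annotate
from .model import (
    Cohort,
    FilterResult,
    ResultLevel,
    ResultRow,
    Role,
    RoleError,
    SampleVariantSet,
    UnannotatedVariantError,
    Variant,
    Zygosity,
    variant_sort_key,
)
from .pendet import PenDetThresholds


# ---------------------------------------------------------------- nucleotide

def _carriers(samples: Sequence[SampleVariantSet], v: Variant, hom_only: bool) -> int:
    if hom_only:
        return sum(
            1 for s in samples if s.observations.get(v) is Zygosity.HOM_ALT
        )
    return sum(1 for s in samples if v in s.observations)


def _nucleotide_filter(cohort: Cohort, th: PenDetThresholds, hom_only: bool) -> FilterResult:
    candidates: Set[Variant] = set()
    for s in cohort.cases:
        for v, z in s.observations.items():
            if not hom_only or z is Zygosity.HOM_ALT:
                candidates.add(v)
    rows = []
    for v in sorted(candidates, key=variant_sort_key):
        n_case = _carriers(cohort.cases, v, hom_only)
        n_ctrl = _carriers(cohort.controls, v, hom_only)
        if n_case >= th.n_c and n_ctrl <= th.c_g:
            rows.append(ResultRow(v, n_case, n_ctrl))
    return FilterResult(rows, ResultLevel.NUCLEOTIDE)


def dominant_nucleotide(cohort: Cohort, th: PenDetThresholds) -> FilterResult:
    """Dominant model, single-nucleotide sharing: no zygosity assumptions.

    Every variant called in a case is a candidate and every variant called
    in a control filters; retain variants carried by >= n_c cases and by
    <= c_g controls.
    """
    return _nucleotide_filter(cohort, th, hom_only=False)


def recessive_nucleotide(cohort: Cohort, th: PenDetThresholds) -> FilterResult:
    """Recessive model, single-nucleotide sharing: causal variants are
    assumed homozygous, and only homozygous control observations filter."""
    return _nucleotide_filter(cohort, th, hom_only=True)


# ---------------------------------------------------------------------- unit

@dataclass
class AnnotatedSample:
    """A sample's annotated observations, for the unit-level filters."""

    sample_id: str
    role: Role
    variants: List[AnnotatedVariant]


@dataclass
class AnnotatedCohort:
    cases: List[AnnotatedSample]
    controls: List[AnnotatedSample] = field(default_factory=list)


def annotate_cohort(
    cohort: Cohort, units: Iterable[AnnotationUnit] | UnitIndex
) -> AnnotatedCohort:
    """Annotate every sample of a cohort against one unit index."""
    index = units if isinstance(units, UnitIndex) else UnitIndex(units)

    def one(s: SampleVariantSet) -> AnnotatedSample:
        return AnnotatedSample(
            s.sample_id, s.role, annotate(list(s.observations.items()), index)
        )

    return AnnotatedCohort([one(s) for s in cohort.cases], [one(s) for s in cohort.controls])


def _check_annotated(acohort: AnnotatedCohort) -> None:
    for s in acohort.cases + acohort.controls:
        for av in s.variants:
            if not av.unit_ids:
                raise UnannotatedVariantError(
                    f"variant {av.variant} in sample {s.sample_id!r} has no "
                    "unit assignment; run annotate()/keep_annotated() first "
                    "or drop intergenic variants"
                )


def _unit_map(sample: AnnotatedSample) -> Dict[Tuple[str, str], List[AnnotatedVariant]]:
    by_unit: Dict[Tuple[str, str], List[AnnotatedVariant]] = {}
    for av in sample.variants:
        for key in av.unit_ids:
            by_unit.setdefault(key, []).append(av)
    return by_unit


def _is_comphet(avs: Sequence[AnnotatedVariant]) -> bool:
    hets = {av.variant for av in avs if av.zygosity is Zygosity.HET}
    return len(hets) >= 2


def _qualifies_recessive(avs: Sequence[AnnotatedVariant]) -> bool:
    return any(av.zygosity is Zygosity.HOM_ALT for av in avs) or _is_comphet(avs)


def _unit_result(
    acohort: AnnotatedCohort,
    th: PenDetThresholds,
    survives,  # (unit_key, Variant) -> bool, control filtering verdict
    qualifies,  # surviving AnnotatedVariant list -> bool, per-sample rule
    filtering_controls,  # (unit_key, Variant) -> int, for report counts
) -> FilterResult:
    case_units = [_unit_map(s) for s in acohort.cases]
    all_unit_keys = sorted({k for m in case_units for k in m})
    retained_units: List[Tuple[Tuple[str, str], int]] = []
    rows: List[ResultRow] = []
    for key in all_unit_keys:
        surviving_per_case = []
        for m in case_units:
            avs = [av for av in m.get(key, []) if survives(key, av.variant)]
            surviving_per_case.append(avs)
        n_qual = sum(1 for avs in surviving_per_case if qualifies(avs))
        if n_qual < th.n_c:
            continue
        retained_units.append((key, n_qual))
        variants = sorted(
            {av.variant for avs in surviving_per_case if qualifies(avs) for av in avs},
            key=variant_sort_key,
        )
        for v in variants:
            n_case = sum(
                1 for m in case_units if any(av.variant == v for av in m.get(key, []))
            )
            rows.append(ResultRow(v, n_case, filtering_controls(key, v), unit_id=key))
    return FilterResult(rows, ResultLevel.UNIT, retained_units=retained_units)


def recessive_unit(acohort: AnnotatedCohort, th: PenDetThresholds) -> FilterResult:
    """Recessive model at unit level: homozygous and/or compound-heterozygous.

    Control filtering of case variants happens in two consecutive steps —
    (1) homozygous control variants filter, (2) every variant of a control
    that is compound heterozygous within a unit filters in that unit — with
    the c_g allowance counted per variant across controls.  Units then
    qualifying (>= 1 surviving homozygote or >= 2 surviving distinct HETs)
    in >= n_c cases are retained with their surviving supporting variants.
    """
    _check_annotated(acohort)
    ctrl_units = [_unit_map(s) for s in acohort.controls]
    ctrl_comphet: List[Set[Tuple[str, str]]] = [
        {k for k, avs in m.items() if _is_comphet(avs)} for m in ctrl_units
    ]

    def filtering_controls(key: Tuple[str, str], v: Variant) -> int:
        n = 0
        for s, m, comphet in zip(acohort.controls, ctrl_units, ctrl_comphet):
            hom = any(
                av.variant == v and av.zygosity is Zygosity.HOM_ALT
                for av in s.variants
            )
            in_comphet_unit = key in comphet and any(
                av.variant == v for av in m.get(key, [])
            )
            if hom or in_comphet_unit:
                n += 1
        return n

    def survives(key: Tuple[str, str], v: Variant) -> bool:
        return filtering_controls(key, v) <= th.c_g

    return _unit_result(acohort, th, survives, _qualifies_recessive, filtering_controls)


def dominant_unit(acohort: AnnotatedCohort, th: PenDetThresholds) -> FilterResult:
    """Dominant model at unit level: every unit with >= 1 variant qualifies
    in a case, and every control variant (any zygosity) filters."""
    _check_annotated(acohort)

    def filtering_controls(key: Tuple[str, str], v: Variant) -> int:
        return sum(
            1
            for s in acohort.controls
            if any(av.variant == v for av in s.variants)
        )

    def survives(key: Tuple[str, str], v: Variant) -> bool:
        return filtering_controls(key, v) <= th.c_g

    return _unit_result(
        acohort, th, survives, lambda avs: len(avs) >= 1, filtering_controls
    )


# -------------------------------------------------------------------- family

def _check_family_roles(child, mother, father) -> None:
    if child.role is not Role.CHILD:
        raise RoleError(
            f"family analysis needs a CHILD sample, got role {child.role.value!r} "
            f"for {child.sample_id!r}; unrelated cases/controls must not be "
            "passed to the family filter"
        )
    for parent, want in ((mother, Role.MOTHER), (father, Role.FATHER)):
        if parent is not None and parent.role is not want:
            raise RoleError(
                f"expected role {want.value!r}, got {parent.role.value!r} for "
                f"{parent.sample_id!r}; unrelated controls must not be included "
                "in a family analysis (they would be treated as parents)"
            )


def family_dominant(
    child: SampleVariantSet,
    mother: Optional[SampleVariantSet] = None,
    father: Optional[SampleVariantSet] = None,
) -> FilterResult:
    """Trio de-novo filter: retain variants heterozygous in the child and
    absent (at any zygosity) from every supplied parent.

    One family per call; analyse multiple families separately.  Running
    with a single parent filters against that parent only and is warned
    about, since the de-novo assumption is weaker.
    """
    _check_family_roles(child, mother, father)
    parents = [p for p in (mother, father) if p is not None]
    if len(parents) < 2:
        warnings.warn(
            "family filter running with fewer than two parents: the de-novo "
            "assumption is only partially testable",
            stacklevel=2,
        )
    rows = []
    for v in sorted(child.observations, key=variant_sort_key):
        if child.observations[v] is not Zygosity.HET:
            continue
        if any(v in p.observations for p in parents):
            continue
        rows.append(ResultRow(v, case_count=1, control_count=0))
    return FilterResult(rows, ResultLevel.NUCLEOTIDE)


def family_recessive(
    child: SampleVariantSet,
    mother: SampleVariantSet,
    father: SampleVariantSet,
) -> FilterResult:
    """Convenience trio filter for a recessive model: retain variants
    homozygous in the child and heterozygous in both parents.

    This is an extension beyond the de-novo family mode; both parents are
    required because the carrier assumption is untestable otherwise.
    """
    _check_family_roles(child, mother, father)
    rows = []
    for v in sorted(child.observations, key=variant_sort_key):
        if child.observations[v] is not Zygosity.HOM_ALT:
            continue
        if (
            mother.observations.get(v) is Zygosity.HET
            and father.observations.get(v) is Zygosity.HET
        ):
            rows.append(ResultRow(v, case_count=1, control_count=0))
    return FilterResult(rows, ResultLevel.NUCLEOTIDE)
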