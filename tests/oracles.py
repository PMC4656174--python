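"""Independent brute-force oracles for the filters.

Everything here is written as direct nested-loop evaluation of the filter
definitions over plain observation mappings, deliberately sharing no code
with the package's implementations (only the passive data types are
reused).  Random-fixture helpers live here too so tests and the acceptance
script can exercise implementation-vs-oracle agreement on the same inputs.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Sequence, Set, Tuple

from vcfsieve.annotation import AnnotationUnit
from vcfsieve.model import Role, SampleVariantSet, Variant, Zygosity

Obs = Dict[Variant, Zygosity]
UnitKey = Tuple[str, str]


def units_of(v: Variant, units: Sequence[AnnotationUnit]) -> Set[UnitKey]:
    out = set()
    for u in units:
        if u.chrom != v.chrom:
            continue
        for start, end in u.intervals:
            if start <= v.pos <= end:
                out.add(u.key)
    return out


def oracle_dominant_nucleotide(
    cases: Sequence[Obs], controls: Sequence[Obs], n_c: int, c_g: int
) -> Set[Variant]:
    retained = set()
    for case in cases:
        for v in case:
            n_case = sum(1 for other in cases if v in other)
            n_ctrl = sum(1 for ctrl in controls if v in ctrl)
            if n_case >= n_c and n_ctrl <= c_g:
                retained.add(v)
    return retained


def oracle_recessive_nucleotide(
    cases: Sequence[Obs], controls: Sequence[Obs], n_c: int, c_g: int
) -> Set[Variant]:
    retained = set()
    for case in cases:
        for v, z in case.items():
            if z is not Zygosity.HOM_ALT:
                continue
            n_case = sum(
                1 for other in cases if other.get(v) is Zygosity.HOM_ALT
            )
            n_ctrl = sum(
                1 for ctrl in controls if ctrl.get(v) is Zygosity.HOM_ALT
            )
            if n_case >= n_c and n_ctrl <= c_g:
                retained.add(v)
    return retained


def _comphet_in_unit(obs: Obs, key: UnitKey, units: Sequence[AnnotationUnit]) -> bool:
    hets = [
        v for v, z in obs.items() if z is Zygosity.HET and key in units_of(v, units)
    ]
    return len(set(hets)) >= 2


def oracle_recessive_unit(
    cases: Sequence[Obs],
    controls: Sequence[Obs],
    units: Sequence[AnnotationUnit],
    n_c: int,
    c_g: int,
) -> Tuple[Set[UnitKey], Set[Variant]]:
    """Returns (retained unit keys, surviving supporting variants)."""
    all_keys = {k for case in cases for v in case for k in units_of(v, units)}
    retained_keys: Set[UnitKey] = set()
    retained_variants: Set[Variant] = set()
    for key in all_keys:

        def filtering_controls(v: Variant) -> int:
            n = 0
            for ctrl in controls:
                hom = ctrl.get(v) is Zygosity.HOM_ALT
                comphet_match = (
                    _comphet_in_unit(ctrl, key, units)
                    and v in ctrl
                    and key in units_of(v, units)
                )
                if hom or comphet_match:
                    n += 1
            return n

        qualifying = []
        for case in cases:
            survivors = {
                v: z
                for v, z in case.items()
                if key in units_of(v, units) and filtering_controls(v) <= c_g
            }
            homs = [v for v, z in survivors.items() if z is Zygosity.HOM_ALT]
            hets = {v for v, z in survivors.items() if z is Zygosity.HET}
            if homs or len(hets) >= 2:
                qualifying.append(survivors)
        if len(qualifying) >= n_c:
            retained_keys.add(key)
            for survivors in qualifying:
                retained_variants.update(survivors)
    return retained_keys, retained_variants


def oracle_dominant_unit(
    cases: Sequence[Obs],
    controls: Sequence[Obs],
    units: Sequence[AnnotationUnit],
    n_c: int,
    c_g: int,
) -> Tuple[Set[UnitKey], Set[Variant]]:
    all_keys = {k for case in cases for v in case for k in units_of(v, units)}
    retained_keys: Set[UnitKey] = set()
    retained_variants: Set[Variant] = set()
    for key in all_keys:

        def filtering_controls(v: Variant) -> int:
            return sum(1 for ctrl in controls if v in ctrl)

        qualifying = []
        for case in cases:
            survivors = {
                v: z
                for v, z in case.items()
                if key in units_of(v, units) and filtering_controls(v) <= c_g
            }
            if survivors:
                qualifying.append(survivors)
        if len(qualifying) >= n_c:
            retained_keys.add(key)
            for survivors in qualifying:
                retained_variants.update(survivors)
    return retained_keys, retained_variants


def oracle_family_dominant(
    child: Obs, mother: Optional[Obs], father: Optional[Obs]
) -> Set[Variant]:
    out = set()
    for v, z in child.items():
        if z is not Zygosity.HET:
            continue
        if mother is not None and v in mother:
            continue
        if father is not None and v in father:
            continue
        out.add(v)
    return out


def oracle_db_filter(
    obs: Obs, db: Dict[Variant, Optional[float]], threshold: float
) -> Obs:
    kept = {}
    for v, z in obs.items():
        if v in db and (
            threshold == 0 or (db[v] is not None and db[v] >= threshold)
        ):
            continue
        kept[v] = z
    return kept


# --------------------------------------------------------- random fixtures

_BASES = ("A", "C", "G", "T")


def random_units(rng: random.Random, n_units: int, unit_len: int = 50) -> List[AnnotationUnit]:
    units = []
    for i in range(n_units):
        chrom = f"chr{rng.randint(1, 2)}"
        start = rng.randint(1, 2000)
        units.append(
            AnnotationUnit(f"u{i}", chrom, [(start, start + unit_len)], "rnd")
        )
    return units


def random_variant(rng: random.Random, units: Sequence[AnnotationUnit]) -> Variant:
    """A variant placed inside a random unit (occasionally intergenic-free
    fixtures matter less than dense unit overlap, which this produces)."""
    u = rng.choice(list(units))
    start, end = u.intervals[0]
    pos = rng.randint(start, end)
    ref, alt = rng.sample(_BASES, 2)
    return Variant(u.chrom, pos, ref, alt)


def random_obs(
    rng: random.Random, pool: Sequence[Variant], max_n: int
) -> Obs:
    n = rng.randint(0, min(max_n, len(pool)))
    chosen = rng.sample(list(pool), n)
    return {
        v: (Zygosity.HET if rng.random() < 0.6 else Zygosity.HOM_ALT)
        for v in chosen
    }


def random_cohort_fixture(
    rng: random.Random,
    max_samples: int = 10,
    max_variants: int = 1000,
    max_units: int = 50,
):
    """(cases, controls, units, pool) with heavy variant sharing between
    samples, so control filtering and case sharing both get exercised."""
    units = random_units(rng, rng.randint(2, max_units))
    pool_size = rng.randint(5, max_variants)
    pool = list({random_variant(rng, units) for _ in range(pool_size)})
    n_cases = rng.randint(1, max(1, max_samples - 1))
    n_controls = rng.randint(0, max_samples - n_cases)
    per_sample = max(1, len(pool) // 2)
    cases = [random_obs(rng, pool, per_sample) for _ in range(n_cases)]
    controls = [random_obs(rng, pool, per_sample) for _ in range(n_controls)]
    return cases, controls, units, pool


def to_sample_sets(
    cases: Sequence[Obs], controls: Sequence[Obs]
) -> Tuple[List[SampleVariantSet], List[SampleVariantSet]]:
    case_sets = [
        SampleVariantSet(f"case{i}", Role.CASE, dict(obs))
        for i, obs in enumerate(cases)
    ]
    control_sets = [
        SampleVariantSet(f"ctrl{i}", Role.CONTROL, dict(obs))
        for i, obs in enumerate(controls)
    ]
    return case_sets, control_sets
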