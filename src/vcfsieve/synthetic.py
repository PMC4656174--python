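"""Synthetic cohorts with a planted causal variant.

The generator emulates the structure the inheritance filters assume: a
cohort (or trio) sharing one causal variant — or a compound-heterozygous
pair within one unit — on top of background variation, a database VCF that
contains a configurable fraction of the background but never the causal
variant, and a BED file of units.

Phenocopies (``n_d`` cases without the causal genotype) and non-penetrant
carriers (``c_g`` controls with it) are planted exactly, so the truth
record's carrier counts are exact by construction: the causal variant is
carried, per model, by exactly ``n_cases - n_d`` cases and ``c_g``
controls.  Background variants never land inside the causal unit and never
reuse a planted position, which keeps those guarantees independent of the
background draw.

In trio mode the child carries every background variant; each one is
inherited (present in at least one parent) with probability
``parental_sharing`` and is in the database with probability
``background_sharing``.  The default parental sharing of 0.99 reflects
that genuine de novo variants are a tiny fraction of a child's callset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .annotation import AnnotationUnit
from .model import (
    Role,
    SampleVariantSet,
    Variant,
    Zygosity,
    chrom_sort_key,
    variant_sort_key,
)

_BASES = ("A", "C", "G", "T")


class SimModel(Enum):
    DOMINANT = "dominant"
    RECESSIVE_HOM = "recessive_hom"
    RECESSIVE_COMPHET = "recessive_comphet"
    DENOVO_TRIO = "denovo_trio"


@dataclass
class SimulationConfig:
    model: SimModel = SimModel.DOMINANT
    n_cases: int = 4
    n_controls: int = 2
    n_background_variants: int = 200
    background_sharing: float = 0.7  # P(background variant is in the database)
    parental_sharing: float = 0.99  # trio: P(child background variant is inherited)
    background_carrier_rate: float = 0.3  # cohort: P(sample carries a background site)
    het_fraction: float = 0.7  # background zygosity: HET vs HOM_ALT
    n_units: int = 20
    unit_length: int = 1000
    n_d: int = 0  # phenocopy cases (lack the causal genotype)
    c_g: int = 0  # non-penetrant carrier controls
    seed: int = 0
    chroms: Tuple[str, ...] = ("chr1", "chr2", "chr3")

    def __post_init__(self) -> None:
        if isinstance(self.model, str):
            self.model = SimModel(self.model)
        if self.model is SimModel.DENOVO_TRIO:
            if self.n_d != 0 or self.c_g != 0:
                raise ValueError(
                    "a trio has one affected child and no unrelated controls; "
                    "n_d and c_g must be 0 for DENOVO_TRIO"
                )
            self.n_cases = 1
            self.n_controls = 0
        if self.n_cases < 1:
            raise ValueError("need at least one case")
        if not 0 <= self.n_d < self.n_cases:
            raise ValueError(f"need 0 <= n_d < n_cases, got n_d={self.n_d}")
        if not 0 <= self.c_g <= self.n_controls:
            raise ValueError(f"need 0 <= c_g <= n_controls, got c_g={self.c_g}")
        for name, p in (
            ("background_sharing", self.background_sharing),
            ("parental_sharing", self.parental_sharing),
            ("background_carrier_rate", self.background_carrier_rate),
            ("het_fraction", self.het_fraction),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_units < 2:
            raise ValueError("need at least 2 units (one causal, one background)")
        capacity = (self.n_units - 1) * self.unit_length
        if self.n_background_variants > capacity:
            raise ValueError(
                f"{self.n_background_variants} background variants do not fit "
                f"in {self.n_units - 1} background units of length "
                f"{self.unit_length} ({capacity} positions)"
            )


@dataclass
class TruthRecord:
    """What was planted: the causal variant(s), their unit and who carries them."""

    model: SimModel
    variants: List[Variant]
    unit: Tuple[str, str]  # (source, unit_id)
    carriers: Dict[str, Optional[str]]  # sample_id -> zygosity value or None

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model.value,
                "variants": [
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
                    for v in self.variants
                ],
                "unit": {"source": self.unit[0], "unit_id": self.unit[1]},
                "carriers": self.carriers,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    samples: List[SampleVariantSet]
    units: List[AnnotationUnit]
    db_entries: Dict[Variant, Optional[float]]
    truth: TruthRecord

    @property
    def cases(self) -> List[SampleVariantSet]:
        return [s for s in self.samples if s.role is Role.CASE]

    @property
    def controls(self) -> List[SampleVariantSet]:
        return [s for s in self.samples if s.role is Role.CONTROL]

    def by_role(self, role: Role) -> Optional[SampleVariantSet]:
        for s in self.samples:
            if s.role is role:
                return s
        return None


def _make_units(config: SimulationConfig) -> List[AnnotationUnit]:
    units = []
    per_chrom: Dict[str, int] = {}
    for i in range(config.n_units):
        chrom = config.chroms[i % len(config.chroms)]
        slot = per_chrom.get(chrom, 0)
        per_chrom[chrom] = slot + 1
        start = 1001 + slot * (config.unit_length + 9000)
        units.append(
            AnnotationUnit(
                f"unit{i:03d}",
                chrom,
                [(start, start + config.unit_length - 1)],
                source="synthetic",
            )
        )
    return units


def _draw_alleles(rng: np.random.Generator) -> Tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _bg_zygosity(rng: np.random.Generator, config: SimulationConfig) -> Zygosity:
    return Zygosity.HET if rng.random() < config.het_fraction else Zygosity.HOM_ALT


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Generate one deterministic cohort (same config + seed => same output)."""
    rng = np.random.default_rng(config.seed)
    units = _make_units(config)

    causal_idx = int(rng.integers(config.n_units))
    causal_unit = units[causal_idx]
    (cu_start, cu_end) = causal_unit.intervals[0]
    n_causal = 2 if config.model is SimModel.RECESSIVE_COMPHET else 1
    causal_pos = sorted(
        int(p) for p in rng.choice(
            np.arange(cu_start, cu_end + 1), size=n_causal, replace=False
        )
    )
    causal_variants = [
        Variant(causal_unit.chrom, pos, *_draw_alleles(rng)) for pos in causal_pos
    ]

    bg_units = [u for j, u in enumerate(units) if j != causal_idx]
    pool = np.array(
        [(j, p) for j, u in enumerate(bg_units) for p in range(u.intervals[0][0], u.intervals[0][1] + 1)]
    )
    picks = rng.choice(len(pool), size=config.n_background_variants, replace=False)
    background: List[Variant] = []
    for k in sorted(int(i) for i in picks):
        j, pos = int(pool[k][0]), int(pool[k][1])
        background.append(Variant(bg_units[j].chrom, pos, *_draw_alleles(rng)))

    db_entries: Dict[Variant, Optional[float]] = {}
    for v in background:
        if rng.random() < config.background_sharing:
            db_entries[v] = float(rng.uniform(0.01, 0.99))

    if config.model is SimModel.DENOVO_TRIO:
        samples, carriers = _simulate_trio(config, rng, causal_variants[0], background)
    else:
        samples, carriers = _simulate_cohort_samples(
            config, rng, causal_variants, background
        )

    truth = TruthRecord(config.model, causal_variants, causal_unit.key, carriers)
    return SimulatedCohort(config, samples, units, db_entries, truth)


def _simulate_cohort_samples(
    config: SimulationConfig,
    rng: np.random.Generator,
    causal_variants: List[Variant],
    background: List[Variant],
) -> Tuple[List[SampleVariantSet], Dict[str, Optional[str]]]:
    cases = [
        SampleVariantSet(f"case{i + 1:02d}", Role.CASE) for i in range(config.n_cases)
    ]
    controls = [
        SampleVariantSet(f"control{i + 1:02d}", Role.CONTROL)
        for i in range(config.n_controls)
    ]
    n_carrier_cases = config.n_cases - config.n_d
    carrier_cases = set(
        int(i) for i in rng.choice(config.n_cases, size=n_carrier_cases, replace=False)
    )
    carrier_controls = (
        set(int(i) for i in rng.choice(config.n_controls, size=config.c_g, replace=False))
        if config.c_g
        else set()
    )
    causal_zyg = {
        SimModel.DOMINANT: Zygosity.HET,
        SimModel.RECESSIVE_HOM: Zygosity.HOM_ALT,
        SimModel.RECESSIVE_COMPHET: Zygosity.HET,
    }[config.model]

    carriers: Dict[str, Optional[str]] = {}
    for i, s in enumerate(cases):
        if i in carrier_cases:
            for v in causal_variants:
                s.observations[v] = causal_zyg
            carriers[s.sample_id] = causal_zyg.value
        else:
            carriers[s.sample_id] = None
    for i, s in enumerate(controls):
        if i in carrier_controls:
            for v in causal_variants:
                s.observations[v] = causal_zyg
            carriers[s.sample_id] = causal_zyg.value
        else:
            carriers[s.sample_id] = None

    for v in background:
        for s in cases + controls:
            if rng.random() < config.background_carrier_rate:
                s.observations[v] = _bg_zygosity(rng, config)
    return cases + controls, carriers


def _simulate_trio(
    config: SimulationConfig,
    rng: np.random.Generator,
    causal: Variant,
    background: List[Variant],
) -> Tuple[List[SampleVariantSet], Dict[str, Optional[str]]]:
    child = SampleVariantSet("child", Role.CHILD)
    mother = SampleVariantSet("mother", Role.MOTHER)
    father = SampleVariantSet("father", Role.FATHER)
    child.observations[causal] = Zygosity.HET

    for v in background:
        zyg = _bg_zygosity(rng, config)
        child.observations[v] = zyg
        inherited = rng.random() < config.parental_sharing
        if not inherited:
            continue
        if zyg is Zygosity.HOM_ALT:
            transmitting = [mother, father]
        else:
            transmitting = [mother if rng.random() < 0.5 else father]
        for parent in transmitting:
            parent.observations[v] = _bg_zygosity(rng, config)
    carriers = {"child": Zygosity.HET.value, "mother": None, "father": None}
    return [child, mother, father], carriers


# ------------------------------------------------------------------- writers

def write_fixture_vcf(
    samples: Sequence[SampleVariantSet] | SampleVariantSet,
    path: str,
    *,
    multiallelic: bool = False,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write sample observations as a valid VCF 4.2 file.

    By default each Variant becomes its own biallelic record (two alts at
    one site give two records); with ``multiallelic`` they collapse into one
    multi-allelic record, a 1/2 genotype encoding a double-HET carrier.
    Round-trips through :func:`vcfsieve.vcf_io.read_vcf_samples` under both
    dialects.
    """
    if isinstance(samples, SampleVariantSet):
        samples = [samples]
    all_variants = sorted(
        {v for s in samples for v in s.observations}, key=variant_sort_key
    )
    chroms = sorted({v.chrom for v in all_variants}, key=chrom_sort_key)
    lengths = dict(contig_lengths or {})
    for v in all_variants:
        lengths[v.chrom] = max(lengths.get(v.chrom, 0), v.pos + 1000)

    header = pysam.VariantHeader()
    for chrom in chroms or list(lengths):
        header.contigs.add(chrom, length=lengths.get(chrom, 1_000_000))
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s.sample_id)

    if multiallelic:
        grouped: Dict[Tuple[str, int, str], List[Variant]] = {}
        for v in all_variants:
            grouped.setdefault((v.chrom, v.pos, v.ref), []).append(v)
        records = [
            (chrom, pos, ref, tuple(v.alt for v in vs))
            for (chrom, pos, ref), vs in sorted(
                grouped.items(), key=lambda kv: (chrom_sort_key(kv[0][0]), kv[0][1], kv[0][2])
            )
        ]
    else:
        records = [(v.chrom, v.pos, v.ref, (v.alt,)) for v in all_variants]

    with pysam.VariantFile(path, "w", header=header) as out:
        for chrom, pos, ref, alts in records:
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref,) + alts)
            rec.id = "."
            for s in samples:
                zygs = [
                    (i + 1, s.observations.get(Variant(chrom, pos, ref, alt)))
                    for i, alt in enumerate(alts)
                ]
                carried = [(i, z) for i, z in zygs if z is not None]
                if not carried:
                    gt: Tuple[int, int] = (0, 0)
                elif len(carried) == 1:
                    i, z = carried[0]
                    gt = (i, i) if z is Zygosity.HOM_ALT else (0, i)
                elif len(carried) == 2 and all(
                    z is Zygosity.HET for _, z in carried
                ):
                    gt = (carried[0][0], carried[1][0])
                else:
                    raise ValueError(
                        f"cannot encode {len(carried)} carried alt alleles at "
                        f"{chrom}:{pos} for sample {s.sample_id!r} in one "
                        "diploid genotype"
                    )
                rec.samples[s.sample_id]["GT"] = gt
                rec.samples[s.sample_id].phased = False
            out.write(rec)


def write_database_vcf(
    entries: Dict[Variant, Optional[float]], path: str, af_field: str = "AF"
) -> None:
    """Write a sites-only database VCF with per-alt allele frequencies."""
    header = pysam.VariantHeader()
    chroms = sorted({v.chrom for v in entries}, key=chrom_sort_key)
    for chrom in chroms:
        length = max(v.pos for v in entries if v.chrom == chrom) + 1000
        header.contigs.add(chrom, length=length)
    header.info.add(af_field, "A", "Float", "Allele frequency")
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(entries, key=variant_sort_key):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            af = entries[v]
            if af is not None:
                rec.info[af_field] = (af,)
            out.write(rec)


def write_units_bed(units: Sequence[AnnotationUnit], path: str) -> None:
    """Write units as 4-column BED (back to 0-based half-open)."""
    with open(path, "w") as fh:
        for u in units:
            for start, end in u.intervals:
                fh.write(f"{u.chrom}\t{start - 1}\t{end}\t{u.unit_id}\n")


def simulate_cohort(config: SimulationConfig, outdir: str) -> Tuple[SimulatedCohort, Dict[str, str]]:
    """Simulate and write the full fixture set; returns (cohort, paths).

    Writes one VCF per sample, a database VCF, a BED of units, a YAML
    cohort manifest and a JSON truth record.  Deterministic per seed.
    """
    sim = simulate(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    manifest_lines = ["samples:"]
    if config.model is SimModel.DENOVO_TRIO:
        manifest_lines.insert(0, "family: true")
    for s in sim.samples:
        p = out / f"{s.sample_id}.vcf"
        write_fixture_vcf(s, str(p))
        paths[s.sample_id] = str(p)
        manifest_lines.append(f"- {{path: {s.sample_id}.vcf, role: {s.role.value}}}")
    db_path = out / "database.vcf"
    write_database_vcf(sim.db_entries, str(db_path))
    paths["database"] = str(db_path)
    bed_path = out / "units.bed"
    write_units_bed(sim.units, str(bed_path))
    paths["units"] = str(bed_path)
    truth_path = out / "truth.json"
    truth_path.write_text(sim.truth.to_json() + "\n")
    paths["truth"] = str(truth_path)
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    paths["manifest"] = str(manifest_path)
    return sim, paths
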