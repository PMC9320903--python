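"""Core domain model: variant sites, annotations, pedigrees and their readers.

The internal representation keeps one alternate allele per record;
multi-allelic VCF rows are decomposed at ingest. Coordinates are 1-based
(VCF convention) and a variant is identified by ``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "SiteCall",
    "Callset",
    "VariantAnnotation",
    "GeneConstraint",
    "Trio",
    "TrioCohort",
    "ConsequenceClass",
    "Thresholds",
    "VcfParseError",
    "ConfigurationError",
    "read_callset",
    "write_callset",
    "read_annotations",
    "read_constraint",
    "read_pedigree",
    "write_pedigree",
    "classify_consequence",
    "cohort_recurrence",
]

VariantKey = tuple[str, int, str, str]


class VcfParseError(ValueError):
    """Raised for malformed VCF input; message names the offending line."""


class ConfigurationError(ValueError):
    """Raised for inconsistent cohort / configuration input."""


MISSING_GT = -1

#: Ensembl consequence terms grouped as loss-of-function.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)
MISSENSE_TERMS = frozenset({"missense_variant"})
INFRAME_TERMS = frozenset({"inframe_insertion", "inframe_deletion"})


class ConsequenceClass(str, Enum):
    LOF = "LOF"
    missense = "missense"
    inframe_indel = "inframe_indel"
    other = "other"


def classify_consequence(term: str) -> ConsequenceClass:
    """Map an Ensembl consequence term to its analysis class.

    Matching is case-insensitive and tolerant to underscore/space spelling
    variants. Unknown terms map to :attr:`ConsequenceClass.other`.
    """
    norm = term.strip().lower().replace(" ", "_")
    if norm in LOF_TERMS:
        return ConsequenceClass.LOF
    if norm in MISSENSE_TERMS:
        return ConsequenceClass.missense
    if norm in INFRAME_TERMS:
        return ConsequenceClass.inframe_indel
    return ConsequenceClass.other


@dataclass(frozen=True)
class Thresholds:
    """All analysis cutoffs, surfaced so no stage hard-codes them."""

    qual_snv: float = 300.0
    qual_indel: float = 1000.0
    gq: float = 30.0
    af_rare: float = 0.001
    cohort_freq: float = 0.01
    cadd_damaging: float = 25.0
    oe_upper: float = 0.35
    tpm: float = 2.0
    vaf_low: float = 0.10
    vaf_high: float = 0.40
    parental_alt_reads: int = 2
    recurrence: int = 2
    posterior: float = 0.90
    gate: int = 5
    fdr: float = 0.05


@dataclass
class SiteCall:
    """One bi-allelic variant site across all samples of a callset.

    ``genotypes`` holds per-sample alternate-allele counts in {0, 1, 2},
    with -1 for missing. ``gq`` is NaN wherever the genotype is missing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    genotypes: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=float)
        self.ad_ref = np.asarray(self.ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(self.ad_alt, dtype=np.int32)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        if (self.ad_ref < 0).any() or (self.ad_alt < 0).any():
            raise ValueError("read depths must be >= 0")
        # missing genotype implies missing GQ
        self.gq = np.where(self.genotypes == MISSING_GT, np.nan, self.gq)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)


class Callset:
    """A decomposed multi-sample callset: sample order plus site records."""

    def __init__(self, samples: Sequence[str], records: Iterable[SiteCall]):
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ConfigurationError("duplicate sample ids in callset")
        self.samples = samples
        self.records: list[SiteCall] = list(records)
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._by_key: dict[VariantKey, SiteCall] = {}
        for rec in self.records:
            if rec.n_samples != len(samples):
                raise ConfigurationError(
                    f"record {rec.key} has {rec.n_samples} genotypes for "
                    f"{len(samples)} samples"
                )
            self._by_key.setdefault(rec.key, rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def get(self, key: VariantKey) -> SiteCall | None:
        return self._by_key.get(key)

    def genotype_matrix(
        self,
        keys: Sequence[VariantKey] | None = None,
        samples: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Samples x variants matrix of alt-allele counts; NaN = missing."""
        recs = self.records if keys is None else [self._by_key[k] for k in keys]
        idx = (
            slice(None)
            if samples is None
            else [self._sample_index[s] for s in samples]
        )
        cols = []
        for rec in recs:
            g = rec.genotypes[idx].astype(float)
            g[g == MISSING_GT] = np.nan
            cols.append(g)
        if not cols:
            n = len(self.samples) if samples is None else len(samples)
            return np.empty((n, 0))
        return np.column_stack(cols)


@dataclass(frozen=True)
class VariantAnnotation:
    gene: str
    consequence: str
    variant_class: str  # SNV | indel | inframe_indel
    gnomad_af: float  # NaN when the variant is absent from the database
    cadd: float

    def __post_init__(self) -> None:
        if not math.isnan(self.gnomad_af) and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if not math.isnan(self.cadd) and self.cadd < 0:
            raise ValueError(f"cadd must be >= 0: {self.cadd}")
        if self.variant_class == "inframe_indel":
            if classify_consequence(self.consequence) is not ConsequenceClass.inframe_indel:
                raise ValueError(
                    "variant_class inframe_indel requires an inframe "
                    f"insertion/deletion consequence, got {self.consequence!r}"
                )

    @property
    def consequence_class(self) -> ConsequenceClass:
        return classify_consequence(self.consequence)


@dataclass(frozen=True)
class GeneConstraint:
    gene: str
    lof_oe_upper: float
    mis_oe_upper: float

    def __post_init__(self) -> None:
        for v in (self.lof_oe_upper, self.mis_oe_upper):
            if not math.isnan(v) and v < 0:
                raise ValueError("oe upper bounds must be >= 0")


@dataclass(frozen=True)
class Trio:
    proband: str
    father: str
    mother: str

    def __post_init__(self) -> None:
        if len({self.proband, self.father, self.mother}) != 3:
            raise ConfigurationError(f"trio members not distinct: {self}")


@dataclass
class TrioCohort:
    trios: list[Trio]
    cases: set[str]
    controls: set[str]
    defects: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cases & self.controls:
            raise ConfigurationError(
                f"cases and controls overlap: {sorted(self.cases & self.controls)}"
            )
        for trio in self.trios:
            if trio.proband not in self.cases:
                raise ConfigurationError(
                    f"proband {trio.proband} not in case set"
                )

    @property
    def probands(self) -> list[str]:
        return [t.proband for t in self.trios]

    @property
    def parents(self) -> list[str]:
        out: list[str] = []
        for t in self.trios:
            out.extend((t.father, t.mother))
        return out


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _validate_vcf_text(path: Path) -> None:
    """Cheap structural scan so malformed input fails with a line number."""
    n_fields = None
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                fields = line.rstrip("\n").split("\t")
                n_fields = len(fields)
                if n_fields < 8:
                    raise VcfParseError(
                        f"{path}: line {lineno}: truncated #CHROM header"
                    )
                sample_ids = fields[9:]
                if len(set(sample_ids)) != len(sample_ids):
                    raise ConfigurationError(f"{path}: duplicated sample ids")
                continue
            if not saw_header:
                raise VcfParseError(
                    f"{path}: line {lineno}: data before #CHROM header"
                )
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"found {len(fields)}"
                )
    if not saw_header:
        raise VcfParseError(f"{path}: no #CHROM header line found")


def read_callset(vcf_path: str | Path) -> Callset:
    """Read a multi-sample VCF, decomposing multi-allelic records.

    Each alternate allele becomes its own :class:`SiteCall` carrying the
    site QUAL. Half-missing genotypes (e.g. ``0/.``) are treated as missing.
    """
    from cyvcf2 import VCF

    path = Path(vcf_path)
    _validate_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ConfigurationError(f"{path}: duplicated sample ids")
    n = len(samples)
    records: list[SiteCall] = []
    for v in vcf:
        qual = 0.0 if v.QUAL is None else float(v.QUAL)
        gts = v.genotypes  # [a0, a1, phased] per sample
        gqs = v.gt_quals
        ad = v.format("AD")
        for k, alt in enumerate(v.ALT):
            genotypes = np.zeros(n, dtype=np.int8)
            gq = np.full(n, np.nan)
            ad_ref = np.zeros(n, dtype=np.int32)
            ad_alt = np.zeros(n, dtype=np.int32)
            for i in range(n):
                alleles = gts[i][:-1]
                if any(a < 0 for a in alleles) or len(alleles) == 0:
                    genotypes[i] = MISSING_GT
                else:
                    genotypes[i] = sum(1 for a in alleles if a == k + 1)
                    if gqs is not None and gqs[i] >= 0:
                        gq[i] = float(gqs[i])
                if ad is not None:
                    ad_ref[i] = max(int(ad[i][0]), 0)
                    ad_alt[i] = max(int(ad[i][k + 1]), 0)
            records.append(
                SiteCall(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    qual=qual,
                    genotypes=genotypes,
                    gq=gq,
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                )
            )
    vcf.close()
    return Callset(samples, records)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GT: "./."}


def write_callset(callset: Callset, vcf_path: str | Path) -> None:
    """Write a decomposed callset as a plain-text VCF 4.2 file."""
    path = Path(vcf_path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    chroms = []
    for rec in callset.records:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(callset.samples)
    )
    for rec in callset.records:
        cols = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            rec.alt,
            f"{rec.qual:.6g}",
            "PASS",
            ".",
            "GT:GQ:AD",
        ]
        for i in range(rec.n_samples):
            gt = _GT_STRINGS[int(rec.genotypes[i])]
            gq = "." if math.isnan(rec.gq[i]) else str(int(round(rec.gq[i])))
            cols.append(f"{gt}:{gq}:{rec.ad_ref[i]},{rec.ad_alt[i]}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------


def _key_from_row(row) -> VariantKey:
    return (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))


def read_annotations(path: str | Path) -> dict[VariantKey, VariantAnnotation]:
    """Read the per-variant annotation table (tab-separated, one header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[VariantKey, VariantAnnotation] = {}
    for _, row in df.iterrows():
        af = row["gnomad_af"]
        out[_key_from_row(row)] = VariantAnnotation(
            gene=str(row["gene"]),
            consequence=str(row["consequence"]),
            variant_class=str(row["variant_class"]),
            gnomad_af=float(af) if pd.notna(af) else float("nan"),
            cadd=float(row["cadd"]),
        )
    return out


def read_constraint(path: str | Path) -> dict[str, GeneConstraint]:
    df = pd.read_csv(path, sep="\t")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ConfigurationError(f"duplicate constraint records for {dups}")
    return {
        str(row["gene"]): GeneConstraint(
            gene=str(row["gene"]),
            lof_oe_upper=float(row["lof_oe_upper"]),
            mis_oe_upper=float(row["mis_oe_upper"]),
        )
        for _, row in df.iterrows()
    }


_NO_PARENT = {"", "0", ".", "nan"}


def read_pedigree(path: str | Path) -> TrioCohort:
    """Read the cohort table: sample_id, father_id, mother_id, status[, defect].

    ``status`` is one of case / control / parent; a row whose father and
    mother are both present and whose status is ``case`` defines a trio.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    trios = []
    cases: set[str] = set()
    controls: set[str] = set()
    defects: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        status = row["status"].strip().lower()
        father = row["father_id"].strip()
        mother = row["mother_id"].strip()
        if status == "case":
            cases.add(sid)
            if father not in _NO_PARENT and mother not in _NO_PARENT:
                trios.append(Trio(sid, father, mother))
            if "defect" in row and str(row["defect"]).strip():
                defects[sid] = str(row["defect"]).strip()
        elif status == "control":
            controls.add(sid)
        elif status != "parent":
            raise ConfigurationError(f"unknown status {row['status']!r} for {sid}")
    return TrioCohort(trios=trios, cases=cases, controls=controls, defects=defects)


def write_pedigree(cohort: TrioCohort, path: str | Path) -> None:
    rows = []
    for trio in cohort.trios:
        rows.append(
            {
                "sample_id": trio.proband,
                "father_id": trio.father,
                "mother_id": trio.mother,
                "status": "case",
                "defect": cohort.defects.get(trio.proband, ""),
            }
        )
        for parent in (trio.father, trio.mother):
            rows.append(
                {
                    "sample_id": parent,
                    "father_id": "0",
                    "mother_id": "0",
                    "status": "parent",
                    "defect": "",
                }
            )
    for ctrl in sorted(cohort.controls):
        rows.append(
            {
                "sample_id": ctrl,
                "father_id": "0",
                "mother_id": "0",
                "status": "control",
                "defect": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def cohort_recurrence(
    key: VariantKey, callset: Callset, cohort: TrioCohort
) -> int:
    """Number of case-cohort probands carrying >= 1 alt allele at ``key``."""
    rec = callset.get(key)
    if rec is None:
        return 0
    count = 0
    for trio in cohort.trios:
        g = rec.genotypes[callset.sample_index(trio.proband)]
        if g >= 1:
            count += 1
    return count
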