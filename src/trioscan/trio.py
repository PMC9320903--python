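"""High-quality de novo / inherited classification and the proband report.

Quality gates follow GATK semantics: strict inequality on site QUAL
(SNV > 300, indel > 1000), inclusive on parental GQ (>= 30). Recurrence is
the number of case probands carrying the allele and must be <= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Callset,
    ConsequenceClass,
    GeneConstraint,
    SiteCall,
    Thresholds,
    Trio,
    TrioCohort,
    VariantAnnotation,
    VariantKey,
    classify_consequence,
    cohort_recurrence,
)
from .panels import ExpressionTable, GenePanel, damaging_flags, panel_memberships

__all__ = [
    "ClassifiedVariant",
    "qual_ok",
    "is_hq_denovo",
    "is_hq_inherited",
    "classify_trios",
    "retain_rare_damaging",
    "merge_mnv",
    "evaluate_variant_relevance",
    "per_proband_report",
]

HQ_DNV = "HQ_DNV"
HQ_INHERITED = "HQ_INHERITED"


@dataclass
class ClassifiedVariant:
    key: VariantKey
    proband: str
    category: str  # HQ_DNV | HQ_INHERITED
    gene: str | None = None
    consequence_class: ConsequenceClass | None = None
    variant_class: str | None = None
    gnomad_af: float = float("nan")
    cadd: float = float("nan")
    rare: bool | None = None
    damaging: bool | None = None
    damaging_oe: bool | None = None
    damaging_cadd: bool | None = None
    expressed: bool | None = None
    panels: list[str] = field(default_factory=list)
    mnv_group: str | None = None


def qual_ok(site: SiteCall, thresholds: Thresholds = Thresholds()) -> bool:
    """SNVs must exceed the SNV QUAL cutoff, indels the indel cutoff."""
    if site.is_snv:
        return site.qual > thresholds.qual_snv
    return site.qual > thresholds.qual_indel


def is_hq_denovo(
    site: SiteCall,
    trio: Trio,
    callset: Callset,
    recurrence: int,
    thresholds: Thresholds = Thresholds(),
) -> bool:
    """Heterozygous proband, QUAL above the class cutoff, both parents
    confidently homozygous reference (GQ >= cutoff), recurrence <= cutoff.

    A missing parental genotype makes de novo status uncertifiable.
    """
    th = thresholds
    gp = site.genotypes[callset.sample_index(trio.proband)]
    gf = site.genotypes[callset.sample_index(trio.father)]
    gm = site.genotypes[callset.sample_index(trio.mother)]
    if gp != 1:
        return False
    if not qual_ok(site, th):
        return False
    for g, parent in ((gf, trio.father), (gm, trio.mother)):
        if g != 0:
            return False
        gq = site.gq[callset.sample_index(parent)]
        if not (gq == gq and gq >= th.gq):  # NaN-safe
            return False
    return recurrence <= th.recurrence


def is_hq_inherited(
    site: SiteCall,
    trio: Trio,
    callset: Callset,
    recurrence: int,
    thresholds: Thresholds = Thresholds(),
) -> bool:
    """Proband carries the allele, QUAL passes, and at least one parent
    carries it too; recurrence <= cutoff. Parental GQ is not required here.
    """
    th = thresholds
    gp = site.genotypes[callset.sample_index(trio.proband)]
    gf = site.genotypes[callset.sample_index(trio.father)]
    gm = site.genotypes[callset.sample_index(trio.mother)]
    if gp < 1:
        return False
    if not qual_ok(site, th):
        return False
    if not (gf >= 1 or gm >= 1):
        return False
    return recurrence <= th.recurrence


def classify_trios(
    callset: Callset,
    cohort: TrioCohort,
    thresholds: Thresholds = Thresholds(),
) -> list[ClassifiedVariant]:
    """Run both classifiers over every (site, trio) pair.

    The two categories are mutually exclusive at any pair by construction
    (de novo requires both parents hom-ref; inherited requires a carrier
    parent).
    """
    out: list[ClassifiedVariant] = []
    for site in callset.records:
        rec = cohort_recurrence(site.key, callset, cohort)
        for trio in cohort.trios:
            if is_hq_denovo(site, trio, callset, rec, thresholds):
                out.append(
                    ClassifiedVariant(key=site.key, proband=trio.proband, category=HQ_DNV)
                )
            elif is_hq_inherited(site, trio, callset, rec, thresholds):
                out.append(
                    ClassifiedVariant(
                        key=site.key, proband=trio.proband, category=HQ_INHERITED
                    )
                )
    return out


def annotate_classified(
    classified: Sequence[ClassifiedVariant],
    annotations: Mapping[VariantKey, VariantAnnotation],
) -> list[ClassifiedVariant]:
    """Attach gene / consequence / AF / CADD fields from the annotation table."""
    for cv in classified:
        ann = annotations.get(cv.key)
        if ann is None:
            continue
        cv.gene = ann.gene
        cv.consequence_class = ann.consequence_class
        cv.variant_class = ann.variant_class
        cv.gnomad_af = ann.gnomad_af
        cv.cadd = ann.cadd
    return list(classified)


def _af_or_zero(af: float) -> float:
    # absent from gnomAD => rarer than anything listed
    return 0.0 if af != af else af


def retain_rare_damaging(
    classified: Sequence[ClassifiedVariant],
    annotations: Mapping[VariantKey, VariantAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> list[ClassifiedVariant]:
    """Keep LOF / missense variants with gnomAD AF <= the rare cutoff.

    Inframe indels are dropped (false-positive-prone variant class);
    a missing AF counts as 0.
    """
    annotate_classified(classified, annotations)
    kept = []
    for cv in classified:
        if cv.consequence_class is None:
            continue
        if cv.consequence_class is ConsequenceClass.inframe_indel:
            continue
        if cv.variant_class == "inframe_indel":
            continue
        if cv.consequence_class not in (ConsequenceClass.LOF, ConsequenceClass.missense):
            continue
        if _af_or_zero(cv.gnomad_af) > thresholds.af_rare:
            continue
        cv.rare = True
        kept.append(cv)
    return kept


def merge_mnv(classified: Sequence[ClassifiedVariant]) -> list[ClassifiedVariant]:
    """Group per-proband variants at directly adjacent positions.

    Variants of the same proband and category at consecutive positions
    (pos difference exactly 1, same chromosome) form one multi-nucleotide
    variant: they share an ``mnv_group`` id and count once in all tallies.
    The group carries the maximum CADD and minimum gnomAD AF of its members.
    """
    ordered = sorted(
        classified, key=lambda cv: (cv.proband, cv.category, cv.key[0], cv.key[1])
    )
    group_id = 0
    prev: ClassifiedVariant | None = None
    for cv in ordered:
        adjacent = (
            prev is not None
            and cv.proband == prev.proband
            and cv.category == prev.category
            and cv.key[0] == prev.key[0]
            and cv.key[1] == prev.key[1] + 1
        )
        if not adjacent:
            group_id += 1
        cv.mnv_group = f"mnv{group_id}"
        prev = cv
    # propagate max CADD / min AF within each group
    by_group: dict[str, list[ClassifiedVariant]] = {}
    for cv in ordered:
        by_group.setdefault(cv.mnv_group, []).append(cv)
    for members in by_group.values():
        if len(members) > 1:
            cadds = [cv.cadd for cv in members if cv.cadd == cv.cadd]
            afs = [_af_or_zero(cv.gnomad_af) for cv in members]
            best_cadd = max(cadds) if cadds else float("nan")
            best_af = min(afs)
            for cv in members:
                cv.cadd = best_cadd
                cv.gnomad_af = best_af
    return ordered


def evaluate_variant_relevance(
    classified: Sequence[ClassifiedVariant],
    annotations: Mapping[VariantKey, VariantAnnotation],
    constraint: Mapping[str, GeneConstraint],
    expression: ExpressionTable,
    panels: Sequence[GenePanel],
    thresholds: Thresholds = Thresholds(),
) -> list[ClassifiedVariant]:
    """Set expressed / damaging / panel-membership flags on retained variants."""
    for cv in classified:
        ann = annotations.get(cv.key)
        if ann is None or cv.gene is None:
            continue
        flags = damaging_flags(ann, constraint, thresholds)
        # MNV merging may have promoted the group CADD past the cutoff
        if (
            cv.consequence_class is ConsequenceClass.missense
            and cv.cadd == cv.cadd
            and cv.cadd >= thresholds.cadd_damaging
        ):
            flags["cadd"] = True
            flags["damaging"] = True
        cv.damaging = flags["damaging"]
        cv.damaging_oe = flags["oe"]
        cv.damaging_cadd = flags["cadd"]
        cv.expressed = expression.is_embryonically_expressed(cv.gene)
        cv.panels = panel_memberships(cv.gene, panels)
    return list(classified)


def _count_groups(variants: Sequence[ClassifiedVariant]) -> int:
    """Number of distinct variants, counting each MNV group once."""
    seen = set()
    n = 0
    for cv in variants:
        token = cv.mnv_group or ("solo", cv.key, cv.proband, cv.category)
        if token not in seen:
            seen.add(token)
            n += 1
    return n


def per_proband_report(
    classified: Sequence[ClassifiedVariant],
    cohort: TrioCohort,
    thresholds: Thresholds = Thresholds(),
    sample_sd: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-proband counts plus cohort-level descriptive statistics.

    Columns: HQ DNVs, rare HQ DNVs, rare retained (LOF+missense) DNVs,
    HQ inherited, rare HQ inherited (all consequences), the LOF+missense
    subset, and 'variants of interest' (rare + damaging + expressed +
    present in >= 1 panel). Means are totals over the number of probands;
    the standard deviation is the sample sd (n-1) unless ``sample_sd`` is
    False.
    """
    th = thresholds
    probands = cohort.probands
    cols = [
        "hq_dnv",
        "rare_hq_dnv",
        "retained_dnv",
        "hq_inherited",
        "rare_hq_inherited",
        "rare_hq_inherited_lofmis",
        "variants_of_interest",
    ]
    counts = pd.DataFrame(0, index=probands, columns=cols)

    def bucket(cv: ClassifiedVariant) -> list[str]:
        rare = _af_or_zero(cv.gnomad_af) <= th.af_rare
        inframe = (
            cv.consequence_class is ConsequenceClass.inframe_indel
            or cv.variant_class == "inframe_indel"
        )
        lofmis = cv.consequence_class in (
            ConsequenceClass.LOF,
            ConsequenceClass.missense,
        )
        out = []
        if cv.category == HQ_DNV:
            out.append("hq_dnv")
            if rare and not inframe:
                out.append("rare_hq_dnv")
            if rare and lofmis:
                out.append("retained_dnv")
        else:
            out.append("hq_inherited")
            if rare and not inframe:
                out.append("rare_hq_inherited")
            if rare and lofmis:
                out.append("rare_hq_inherited_lofmis")
        if (
            rare
            and lofmis
            and cv.damaging is True
            and cv.expressed is True
            and len(cv.panels) > 0
        ):
            out.append("variants_of_interest")
        return out

    seen: dict[str, set] = {c: set() for c in cols}
    for cv in classified:
        if cv.proband not in counts.index:
            continue
        token = cv.mnv_group or ("solo", cv.key, cv.proband, cv.category)
        for col in bucket(cv):
            if (cv.proband, token) in seen[col]:
                continue
            seen[col].add((cv.proband, token))
            counts.loc[cv.proband, col] += 1

    n = len(probands)
    ddof = 1 if sample_sd else 0
    summary_rows = []
    for col in cols:
        vals = counts[col].to_numpy(dtype=float)
        summary_rows.append(
            {
                "count": col,
                "total": int(vals.sum()),
                "min": int(vals.min()) if n else 0,
                "max": int(vals.max()) if n else 0,
                "median": float(np.median(vals)) if n else 0.0,
                "mean": float(vals.sum() / n) if n else 0.0,
                "sd": float(np.std(vals, ddof=ddof)) if n > ddof else 0.0,
            }
        )
    return counts, pd.DataFrame(summary_rows)
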