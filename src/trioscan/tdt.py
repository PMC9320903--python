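"""Transmission disequilibrium testing at gene and panel level.

Informative alleles are heterozygous parental genotypes at HQ rare LOF /
missense sites in embryonically expressed genes. Transmission is resolved
at the allele level: a double-heterozygous parent pair contributes two
informative alleles, and a heterozygous child then counts one transmission
and one non-transmission.

Two test methods are provided: an exact two-sided binomial test (default;
appropriate at the gated minimum of five alleles, conservative) and the
classical chi-square TDT statistic (b-c)^2/(b+c) (asymptotic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    Callset,
    ConsequenceClass,
    Thresholds,
    Trio,
    TrioCohort,
    VariantAnnotation,
    VariantKey,
)
from .panels import ExpressionTable, GenePanel
from .stats import bh_adjust
from .trio import qual_ok

logger = logging.getLogger(__name__)

__all__ = [
    "ParentalVariant",
    "TransmissionCount",
    "TdtResult",
    "select_parental_variants",
    "count_transmissions",
    "tdt_test",
    "run_tdt",
]


@dataclass(frozen=True)
class ParentalVariant:
    key: VariantKey
    gene: str
    consequence_class: ConsequenceClass
    trio: Trio
    parent: str


@dataclass
class TransmissionCount:
    unit: str
    consequence_class: ConsequenceClass
    b: int = 0  # transmitted
    c: int = 0  # untransmitted

    @property
    def informative(self) -> int:
        return self.b + self.c


@dataclass
class TdtResult:
    unit: str
    consequence_class: ConsequenceClass
    b: int
    c: int
    statistic: float | None
    p: float | None
    q: float | None
    tested: bool


def select_parental_variants(
    callset: Callset,
    annotations: Mapping[VariantKey, VariantAnnotation],
    cohort: TrioCohort,
    expression: ExpressionTable,
    thresholds: Thresholds = Thresholds(),
) -> list[ParentalVariant]:
    """HQ rare heterozygous LOF/missense parental alleles in expressed genes."""
    th = thresholds
    out: list[ParentalVariant] = []
    for site in callset.records:
        ann = annotations.get(site.key)
        if ann is None:
            continue
        cclass = ann.consequence_class
        if cclass not in (ConsequenceClass.LOF, ConsequenceClass.missense):
            continue
        if ann.variant_class == "inframe_indel":
            continue
        af = 0.0 if ann.gnomad_af != ann.gnomad_af else ann.gnomad_af
        if af > th.af_rare:
            continue
        if not qual_ok(site, th):
            continue
        if expression.is_embryonically_expressed(ann.gene) is not True:
            continue
        for trio in cohort.trios:
            for parent in (trio.father, trio.mother):
                if site.genotypes[callset.sample_index(parent)] == 1:
                    out.append(
                        ParentalVariant(
                            key=site.key,
                            gene=ann.gene,
                            consequence_class=cclass,
                            trio=trio,
                            parent=parent,
                        )
                    )
    return out


def count_transmissions(
    parental: Sequence[ParentalVariant],
    callset: Callset,
    panels: Sequence[GenePanel] | None = None,
) -> dict[tuple[str, ConsequenceClass], TransmissionCount]:
    """Tally transmitted (b) / untransmitted (c) alleles per unit and class.

    With ``panels`` given, units are panel names and a variant contributes
    to every panel containing its gene; otherwise units are genes.
    Child-missing genotypes are uninformative and excluded.
    """
    # group informative parents per (site, trio)
    grouped: dict[tuple[VariantKey, Trio], list[ParentalVariant]] = {}
    for pv in parental:
        grouped.setdefault((pv.key, pv.trio), []).append(pv)

    counts: dict[tuple[str, ConsequenceClass], TransmissionCount] = {}

    def units_for(gene: str) -> list[str]:
        if panels is None:
            return [gene]
        return [p.name for p in panels if gene in p]

    for (key, trio), pvs in grouped.items():
        site = callset.get(key)
        if site is None:
            continue
        g_child = int(site.genotypes[callset.sample_index(trio.proband)])
        if g_child < 0:
            continue
        h = len(pvs)  # het parents (1 or 2)
        f = 0  # alt alleles forced by a hom-alt other parent
        if h == 1:
            other = trio.mother if pvs[0].parent == trio.father else trio.father
            g_other = int(site.genotypes[callset.sample_index(other)])
            if g_other < 0:
                continue  # cannot attribute the child's alleles
            if g_other == 2:
                f = 1
        transmitted = min(max(g_child - f, 0), h)
        gene = pvs[0].gene
        cclass = pvs[0].consequence_class
        for unit in units_for(gene):
            tc = counts.setdefault(
                (unit, cclass), TransmissionCount(unit=unit, consequence_class=cclass)
            )
            tc.b += transmitted
            tc.c += h - transmitted
    return counts


def tdt_test(
    count: TransmissionCount, method: str = "binomial"
) -> tuple[float, float]:
    """Test b transmitted vs c untransmitted alleles against 0.5.

    ``binomial``: two-sided exact binomial p on b out of b+c (statistic b).
    ``chi2``: statistic (b-c)^2/(b+c), p from chi-square with 1 df.
    """
    b, c = count.b, count.c
    n = b + c
    if n == 0:
        raise ValueError("b + c must be positive; gate before testing")
    if method == "chi2":
        stat = (b - c) ** 2 / n
        return float(stat), float(sps.chi2.sf(stat, df=1))
    if method == "binomial":
        p = sps.binomtest(b, n, 0.5, alternative="two-sided").pvalue
        return float(b), float(min(p, 1.0))
    raise ValueError(f"unknown method {method!r}")


def run_tdt(
    callset: Callset,
    annotations: Mapping[VariantKey, VariantAnnotation],
    cohort: TrioCohort,
    expression: ExpressionTable,
    level: str = "gene",
    consequence_class: ConsequenceClass | str = ConsequenceClass.LOF,
    panels: Sequence[GenePanel] | None = None,
    method: str = "binomial",
    thresholds: Thresholds = Thresholds(),
) -> list[TdtResult]:
    """One TDT per unit x class with b+c >= gate; BH within the family."""
    cclass = ConsequenceClass(consequence_class)
    if level == "panel":
        if panels is None:
            raise ValueError("panel-level TDT requires panels")
        use_panels: Sequence[GenePanel] | None = panels
    elif level == "gene":
        use_panels = None
    else:
        raise ValueError(f"unknown level {level!r}")
    parental = [
        pv
        for pv in select_parental_variants(callset, annotations, cohort, expression, thresholds)
        if pv.consequence_class is cclass
    ]
    counts = count_transmissions(parental, callset, use_panels)
    results: list[TdtResult] = []
    for (unit, kls), tc in sorted(counts.items(), key=lambda kv: kv[0][0]):
        if tc.informative >= thresholds.gate:
            stat, p = tdt_test(tc, method)
            results.append(TdtResult(unit, kls, tc.b, tc.c, stat, p, None, True))
        else:
            results.append(TdtResult(unit, kls, tc.b, tc.c, None, None, None, False))
    tested = [r for r in results if r.tested]
    if tested:
        qs = bh_adjust([r.p for r in tested])
        for r, q in zip(tested, qs):
            r.q = float(q)
    else:
        logger.warning("TDT (%s, %s): no testable units", level, cclass.value)
    return results
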