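"""Post-filtering of mosaic (post-zygotic) candidate variants.

Candidates arrive as an external table (site, proband, posterior, VAF,
per-parent alt-read counts); the Bayesian caller that produced them is not
re-implemented. The filter is a pure conjunction of five criteria, and each
candidate is returned with its per-criterion verdicts for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    Callset,
    ConsequenceClass,
    GeneConstraint,
    Thresholds,
    TrioCohort,
    VariantAnnotation,
    VariantKey,
    cohort_recurrence,
)
from .panels import ExpressionTable, GenePanel, damaging_flags, panel_memberships

__all__ = [
    "MosaicCandidate",
    "MosaicFilterResult",
    "MosaicRelevance",
    "read_mosaic_candidates",
    "filter_mosaic_candidates",
    "evaluate_mosaic_relevance",
    "write_filter_report",
]


@dataclass(frozen=True)
class MosaicCandidate:
    key: VariantKey
    proband: str
    posterior: float
    vaf: float
    father_alt_reads: int
    mother_alt_reads: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"posterior out of [0,1]: {self.posterior}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.father_alt_reads < 0 or self.mother_alt_reads < 0:
            raise ValueError("parental alt-read counts must be >= 0")

    @property
    def parental_alt_reads(self) -> int:
        """Maximum alt-read count across the two parents."""
        return max(self.father_alt_reads, self.mother_alt_reads)


@dataclass
class MosaicFilterResult:
    candidate: MosaicCandidate
    checks: dict[str, bool]
    passed: bool
    reason: str | None = None


CRITERIA = ("posterior", "vaf", "parental_background", "recurrence", "consequence")


@dataclass
class MosaicRelevance:
    candidate: MosaicCandidate
    gene: str
    rare: bool
    expressed: bool | None
    damaging: bool | None
    damaging_oe: bool | None
    damaging_cadd: bool | None
    panels: list[str] = field(default_factory=list)


def read_mosaic_candidates(path: str | Path) -> list[MosaicCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        MosaicCandidate(
            key=(str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"])),
            proband=str(r["proband"]),
            posterior=float(r["posterior"]),
            vaf=float(r["vaf"]),
            father_alt_reads=int(r["father_alt_reads"]),
            mother_alt_reads=int(r["mother_alt_reads"]),
        )
        for _, r in df.iterrows()
    ]


def filter_mosaic_candidates(
    candidates: Sequence[MosaicCandidate],
    callset: Callset,
    cohort: TrioCohort,
    annotations: Mapping[VariantKey, VariantAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> list[MosaicFilterResult]:
    """Apply the five-way conjunction filter.

    posterior >= 0.90, VAF within the closed window, <= 2 alt reads in each
    parent, cohort recurrence <= 2, consequence LOF or missense.
    Unannotated candidates are excluded with reason ``unannotated``.
    """
    th = thresholds
    results = []
    for cand in candidates:
        ann = annotations.get(cand.key)
        if ann is None:
            results.append(
                MosaicFilterResult(
                    candidate=cand,
                    checks={c: False for c in CRITERIA},
                    passed=False,
                    reason="unannotated",
                )
            )
            continue
        cclass = ann.consequence_class
        checks = {
            "posterior": cand.posterior >= th.posterior,
            "vaf": th.vaf_low <= cand.vaf <= th.vaf_high,
            "parental_background": (
                cand.father_alt_reads <= th.parental_alt_reads
                and cand.mother_alt_reads <= th.parental_alt_reads
            ),
            "recurrence": cohort_recurrence(cand.key, callset, cohort)
            <= th.recurrence,
            "consequence": cclass
            in (ConsequenceClass.LOF, ConsequenceClass.missense),
        }
        results.append(
            MosaicFilterResult(
                candidate=cand, checks=checks, passed=all(checks.values())
            )
        )
    return results


def evaluate_mosaic_relevance(
    candidate: MosaicCandidate,
    annotation: VariantAnnotation,
    constraint: Mapping[str, GeneConstraint],
    expression: ExpressionTable,
    panels: Sequence[GenePanel],
    thresholds: Thresholds = Thresholds(),
) -> MosaicRelevance:
    """Annotate a surviving candidate for phenotype relevance."""
    af = annotation.gnomad_af
    rare = bool(af <= thresholds.af_rare) if af == af else True  # NaN => rare
    flags = damaging_flags(annotation, constraint, thresholds)
    return MosaicRelevance(
        candidate=candidate,
        gene=annotation.gene,
        rare=rare,
        expressed=expression.is_embryonically_expressed(annotation.gene),
        damaging=flags["damaging"],
        damaging_oe=flags["oe"],
        damaging_cadd=flags["cadd"],
        panels=panel_memberships(annotation.gene, panels),
    )


def write_filter_report(
    results: Sequence[MosaicFilterResult], path: str | Path
) -> None:
    rows = []
    for res in results:
        chrom, pos, ref, alt = res.candidate.key
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "proband": res.candidate.proband,
            "posterior": res.candidate.posterior,
            "vaf": res.candidate.vaf,
            "father_alt_reads": res.candidate.father_alt_reads,
            "mother_alt_reads": res.candidate.mother_alt_reads,
        }
        for crit in CRITERIA:
            row[f"pass_{crit}"] = res.checks[crit]
        row["passed"] = res.passed
        row["reason"] = res.reason or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
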