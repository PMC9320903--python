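"""End-to-end pipeline: simulate/load -> classify -> mosaic -> TDT -> AT -> report.

Every stage logs its input/output counts (filter-attrition funnel) and the
cohort summary reports defect-type frequencies as count and percentage of
probands alongside the per-proband variant-count distributions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import mosaic as mosaic_mod
from . import tdt as tdt_mod
from . import trio as trio_mod
from .core import (
    Callset,
    ConsequenceClass,
    Thresholds,
    TrioCohort,
    read_annotations,
    read_callset,
    read_constraint,
    read_pedigree,
)
from .panels import ExpressionTable, load_panels, read_expression, restrict_panel
from .stats import percent_of_cohort
from .synthetic import SimConfig, simulate_cohort, write_fixture_bundle

logger = logging.getLogger("trioscan")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Single-document pipeline configuration.

    Either ``sim`` (a synthetic-cohort config) or ``inputs`` (a mapping of
    file paths: vcf, annotations, constraint, expression, panels_dir,
    pedigree, mosaic_candidates) must be provided.
    """

    out_dir: str
    sim: SimConfig | None = None
    inputs: dict[str, str] | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    tdt_method: str = "binomial"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        sim = None
        if "sim" in doc:
            sim = SimConfig(**doc["sim"])
        th = Thresholds(**doc.get("thresholds", {}))
        return cls(
            out_dir=doc["out_dir"],
            sim=sim,
            inputs=doc.get("inputs"),
            thresholds=th,
            tdt_method=doc.get("tdt_method", "binomial"),
            seed=doc.get("seed", 0),
        )


@dataclass
class PipelineResult:
    cohort: TrioCohort
    proband_counts: pd.DataFrame
    proband_summary: pd.DataFrame
    defect_summary: pd.DataFrame
    mosaic_report: list
    tdt_results: dict[tuple[str, str], list]
    at_results: dict[tuple[str, str], list]
    excluded_controls: set[str]
    funnel: dict[str, int]


def _tdt_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                unit=r.unit,
                consequence_class=r.consequence_class.value,
                b=r.b,
                c=r.c,
                statistic=r.statistic,
                p=r.p,
                q=r.q,
                tested=r.tested,
            )
            for r in results
        ]
    )


def _at_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                unit=r.unit,
                consequence_class=r.consequence_class.value,
                n_variants=r.n_variants,
                allele_count=r.allele_count,
                beta1=r.beta1,
                lrt=r.lrt,
                p=r.p,
                q=r.q,
                tested=r.tested,
                note=r.note,
            )
            for r in results
        ]
    )


def defect_summary(cohort: TrioCohort) -> pd.DataFrame:
    """Defect-type counts and percentage of probands (1 decimal, half-up)."""
    n = len(cohort.probands)
    counts: dict[str, int] = {}
    for p in cohort.probands:
        label = cohort.defects.get(p, "unspecified")
        counts[label] = counts.get(label, 0) + 1
    rows = [
        dict(defect=label, count=c, percent=percent_of_cohort(c, n))
        for label, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    funnel: dict[str, int] = {}

    # --- stage: inputs ----------------------------------------------------
    if config.sim is not None:
        sim = simulate_cohort(dataclasses.replace(config.sim, seed=config.seed))
        bundle_dir = out / "inputs"
        write_fixture_bundle(sim, bundle_dir)
        callset = read_callset(bundle_dir / "callset.vcf")
        annotations = read_annotations(bundle_dir / "annotations.tsv")
        constraint = read_constraint(bundle_dir / "constraint.tsv")
        expression = read_expression(bundle_dir / "expression.tsv")
        panels = load_panels(bundle_dir / "panels")
        cohort = read_pedigree(bundle_dir / "pedigree.tsv")
        mosaic_candidates = mosaic_mod.read_mosaic_candidates(
            bundle_dir / "mosaic_candidates.tsv"
        )
    elif config.inputs is not None:
        paths = config.inputs
        try:
            callset = read_callset(paths["vcf"])
            annotations = read_annotations(paths["annotations"])
            constraint = read_constraint(paths["constraint"])
            expression = read_expression(paths["expression"])
            panels = load_panels(paths["panels_dir"])
            cohort = read_pedigree(paths["pedigree"])
            mosaic_candidates = (
                mosaic_mod.read_mosaic_candidates(paths["mosaic_candidates"])
                if "mosaic_candidates" in paths
                else []
            )
        except KeyError as exc:
            raise FileNotFoundError(f"stage 'inputs': missing input entry {exc}") from exc
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"stage 'inputs': {exc}") from exc
    else:
        raise ValueError("PipelineConfig needs either 'sim' or 'inputs'")
    funnel["sites"] = len(callset)
    logger.info("inputs: %d sites, %d samples, %d trios", len(callset), len(callset.samples), len(cohort.trios))

    restricted = [restrict_panel(p, expression) for p in panels]

    # --- stage: trio classification --------------------------------------
    classified = trio_mod.classify_trios(callset, cohort, th)
    funnel["classified"] = len(classified)
    retained = trio_mod.retain_rare_damaging(list(classified), annotations, th)
    funnel["rare_damaging"] = len(retained)
    trio_mod.annotate_classified(classified, annotations)
    merged = trio_mod.merge_mnv(classified)
    trio_mod.evaluate_variant_relevance(merged, annotations, constraint, expression, panels, th)
    counts, summary = trio_mod.per_proband_report(merged, cohort, th)
    logger.info(
        "trio classification: %d classified -> %d rare LOF/missense", len(classified), len(retained)
    )

    # --- stage: mosaic filtering -----------------------------------------
    mosaic_results = mosaic_mod.filter_mosaic_candidates(
        mosaic_candidates, callset, cohort, annotations, th
    )
    survivors = [r for r in mosaic_results if r.passed]
    funnel["mosaic_candidates"] = len(mosaic_results)
    funnel["mosaic_survivors"] = len(survivors)
    logger.info("mosaic: %d candidates -> %d survivors", len(mosaic_results), len(survivors))

    # --- stage: TDT -------------------------------------------------------
    tdt_results = {}
    for level in ("gene", "panel"):
        for cclass in (ConsequenceClass.LOF, ConsequenceClass.missense):
            res = tdt_mod.run_tdt(
                callset,
                annotations,
                cohort,
                expression,
                level=level,
                consequence_class=cclass,
                panels=restricted if level == "panel" else None,
                method=config.tdt_method,
                thresholds=th,
            )
            tdt_results[(level, cclass.value)] = res
            funnel[f"tdt_{level}_{cclass.value}_tested"] = sum(r.tested for r in res)

    # --- stage: burden AT -------------------------------------------------
    controls_sorted = sorted(cohort.controls)
    # common-variant set for GRM/PCA: cohort MAF >= 5%, missingness <= 10%
    common_keys = []
    for rec in callset.records:
        g = rec.genotypes.astype(float)
        missing = g < 0
        if missing.mean() > 0.10:
            continue
        p = g[~missing].mean() / 2 if (~missing).any() else 0.0
        if 0.05 <= p <= 0.95:
            common_keys.append(rec.key)
    excluded: set[str] = set()
    if common_keys and controls_sorted:
        Gc = callset.genotype_matrix(keys=common_keys, samples=controls_sorted)
        grm = burden_mod.compute_grm(Gc)
        excluded = burden_mod.exclude_related(grm, controls_sorted)
    kept_controls = [c for c in controls_sorted if c not in excluded]
    funnel["controls_excluded_related"] = len(excluded)
    logger.info("relatedness: excluded %d of %d controls", len(excluded), len(controls_sorted))

    at_samples = cohort.probands + kept_controls
    at_results = {}
    if common_keys and kept_controls:
        Ga = callset.genotype_matrix(keys=common_keys, samples=at_samples)
        pc1 = burden_mod.compute_pc1(Ga)
        for level in ("gene", "panel"):
            for cclass in (ConsequenceClass.LOF, ConsequenceClass.missense):
                res = burden_mod.run_at(
                    callset,
                    annotations,
                    expression,
                    cohort,
                    kept_controls,
                    pc1,
                    level=level,
                    consequence_class=cclass,
                    panels=restricted if level == "panel" else None,
                    thresholds=th,
                )
                at_results[(level, cclass.value)] = res
                funnel[f"at_{level}_{cclass.value}_tested"] = sum(r.tested for r in res)

    # --- stage: report ----------------------------------------------------
    defects = defect_summary(cohort)
    counts.to_csv(out / "proband_counts.tsv", sep="\t", float_format="%.6g")
    summary.to_csv(out / "proband_summary.tsv", sep="\t", index=False, float_format="%.6g")
    defects.to_csv(out / "defect_summary.tsv", sep="\t", index=False, float_format="%.6g")
    mosaic_mod.write_filter_report(mosaic_results, out / "mosaic_report.tsv")
    for (level, cname), res in tdt_results.items():
        _tdt_frame(res).to_csv(
            out / f"tdt_{level}_{cname}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    for (level, cname), res in at_results.items():
        _at_frame(res).to_csv(
            out / f"at_{level}_{cname}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    (out / "funnel.json").write_text(json.dumps(funnel, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        cohort=cohort,
        proband_counts=counts,
        proband_summary=summary,
        defect_summary=defects,
        mosaic_report=mosaic_results,
        tdt_results=tdt_results,
        at_results=at_results,
        excluded_controls=excluded,
        funnel=funnel,
    )
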