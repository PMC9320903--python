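"""Case/control burden association with the CADD-weighted variant fraction.

Per sample and unit (gene or panel), the variant fraction is
VF = sum over selected variants of VAC * (CADD / 10), VAC the sample's
alt-allele count. Association is a logistic regression
logit(p) = b0 + b1*VF + b2*PC1 tested against the PC1-only reduced model by
likelihood ratio. Relatedness pruning uses a standardized genetic
relationship matrix; population structure enters through the leading
principal component of the common-variant genotype matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    Callset,
    ConsequenceClass,
    Thresholds,
    TrioCohort,
    VariantAnnotation,
    VariantKey,
)
from .panels import ExpressionTable, GenePanel
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SelectedVariant",
    "BurdenFit",
    "BurdenResult",
    "compute_grm",
    "exclude_related",
    "compute_pc1",
    "select_at_variants",
    "variant_fraction",
    "fit_burden_model",
    "lrt_pvalue",
    "run_at",
]


@dataclass(frozen=True)
class SelectedVariant:
    key: VariantKey
    gene: str
    consequence_class: ConsequenceClass
    cadd: float


@dataclass
class BurdenFit:
    beta0: float
    beta1: float
    beta2: float
    loglik_full: float
    loglik_reduced: float
    converged: bool
    separated: bool
    note: str = ""


@dataclass
class BurdenResult:
    unit: str
    consequence_class: ConsequenceClass
    n_variants: int
    allele_count: int
    beta1: float | None
    lrt: float | None
    p: float | None
    q: float | None
    tested: bool
    note: str = ""


def compute_grm(genotypes: np.ndarray) -> np.ndarray:
    """Standardized (Yang-style) GRM from a samples x variants matrix.

    Entry (j,k) = mean over variants of
    (g_j - 2p)(g_k - 2p) / (2p(1-p)) with p the sample allele frequency.
    Missing genotypes (NaN) are mean-imputed per variant; monomorphic
    variants are skipped.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 samples")
    p = np.nanmean(G, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all variants are monomorphic")
    G = G[:, keep]
    p = p[keep]
    G = np.where(np.isnan(G), 2.0 * p, G)
    Z = (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    M = Z.shape[1]
    return Z @ Z.T / M


def exclude_related(grm: np.ndarray, sample_ids: Sequence[str]) -> set[str]:
    """Samples with any pairwise relationship above the smallest self value.

    Threshold t = min diagonal entry; every sample with an off-diagonal
    entry > t is excluded, so both members of an offending pair go.
    """
    K = np.asarray(grm, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or n != len(sample_ids):
        raise ValueError("GRM dimensions must match sample count")
    t = float(np.min(np.diag(K)))
    off = K.copy()
    np.fill_diagonal(off, -np.inf)
    mask = (off > t).any(axis=1)
    return {sample_ids[i] for i in np.nonzero(mask)[0]}


def compute_pc1(genotypes: np.ndarray) -> np.ndarray:
    """Leading principal-component score per sample.

    Variants are standardized to mean 0 / variance 1 (missing values
    mean-imputed); the sign is fixed so the largest-magnitude variant
    loading is positive.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ValueError("need at least one variant")
    mu = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), mu, G)
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no polymorphic variants for PCA")
    X = (G[:, keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0] * S[0]
    loading = Vt[0]
    if loading[int(np.argmax(np.abs(loading)))] < 0:
        scores = -scores
    return scores


def select_at_variants(
    callset: Callset,
    annotations: Mapping[VariantKey, VariantAnnotation],
    expression: ExpressionTable,
    samples: Sequence[str],
    thresholds: Thresholds = Thresholds(),
) -> list[SelectedVariant]:
    """Rare LOF/missense variants in expressed genes, with an in-house
    cohort allele-frequency guard (cases and controls combined).
    """
    th = thresholds
    idx = [callset.sample_index(s) for s in samples]
    out: list[SelectedVariant] = []
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
        g = site.genotypes[idx].astype(float)
        observed = g >= 0
        n_alleles = 2 * observed.sum()
        if n_alleles == 0:
            continue
        cohort_af = g[observed].sum() / n_alleles
        if cohort_af > th.cohort_freq:
            continue
        if expression.is_embryonically_expressed(ann.gene) is not True:
            continue
        out.append(SelectedVariant(site.key, ann.gene, cclass, ann.cadd))
    return out


def variant_fraction(
    genotypes: np.ndarray, cadds: Sequence[float]
) -> np.ndarray:
    """VF per sample: sum of VAC * CADD/10 over the selected variants.

    ``genotypes`` is samples x variants (NaN/negative treated as 0 carriage);
    a missing CADD contributes weight 0 with a warning.
    """
    G = np.asarray(genotypes, dtype=float)
    w = np.asarray(cadds, dtype=float) / 10.0
    if np.isnan(w).any():
        logger.warning("missing CADD for %d variants; weight 0 used", int(np.isnan(w).sum()))
        w = np.nan_to_num(w)
    G = np.where(np.isnan(G) | (G < 0), 0.0, G)
    return G @ w


def fit_burden_model(
    status: np.ndarray, vf: np.ndarray, pc1: np.ndarray
) -> BurdenFit:
    """ML fit of the full (VF + PC1) and reduced (PC1-only) logistic models."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    except ImportError:  # older statsmodels
        PerfectSeparationWarning = UserWarning

    y = np.asarray(status, dtype=float)
    vf = np.asarray(vf, dtype=float)
    pc1 = np.asarray(pc1, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    X_full = np.column_stack([np.ones_like(y), vf, pc1])
    X_red = np.column_stack([np.ones_like(y), pc1])

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    def _fit(X):
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            # non-convergence is detected and flagged via mle_retvals below
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, X).fit(
                disp=0, method="newton", maxiter=100, tol=1e-8
            )
        return res

    try:
        full = _fit(X_full)
        red = _fit(X_red)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        return BurdenFit(
            beta0=float("nan"),
            beta1=float("nan"),
            beta2=float("nan"),
            loglik_full=float("nan"),
            loglik_reduced=float("nan"),
            converged=False,
            separated=True,
            note=f"separation: {exc}",
        )
    converged = bool(full.mle_retvals["converged"] and red.mle_retvals["converged"])
    separated = bool(np.abs(full.params).max() > 50) or not np.isfinite(full.llf)
    return BurdenFit(
        beta0=float(full.params[0]),
        beta1=float(full.params[1]),
        beta2=float(full.params[2]),
        loglik_full=float(full.llf),
        loglik_reduced=float(red.llf),
        converged=converged,
        separated=separated,
        note="" if converged and not separated else "non-convergence or separation",
    )


def lrt_pvalue(loglik_full: float, loglik_reduced: float) -> tuple[float, float]:
    """Likelihood-ratio statistic (clamped at 0) and chi-square(1) p-value."""
    stat = 2.0 * (loglik_full - loglik_reduced)
    if stat < -1e-6:
        raise ValueError(
            f"full-model log-likelihood below reduced ({loglik_full} < {loglik_reduced})"
        )
    stat = max(stat, 0.0)
    return stat, float(sps.chi2.sf(stat, df=1))


def run_at(
    callset: Callset,
    annotations: Mapping[VariantKey, VariantAnnotation],
    expression: ExpressionTable,
    cohort: TrioCohort,
    controls: Sequence[str],
    pc1: np.ndarray,
    level: str = "gene",
    consequence_class: ConsequenceClass | str = ConsequenceClass.missense,
    panels: Sequence[GenePanel] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> list[BurdenResult]:
    """Burden association per unit x class, gated at >= 5 alt alleles.

    ``controls`` is the post-exclusion control list; cases are the cohort
    probands. ``pc1`` must align with cases followed by controls.
    """
    cclass = ConsequenceClass(consequence_class)
    cases = cohort.probands
    samples = list(cases) + list(controls)
    if len(pc1) != len(samples):
        raise ValueError("pc1 must align with cases + controls")
    status = np.array([1.0] * len(cases) + [0.0] * len(controls))
    selected = [
        sv
        for sv in select_at_variants(callset, annotations, expression, samples, thresholds)
        if sv.consequence_class is cclass
    ]
    if level == "gene":
        unit_map: dict[str, list[SelectedVariant]] = {}
        for sv in selected:
            unit_map.setdefault(sv.gene, []).append(sv)
    elif level == "panel":
        if panels is None:
            raise ValueError("panel-level AT requires panels")
        unit_map = {}
        for p in panels:
            members = [sv for sv in selected if sv.gene in p]
            if members:
                unit_map[p.name] = members
    else:
        raise ValueError(f"unknown level {level!r}")

    idx = [callset.sample_index(s) for s in samples]
    results: list[BurdenResult] = []
    for unit in sorted(unit_map):
        svs = unit_map[unit]
        G = np.column_stack(
            [callset.get(sv.key).genotypes[idx].astype(float) for sv in svs]
        )
        G[G < 0] = np.nan
        allele_count = int(np.nansum(G))
        if allele_count < thresholds.gate:
            results.append(
                BurdenResult(unit, cclass, len(svs), allele_count, None, None, None, None, False, "below gate")
            )
            continue
        vf = variant_fraction(G, [sv.cadd for sv in svs])
        if np.ptp(vf) == 0:
            results.append(
                BurdenResult(unit, cclass, len(svs), allele_count, None, None, None, None, False, "constant VF")
            )
            continue
        fit = fit_burden_model(status, vf, pc1)
        if fit.separated or not fit.converged:
            results.append(
                BurdenResult(unit, cclass, len(svs), allele_count, None, None, None, None, False, fit.note)
            )
            continue
        stat, p = lrt_pvalue(fit.loglik_full, fit.loglik_reduced)
        results.append(
            BurdenResult(unit, cclass, len(svs), allele_count, fit.beta1, stat, p, None, True)
        )
    tested = [r for r in results if r.tested]
    if tested:
        qs = bh_adjust([r.p for r in tested])
        for r, q in zip(tested, qs):
            r.q = float(q)
    else:
        logger.warning("AT (%s, %s): no testable units", level, cclass.value)
    return results
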