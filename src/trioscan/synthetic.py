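"""Synthetic trio + control cohort generator with a known truth table.

Simulation starts at the genotype/annotation level (no reads). Founders
(parents and controls) receive rare variants at a configurable carrier
frequency and common variants under a two-block Balding-Nichols model;
children are formed by Mendelian transmission, with a per-gene transmission
probability tau (0.5 unless the gene is listed as distorted). De novo and
mosaic events are injected on top with ground truth recorded, and a
configurable fraction of calls is given sub-threshold QUAL/GQ so the
quality cascade is exercised on both sides.

The same seed yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Callset,
    ConfigurationError,
    SiteCall,
    Thresholds,
    Trio,
    TrioCohort,
    write_callset,
    write_pedigree,
)
from .panels import DEFAULT_EMBRYONIC_STAGES, GenePanel

__all__ = ["SimConfig", "TruthTable", "SimResult", "simulate_cohort", "write_fixture_bundle"]

_LOF_CHOICES = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``distortion_genes`` maps gene name -> transmission probability tau;
    ``burden_genes`` maps gene name -> case-enrichment effect on the
    carrier-frequency scale (case parents carry at rate
    carrier_freq * (1 + beta1)).
    """

    n_trios: int = 30
    n_controls: int = 100
    n_genes: int = 40
    variants_per_gene: float = 3.0
    rare_af_min: float = 1e-6
    rare_af_max: float = 1e-3
    rare_af_alpha: float = 1.5  # power-law exponent of the AF sampler
    denovo_rate: float = 1.0
    mosaic_rate: float = 0.0
    mosaic_vaf_min: float = 0.02
    mosaic_vaf_max: float = 0.48
    distortion_genes: dict[str, float] = field(default_factory=dict)
    burden_genes: dict[str, float] = field(default_factory=dict)
    n_subpops: int = 2
    subpop_fst: float = 0.05
    related_pairs: int = 0
    quality_noise: float = 0.0
    n_common_variants: int = 200
    carrier_freq: float = 0.015
    coverage: int = 60
    unexpressed_fraction: float = 0.3
    panels: dict[str, int] | None = None
    defect_labels: dict[str, int] | None = None
    seed: int = 0

    def validate(self, gene_universe: list[str]) -> None:
        for name, count in (
            ("n_trios", self.n_trios),
            ("n_controls", self.n_controls),
            ("n_genes", self.n_genes),
            ("related_pairs", self.related_pairs),
            ("n_common_variants", self.n_common_variants),
        ):
            if count < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        universe = set(gene_universe)
        for gene, tau in self.distortion_genes.items():
            if gene not in universe:
                raise ConfigurationError(f"distortion gene {gene!r} not in gene universe")
            if not 0.0 < tau <= 1.0:
                # tau=1.0 allowed: full-transmission edge case used in tests
                raise ConfigurationError(f"tau must be in (0,1], got {tau} for {gene}")
        for gene, beta in self.burden_genes.items():
            if gene not in universe:
                raise ConfigurationError(f"burden gene {gene!r} not in gene universe")
            if beta < 0:
                raise ConfigurationError(f"burden effect must be >= 0, got {beta}")
        if not 0.0 <= self.quality_noise <= 1.0:
            raise ConfigurationError("quality_noise must be in [0,1]")
        if self.related_pairs * 2 > self.n_controls:
            raise ConfigurationError("too many related pairs for the control count")
        if not self.rare_af_min <= self.rare_af_max <= 0.001:
            raise ConfigurationError("rare AFs must lie in [0, 0.001]")


def gene_names(n_genes: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n_genes + 1)]


class TruthTable:
    """Record of every injected variant, plus the injected related pairs."""

    def __init__(self, rows: list[dict]):
        self.df = pd.DataFrame(rows)

    def of_kind(self, kind: str) -> pd.DataFrame:
        if self.df.empty:
            return self.df
        return self.df[self.df["kind"] == kind]

    @property
    def related_pairs(self) -> list[tuple[str, str]]:
        rows = self.of_kind("related_pair")
        if rows.empty:
            return []
        return [tuple(c.split("|")) for c in rows["carrier"]]


@dataclass
class SimResult:
    config: SimConfig
    callset: Callset
    annotations: pd.DataFrame
    constraint: pd.DataFrame
    expression: pd.DataFrame
    panels: list[GenePanel]
    cohort: TrioCohort
    mosaic_candidates: pd.DataFrame
    truth: TruthTable


def _power_law_af(rng, cfg: SimConfig, size: int) -> np.ndarray:
    """Truncated power-law sampler on [rare_af_min, rare_af_max]."""
    a = cfg.rare_af_alpha
    u = rng.random(size)
    lo, hi = cfg.rare_af_min, cfg.rare_af_max
    if abs(a - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    e = 1.0 - a
    return (lo**e + u * (hi**e - lo**e)) ** (1.0 / e)


def _transmit(rng, g_parent: int, tau: float) -> int:
    """One allele from a parent; het parents transmit alt w.p. tau."""
    if g_parent == 0:
        return 0
    if g_parent == 2:
        return 1
    return int(rng.random() < tau)


def _snv_alleles(rng) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _indel_alleles(rng) -> tuple[str, str]:
    base = _BASES[rng.integers(4)]
    ins = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
    if rng.random() < 0.5:
        return base, base + ins  # insertion
    return base + ins, base  # deletion


def simulate_cohort(config: SimConfig) -> SimResult:
    rng = np.random.default_rng(config.seed)
    cfg = config
    genes = gene_names(cfg.n_genes)
    cfg.validate(genes)

    probands = [f"P{i:04d}" for i in range(1, cfg.n_trios + 1)]
    fathers = [f"F{i:04d}" for i in range(1, cfg.n_trios + 1)]
    mothers = [f"M{i:04d}" for i in range(1, cfg.n_trios + 1)]
    controls = [f"C{i:04d}" for i in range(1, cfg.n_controls + 1)]
    samples: list[str] = []
    for p, f, m in zip(probands, fathers, mothers):
        samples.extend((p, f, m))
    samples.extend(controls)
    n = len(samples)
    s_idx = {s: i for i, s in enumerate(samples)}

    n_subpops = max(cfg.n_subpops, 1)
    subpop = np.zeros(n, dtype=int)
    for i in range(cfg.n_trios):
        sp = i % n_subpops
        for s in (probands[i], fathers[i], mothers[i]):
            subpop[s_idx[s]] = sp
    for j, c in enumerate(controls):
        subpop[s_idx[c]] = j % n_subpops

    # --- gene coordinates -------------------------------------------------
    gene_chrom = {}
    gene_base = {}
    for i, g in enumerate(genes):
        gene_chrom[g] = str((i % 22) + 1)
        gene_base[g] = 1_000_000 + (i // 22) * 100_000
    used_offsets: dict[str, set[int]] = {g: set() for g in genes}

    def new_position(gene: str) -> int:
        # even spacing prevents accidental MNV adjacency
        while True:
            off = int(rng.integers(0, 20_000)) * 2
            if off not in used_offsets[gene]:
                used_offsets[gene].add(off)
                return gene_base[gene] + off

    variants: list[dict] = []  # parallel to genotype columns
    geno_cols: list[np.ndarray] = []
    truth_rows: list[dict] = []

    def pass_qual(is_snv: bool) -> float:
        return float(rng.uniform(400, 3000)) if is_snv else float(rng.uniform(1500, 6000))

    def fail_qual(is_snv: bool) -> float:
        return float(rng.uniform(20, 300)) if is_snv else float(rng.uniform(100, 1000))

    # --- rare (founder) variants -----------------------------------------
    for g in genes:
        tau = cfg.distortion_genes.get(g, 0.5)
        beta = cfg.burden_genes.get(g, 0.0)
        n_var = max(1, int(rng.poisson(cfg.variants_per_gene)))
        afs = _power_law_af(rng, cfg, n_var)
        for v in range(n_var):
            conseq = str(
                rng.choice(
                    ["missense_variant", "synonymous_variant", "LOF", "inframe", "intron_variant"],
                    p=[0.45, 0.15, 0.20, 0.05, 0.15],
                )
            )
            if conseq == "LOF":
                conseq = str(rng.choice(_LOF_CHOICES))
            if conseq in ("frameshift_variant", "inframe"):
                ref, alt = _indel_alleles(rng)
                if conseq == "inframe":
                    conseq = str(rng.choice(["inframe_insertion", "inframe_deletion"]))
                    vclass = "inframe_indel"
                else:
                    vclass = "indel"
            else:
                ref, alt = _snv_alleles(rng)
                vclass = "SNV"
            pos = new_position(g)
            cadd = (
                float(rng.uniform(10, 40))
                if conseq == "missense_variant" or conseq in _LOF_CHOICES
                else float(rng.uniform(0, 20))
            )
            q_case = cfg.carrier_freq * (1.0 + beta)
            q_ctrl = cfg.carrier_freq
            col = np.zeros(n, dtype=np.int8)
            for i in range(cfg.n_trios):
                for parent in (fathers[i], mothers[i]):
                    r = rng.random()
                    if r < q_case:
                        col[s_idx[parent]] = 1
                    elif r < q_case + (q_case / 2) ** 2:
                        col[s_idx[parent]] = 2
            for c in controls:
                r = rng.random()
                if r < q_ctrl:
                    col[s_idx[c]] = 1
                elif r < q_ctrl + (q_ctrl / 2) ** 2:
                    col[s_idx[c]] = 2
            for i in range(cfg.n_trios):
                gf = col[s_idx[fathers[i]]]
                gm = col[s_idx[mothers[i]]]
                col[s_idx[probands[i]]] = _transmit(rng, gf, tau) + _transmit(rng, gm, tau)
            qual_fails = rng.random() < cfg.quality_noise
            is_snv = len(ref) == 1 and len(alt) == 1
            qual = fail_qual(is_snv) if qual_fails else pass_qual(is_snv)
            variants.append(
                dict(
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g,
                    consequence=conseq,
                    variant_class=vclass,
                    gnomad_af=float(afs[v]),
                    cadd=cadd,
                    qual=qual,
                )
            )
            geno_cols.append(col)
            kind = (
                "distorted"
                if g in cfg.distortion_genes
                else "burden"
                if g in cfg.burden_genes
                else "inherited"
            )
            truth_rows.append(
                dict(
                    kind=kind,
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g,
                    carrier="",
                    vaf=np.nan,
                    tau=tau,
                    beta1=beta,
                    qual_pass=not qual_fails,
                    note="",
                )
            )

    # --- de novo injections ----------------------------------------------
    gq_override: dict[tuple[int, int], int] = {}  # (variant idx, sample idx) -> GQ
    for i in range(cfg.n_trios):
        for _ in range(int(rng.poisson(cfg.denovo_rate))):
            g = genes[int(rng.integers(cfg.n_genes))]
            is_snv = rng.random() < 0.8
            ref, alt = _snv_alleles(rng) if is_snv else _indel_alleles(rng)
            is_snv = len(ref) == 1 and len(alt) == 1
            conseq = str(
                rng.choice(["missense_variant", "synonymous_variant", "LOF"], p=[0.55, 0.15, 0.30])
            )
            if conseq == "LOF":
                # frameshift only makes sense for indels
                snv_lof = ("stop_gained", "stop_lost", "start_lost")
                conseq = str(rng.choice(snv_lof)) if is_snv else "frameshift_variant"
            pos = new_position(g)
            col = np.zeros(n, dtype=np.int8)
            col[s_idx[probands[i]]] = 1
            corruption = ""
            if cfg.quality_noise > 0 and rng.random() < cfg.quality_noise:
                corruption = str(rng.choice(["low_qual", "low_gq", "recurrent"]))
            qual = pass_qual(is_snv)
            vidx = len(variants)
            if corruption == "low_qual":
                qual = fail_qual(is_snv)
            elif corruption == "low_gq":
                parent = fathers[i] if rng.random() < 0.5 else mothers[i]
                gq_override[(vidx, s_idx[parent])] = int(rng.integers(0, 30))
            elif corruption == "recurrent":
                others = [p for p in probands if p != probands[i]]
                extra = rng.choice(len(others), size=min(3, len(others)), replace=False)
                for e in extra:
                    col[s_idx[others[int(e)]]] = 1
            variants.append(
                dict(
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g,
                    consequence=conseq,
                    variant_class="SNV" if is_snv else "indel",
                    gnomad_af=float(_power_law_af(rng, cfg, 1)[0]),
                    cadd=float(rng.uniform(10, 40)),
                    qual=qual,
                )
            )
            geno_cols.append(col)
            truth_rows.append(
                dict(
                    kind="denovo",
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g,
                    carrier=probands[i],
                    vaf=np.nan,
                    tau=np.nan,
                    beta1=np.nan,
                    qual_pass=corruption == "",
                    note=corruption,
                )
            )

    # --- mosaic injections ------------------------------------------------
    mosaic_rows: list[dict] = []
    th = Thresholds()
    for i in range(cfg.n_trios):
        for _ in range(int(rng.poisson(cfg.mosaic_rate))):
            g = genes[int(rng.integers(cfg.n_genes))]
            ref, alt = _snv_alleles(rng)
            pos = new_position(g)
            conseq = str(
                rng.choice(
                    ["missense_variant", "stop_gained", "synonymous_variant"], p=[0.6, 0.2, 0.2]
                )
            )
            posterior = float(rng.uniform(0.85, 1.0))
            vaf = float(rng.uniform(cfg.mosaic_vaf_min, cfg.mosaic_vaf_max))
            f_alt = int(rng.choice([0, 1, 2, 3, 4], p=[0.55, 0.15, 0.10, 0.12, 0.08]))
            m_alt = int(rng.choice([0, 1, 2, 3, 4], p=[0.55, 0.15, 0.10, 0.12, 0.08]))
            in_vcf = rng.random() < 0.7
            col = np.zeros(n, dtype=np.int8)
            n_extra = 0
            if in_vcf:
                col[s_idx[probands[i]]] = 1
                if rng.random() < 0.15:
                    others = [p for p in probands if p != probands[i]]
                    extra = rng.choice(len(others), size=min(3, len(others)), replace=False)
                    n_extra = len(extra)
                    for e in extra:
                        col[s_idx[others[int(e)]]] = 1
            recurrence = (1 + n_extra) if in_vcf else 0
            variants.append(
                dict(
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g,
                    consequence=conseq,
                    variant_class="SNV",
                    gnomad_af=float(_power_law_af(rng, cfg, 1)[0]),
                    cadd=float(rng.uniform(10, 40)),
                    qual=pass_qual(True),
                    mosaic_vaf=vaf,
                )
            )
            geno_cols.append(col)
            mosaic_rows.append(
                dict(
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    proband=probands[i],
                    posterior=posterior,
                    vaf=vaf,
                    father_alt_reads=f_alt,
                    mother_alt_reads=m_alt,
                )
            )
            expected = dict(
                posterior=posterior >= th.posterior,
                vaf=th.vaf_low <= vaf <= th.vaf_high,
                parental_background=f_alt <= th.parental_alt_reads
                and m_alt <= th.parental_alt_reads,
                recurrence=recurrence <= th.recurrence,
                consequence=conseq in ("missense_variant", "stop_gained"),
            )
            truth_rows.append(
                dict(
                    kind="mosaic",
                    chrom=gene_chrom[g],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g,
                    carrier=probands[i],
                    vaf=vaf,
                    tau=np.nan,
                    beta1=np.nan,
                    qual_pass=True,
                    note="pass" if all(expected.values()) else "fail:"
                    + ",".join(k for k, v in expected.items() if not v),
                )
            )

    # --- common variants (Balding-Nichols two-block structure) ------------
    fst = max(cfg.subpop_fst, 1e-6)
    for m in range(cfg.n_common_variants):
        p_anc = float(rng.uniform(0.1, 0.9))
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_sub = rng.beta(a, b, size=n_subpops)
        col = np.zeros(n, dtype=np.int8)
        for i in range(cfg.n_trios):
            for parent in (fathers[i], mothers[i]):
                col[s_idx[parent]] = rng.binomial(2, p_sub[subpop[s_idx[parent]]])
        for c in controls:
            col[s_idx[c]] = rng.binomial(2, p_sub[subpop[s_idx[c]]])
        for i in range(cfg.n_trios):
            gf = col[s_idx[fathers[i]]]
            gm = col[s_idx[mothers[i]]]
            col[s_idx[probands[i]]] = _transmit(rng, gf, 0.5) + _transmit(rng, gm, 0.5)
        variants.append(
            dict(
                chrom="22",
                pos=10_000_000 + m * 100,
                ref="A",
                alt="G",
                gene=".",
                consequence="intergenic_variant",
                variant_class="SNV",
                gnomad_af=round(p_anc, 4),
                cadd=float(rng.uniform(0, 10)),
                qual=pass_qual(True),
            )
        )
        geno_cols.append(col)

    G = np.column_stack(geno_cols) if geno_cols else np.zeros((n, 0), dtype=np.int8)

    # --- injected related control pairs (near-duplicates) -----------------
    ctrl_pool = list(controls)
    for k in range(cfg.related_pairs):
        c1, c2 = ctrl_pool[2 * k], ctrl_pool[2 * k + 1]
        i1, i2 = s_idx[c1], s_idx[c2]
        # mild excess homozygosity (as in a real duplicated/inbred sample)
        # lifts the pair's self-relationship above the cohort minimum so the
        # strict off-diagonal rule can catch the pair deterministically
        hets = np.nonzero(G[i1, :] == 1)[0]
        to_hom = hets[rng.random(hets.size) < 0.3]
        G[i1, to_hom] = 2 * rng.integers(0, 2, size=to_hom.size).astype(np.int8)
        G[i2, :] = G[i1, :]
        flip = rng.random(G.shape[1]) < 0.005
        G[i2, flip] = rng.integers(0, 3, size=int(flip.sum()))
        truth_rows.append(
            dict(
                kind="related_pair",
                chrom="",
                pos=0,
                ref="",
                alt="",
                gene="",
                carrier=f"{c1}|{c2}",
                vaf=np.nan,
                tau=np.nan,
                beta1=np.nan,
                qual_pass=True,
                note="",
            )
        )

    # --- assemble SiteCall records ---------------------------------------
    order = sorted(
        range(len(variants)),
        key=lambda j: (int(variants[j]["chrom"]), variants[j]["pos"], variants[j]["alt"]),
    )
    records = []
    for j in order:
        v = variants[j]
        col = G[:, j]
        gq = rng.integers(30, 100, size=n).astype(float)
        for (vidx, sidx), val in gq_override.items():
            if vidx == j:
                gq[sidx] = val
        depth = np.maximum(rng.poisson(cfg.coverage, size=n), 8)
        ad_alt = np.zeros(n, dtype=np.int64)
        het = col == 1
        ad_alt[het] = np.clip(
            rng.binomial(depth[het], 0.5), 1, np.maximum(depth[het] - 1, 1)
        )
        ad_alt[col == 2] = depth[col == 2]
        if "mosaic_vaf" in v:
            carrier_idx = int(np.nonzero(col == 1)[0][0]) if het.any() else None
            if carrier_idx is not None:
                ad_alt[carrier_idx] = max(
                    int(rng.binomial(depth[carrier_idx], v["mosaic_vaf"])), 1
                )
        ad_ref = depth - ad_alt
        records.append(
            SiteCall(
                chrom=v["chrom"],
                pos=v["pos"],
                ref=v["ref"],
                alt=v["alt"],
                qual=round(v["qual"], 2),
                genotypes=col,
                gq=gq,
                ad_ref=ad_ref,
                ad_alt=ad_alt,
            )
        )
    callset = Callset(samples, records)

    ann_df = pd.DataFrame(
        [
            dict(
                chrom=v["chrom"],
                pos=v["pos"],
                ref=v["ref"],
                alt=v["alt"],
                gene=v["gene"],
                consequence=v["consequence"],
                variant_class=v["variant_class"],
                gnomad_af=v["gnomad_af"],
                cadd=round(v["cadd"], 2),
            )
            for v in (variants[j] for j in order)
        ]
    )

    constraint_df = pd.DataFrame(
        dict(
            gene=genes,
            lof_oe_upper=np.round(rng.uniform(0.1, 2.0, size=cfg.n_genes), 3),
            mis_oe_upper=np.round(rng.uniform(0.1, 2.0, size=cfg.n_genes), 3),
        )
    )

    # --- expression table -------------------------------------------------
    stages = list(DEFAULT_EMBRYONIC_STAGES) + ["newborn", "adult"]
    must_express = set(cfg.distortion_genes) | set(cfg.burden_genes)
    expr_rows = []
    for g in genes:
        unexpressed = (rng.random() < cfg.unexpressed_fraction) and g not in must_express
        if unexpressed:
            emb = rng.uniform(0.0, 1.9, size=len(DEFAULT_EMBRYONIC_STAGES))
        else:
            emb = np.exp(rng.normal(0.5, 1.0, size=len(DEFAULT_EMBRYONIC_STAGES)))
            peak = int(rng.integers(len(emb)))
            emb[peak] = 2.0 + float(np.exp(rng.normal(1.0, 1.0)))
        post = np.exp(rng.normal(0.5, 1.5, size=2))
        row = dict(gene=g)
        for s, t in zip(stages, np.concatenate([emb, post])):
            row[s] = round(float(t), 3)
        expr_rows.append(row)
    expression_df = pd.DataFrame(expr_rows)

    # --- panels -----------------------------------------------------------
    panel_spec = cfg.panels or {
        "CHD": 15,
        "transcription_factors": 12,
        "GO_cilium": 10,
        "GO_sarcomere": 10,
    }
    panels = []
    special = sorted(must_express)
    for pi, (name, size) in enumerate(panel_spec.items()):
        size = min(size, cfg.n_genes)
        members = set(
            np.array(genes)[rng.choice(cfg.n_genes, size=size, replace=False)]
        )
        if pi == 0:
            members |= set(special)
        panels.append(GenePanel(name=name, genes=frozenset(str(m) for m in members)))

    # --- pedigree / defect labels ----------------------------------------
    defects: dict[str, str] = {}
    if cfg.defect_labels:
        if sum(cfg.defect_labels.values()) > cfg.n_trios:
            raise ConfigurationError("defect label counts exceed n_trios")
        pool = list(rng.permutation(probands))
        for label, count in cfg.defect_labels.items():
            for _ in range(count):
                defects[pool.pop()] = label
        for p in pool:
            defects[p] = "other"
    else:
        defects = {p: "unspecified" for p in probands}
    cohort = TrioCohort(
        trios=[Trio(p, f, m) for p, f, m in zip(probands, fathers, mothers)],
        cases=set(probands),
        controls=set(controls),
        defects=defects,
    )

    mosaic_df = pd.DataFrame(
        mosaic_rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "proband",
            "posterior",
            "vaf",
            "father_alt_reads",
            "mother_alt_reads",
        ],
    )
    truth = TruthTable(truth_rows)
    return SimResult(
        config=cfg,
        callset=callset,
        annotations=ann_df,
        constraint=constraint_df,
        expression=expression_df,
        panels=panels,
        cohort=cohort,
        mosaic_candidates=mosaic_df,
        truth=truth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(sim: SimResult, directory: str | Path) -> dict[str, str]:
    """Write all simulated files; returns {relative path: sha256} manifest."""
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {directory.parent}")
    directory.mkdir(exist_ok=True)
    (directory / "panels").mkdir(exist_ok=True)

    write_callset(sim.callset, directory / "callset.vcf")
    sim.annotations.to_csv(
        directory / "annotations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    sim.constraint.to_csv(
        directory / "constraint.tsv", sep="\t", index=False, float_format="%.6g"
    )
    sim.expression.to_csv(
        directory / "expression.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_pedigree(sim.cohort, directory / "pedigree.tsv")
    sim.mosaic_candidates.to_csv(
        directory / "mosaic_candidates.tsv", sep="\t", index=False, float_format="%.6g"
    )
    sim.truth.df.to_csv(
        directory / "truth.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for panel in sim.panels:
        (directory / "panels" / f"{panel.name}.txt").write_text(
            "\n".join(sorted(panel.genes)) + "\n"
        )

    manifest: dict[str, str] = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(directory))] = _sha256(path)
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
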