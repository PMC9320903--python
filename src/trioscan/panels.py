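"""Gene panels, developmental expression, and the shared relevance predicates.

The embryonic window defaults to the five stages 4wpc..8wpc; a gene is
"expressed" when it reaches >= 2 TPM at at least one stage in that window.
Genes absent from the expression table are *unknown* (``None``), which is
distinct from not expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    ConsequenceClass,
    GeneConstraint,
    Thresholds,
    VariantAnnotation,
)

__all__ = [
    "GenePanel",
    "ExpressionTable",
    "DEFAULT_EMBRYONIC_STAGES",
    "read_expression",
    "load_panels",
    "restrict_panel",
    "damaging_flags",
    "panel_memberships",
]

DEFAULT_EMBRYONIC_STAGES = ("4wpc", "5wpc", "6wpc", "7wpc", "8wpc")


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("panel name must be non-empty")
        if any(not g for g in self.genes):
            raise ValueError(f"panel {self.name}: empty gene symbol")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


class ExpressionTable:
    """Gene-by-stage TPM matrix with an ordered embryonic window."""

    def __init__(
        self,
        tpm: pd.DataFrame,
        embryonic_stages: Sequence[str] = DEFAULT_EMBRYONIC_STAGES,
        tpm_threshold: float = 2.0,
    ):
        missing = [s for s in embryonic_stages if s not in tpm.columns]
        if missing:
            raise ValueError(f"expression table lacks embryonic stages {missing}")
        if (tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be >= 0")
        self.tpm = tpm
        self.embryonic_stages = list(embryonic_stages)
        self.tpm_threshold = float(tpm_threshold)

    @property
    def genes(self) -> set[str]:
        return set(self.tpm.index)

    def is_embryonically_expressed(self, gene: str) -> bool | None:
        """True/False for genes in the table; None when the gene is unknown."""
        if gene not in self.tpm.index:
            return None
        row = self.tpm.loc[gene, self.embryonic_stages]
        return bool((row >= self.tpm_threshold).any())

    def expressed_genes(self) -> set[str]:
        emb = self.tpm[self.embryonic_stages]
        mask = (emb >= self.tpm_threshold).any(axis=1)
        return set(self.tpm.index[mask])


def read_expression(
    path: str | Path,
    embryonic_stages: Sequence[str] = DEFAULT_EMBRYONIC_STAGES,
    tpm_threshold: float = 2.0,
) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionTable(df, embryonic_stages, tpm_threshold)


def load_panels(directory: str | Path) -> list[GenePanel]:
    """Load one panel per ``*.txt`` file; the panel name is the file stem.

    Duplicate symbols within a file are deduplicated; an empty file yields
    an empty panel with a warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"panel directory not found: {directory}")
    panels = []
    for path in sorted(directory.glob("*.txt")):
        genes = frozenset(
            line.strip() for line in path.read_text().splitlines() if line.strip()
        )
        if not genes:
            warnings.warn(f"panel file {path} is empty", stacklevel=2)
        panels.append(GenePanel(name=path.stem, genes=genes))
    return panels


def restrict_panel(panel: GenePanel, expression: ExpressionTable) -> GenePanel:
    """Intersect a panel with the embryonically expressed genes.

    Genes with unknown expression are dropped. Idempotent.
    """
    return GenePanel(
        name=panel.name, genes=panel.genes & expression.expressed_genes()
    )


def panel_memberships(gene: str, panels: Sequence[GenePanel]) -> list[str]:
    return [p.name for p in panels if gene in p]


def damaging_flags(
    annotation: VariantAnnotation,
    constraint: Mapping[str, GeneConstraint],
    thresholds: Thresholds = Thresholds(),
) -> dict[str, bool | None]:
    """Per-criterion 'damaging' verdicts for a LOF or missense variant.

    LOF: constrained gene (LOF oe upper bound below the cutoff).
    missense: constrained gene (missense oe upper bound below the cutoff)
    or CADD at/above the cutoff. oe flags are None when the gene has no
    constraint record; the CADD criterion is still evaluated.
    """
    cclass = annotation.consequence_class
    con = constraint.get(annotation.gene)
    oe: bool | None
    cadd_flag: bool | None
    if cclass is ConsequenceClass.LOF:
        oe = None if con is None else bool(con.lof_oe_upper < thresholds.oe_upper)
        cadd_flag = None  # CADD criterion applies to missense only
        overall = oe
    elif cclass is ConsequenceClass.missense:
        oe = None if con is None else bool(con.mis_oe_upper < thresholds.oe_upper)
        cadd_flag = bool(annotation.cadd >= thresholds.cadd_damaging)
        overall = cadd_flag or bool(oe)
    else:
        oe = None
        cadd_flag = None
        overall = False
    return {"oe": oe, "cadd": cadd_flag, "damaging": overall}
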