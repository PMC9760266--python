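"""Combined miRNA + clinical diagnostic-index models.

A combination model refits a single OLS linear index on the union of one
miRNA panel's probe log2 levels and the clinical covariates — one
coefficient per probe and per clinical variable, jointly estimated (the
clinical coefficients are therefore re-fit, not frozen from the
clinical-only model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .clinical import DiagnosticIndexModel, DiagnosticIndexResults, LinearIndex
from .discriminant import DiscriminantCandidate
from .preprocess import ExpressionMatrix

__all__ = ["CombinedModel", "fit_combined", "evaluate_combined", "combined_design"]

#: clinical covariates entering the published combination models
DEFAULT_CLINICAL_VARS = ("Alb", "CRP", "ps", "LDH", "Hb", "Neut")


@dataclass
class CombinedModel:
    """A fitted combination index plus its provenance."""

    index_model: LinearIndex
    probes: tuple[str, ...]
    clinical_vars: tuple[str, ...]
    results: DiagnosticIndexResults | None = None

    def evaluate(self, design: pd.DataFrame):
        return self.index_model.evaluate(design)


def combined_design(cohort: pd.DataFrame, expr: ExpressionMatrix,
                    probes: Sequence[str]) -> pd.DataFrame:
    """Per-sample design: probe log2 levels joined to clinical covariates."""
    missing = [p for p in probes if p not in expr.values.index]
    if missing:
        raise KeyError(f"probes absent from expression matrix: {missing}")
    common = [s for s in expr.values.columns if s in cohort.index]
    if not common:
        raise ValueError("no samples shared between cohort and expression matrix")
    design = cohort.loc[common].copy()
    if "ps" in design:
        design["ps"] = design["ps"].astype(int)
    for p in probes:
        design[p] = expr.values.loc[p, common].to_numpy(dtype=float)
    return design


def fit_combined(cohort: pd.DataFrame, expr: ExpressionMatrix,
                 discriminant: DiscriminantCandidate | Sequence[str],
                 clinical_vars: Sequence[str] = DEFAULT_CLINICAL_VARS,
                 outcome: str = "early_deterioration") -> CombinedModel:
    """OLS of the 0/1 outcome on one panel's probes plus clinical variables.

    ``discriminant`` is a beam-search candidate or a bare probe-name list; an
    empty probe set reduces exactly to the clinical-only refit.
    """
    probes = tuple(discriminant.probes if isinstance(discriminant, DiscriminantCandidate)
                   else discriminant)
    design = combined_design(cohort, expr, probes)
    variables = list(probes) + list(clinical_vars)
    res = DiagnosticIndexModel(design, variables, outcome=outcome).fit()
    return CombinedModel(index_model=res.index_model, probes=probes,
                         clinical_vars=tuple(clinical_vars), results=res)


def evaluate_combined(model: CombinedModel, cohort: pd.DataFrame,
                      expr: ExpressionMatrix) -> pd.Series:
    """Per-sample combined diagnostic index."""
    design = combined_design(cohort, expr, model.probes)
    return model.index_model.evaluate(design)
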