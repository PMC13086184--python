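"""Factorial analysis of mixed data (FAMD), implemented from first principles.

FAMD jointly reduces quantitative and qualitative variables: quantitative
columns are centered and scaled to unit variance (population divisor n, the
convention of the reference FAMD implementations), each qualitative column is
expanded to its indicator matrix with category k scaled by 1/sqrt(p_k) and
centered, and the combined matrix is decomposed by SVD.  Quantitative columns
then contribute inertia 1 each and a qualitative column with K observed
levels contributes K - 1, so the total inertia is
``p_quant + (total categories - p_qual)``.

Here the analysis contrasts conventional point-in-time exposure metrics
(counts and presence of polypharmacy, hyperpolypharmacy and drug-drug
interactions at admission and discharge) with the cumulative metrics (CDE or
CDED): if the cumulative metrics load on their own dimensions they carry
information the point-in-time variables do not.  PIM variables never enter
the analysis — they exist only for the aged subgroup and would introduce
structural missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import DDI, HPP, PP, DeterminantMetrics
from .records_io import ValidationError

logger = logging.getLogger("cdexposure")

__all__ = [
    "MixedTable",
    "FAMDResult",
    "build_mixed_table",
    "famd_fit",
    "top_contributors",
    "eigen_frame",
    "contrib_frame",
]

_RANK_TOL = 1e-10


@dataclass
class MixedTable:
    """Patients × mixed variables, ready for FAMD.

    ``quantitative`` holds numeric columns, ``qualitative`` categorical ones
    (each with at least two observed levels).  Rows with missing values have
    already been dropped at construction.
    """

    quantitative: pd.DataFrame
    qualitative: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.quantitative) != len(self.qualitative):
            raise ValidationError("quantitative and qualitative blocks disagree on rows")
        if len(self.quantitative) < 2:
            raise ValidationError("FAMD needs at least 2 rows")
        if self.quantitative.shape[1] + self.qualitative.shape[1] == 0:
            raise ValidationError("FAMD needs at least one variable")

    @property
    def n_rows(self) -> int:
        return len(self.quantitative)

    @property
    def variables(self) -> list[str]:
        return list(self.quantitative.columns) + list(self.qualitative.columns)


@dataclass
class FAMDResult:
    """Fitted FAMD decomposition.

    ``eigenvalues`` are the retained components' inertias (non-increasing);
    ``explained_pct`` is each one as a share of the *total* inertia, so the
    shares over all components sum to 100.  ``variable_contributions_pct``
    and ``variable_cos2`` are variable × dimension tables; qualitative
    variables aggregate their categories.  ``expected_contribution_threshold_pct``
    = 100 / number of variables is the flag line for above-average
    contributors.
    """

    eigenvalues: np.ndarray
    total_inertia: float
    explained_pct: np.ndarray
    row_coordinates: pd.DataFrame
    column_coordinates: pd.DataFrame
    variable_contributions_pct: pd.DataFrame
    variable_cos2: pd.DataFrame
    variable_types: Mapping[str, str]
    expected_contribution_threshold_pct: float
    n_components: int


def build_mixed_table(
    metrics: Sequence[DeterminantMetrics],
    mode: str = "cde",
    quantitative: Sequence[str] | None = None,
    qualitative: Sequence[str] | None = None,
) -> MixedTable:
    """Assemble the FAMD input from per-patient determinant metrics.

    Default variable list (overridable through ``quantitative`` /
    ``qualitative``):

    * quantitative — distinct-drug counts at admission/discharge, DDI counts
      at admission/discharge, and the cumulative metric (``mode``: ``cde`` or
      ``cded``) for PP, HPP and DDI;
    * qualitative — presence (yes/no) of PP, HPP and DDI at admission and
      discharge.

    PIM metrics are never included.  Qualitative columns with a single
    observed level are dropped with a warning, as are zero-variance
    quantitative columns; rows with any missing value are dropped with a
    logged count.
    """
    if mode not in ("cde", "cded"):
        raise ValidationError(f"mode must be 'cde' or 'cded', got {mode!r}")
    per_patient: dict[str, dict[str, DeterminantMetrics]] = {}
    for m in metrics:
        per_patient.setdefault(m.patient_id, {})[m.determinant] = m

    quant_rows, qual_rows, index = [], [], []
    for pid, dets in per_patient.items():
        needed = [d for d in (PP, HPP, DDI) if d in dets and dets[d].applicable]
        if len(needed) < 3:
            continue
        pp, hpp, ddi = dets[PP], dets[HPP], dets[DDI]
        quant_rows.append(
            {
                "n_drugs_admission": pp.count_admission,
                "n_drugs_discharge": pp.count_discharge,
                "n_ddis_admission": ddi.count_admission,
                "n_ddis_discharge": ddi.count_discharge,
                f"{mode}_pp": getattr(pp, mode),
                f"{mode}_hpp": getattr(hpp, mode),
                f"{mode}_ddi": getattr(ddi, mode),
            }
        )
        qual_rows.append(
            {
                "pp_admission": "yes" if pp.present_admission else "no",
                "pp_discharge": "yes" if pp.present_discharge else "no",
                "hpp_admission": "yes" if hpp.present_admission else "no",
                "hpp_discharge": "yes" if hpp.present_discharge else "no",
                "ddi_admission": "yes" if ddi.present_admission else "no",
                "ddi_discharge": "yes" if ddi.present_discharge else "no",
            }
        )
        index.append(pid)

    quant = pd.DataFrame(quant_rows, index=index, dtype=float)
    qual = pd.DataFrame(qual_rows, index=index, dtype=str)
    if quantitative is not None:
        quant = quant[list(quantitative)]
    if qualitative is not None:
        qual = qual[list(qualitative)]

    n_before = len(quant)
    keep = quant.notna().all(axis=1)
    quant, qual = quant[keep], qual[keep]
    if len(quant) < n_before:
        logger.warning("FAMD: dropped %d row(s) with missing values", n_before - len(quant))

    for col in list(qual.columns):
        if qual[col].nunique() < 2:
            logger.warning("FAMD: dropping single-level qualitative column %r", col)
            qual = qual.drop(columns=col)
    for col in list(quant.columns):
        if float(quant[col].std(ddof=0)) == 0.0:
            logger.warning("FAMD: dropping zero-variance quantitative column %r", col)
            quant = quant.drop(columns=col)
    return MixedTable(quantitative=quant, qualitative=qual)


def _weighted_matrix(table: MixedTable) -> tuple[np.ndarray, list[str], list[str]]:
    """Standardized quantitative block and weighted centered indicator block.

    Returns the combined matrix, its column names, and the owning variable of
    each column.
    """
    blocks: list[np.ndarray] = []
    col_names: list[str] = []
    col_owner: list[str] = []
    X = table.quantitative.to_numpy(dtype=float)
    if X.shape[1]:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        blocks.append((X - mu) / sd)
        col_names += list(table.quantitative.columns)
        col_owner += list(table.quantitative.columns)
    for col in table.qualitative.columns:
        dummies = pd.get_dummies(table.qualitative[col], dtype=float)
        D = dummies.to_numpy()
        p = D.mean(axis=0)
        blocks.append((D - p) / np.sqrt(p))
        col_names += [f"{col}={lvl}" for lvl in dummies.columns]
        col_owner += [col] * dummies.shape[1]
    return np.hstack(blocks), col_names, col_owner


def famd_fit(table: MixedTable, n_components: int = 3) -> FAMDResult:
    """Fit the FAMD decomposition and derive variable diagnostics.

    Eigenvalues are the squared singular values of the weighted matrix
    divided by n.  A column's contribution to a dimension is its squared
    right-singular-vector entry (in percent; per dimension they sum to 100);
    a variable aggregates its categories.  cos² measures representation
    quality: squared correlation with the component for a quantitative
    variable, correlation ratio normalized by (levels - 1) for a qualitative
    one; either sums to 1 over the full decomposition.  Component signs are
    fixed so the column with the largest |loading| on each dimension loads
    positively.  If the matrix rank is below ``n_components`` the available
    components are returned with a warning.
    """
    n = table.n_rows
    Z, col_names, col_owner = _weighted_matrix(table)
    total_inertia = float((Z.var(axis=0, ddof=0)).sum())

    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eig_all = s**2
    rank = int((eig_all > _RANK_TOL * max(eig_all[0], 1.0)).sum())
    if n_components > rank:
        logger.warning(
            "FAMD: requested %d components but rank is %d; returning %d",
            n_components,
            rank,
            rank,
        )
    m = min(n_components, rank)
    U, s, V = U[:, :m], s[:m], Vt[:m].T

    # deterministic sign: largest-|loading| column positive on each dimension
    for j in range(m):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]

    eigenvalues = s**2
    dims = [f"dim{j + 1}" for j in range(m)]
    row_coords = pd.DataFrame(
        np.sqrt(n) * U * s, index=table.quantitative.index, columns=dims
    )
    col_coords = pd.DataFrame(V * s, index=col_names, columns=dims)

    ctr_cols = V**2 * 100.0
    owners = pd.Index(col_owner, name="variable")
    ctr_var = pd.DataFrame(ctr_cols, index=owners, columns=dims).groupby(level=0).sum()

    variables = table.variables
    types = {c: "quantitative" for c in table.quantitative.columns}
    types.update({c: "qualitative" for c in table.qualitative.columns})

    cos2 = pd.DataFrame(0.0, index=pd.Index(variables, name="variable"), columns=dims)
    inertia_cols = (V**2) * eigenvalues  # column inertia on each dimension
    per_var = pd.DataFrame(inertia_cols, index=owners, columns=dims).groupby(level=0).sum()
    for var in variables:
        if types[var] == "quantitative":
            cos2.loc[var] = per_var.loc[var]  # squared correlation
        else:
            k_levels = table.qualitative[var].nunique()
            cos2.loc[var] = per_var.loc[var] / (k_levels - 1)

    return FAMDResult(
        eigenvalues=eigenvalues,
        total_inertia=total_inertia,
        explained_pct=eigenvalues / total_inertia * 100.0,
        row_coordinates=row_coords,
        column_coordinates=col_coords,
        variable_contributions_pct=ctr_var.reindex(variables),
        variable_cos2=cos2,
        variable_types=types,
        expected_contribution_threshold_pct=100.0 / len(variables),
        n_components=m,
    )


def top_contributors(result: FAMDResult, dimension: int) -> pd.DataFrame:
    """Variables ranked by contribution to one dimension (1-based).

    ``above_threshold`` flags contributions exceeding the expected average
    100 / n_variables — the usual reference line on contribution bar plots.
    """
    if not 1 <= dimension <= result.n_components:
        raise ValidationError(
            f"dimension {dimension} out of range 1..{result.n_components}"
        )
    col = f"dim{dimension}"
    out = pd.DataFrame(
        {
            "variable": result.variable_contributions_pct.index,
            "contribution_pct": result.variable_contributions_pct[col].to_numpy(),
            "cos2": result.variable_cos2[col].to_numpy(),
        }
    )
    out["above_threshold"] = (
        out["contribution_pct"] > result.expected_contribution_threshold_pct
    )
    return out.sort_values("contribution_pct", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def eigen_frame(result: FAMDResult) -> pd.DataFrame:
    """Eigenvalue table: dimension, eigenvalue, explained and cumulative %."""
    return pd.DataFrame(
        {
            "dimension": np.arange(1, result.n_components + 1),
            "eigenvalue": result.eigenvalues,
            "explained_pct": result.explained_pct,
            "cumulative_pct": np.cumsum(result.explained_pct),
        }
    )


def contrib_frame(result: FAMDResult) -> pd.DataFrame:
    """Long contribution/cos² table: variable × dimension."""
    rows = []
    for j in range(1, result.n_components + 1):
        ranked = top_contributors(result, j)
        for rec in ranked.itertuples(index=False):
            rows.append(
                {
                    "variable": rec.variable,
                    "dimension": j,
                    "contribution_pct": rec.contribution_pct,
                    "cos2": rec.cos2,
                    "above_threshold": rec.above_threshold,
                }
            )
    return pd.DataFrame(rows)
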