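"""Cross-species stress-expression processing.

Microarray replicate matrices are quantile normalized and collapsed
(median); per-species stress log-fold-change (LFC) matrices are z-normalized
over all conditions jointly (pooled mean/sd, population denominator) so they
are comparable across species.  Conditions resembling PKA inhibition are
selected by Pearson correlation with the measured PKA-inhibition LFC vectors
of the two reference species, and the per-gene ``LFC_est`` statistic is the
mean normalized LFC over the selected conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def collapse_duplicates(matrix: pd.DataFrame, rule: str = "median") -> pd.DataFrame:
    """Collapse duplicate gene rows to one row per gene (cell-wise median).

    Missing cells are ignored per cell; the row order of first appearance is
    preserved.
    """
    if rule != "median":
        raise ValueError(f"unsupported collapse rule {rule!r}")
    collapsed = matrix.groupby(level=0, sort=False).median()
    return collapsed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (replicate) onto the common sorted-mean distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    each column's values are replaced by the reference value at their rank.
    Tied values receive the mean of the reference values at their tied ranks.
    A single column is returned unchanged.
    """
    if matrix.shape[1] <= 1:
        return matrix.copy()
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("quantile normalization requires complete rows")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: every member of a tie group gets the mean reference value
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class StressMatrix:
    """Genes x conditions LFC table for one species (missing allowed)."""

    data: pd.DataFrame
    species: str
    normalized: bool = False

    def z_normalize(self) -> "StressMatrix":
        return z_normalize_species(self)


def z_normalize_species(matrix: StressMatrix) -> StressMatrix:
    """Center and scale all conditions of a species jointly.

    The pooled mean and (population) standard deviation are computed over
    every non-missing cell of the matrix — not per column — so relative
    condition strengths are preserved.  Idempotent to numerical precision.
    """
    values = matrix.data.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise ValueError(
            f"species {matrix.species}: need >= 2 distinct values to normalize"
        )
    mu = finite.mean()
    sd = finite.std()  # population denominator: makes renormalization exact
    out = (matrix.data - mu) / sd
    return StressMatrix(out, matrix.species, normalized=True)


def pearson_pairwise(x: pd.Series, y: pd.Series) -> Tuple[float, int]:
    """Pearson r over indices where both series are non-missing."""
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        return np.nan, n
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return np.nan, n
    return float(np.corrcoef(a, b)[0, 1]), n


def select_pka_like(
    stress_by_species: Mapping[str, StressMatrix],
    pka_lfc: Mapping[str, pd.Series],
    ortholog_map: Optional[Mapping[str, Mapping[str, str]]] = None,
    r_min: Optional[Mapping[str, float]] = None,
    min_shared_genes: int = 10,
) -> Tuple[List[str], pd.DataFrame]:
    """Select stress conditions that resemble PKA inhibition in every reference species.

    A condition is selected when, for each species with a PKA-inhibition LFC
    vector, the Pearson correlation between the condition's stress LFC in
    that species and the PKA vector exceeds that species' threshold
    (defaults: 0.75 for the post-WGH reference, 0.65 otherwise).  Gene ids
    are mapped across species with ``ortholog_map[species]`` (species gene ->
    reference id) before correlating.  Conditions sharing fewer than
    ``min_shared_genes`` genes with a PKA vector are skipped with a warning.

    Returns the selected condition names and a per-(condition, species)
    correlation report.
    """
    species_list = list(pka_lfc)
    if r_min is None:
        r_min = {sp: (0.75 if i == 0 else 0.65) for i, sp in enumerate(species_list)}
    conditions: List[str] = []
    for sp in species_list:
        for c in stress_by_species[sp].data.columns:
            if c not in conditions:
                conditions.append(c)
    rows = []
    selected = []
    for cond in conditions:
        ok = True
        for sp in species_list:
            sm = stress_by_species[sp]
            if cond not in sm.data.columns:
                ok = False
                continue
            col = sm.data[cond]
            if ortholog_map and sp in ortholog_map:
                mapping = ortholog_map[sp]
                col = col.rename(index=mapping)
                col = col[~col.index.duplicated()]
            r, n = pearson_pairwise(col, pka_lfc[sp])
            rows.append({"condition": cond, "species": sp, "r": r, "n_shared": n})
            if n < min_shared_genes:
                warnings.warn(
                    f"condition {cond!r}: only {n} shared genes with {sp} PKA vector"
                )
                ok = False
            elif not (np.isfinite(r) and r > r_min[sp]):
                ok = False
        if ok:
            selected.append(cond)
    report = pd.DataFrame(rows, columns=["condition", "species", "r", "n_shared"])
    return selected, report


def compute_lfc_est(
    stress: StressMatrix,
    selected_conditions: Sequence[str],
    min_conditions: int = 1,
) -> pd.DataFrame:
    """Per-gene mean normalized LFC over the selected PKA-like conditions.

    Genes observed in fewer than ``min_conditions`` selected conditions get a
    missing value.  Returns columns ``lfc_est`` and ``n_conditions_used``.
    """
    if not selected_conditions:
        raise ValueError("need at least one selected condition")
    missing = [c for c in selected_conditions if c not in stress.data.columns]
    if missing:
        raise KeyError(f"conditions absent from matrix: {missing}")
    sub = stress.data[list(selected_conditions)]
    n_used = sub.notna().sum(axis=1)
    est = sub.mean(axis=1, skipna=True)
    est[n_used < min_conditions] = np.nan
    return pd.DataFrame({"lfc_est": est, "n_conditions_used": n_used})


def read_matrix(path) -> pd.DataFrame:
    """Genes-as-rows TSV matrix; empty cells become missing values."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")
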