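"""Cohort harmonization: covariate removal, gene centering, age binning.

The expression matrix is a genes x samples :class:`pandas.DataFrame` of log2
expression values.  Sample metadata is a DataFrame indexed by sample id with
columns ``diagnosis`` (CNTRL/SCZ/BD/MDD), ``age`` (years), ``sex`` (M/F),
``ph``, ``pmi`` (hours) and ``batch``.  After :func:`adjust_covariates` and
:func:`center_genes` the matrix holds signed log2 fold changes relative to
each gene's cohort mean — the universal currency of every downstream stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: The nine age bins tiling (0, 100] years, following developmental stages of
#: the prefrontal cortex.  Membership is left-exclusive / right-inclusive:
#: age a belongs to (lo, hi] iff lo < a <= hi.
AGE_GROUPS: list[tuple[float, float]] = [
    (0, 1),
    (1, 5),
    (5, 10),
    (10, 18),
    (18, 35),
    (35, 50),
    (50, 65),
    (65, 85),
    (85, 100),
]

AGE_GROUP_LABELS: list[str] = [f"({lo}-{hi}]" for lo, hi in AGE_GROUPS]

DIAGNOSES = ("CNTRL", "SCZ", "BD", "MDD")


def validate_metadata(meta: pd.DataFrame, X: pd.DataFrame | None = None) -> None:
    """Sanity-check a metadata table (one row per sample).

    Raises ``ValueError`` on structural problems; emits a warning (not an
    error) when disease samples are younger than 18 years, which does not
    occur in paper-like cohorts but is legal input.
    """
    required = {"diagnosis", "age"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids in metadata: {dups}")
    if X is not None:
        if set(X.columns) != set(meta.index):
            raise ValueError("metadata samples do not match matrix columns")
    bad = meta.loc[(meta["diagnosis"] != "CNTRL") & (meta["age"] < 18)]
    if len(bad):
        warnings.warn(
            f"{len(bad)} disease samples younger than 18 y "
            "(unexpected for a post-onset cohort)",
            stacklevel=2,
        )


def _effect_code(series: pd.Series, name: str) -> pd.DataFrame:
    """Effect (sum-to-zero) coding of a categorical covariate.

    Levels are sorted; one column per non-reference level, the last level
    acting as reference with value -1.  A single-level covariate contributes
    no columns (a no-op in the design).
    """
    levels = sorted(pd.unique(series.astype(str)))
    cols = {}
    for lev in levels[:-1]:
        col = np.where(series.astype(str) == lev, 1.0, 0.0)
        col[series.astype(str) == levels[-1]] = -1.0
        cols[f"{name}[{lev}]"] = col
    return pd.DataFrame(cols, index=series.index)


def build_nuisance_design(meta: pd.DataFrame, nuisance: list[str]) -> pd.DataFrame:
    """Design matrix (without intercept) for the nuisance covariates.

    Categorical covariates (non-numeric dtype) are effect-coded; continuous
    covariates are mean-centered.
    """
    parts: list[pd.DataFrame] = []
    for name in nuisance:
        if name not in meta.columns:
            raise ValueError(f"nuisance covariate {name!r} not in metadata")
        col = meta[name]
        if pd.api.types.is_numeric_dtype(col):
            centered = col.astype(float) - float(col.astype(float).mean())
            parts.append(centered.to_frame(name))
        else:
            parts.append(_effect_code(col, name))
    if not parts:
        return pd.DataFrame(index=meta.index)
    return pd.concat(parts, axis=1)


def adjust_covariates(
    X: pd.DataFrame, meta: pd.DataFrame, nuisance: list[str]
) -> pd.DataFrame:
    """Remove nuisance-covariate effects from every gene by OLS residualization.

    Per gene, expression is regressed on an intercept plus the nuisance
    design (batch, sex, pH, PMI, ...).  The returned value is observed minus
    the fitted nuisance component; the component is mean-centered before
    subtraction so each gene's grand mean is preserved exactly even for
    unbalanced designs.

    Raises ``ValueError`` naming the offending columns if the design is rank
    deficient (collinear covariates).
    """
    validate_metadata(meta, X)
    meta = meta.loc[X.columns]
    D_n = build_nuisance_design(meta, nuisance)
    if D_n.shape[1] == 0:
        return X.copy()
    ones = np.ones((len(meta), 1))
    D = np.hstack([ones, D_n.to_numpy(float)])
    colnames = ["intercept"] + list(D_n.columns)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify columns past the numerical rank via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(D, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(D.shape) * np.finfo(float).eps
        bad = [colnames[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(
            f"rank-deficient nuisance design (collinear columns: {bad})"
        )
    Y = X.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    fitted_nuis = D[:, 1:] @ beta[1:, :]  # exclude intercept
    fitted_nuis -= fitted_nuis.mean(axis=0, keepdims=True)
    adjusted = Y - fitted_nuis
    return pd.DataFrame(adjusted.T, index=X.index, columns=X.columns)


def center_genes(X: pd.DataFrame) -> pd.DataFrame:
    """Center each gene at its cohort mean.

    Returns value - mean(gene), i.e. signed log2 fold change relative to the
    gene's average expression across all samples.  Idempotent.
    """
    if X.size == 0:
        raise ValueError("cannot center an empty expression matrix")
    if not np.isfinite(X.to_numpy(float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return X.sub(X.mean(axis=1), axis=0)


def assign_age_groups(meta: pd.DataFrame | pd.Series) -> pd.Series:
    """Assign each sample to one of the nine (lo, hi] age bins.

    Accepts a metadata frame (uses its ``age`` column) or a Series of ages.
    Ages must lie in (0, 100]; anything outside raises ``ValueError``.
    """
    ages = meta["age"] if isinstance(meta, pd.DataFrame) else meta
    ages = ages.astype(float)
    bad = ages[(ages <= 0) | (ages > 100)]
    if len(bad):
        raise ValueError(
            f"ages outside (0, 100]: {bad.to_dict()}"
        )
    edges = [lo for lo, _ in AGE_GROUPS] + [AGE_GROUPS[-1][1]]
    labels = pd.cut(ages, bins=edges, right=True, labels=AGE_GROUP_LABELS)
    return labels.rename("age_group")
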