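"""Differential expression: per-gene DEG counts per disease x age group, and
spot-level disease vs control regression adjusted for age.

Gene-level testing is a plain two-sample linear model (equivalent to the
equal-variance t-test of expression ~ diagnosis) within one age group, with
Benjamini-Hochberg adjustment across genes; a gene is a DEG iff its logFC is
non-zero and its adjusted p < 0.05.  Spot-level testing regresses spot
expression on diagnosis plus continuous age over the union of the disease's
and the control samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chronosom.preprocess import assign_age_groups

#: smallest positive subnormal double; reported when a pooled variance of
#: exactly zero meets a non-zero mean difference (degenerate but legal input)
TINY_P = float(np.nextafter(0, 1))


def gene_deg(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    disease: str,
    age_group: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Disease vs control DEGs within one age group.

    Returns (records, (n_up, n_down)).  Records carry logFC (disease mean
    minus control mean, log2 units), raw p from the pooled-variance
    two-sample test, BH-adjusted p, direction, and the DEG flag
    (logFC != 0 and adjusted p < alpha).
    """
    labels = assign_age_groups(meta)
    in_group = labels.astype(str) == age_group
    dis_cols = meta.index[(meta["diagnosis"] == disease) & in_group]
    ctl_cols = meta.index[(meta["diagnosis"] == "CNTRL") & in_group]
    if len(dis_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError(
            f"need >=2 samples per arm in {age_group}: "
            f"{disease}={len(dis_cols)}, CNTRL={len(ctl_cols)}"
        )
    A = X[dis_cols].to_numpy(float)
    B = X[ctl_cols].to_numpy(float)
    logfc = A.mean(axis=1) - B.mean(axis=1)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    # zero-pooled-variance guard: identical constant arms give p=1 (no
    # effect), differing constant arms give the smallest representable p
    degenerate |= ~np.isfinite(p)
    p = np.where(degenerate & (logfc != 0), TINY_P, p)
    p = np.where(degenerate & (logfc == 0), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    records = pd.DataFrame(
        {
            "gene": X.index,
            "disease": disease,
            "age_group": age_group,
            "logFC": logfc,
            "p": p,
            "p_adjusted": padj,
            "direction": np.sign(logfc).astype(int),
            "degenerate_variance": degenerate,
        }
    )
    records["is_deg"] = (records["logFC"] != 0) & (records["p_adjusted"] < alpha)
    n_up = int(((records["is_deg"]) & (records["logFC"] > 0)).sum())
    n_down = int(((records["is_deg"]) & (records["logFC"] < 0)).sum())
    return records, (n_up, n_down)


def deg_counts_by_age(
    X: pd.DataFrame, meta: pd.DataFrame, diseases: list[str] | None = None,
    min_per_arm: int = 2,
) -> pd.DataFrame:
    """Up/down DEG counts per disease x age group (bar-chart bookkeeping)."""
    labels = assign_age_groups(meta).astype(str)
    diseases = diseases or [d for d in meta["diagnosis"].unique() if d != "CNTRL"]
    rows = []
    for disease in diseases:
        for group in labels.unique():
            in_g = labels == group
            n_d = int(((meta["diagnosis"] == disease) & in_g).sum())
            n_c = int(((meta["diagnosis"] == "CNTRL") & in_g).sum())
            if n_d < min_per_arm or n_c < min_per_arm:
                continue
            _, (up, down) = gene_deg(X, meta, disease, group)
            rows.append(
                {"disease": disease, "age_group": group, "up": up, "down": down}
            )
    return pd.DataFrame(rows, columns=["disease", "age_group", "up", "down"])


def spot_diff(
    spot_expr: pd.DataFrame, meta: pd.DataFrame, disease: str
) -> pd.DataFrame:
    """Per-spot disease effect from spot_expression ~ diagnosis + age.

    Uses the union of the disease's samples and all controls; reports the
    diagnosis coefficient (disease minus control, age-adjusted) and its
    two-sided p.  Fails explicitly if diagnosis and age are confounded
    (rank-deficient design).
    """
    keep = meta.index[(meta["diagnosis"] == disease) | (meta["diagnosis"] == "CNTRL")]
    keep = keep.intersection(spot_expr.columns)
    sub = meta.loc[keep]
    if (sub["diagnosis"] == disease).sum() == 0 or (sub["diagnosis"] == "CNTRL").sum() == 0:
        raise ValueError(f"both arms required for {disease} vs CNTRL")
    diag = (sub["diagnosis"] == disease).to_numpy(float)
    age = sub["age"].to_numpy(float)
    D = np.column_stack([np.ones(len(sub)), diag, age])
    if np.linalg.matrix_rank(D) < 3:
        raise ValueError(
            "confounded design: diagnosis and age are collinear (after "
            "centering), the diagnosis effect is not identifiable"
        )
    rows = []
    XtX_inv = np.linalg.inv(D.T @ D)
    dof = len(sub) - 3
    for spot_name, row in spot_expr[keep].iterrows():
        y = row.to_numpy(float)
        beta = XtX_inv @ (D.T @ y)
        resid = y - D @ beta
        rss = float(resid @ resid)
        sigma2 = rss / dof if dof > 0 else np.nan
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        if se == 0:
            p = 1.0 if beta[1] == 0 else TINY_P
        else:
            tval = beta[1] / se
            p = float(2 * stats.t.sf(abs(tval), dof))
        rows.append(
            {
                "spot": spot_name,
                "disease": disease,
                "coefficient": float(beta[1]),
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["spot", "disease", "coefficient", "p"])
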