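"""Functional and cell-type annotation of spots.

Three tools: per-sample Gene Set Z-scores (standardized mean shift of a
set's centered expression against all genes), one-tailed Fisher
overrepresentation of gene sets in spot gene lists (hypergeometric upper
tail), and correlation of cell-type signature Z-scores with spot expression
profiles (edges kept where Pearson r strictly exceeds the threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chronosom.spots import Spot


class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-serializable)."""

    def __init__(
        self,
        sets: dict[str, list[str]],
        descriptions: dict[str, str] | None = None,
    ):
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = dict(sets)
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class EnrichmentRecord:
    """One spot x gene-set 2x2 overrepresentation test."""

    spot: str
    set_name: str
    in_spot_in_set: int
    in_spot_not_set: int
    out_spot_in_set: int
    out_spot_not_set: int
    odds_ratio: float
    p: float
    p_adjusted: float = float("nan")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.in_spot_in_set, self.in_spot_not_set],
                [self.out_spot_in_set, self.out_spot_not_set],
            ]
        )


def geneset_zscore(X: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Per-sample Gene Set Z-score.

    Z_s = (mean over set genes of centered expression - mean over all genes)
    / (sd over all genes / sqrt(n_set)), with the sd taken across genes
    within the sample (ddof=1) and n_set counting set genes present in the
    matrix.
    """
    present = X.index.intersection(pd.Index(gene_set))
    if len(present) == 0:
        raise ValueError("gene set has no genes in the expression matrix")
    set_mean = X.loc[present].mean(axis=0)
    all_mean = X.mean(axis=0)
    all_sd = X.std(axis=0, ddof=1)
    z = (set_mean - all_mean) / (all_sd / np.sqrt(len(present)))
    return z.rename("geneset_z")


def fisher_overrepresentation(
    spot: Spot | list[str], gene_set: list[str], universe: list[str],
    set_name: str = "", spot_label: str | None = None,
) -> EnrichmentRecord:
    """One-tailed (enrichment) Fisher exact test of a set in a spot gene list.

    p is the hypergeometric upper tail P(X >= overlap) for the 2x2 table of
    spot membership against set membership within the universe; the odds
    ratio is the plain cross-product ratio without continuity correction.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    spot_genes = set(spot.genes if isinstance(spot, Spot) else spot) & uni
    set_genes = set(gene_set) & uni
    a = len(spot_genes & set_genes)
    b = len(spot_genes - set_genes)
    c = len(set_genes - spot_genes)
    d = len(uni) - a - b - c
    # upper tail of Hypergeometric(N=|U|, K=|set|, n=|spot|) at the overlap
    p = float(stats.hypergeom.sf(a - 1, len(uni), len(set_genes), len(spot_genes)))
    p = min(p, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    label = spot_label if spot_label is not None else (
        spot.label if isinstance(spot, Spot) else ""
    )
    return EnrichmentRecord(
        spot=label,
        set_name=set_name,
        in_spot_in_set=a,
        in_spot_not_set=b,
        out_spot_in_set=c,
        out_spot_not_set=d,
        odds_ratio=float(odds),
        p=p,
    )


def annotate_spots(
    spots: list[Spot], collection: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Fisher overrepresentation of every gene set in every spot.

    p-values are Benjamini-Hochberg adjusted across gene sets within each
    spot.  Returns a tidy records table sorted by spot then adjusted p.
    """
    records: list[EnrichmentRecord] = []
    for spot in spots:
        spot_records = [
            fisher_overrepresentation(spot, genes, universe, set_name=name)
            for name, genes in collection.items()
        ]
        if spot_records:
            _, padj, _, _ = multipletests(
                [r.p for r in spot_records], method="fdr_bh"
            )
            for r, q in zip(spot_records, padj):
                r.p_adjusted = float(q)
        records.extend(spot_records)
    out = pd.DataFrame(
        [
            {
                "spot": r.spot,
                "set": r.set_name,
                "overlap": r.in_spot_in_set,
                "spot_size": r.in_spot_in_set + r.in_spot_not_set,
                "set_size": r.in_spot_in_set + r.out_spot_in_set,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
            }
            for r in records
        ]
    )
    if len(out):
        out = out.sort_values(["spot", "p_adjusted", "p"]).reset_index(drop=True)
    return out


def correlate_celltypes(
    spot_expr: pd.DataFrame,
    signature_z: pd.DataFrame,
    r_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate spot expression with cell-type signature Z-scores.

    Both inputs are feature x sample tables sharing sample columns.  Returns
    the full spot x signature Pearson r matrix and the edge list of pairs
    with r strictly greater than the threshold.  Constant rows are skipped
    with a warning (their correlations are undefined).
    """
    common = spot_expr.columns.intersection(signature_z.columns)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    A = spot_expr[common]
    B = signature_z[common]
    r_matrix = pd.DataFrame(
        np.nan, index=A.index, columns=B.index, dtype=float
    )
    edges = []
    for spot_name, arow in A.iterrows():
        if np.ptp(arow.to_numpy(float)) == 0:
            warnings.warn(f"constant spot profile {spot_name!r} skipped", stacklevel=2)
            continue
        for sig_name, brow in B.iterrows():
            if np.ptp(brow.to_numpy(float)) == 0:
                warnings.warn(
                    f"constant signature {sig_name!r} skipped", stacklevel=2
                )
                continue
            r, _ = stats.pearsonr(arow.to_numpy(float), brow.to_numpy(float))
            r_matrix.loc[spot_name, sig_name] = r
            if r > r_threshold:
                edges.append({"spot": spot_name, "signature": sig_name, "r": float(r)})
    edge_df = pd.DataFrame(edges, columns=["spot", "signature", "r"])
    return r_matrix, edge_df
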