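"""eQTL enrichment of spot gene lists and the perturbed-and-enriched report.

Each spot x tissue pair gets a one-tailed Fisher exact test of the 2x2 table
(spot membership x eQTL flag) over the gene universe, Bonferroni-corrected
by the number of tissues tested per spot (adjusted p = min(1, p * n_tissues),
enriched iff adjusted p < 0.05).  The final report joins spots whose
likelihood ratio exceeds the soft cut-off (LR > 1) with their enriched
tissues into a perturbation-timeline table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from chronosom.perturbation_time import PerturbationResult
from chronosom.spots import Spot


def eqtl_enrichment(
    spots: list[Spot],
    table: pd.DataFrame,
    universe: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Fisher enrichment of eQTL-flagged genes per spot x tissue.

    ``table`` is a binary gene x tissue flag matrix.  The universe defaults
    to all genes of the table; spot genes outside the universe are ignored.
    """
    if table.shape[1] == 0:
        raise ValueError("eQTL table has no tissues")
    uni = pd.Index(universe) if universe is not None else table.index
    uni = uni.intersection(table.index)
    sub = table.loc[uni]
    n_tissues = sub.shape[1]
    n_universe = len(uni)
    rows = []
    for spot in spots:
        spot_genes = uni.intersection(pd.Index(spot.genes))
        if len(spot_genes) == 0:
            raise ValueError(f"spot {spot.label} has no genes in the universe")
        in_spot = uni.isin(spot_genes)
        for tissue in sub.columns:
            flags = sub[tissue].to_numpy() > 0
            a = int((flags & in_spot).sum())
            n_flagged = int(flags.sum())
            p = float(
                stats.hypergeom.sf(a - 1, n_universe, n_flagged, len(spot_genes))
            )
            p = min(p, 1.0)
            p_adj = min(1.0, p * n_tissues)
            rows.append(
                {
                    "spot": spot.label,
                    "tissue": tissue,
                    "overlap": a,
                    "spot_size": len(spot_genes),
                    "n_flagged": n_flagged,
                    "p": p,
                    "p_bonferroni": p_adj,
                    "enriched": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def select_perturbed_enriched(
    perturbation_results: list[PerturbationResult],
    enrichment_records: pd.DataFrame,
    lr_cutoff: float = 1.0,
    spot_diff_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Timeline report of time-perturbed spots and their enriched tissues.

    Keeps spot x disease results with LR > ``lr_cutoff``; attaches the MAP
    perturbation age, the direction of the age-adjusted disease effect when
    spot_diff records are supplied, and the comma-joined list of tissues
    whose Bonferroni-adjusted enrichment p is below 0.05.
    """
    enriched_by_spot: dict[str, list[str]] = {}
    if len(enrichment_records):
        for spot_label, grp in enrichment_records.groupby("spot"):
            enriched_by_spot[spot_label] = grp.loc[grp["enriched"], "tissue"].tolist()

    known_spots = set(enrichment_records["spot"]) if len(enrichment_records) else set()
    rows = []
    for res in perturbation_results:
        if not res.likelihood_ratio > lr_cutoff:  # strict; inf cutoff keeps none
            continue
        if known_spots and res.spot not in known_spots:
            raise KeyError(
                f"perturbation result for spot {res.spot!r} has no enrichment records"
            )
        direction = ""
        if spot_diff_records is not None and len(spot_diff_records):
            hit = spot_diff_records[
                (spot_diff_records["spot"] == res.spot)
                & (spot_diff_records["disease"] == res.disease)
            ]
            if len(hit):
                coef = float(hit["coefficient"].iloc[0])
                direction = "up" if coef > 0 else ("down" if coef < 0 else "flat")
        rows.append(
            {
                "spot": res.spot,
                "disease": res.disease,
                "map_tau": res.map_tau,
                "likelihood_ratio": res.likelihood_ratio,
                "direction": direction,
                "enriched_tissues": ",".join(enriched_by_spot.get(res.spot, [])),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "spot",
            "disease",
            "map_tau",
            "likelihood_ratio",
            "direction",
            "enriched_tissues",
        ],
    )
    if len(out):
        out = out.sort_values(["map_tau", "spot"]).reset_index(drop=True)
    return out
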