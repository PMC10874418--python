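"""Summary maps over all portraits and spot (gene-module) segmentation.

The variance summary map holds each metagene's expression variance across
all samples; the overexpression map holds the maximum of the group-mean
metagene expression over groups.  Spots are connected clusters of metagenes
whose summary-map value exceeds a quantile threshold; each spot carries its
member metagenes, the union of their assigned genes, and a per-sample
expression profile (mean of member metagene weights).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from chronosom.som_portrait import SOMModel


@dataclass
class SummaryMaps:
    """Per-metagene variance and max-group-mean overexpression maps (k x k)."""

    variance: np.ndarray
    overexpression: np.ndarray

    @property
    def k(self) -> int:
        return self.variance.shape[0]


@dataclass
class Spot:
    """A connected metagene cluster treated as a gene module."""

    label: str
    metagenes: list[int]  # flat row-major indices
    genes: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.metagenes)


def summary_maps(model: SOMModel, group_labels: pd.Series) -> SummaryMaps:
    """Build variance and overexpression summary maps from a trained model."""
    W = model.weights  # K x M
    if W.shape[1] < 2:
        raise ValueError("variance map needs at least 2 samples")
    labels = group_labels.loc[model.sample_ids]
    variance = W.var(axis=1, ddof=1).reshape(model.k, model.k)
    group_means = []
    for g in pd.unique(labels):
        cols = np.asarray(labels == g)
        group_means.append(W[:, cols].mean(axis=1))
    over = np.max(np.stack(group_means), axis=0).reshape(model.k, model.k)
    return SummaryMaps(variance=variance, overexpression=over)


def _spot_labels(n: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    labels = letters + [a + b for a in letters for b in letters]
    return labels[:n]


def _similarity_components(
    foreground: np.ndarray,
    weights: np.ndarray,
    adjacency: int,
    r_min: float,
) -> list[list[int]]:
    """Connected components of foreground cells, edges gated by profile similarity.

    Two grid-adjacent foreground metagenes are linked only if the Pearson
    correlation of their weight profiles exceeds ``r_min``; union-find over
    the gated edges.  Severs borders between adjacent but distinct modules,
    whose cross-correlation is far below the within-module level.
    """
    k = foreground.shape[0]
    idx = np.flatnonzero(foreground.ravel())
    members = set(idx.tolist())
    Wn = weights - weights.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Wn, axis=1, keepdims=True)
    Wn = Wn / np.where(norms > 0, norms, 1.0)
    if adjacency == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    parent = {c: c for c in idx}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for c in idx:
        i, j = divmod(c, k)
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            nc = ni * k + nj
            if 0 <= ni < k and 0 <= nj < k and nc in members and nc > c:
                if float(Wn[c] @ Wn[nc]) > r_min:
                    ra, rb = find(c), find(nc)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for c in idx:
        groups.setdefault(find(c), []).append(c)
    return [sorted(g) for g in groups.values()]


def segment_spots(
    summary_map: np.ndarray,
    quantile: float = 0.90,
    min_size: int = 3,
    adjacency: int = 8,
    model: SOMModel | None = None,
    similarity_threshold: float | None = None,
) -> list[Spot]:
    """Segment a k x k summary map into labelled spots.

    Metagenes strictly above the given quantile of all map values are
    foreground; connected components under the chosen adjacency (8 by
    default, 4 optional) smaller than ``min_size`` are dropped; survivors
    are labelled A, B, C, ... in decreasing size (ties broken by the smallest
    row-major member index).

    If ``model`` is given, each spot also receives the union of its member
    metagenes' assigned genes, and metagenes carrying no genes are treated
    as background (geneless cells are interpolation artifacts of the SOM and
    must not glue distinct gene modules together).  ``similarity_threshold``
    additionally gates connectivity by the Pearson correlation of adjacent
    metagene weight profiles (requires ``model``): adjacent cells belonging
    to distinct co-expression modules correlate only at the module-module
    level and are disconnected.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if adjacency not in (4, 8):
        raise ValueError("adjacency must be 4 or 8")
    if similarity_threshold is not None and model is None:
        raise ValueError("similarity_threshold requires a trained model")
    m = np.asarray(summary_map, dtype=float)
    threshold = np.quantile(m.ravel(), quantile)
    foreground = m > threshold
    if model is not None:
        occupied = np.bincount(model.assignment, minlength=model.n_metagenes) > 0
        foreground = foreground & occupied.reshape(m.shape)

    if similarity_threshold is not None:
        raw = _similarity_components(
            foreground, model.weights, adjacency, similarity_threshold
        )
    else:
        structure = (
            np.ones((3, 3), bool)
            if adjacency == 8
            else ndimage.generate_binary_structure(2, 1)
        )
        labeled, n_comp = ndimage.label(foreground, structure=structure)
        raw = [
            sorted(np.flatnonzero((labeled == comp).ravel()).tolist())
            for comp in range(1, n_comp + 1)
        ]

    components = [c for c in raw if len(c) >= min_size]
    components.sort(key=lambda c: (-len(c), c[0]))

    spots = []
    for label, metagenes in zip(_spot_labels(len(components)), components):
        genes: list[str] = []
        if model is not None:
            for mg in metagenes:
                genes.extend(model.genes_of_metagene(mg))
        spots.append(Spot(label=label, metagenes=metagenes, genes=genes))
    return spots


def spot_profiles(spots: list[Spot], model: SOMModel) -> pd.DataFrame:
    """Spots x samples expression table: mean of member metagene weights.

    Spots without member genes carry no gene-level signal; they are flagged
    with a warning and excluded (they must not enter the GP stage).
    """
    counts = np.bincount(model.assignment, minlength=model.n_metagenes)
    rows = {}
    for spot in spots:
        if counts[spot.metagenes].sum() == 0:
            warnings.warn(
                f"spot {spot.label} has no member genes; excluded from profiles",
                stacklevel=2,
            )
            continue
        rows[spot.label] = model.weights[spot.metagenes, :].mean(axis=0)
    out = pd.DataFrame(rows, index=model.sample_ids).T
    out.index.name = "spot"
    return out
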