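"""Self-organizing-map expression portraits.

The SOM compresses the N (genes) x M (samples) centered expression matrix
into a K = k x k grid of metagenes, each carrying an M-length weight profile.
Genes are assigned to their best-matching unit (BMU, Euclidean distance);
the assignment is shared by all samples, so the k x k reshape of the weight
column for one sample is that sample's expression "portrait" and portraits
are directly comparable across samples and groups.

Training is batch-mode: per epoch every gene is assigned to its BMU, then
each metagene's weights are replaced by the neighborhood-weighted mean of
the gene profiles, with a Gaussian neighborhood on grid coordinates whose
radius decays linearly from k/2 to 0.5 over the epochs.  Weights are
initialized linearly on the plane spanned by the first two principal axes of
the gene profiles.  Batch updates make training deterministic given the
initialization and turn the zero-radius limit into Lloyd's k-means
iteration, which the tests exploit as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr


@dataclass
class SOMModel:
    """Trained SOM: grid side ``k``, K x M ``weights``, gene -> BMU assignment.

    Metagene indices are row-major and 0-based: metagene (i, j) has flat
    index i * k + j.
    """

    k: int
    weights: np.ndarray  # K x M
    gene_ids: pd.Index
    sample_ids: pd.Index
    assignment: np.ndarray  # len N, values in [0, K)
    #: mean gene-to-BMU distance after each completed epoch (training loss)
    quantization_errors: list[float] = field(default_factory=list)
    #: the same measure for the initial (untrained) weights
    initial_quantization_error: float = float("nan")

    @property
    def n_metagenes(self) -> int:
        return self.k * self.k

    def genes_of_metagene(self, flat_index: int) -> list[str]:
        return self.gene_ids[self.assignment == flat_index].tolist()

    def metagene_matrix(self) -> pd.DataFrame:
        """K x M metagene expression matrix as a DataFrame."""
        return pd.DataFrame(
            self.weights,
            index=pd.RangeIndex(self.n_metagenes, name="metagene"),
            columns=self.sample_ids,
        )


@dataclass
class Portrait:
    """k x k metagene expression image for one sample or one group mean."""

    values: np.ndarray  # k x k
    label: str

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        return self.values.ravel()


def _grid_coordinates(k: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel()]).astype(float)


def _linear_init(data: np.ndarray, k: int) -> np.ndarray:
    """Map grid coordinates affinely onto +-2 sd along the first two PCs."""
    n, m = data.shape
    mean = data.mean(axis=0)
    centered = data - mean
    # principal axes of the gene cloud in sample space
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    sd = s / max(np.sqrt(n - 1), 1.0)
    coords = _grid_coordinates(k)
    if k > 1:
        scaled = coords / (k - 1) * 2.0 - 1.0  # in [-1, 1]
    else:
        scaled = np.zeros_like(coords)
    w = np.tile(mean, (k * k, 1))
    for axis in range(min(2, len(s))):
        if sd[axis] <= 0:
            continue
        w += np.outer(scaled[:, axis], 2.0 * sd[axis] * vt[axis])
    return w


def train_som(
    X: pd.DataFrame,
    k: int,
    epochs: int = 40,
    seed: int = 0,
    radius_start: float | None = None,
    radius_end: float = 0.5,
) -> SOMModel:
    """Train a batch SOM on gene profiles (rows of the centered matrix X).

    ``seed`` is kept in the signature for interface stability; linear
    initialization and batch updates make the procedure deterministic, so it
    only matters if a future initializer draws random numbers.
    """
    if k < 1:
        raise ValueError("grid side k must be >= 1")
    data = X.to_numpy(float)
    if not np.isfinite(data).all():
        raise ValueError("expression matrix contains non-finite values")
    n, m = data.shape
    K = k * k
    if K > n:
        warnings.warn(
            f"grid has {K} metagenes but only {n} genes; empty metagenes allowed",
            stacklevel=2,
        )
    if radius_start is None:
        radius_start = k / 2.0

    weights = _linear_init(data, k)
    coords = _grid_coordinates(k)
    grid_d2 = cdist(coords, coords, metric="sqeuclidean")

    qe_history: list[float] = []
    initial_qe = float("nan")
    bmu = np.zeros(n, dtype=int)
    for epoch in range(epochs):
        d2 = cdist(data, weights, metric="sqeuclidean")
        bmu = np.argmin(d2, axis=1)  # argmin breaks ties toward lowest index
        qe = float(np.sqrt(d2[np.arange(n), bmu]).mean())
        if epoch == 0:
            initial_qe = qe
        else:
            qe_history.append(qe)

        if epochs > 1:
            sigma = radius_start + (radius_end - radius_start) * epoch / (epochs - 1)
        else:
            sigma = radius_end
        if sigma > 1e-9:
            H = np.exp(-grid_d2 / (2.0 * sigma**2))
        else:
            H = np.eye(K)

        sums = np.zeros((K, m))
        np.add.at(sums, bmu, data)
        counts = np.bincount(bmu, minlength=K).astype(float)
        numer = H @ sums
        denom = H @ counts
        occupied = denom > 0
        weights[occupied] = numer[occupied] / denom[occupied, np.newaxis]

    # final assignment and quantization error for the converged weights
    d2 = cdist(data, weights, metric="sqeuclidean")
    bmu = np.argmin(d2, axis=1)
    qe_history.append(float(np.sqrt(d2[np.arange(n), bmu]).mean()))

    return SOMModel(
        k=k,
        weights=weights,
        gene_ids=X.index,
        sample_ids=X.columns,
        assignment=bmu,
        quantization_errors=qe_history,
        initial_quantization_error=initial_qe,
    )


def sample_portrait(model: SOMModel, sample_id: str) -> Portrait:
    """k x k portrait of one sample: row-major reshape of its weight column."""
    try:
        col = model.sample_ids.get_loc(sample_id)
    except KeyError:
        raise KeyError(f"unknown sample id {sample_id!r}") from None
    return Portrait(model.weights[:, col].reshape(model.k, model.k).copy(), str(sample_id))


def group_portrait(portraits: list[Portrait], label: str = "group mean") -> Portrait:
    """Element-wise mean of portraits (a group-mean transcriptome landscape)."""
    if not portraits:
        raise ValueError("cannot average an empty list of portraits")
    ks = {p.k for p in portraits}
    if len(ks) > 1:
        raise ValueError(f"mixed grid sizes {sorted(ks)}")
    stack = np.stack([p.values for p in portraits])
    return Portrait(stack.mean(axis=0), label)


def portrait_correlation(a: Portrait, b: Portrait) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two portraits over the K cells."""
    if a.k != b.k:
        raise ValueError("portraits have different grid sizes")
    x, y = a.flatten(), b.flatten()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant portrait")
    r, p = pearsonr(x, y)
    return float(r), float(p)
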