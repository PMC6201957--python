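"""Alpha diversity (bias-corrected Chao1, Shannon) and sample dendrograms.

Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) with F1/F2
the singleton/doubleton OTU counts; Shannon is -sum p_i ln p_i in natural
log (a ``base`` argument covers log2/log10 reporting).  Between-sample
structure is summarised as a UPGMA (average linkage) dendrogram on
Bray-Curtis dissimilarities of relative OTU abundances, emitted as newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


@dataclass
class DiversityResult:
    sample: str
    s_obs: int
    chao1: float
    shannon: float


def _check_counts(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(list(counts))
    if arr.size == 0:
        raise ValueError("empty counts")
    if (arr < 1).any():
        raise ValueError("counts must be positive integers")
    return arr


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness from per-OTU abundances."""
    arr = _check_counts(counts)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return float(arr.size + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon(counts: Sequence[int], base: float | None = None) -> float:
    """Shannon diversity; natural log unless a base is given."""
    arr = _check_counts(counts).astype(float)
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def diversity_result(sample: str, counts: Sequence[int]) -> DiversityResult:
    arr = _check_counts(counts)
    return DiversityResult(sample=sample, s_obs=int(arr.size),
                           chao1=chao1(arr), shannon=shannon(arr))


def sample_dendrogram(table, *, metric: str = "braycurtis",
                      method: str = "average") -> str:
    """UPGMA tree over the samples (columns) of an OTU x sample table.

    The table is column-normalised to relative abundances before the
    distance computation; columns are taken in lexicographic order so the
    result is independent of input column order.  Returns a newick string
    with ultrametric branch lengths (leaf-to-root depth = merge height / 2).
    """
    import pandas as pd

    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    table = table.reindex(columns=sorted(table.columns))
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    colsums = table.sum(axis=0)
    if (colsums == 0).any():
        empty = list(table.columns[colsums == 0])
        raise ValueError(f"all-zero sample columns: {empty}")
    rel = (table / colsums).to_numpy().T  # samples x OTUs
    dists = pdist(rel, metric=metric)
    z = linkage(dists, method=method)
    return _linkage_to_newick(z, list(table.columns))


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, h, _ = z[node - n]
        parts = []
        for child in (int(left), int(right)):
            blen = h / 2.0 - height[child] / 2.0
            parts.append(f"{render(child)}:{blen:.6g}")
        return "(" + ",".join(parts) + ")"

    for k in range(z.shape[0]):
        height[n + k] = float(z[k, 2])
    return render(n + z.shape[0] - 1) + ";"
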