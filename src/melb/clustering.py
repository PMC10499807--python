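"""Consensus k-means clustering of serum methylomes.

Samples are clustered repeatedly with k-means (k-means++, Euclidean on beta
values) on random sample subsamples over the most-variable probes; the
co-clustering frequency matrix summarizes stability, and the final
assignment for each k is a hierarchical average-linkage cut of the consensus
dissimilarity (the "hierarchical" part of hierarchical consensus k-means).
The number of clusters is chosen from the Calinski-Harabasz curve subject to
the consensus-CDF elbow criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .errors import ValidationError
from .io_core import BetaMatrix
from .signatures import SignatureSet

#: consensus entries inside this open band count as ambiguous co-clustering
PAC_BAND = (0.1, 0.9)
#: a k is stability-supported when its PAC does not exceed this
PAC_MAX = 0.05


@dataclass
class ConsensusClusterResult:
    k_range: list
    consensus: dict          # k -> sample x sample DataFrame in [0,1]
    assignments: dict        # k -> pd.Series sample -> 1..k
    cdf_area: dict           # k -> area under the consensus-entry CDF
    pac: dict                # k -> proportion of ambiguous consensus entries
    calinski_harabasz: dict  # k -> CH index of the final assignment
    selected_k: int | None = None


def top_variance_probes(m: BetaMatrix, n: int) -> SignatureSet:
    """The n probes of largest sample variance; ties resolve by probe order."""
    if n > len(m.probe_ids):
        raise ValidationError("n exceeds probe count")
    var = m.values.var(axis=1, ddof=1).to_numpy()
    order = np.lexsort((np.arange(len(var)), -var))  # stable: id order on ties
    keep = [m.probe_ids[i] for i in order[:n]]
    return SignatureSet(keep, stage="top_variance", params={"n": n})


def consensus_kmeans(m: BetaMatrix, sig: SignatureSet, k_range=range(2, 9),
                     n_resamples: int = 1000, subsample_frac: float = 0.8,
                     seed: int = 0, n_init: int = 10) -> ConsensusClusterResult:
    """Consensus matrices, assignments and diagnostics for each candidate k."""
    k_range = list(k_range)
    X = m.subset_probes(sig.probe_ids).values.to_numpy().T  # samples x probes
    n = X.shape[0]
    if not all(2 <= k <= n - 1 for k in k_range):
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    if not (0 < subsample_frac <= 1):
        raise ValidationError("subsample_frac must lie in (0,1]")
    sub_n = max(2, int(round(subsample_frac * n)))
    rng = np.random.default_rng(seed)

    consensus, assignments, cdf_area, pac, ch = {}, {}, {}, {}, {}
    for k in k_range:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = (np.arange(n) if sub_n == n
                   else rng.choice(n, size=sub_n, replace=False))
            km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                        random_state=int(rng.integers(0, 2**31 - 1)))
            lab = km.fit_predict(X[idx])
            same = lab[:, None] == lab[None, :]
            tog[np.ix_(idx, idx)] += 1
            co[np.ix_(idx, idx)] += same
        if np.any(tog == 0):
            raise ValidationError(
                "some sample pairs never co-sampled; increase n_resamples")
        C = co / tog
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        lab = fcluster(Z, t=k, criterion="maxclust")
        consensus[k] = pd.DataFrame(C, index=m.sample_ids, columns=m.sample_ids)
        assignments[k] = pd.Series(lab, index=m.sample_ids, name=f"k{k}")
        tri = C[np.triu_indices(n, 1)]
        # area under the empirical CDF of consensus entries
        xs = np.sort(tri)
        cdf_area[k] = float(np.sum((xs[1:] - xs[:-1])
                                   * (np.arange(1, len(xs)) / len(xs))))
        pac[k] = float(np.mean((tri > PAC_BAND[0]) & (tri < PAC_BAND[1])))
        ch[k] = (float(calinski_harabasz_score(X, lab))
                 if len(np.unique(lab)) > 1 else float("nan"))
    res = ConsensusClusterResult(k_range, consensus, assignments, cdf_area,
                                 pac, ch)
    res.selected_k = select_k(res)
    return res


def select_k(res: ConsensusClusterResult) -> int:
    """Choose the number of clusters from consensus stability.

    The proportion of ambiguous consensus entries (PAC, a summary of the
    consensus CDF between 0.1 and 0.9) is near zero for every k at which the
    resampled partitions agree, and jumps as soon as k exceeds the number of
    real groups, which forces arbitrary splits.  The selected k is the
    largest stability-supported k (PAC <= PAC_MAX).  With no structure no k
    is supported and the smallest k is returned.  The CDF-area and
    Calinski-Harabasz curves are reported alongside so the choice is
    auditable.
    """
    ks = sorted(res.k_range)
    supported = [k for k in ks if res.pac[k] <= PAC_MAX]
    return max(supported) if supported else ks[0]
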