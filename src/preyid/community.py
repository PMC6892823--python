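"""Cross-sample analyses: Bray–Curtis similarity, average-linkage clustering,
detection matrices, and between-marker concordance."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .identification import SampleProfile


def bray_curtis(x: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Bray–Curtis similarity 2·Σ min(x,y) / (Σx + Σy) on taxon count maps.

    Symmetric, in [0, 1], invariant to scaling both vectors by a common
    positive constant. Zero-total vectors are an error: empty samples must be
    filtered out beforehand.
    """
    tx, ty = sum(x.values()), sum(y.values())
    if tx <= 0 or ty <= 0:
        raise ValueError("bray_curtis requires positive-total count vectors")
    shared = sum(min(x.get(k, 0.0), y.get(k, 0.0)) for k in set(x) | set(y))
    return 2.0 * shared / (tx + ty)


def filter_empty_samples(profiles: Sequence[SampleProfile]) -> list[SampleProfile]:
    """Drop samples with no detected prey taxa (all-host or unidentified)."""
    kept = [p for p in profiles if p.taxa]
    if not kept:
        raise ValueError("every sample is empty of prey taxa")
    return kept


def similarity_matrix(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Pairwise Bray–Curtis similarity between (non-empty) sample profiles."""
    profiles = filter_empty_samples(profiles)
    ids = [p.sample_id for p in profiles]
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = bray_curtis(profiles[i].counts, profiles[j].counts)
    return pd.DataFrame(sim, index=ids, columns=ids)


@dataclass
class Dendrogram:
    """Binary merge tree over samples with UPGMA merge heights."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage format

    @property
    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage_matrix[:, 2]]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()


def average_linkage_cluster(
    similarity: pd.DataFrame, method: str = "average"
) -> Dendrogram:
    """Agglomerative (UPGMA by default) clustering on 1 − similarity.

    Requires a square, symmetric, unit-diagonal similarity matrix over at
    least two samples.
    """
    sim = similarity.to_numpy(dtype=float)
    if sim.shape[0] != sim.shape[1] or sim.shape[0] < 2:
        raise ValueError("need a square similarity matrix over >= 2 samples")
    if not np.allclose(sim, sim.T, atol=1e-9) or not np.allclose(np.diag(sim), 1.0):
        raise ValueError("similarity matrix must be symmetric with unit diagonal")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(labels=[str(c) for c in similarity.columns], linkage_matrix=Z)


def detection_matrix(
    profiles: Sequence[SampleProfile], floor: int = 0
) -> pd.DataFrame:
    """Samples × taxa boolean matrix: detected iff normalized count > floor."""
    taxa = sorted({t for p in profiles for t in p.counts})
    rows = {
        p.sample_id: {t: p.counts.get(t, 0) > floor for t in taxa} for p in profiles
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa).fillna(False)


@dataclass
class ConcordanceResult:
    """Per-(sample, taxon) cross-marker detection classification."""

    table: pd.DataFrame  # categories: both / 12S_only / 16S_only / neither
    counts: dict[str, int]
    instances_12s: int
    instances_16s: int
    corroborated_12s: int
    corroborated_16s: int


def marker_concordance(
    detections_12s: pd.DataFrame, detections_16s: pd.DataFrame
) -> ConcordanceResult:
    """Compare detection matrices from the two mitochondrial markers.

    An "identification instance" is one (sample, taxon) detection for a
    marker; it is corroborated when the other marker detects the same taxon in
    the same sample.
    """
    if set(detections_12s.index) != set(detections_16s.index):
        raise ValueError("marker detection matrices must share the sample set")
    samples = sorted(detections_12s.index)
    taxa = sorted(set(detections_12s.columns) | set(detections_16s.columns))
    a = detections_12s.reindex(index=samples, columns=taxa, fill_value=False)
    b = detections_16s.reindex(index=samples, columns=taxa, fill_value=False)
    a = a.fillna(False).astype(bool)
    b = b.fillna(False).astype(bool)

    table = pd.DataFrame("neither", index=samples, columns=taxa)
    table = table.mask(a & b, "both").mask(a & ~b, "12S_only").mask(~a & b, "16S_only")
    flat = table.to_numpy().ravel()
    counts = {
        cat: int((flat == cat).sum())
        for cat in ("both", "12S_only", "16S_only", "neither")
    }
    return ConcordanceResult(
        table=table,
        counts=counts,
        instances_12s=int(a.to_numpy().sum()),
        instances_16s=int(b.to_numpy().sum()),
        corroborated_12s=int((a & b).to_numpy().sum()),
        corroborated_16s=int((a & b).to_numpy().sum()),
    )
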