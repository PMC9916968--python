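"""Molecular-subtype differential expression.

Compares antigen expression across the expression-derived ovarian cancer
clusters c1 (high stromal response), c2 (high immune signature), c4 (low
stromal response) and c5 (mesenchymal) on a pre-normalized probe x sample
intensity matrix.  Genes represented by several probe sets use the probe
with the highest average expression.  Differential expression across
clusters is tested with the (tie-corrected) Kruskal-Wallis test; pairwise
post-hoc comparisons use Dunn's z test with Bonferroni correction over all
pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from taavet.expression_filter import ValidationError

__all__ = [
    "VALID_CLUSTERS",
    "SubtypeDataset",
    "select_probe_set",
    "kruskal_wallis",
    "dunn_bonferroni",
    "subtype_analysis",
]

VALID_CLUSTERS = ("c1", "c2", "c4", "c5")


@dataclass
class SubtypeDataset:
    """Probe x sample expression with cluster labels and a probe->gene map.

    ``expression``: DataFrame indexed by probe id with one column per sample
    (non-negative normalized intensities).  ``clusters``: Series mapping
    sample id -> cluster label (subset of c1/c2/c4/c5).  ``probe_map``:
    Series mapping probe id -> gene symbol.
    """

    expression: pd.DataFrame
    clusters: pd.Series
    probe_map: pd.Series

    def __post_init__(self) -> None:
        bad = sorted(set(self.clusters.unique()) - set(VALID_CLUSTERS))
        if bad:
            raise ValidationError(
                f"unknown cluster labels {bad}; expected a subset of {list(VALID_CLUSTERS)} "
                "(the clusters representing true malignant neoplasia)"
            )
        if self.clusters.nunique() < 2:
            raise ValidationError("need at least 2 clusters represented")
        missing = sorted(set(self.expression.columns) - set(self.clusters.index))
        if missing:
            raise ValidationError(f"samples without cluster label: {missing}")
        unmapped = sorted(set(self.expression.index) - set(self.probe_map.index))
        if unmapped:
            raise ValidationError(f"probes without gene mapping: {unmapped}")
        if self.probe_map.index.has_duplicates:
            raise ValidationError("a probe must map to exactly one gene")
        if (self.expression.to_numpy(dtype=float) < 0).any():
            raise ValidationError("expression intensities must be non-negative")

    @property
    def genes(self) -> list[str]:
        return sorted(self.probe_map.loc[self.expression.index].unique())

    def probes_for(self, gene: str) -> list[str]:
        probes = self.probe_map[self.probe_map == gene].index
        return [p for p in probes if p in self.expression.index]

    def values_by_cluster(self, probe: str) -> dict[str, np.ndarray]:
        row = self.expression.loc[probe]
        out: dict[str, np.ndarray] = {}
        for cl in sorted(self.clusters.unique()):
            cols = self.clusters.index[self.clusters == cl]
            out[cl] = row[cols].to_numpy(dtype=float)
        return out


def select_probe_set(gene: str, dataset: SubtypeDataset) -> str:
    """Pick the probe set with the highest average expression for a gene.

    Ties break to the lexicographically smallest probe id.
    """
    probes = dataset.probes_for(gene)
    if not probes:
        raise ValidationError(f"gene {gene!r} has no probe in the dataset")
    means = dataset.expression.loc[probes].mean(axis=1)
    best = means.max()
    return sorted(means.index[means == best])[0]


def _h_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled average ranks."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled, method="average")
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    correction = 1.0 - tie_term / (n**3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]], exact: Optional[bool] = None
) -> tuple[float, float]:
    """Kruskal-Wallis H test across k groups; returns (H, p).

    The p-value comes from the chi-squared distribution on k-1 df; with
    ``exact=True`` (allowed for total n <= 10, and the default there when
    ``exact`` is None stays asymptotic) it is computed by enumerating every
    distinct partition of the pooled values into groups of the observed
    sizes.  All-identical values give H = 0, p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValidationError("every group must be non-empty")
    n = sum(a.size for a in arrs)
    if n < 3:
        raise ValidationError("need total n >= 3")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h = _h_statistic(arrs)
    if exact:
        if n > 10:
            raise ValidationError("exact permutation p limited to total n <= 10")
        sizes = [a.size for a in arrs]
        count = 0
        total = 0
        idx = list(range(n))
        target = h * (1 - 1e-12)
        for assignment in _partitions(idx, sizes):
            perm_groups = [pooled[list(part)] for part in assignment]
            if _h_statistic(perm_groups) >= target:
                count += 1
            total += 1
        return h, count / total
    p = float(stats.chi2.sf(h, df=len(arrs) - 1))
    return h, max(p, np.nextafter(0, 1))


def _partitions(items: list[int], sizes: list[int]):
    """Yield all distinct ordered partitions of ``items`` into blocks of ``sizes``."""
    if len(sizes) == 1:
        yield (tuple(items),)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(items, first):
        remaining = [i for i in items if i not in combo]
        for sub in _partitions(remaining, rest):
            yield (combo,) + sub


def dunn_bonferroni(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on pooled ranks, Bonferroni-adjusted.

    For groups i, j with mean pooled ranks Ri, Rj:

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) * (1/ni + 1/nj))

    where T = sum(t^3 - t) over tie groups.  Raw two-sided p from the
    standard normal; adjusted p = min(1, m * raw p) with m = number of
    pairs.  Returns a DataFrame with columns group_a, group_b, z, p_raw,
    p_adjusted.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("need at least 2 groups for post-hoc comparisons")
    if any(a.size == 0 for a in arrs):
        raise ValidationError("every group must be non-empty")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValidationError("labels must match the number of groups")
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = stats.rankdata(pooled, method="average")
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(len(arrs)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            dict(
                group_a=labels[i],
                group_b=labels[j],
                z=z,
                p_raw=p_raw,
                p_adjusted=min(1.0, m * p_raw),
            )
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])


def subtype_analysis(
    dataset: SubtypeDataset,
    genes: Optional[Sequence[str]] = None,
    posthoc_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential-expression screen across clusters.

    For each gene: pick the highest-mean probe, run Kruskal-Wallis across
    the clusters, and — when the omnibus p falls below ``posthoc_alpha`` —
    Dunn-Bonferroni pairwise comparisons.  Returns a long DataFrame with one
    omnibus row per gene (test = 'kruskal_wallis') and one row per post-hoc
    pair (test = 'dunn_bonferroni').
    """
    rows = []
    for gene in genes if genes is not None else dataset.genes:
        probe = select_probe_set(gene, dataset)
        by_cluster = dataset.values_by_cluster(probe)
        labels = sorted(by_cluster)
        groups = [by_cluster[cl] for cl in labels]
        h, p = kruskal_wallis(groups)
        rows.append(
            dict(gene=gene, probe=probe, test="kruskal_wallis",
                 comparison="omnibus", statistic=h, p=p, p_adjusted=np.nan)
        )
        if p < posthoc_alpha:
            posthoc = dunn_bonferroni(groups, labels)
            for rec in posthoc.itertuples(index=False):
                rows.append(
                    dict(gene=gene, probe=probe, test="dunn_bonferroni",
                         comparison=f"{rec.group_a} vs {rec.group_b}",
                         statistic=rec.z, p=rec.p_raw, p_adjusted=rec.p_adjusted)
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "probe", "test", "comparison", "statistic", "p", "p_adjusted"],
    )
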