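"""Rank-based differential expression and stage-wise gene-set logic.

The test statistic exploits the multiple-probes-per-transcript design: for a
contrast, each probe contributes its mean log2 ratio between the two array
groups; these per-probe ratios are ranked across all probes, and a gene's
statistic is the sum of its probes' ranks (centred, two-sided).  The null
distribution comes from permuting the array condition labels — all distinct
relabelings when there are at most 2000, otherwise Monte-Carlo — with the
permuted statistics pooled across genes of equal probe count, which gives
p-value resolution far below 1/(number of relabelings) at small sample
sizes.

Gene selection uses the conventional thresholds of absolute fold change
>= 1.75 and P < 0.01 (no multiple-testing correction by default; a
Benjamini-Hochberg switch is available).  Down-regulation is reported with
the negative-reciprocal convention (a halving is −2.0).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from emtcre.errors import ConfigurationError, DataError
from emtcre.normalization import NormalizedMatrix

__all__ = [
    "Contrast",
    "rank_de",
    "select_genes",
    "venn_partition",
    "VennPartition",
    "shared_with_endpoint",
    "up_down_ratio",
    "hier_cluster",
    "stage_profiles",
    "qpcr_fold_change",
]

FC_CUTOFF = 1.75
ALPHA = 0.01


@dataclass(frozen=True)
class Contrast:
    """A treatment-vs-control comparison between array groups."""

    name: str
    treatment: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "treatment", tuple(self.treatment))
        object.__setattr__(self, "control", tuple(self.control))
        if not self.treatment or not self.control:
            raise ConfigurationError(
                f"contrast {self.name}: both sides need >= 1 array")
        if set(self.treatment) & set(self.control):
            raise ConfigurationError(
                f"contrast {self.name}: treatment and control overlap")


def signed_fold_change(median_log2: float) -> float:
    """Signed ratio convention: 2x up -> 2.0, 2x down -> -2.0."""
    ratio = 2.0 ** median_log2
    return ratio if ratio >= 1.0 else -1.0 / ratio


def _relabelings(arrays: tuple[str, ...], n_treat: int, limit: int,
                 n_perm: int, rng: np.random.Generator
                 ) -> list[tuple[int, ...]]:
    """Index sets of pseudo-treatment arrays, identity excluded."""
    from math import comb

    n = len(arrays)
    total = comb(n, n_treat)
    identity = tuple(range(n_treat))
    if total <= limit:
        combos = [c for c in itertools.combinations(range(n), n_treat)
                  if c != identity]
    else:
        combos = []
        seen = {identity}
        while len(combos) < n_perm:
            c = tuple(sorted(rng.choice(n, size=n_treat, replace=False)))
            if c in seen:
                continue
            seen.add(c)
            combos.append(c)
    return combos


def rank_de(nm: NormalizedMatrix, contrast: Contrast, n_perm: int = 1000,
            seed: int = 0, fc_cutoff: float = FC_CUTOFF, alpha: float = ALPHA,
            bh_fdr: bool = False) -> pd.DataFrame:
    """Per-gene rank-based differential expression for one contrast.

    Returns a DataFrame indexed by gene with columns ``fold_change`` (signed
    ratio), ``rank_statistic`` (centred absolute rank sum), ``p_value`` and
    ``direction`` (up / down / null).  Metadata (contrast, thresholds, seed)
    is stored in ``DataFrame.attrs``.
    """
    missing = [a for a in (*contrast.treatment, *contrast.control)
               if a not in nm.arrays]
    if missing:
        raise DataError(f"contrast {contrast.name}: arrays {missing} absent")

    counts = nm.gene_ids.value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(f"excluding {len(singletons)} gene(s) with a single "
                      "probe from rank-based testing")
    keep = nm.gene_ids.isin(counts[counts >= 2].index)
    gene_ids = nm.gene_ids[keep]
    genes = gene_ids.unique()

    cols = list(contrast.treatment) + list(contrast.control)
    data = nm.log2.loc[keep, cols].to_numpy()
    n_t = len(contrast.treatment)
    n_probes = data.shape[0]

    # group membership matrix for fast per-gene sums
    gene_index = pd.Categorical(gene_ids, categories=genes).codes
    k_per_gene = np.bincount(gene_index, minlength=len(genes))

    def statistic(treat_idx: Iterable[int]) -> np.ndarray:
        treat_idx = np.asarray(list(treat_idx))
        ctrl_mask = np.ones(len(cols), dtype=bool)
        ctrl_mask[treat_idx] = False
        delta = data[:, treat_idx].mean(axis=1) - data[:, ctrl_mask].mean(axis=1)
        ranks = rankdata(delta)
        sums = np.bincount(gene_index, weights=ranks, minlength=len(genes))
        expected = k_per_gene * (n_probes + 1) / 2.0
        return np.abs(sums - expected), delta

    obs_stat, obs_delta = statistic(range(n_t))

    med = np.empty(len(genes))
    for gi in range(len(genes)):
        med[gi] = np.median(obs_delta[gene_index == gi])
    fc = np.array([signed_fold_change(m) for m in med])

    rng = np.random.default_rng(seed)
    combos = _relabelings(tuple(cols), n_t, limit=2000, n_perm=n_perm, rng=rng)

    # Genes with fold-change evidence are candidate regulated genes; keeping
    # them out of the permutation pool stops truly regulated genes from
    # inflating the null tail (contamination-reduced null).  Fall back to all
    # genes if too few look null.
    null_gene_mask = np.abs(fc) < fc_cutoff
    if null_gene_mask.sum() < max(20, 0.2 * len(genes)):
        null_gene_mask = np.ones(len(genes), dtype=bool)

    if len(cols) == 2 or not combos:
        warnings.warn(f"contrast {contrast.name}: no informative label "
                      "permutations possible; p-values set to 1")
        pvals = np.ones(len(genes))
    else:
        # pool permuted statistics across genes with equal probe count
        null_by_k: dict[int, list[np.ndarray]] = {}
        for c in combos:
            null_stat, _ = statistic(c)
            for k in np.unique(k_per_gene):
                pool = (k_per_gene == k) & null_gene_mask
                if not pool.any():
                    pool = k_per_gene == k
                null_by_k.setdefault(k, []).append(null_stat[pool])
        pvals = np.empty(len(genes))
        for k in np.unique(k_per_gene):
            null = np.sort(np.concatenate(null_by_k[k]))
            sel = k_per_gene == k
            n_ge = len(null) - np.searchsorted(null, obs_stat[sel], side="left")
            pvals[sel] = (1.0 + n_ge) / (1.0 + len(null))

    if bh_fdr:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]

    direction = np.where(
        (pvals < alpha) & (fc >= fc_cutoff), "up",
        np.where((pvals < alpha) & (fc <= -fc_cutoff), "down", "null"))

    out = pd.DataFrame({
        "fold_change": fc,
        "rank_statistic": obs_stat,
        "p_value": pvals,
        "direction": direction,
    }, index=pd.Index(genes, name="gene_id"))
    out.attrs.update(contrast=contrast.name, fc_cutoff=fc_cutoff, alpha=alpha,
                     seed=seed, n_relabelings=len(combos), bh_fdr=bh_fdr)
    return out


def select_genes(table: pd.DataFrame, direction: str) -> set[str]:
    """Genes called in the given direction ('up', 'down' or 'any')."""
    if direction == "any":
        return set(table.index[table["direction"] != "null"])
    return set(table.index[table["direction"] == direction])


def write_de_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for k, v in table.attrs.items():
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Venn partition of three stage sets


@dataclass
class VennPartition:
    """Exact 7-region partition of three named gene sets."""

    names: tuple[str, str, str]
    regions: dict[frozenset, set]
    direction: str | None = None

    @property
    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *names: str) -> set:
        """Genes exclusive to exactly this combination of sets."""
        return self.regions[frozenset(names)]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
            rows.append({
                "region": "&".join(sorted(key)),
                "n_sets": len(key),
                "count": len(self.regions[key]),
                "genes": ",".join(sorted(self.regions[key])),
            })
        return pd.DataFrame(rows)


def venn_partition(sets: dict[str, set], direction: str | None = None
                   ) -> VennPartition:
    """Partition three named gene sets into their 7 disjoint Venn regions."""
    if len(sets) != 3:
        raise ConfigurationError("venn_partition requires exactly three sets")
    names = tuple(sets)
    regions: dict[frozenset, set] = {}
    for r in range(1, 4):
        for inc in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in inc))
            outside = set.union(*(set(sets[n]) for n in names if n not in inc),
                                set())
            regions[frozenset(inc)] = inside - outside
    return VennPartition(names=names, regions=regions, direction=direction)


# ---------------------------------------------------------------------------
# endpoint overlap & up/down balance


class EndpointOverlap(NamedTuple):
    shared: set
    frac_of_stage: float
    frac_of_endpoint: float


def shared_with_endpoint(stage: pd.DataFrame, endpoint: pd.DataFrame,
                         require_direction: bool = True) -> EndpointOverlap:
    """Genes differentially expressed in a stage and the endpoint contrast.

    Both tables must cover the same gene universe.  By default a gene only
    counts as shared when its direction matches in the two contrasts.
    """
    if set(stage.index) != set(endpoint.index):
        raise DataError("stage and endpoint tables cover different gene "
                        "universes")
    s_de = stage["direction"] != "null"
    e_de = endpoint["direction"].reindex(stage.index) != "null"
    both = s_de & e_de
    if require_direction:
        both &= stage["direction"] == endpoint["direction"].reindex(stage.index)
    shared = set(stage.index[both])
    n_stage = int(s_de.sum())
    n_end = int(e_de.sum())
    return EndpointOverlap(
        shared=shared,
        frac_of_stage=len(shared) / n_stage if n_stage else 0.0,
        frac_of_endpoint=len(shared) / n_end if n_end else 0.0)


def up_down_ratio(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Percent up-regulated among selected genes, per stage and pooled."""
    if not tables:
        raise ConfigurationError("need at least one DE table")
    rows = []
    tot_up = tot_down = 0
    for stage, t in tables.items():
        n_up = int((t["direction"] == "up").sum())
        n_down = int((t["direction"] == "down").sum())
        tot_up += n_up
        tot_down += n_down
        pct = 100.0 * n_up / (n_up + n_down) if n_up + n_down else np.nan
        rows.append({"stage": stage, "n_up": n_up, "n_down": n_down,
                     "percent_up": pct})
    pooled = (100.0 * tot_up / (tot_up + tot_down)
              if tot_up + tot_down else np.nan)
    rows.append({"stage": "pooled", "n_up": tot_up, "n_down": tot_down,
                 "percent_up": pooled})
    return pd.DataFrame(rows, columns=["stage", "n_up", "n_down", "percent_up"])


# ---------------------------------------------------------------------------
# hierarchical clustering


def stage_profiles(nm: NormalizedMatrix, genes: Iterable[str],
                   stages: list[str] | None = None,
                   baseline: str | None = None) -> pd.DataFrame:
    """Per-gene per-stage mean log2 ratio versus the baseline condition."""
    from emtcre.probe_matrix import array_condition

    conditions = []
    for c in nm.arrays:
        cond = array_condition(c)
        if cond not in conditions:
            conditions.append(cond)
    base_cond = baseline or array_condition(nm.baseline)
    stages = stages or [c for c in conditions if c != base_cond]

    base_cols = nm.arrays_for(base_cond)
    base_mean = nm.log2[base_cols].mean(axis=1)
    prof = {}
    for s in stages:
        cols = nm.arrays_for(s)
        if not cols:
            raise DataError(f"no arrays for stage {s!r}")
        prof[s] = (nm.log2[cols].mean(axis=1) - base_mean)
    df = pd.DataFrame(prof)
    df["gene_id"] = nm.gene_ids
    gene_means = df.groupby("gene_id").mean()
    genes = [g for g in genes if g in gene_means.index]
    return gene_means.loc[genes]


class ClusterResult(NamedTuple):
    ordered_genes: list[str]
    newick: str
    linkage: np.ndarray
    distances: pd.DataFrame


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hier_cluster(profiles: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of gene expression profiles.

    ``profiles`` has one row per gene (>= 2) and one column per stage; the
    distance is 1 − Pearson correlation of the per-stage mean log2 ratios.
    A constant profile has undefined correlation; its distances are set to
    the maximum (2) with a warning.  Returns the leaf order, a Newick string
    of the dendrogram and the linkage matrix.
    """
    if len(profiles) < 2:
        raise DataError("need at least two genes to cluster")
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profile(s); their "
                      "correlation is undefined, distance set to 2")
    centered = x - x.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, np.linalg.norm(centered, axis=1))
    z = centered / denom[:, None]
    corr = z @ z.T
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)

    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(link)
    labels = list(profiles.index)
    tree = hierarchy.to_tree(link)
    newick = _to_newick(tree, labels) + ";"
    return ClusterResult(
        ordered_genes=[labels[i] for i in order],
        newick=newick,
        linkage=link,
        distances=pd.DataFrame(dist, index=labels, columns=labels))


# ---------------------------------------------------------------------------
# qRT-PCR fold change


def qpcr_fold_change(ct_treatment, ct_control):
    """Fold change from cycle thresholds: ``2**(-(xn - yn))``.

    One PCR cycle earlier in treatment (xn = yn − 1) is a doubling.
    """
    xn = np.asarray(ct_treatment, dtype=float)
    yn = np.asarray(ct_control, dtype=float)
    if not (np.all(np.isfinite(xn)) and np.all(np.isfinite(yn))):
        raise DataError("cycle thresholds must be finite")
    out = np.power(2.0, -(xn - yn))
    return float(out) if out.ndim == 0 else out
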