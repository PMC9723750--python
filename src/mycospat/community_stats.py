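"""Distance-based community statistics and the host-specificity procedure.

Implements the statistical core used to test whether the root-associated
fungal community of a plant species is distinguishable from those of other
species: rarefaction to a common read depth, Bray-Curtis dissimilarity,
one-way PERMANOVA with permutation (or exhaustive) p-values, Mantel tests,
Benjamini-Hochberg FDR control, Gower trait dissimilarity, cophenetic
phylogenetic distance, prevalence-based core-OTU definition, and the
host-specific / host-dependent classification rule.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "CoreOTUSet",
    "HostSpecificityCall",
    "rarefy",
    "bray_curtis",
    "permanova",
    "mantel",
    "bh_fdr",
    "gower_distance",
    "cophenetic_distance",
    "define_core_otus",
    "classify_host_specificity",
]


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, nonnegative distance matrix with entity labels."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.data.shape} does not match {n} labels"
            )
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.data, checks=False)

    def filter(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.data[np.ix_(idx, idx)])

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_perm: int
    group_sizes: dict[str, int]
    exhaustive: bool = False


@dataclass
class CoreOTUSet:
    """Core root-associated fungal OTUs of one host species at one cutoff.

    An OTU is core when its detection frequency (fraction of the species'
    root-tip samples with nonzero count) reaches the cutoff.  ``coverage``
    is the fraction of the species' total reads carried by the core set.
    """

    species: str
    cutoff: float
    otus: frozenset[str]
    coverage: float
    n_samples: int = 0
    stage: str | None = None


@dataclass
class HostSpecificityCall:
    species: str
    n_significant: int
    n_compared: int
    call: str  # host-specific | host-dependent | nonspecific
    stage: str | None = None


def rarefy(counts_row: np.ndarray, depth: int, seed: int | np.random.Generator) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draw: each read of the original sample is
    equally likely to be retained, so expected rarefied counts are
    ``depth * c_k / total``.

    Raises ``ValueError`` if the row total is below the requested depth
    (callers exclude such samples with a warning).
    """
    counts = np.asarray(counts_row)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"row total {total} < rarefaction depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefy_table(
    table: pd.DataFrame, depth: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Rarefy every row of a samples x OTUs count table to ``depth``.

    Rows whose total is below ``depth`` are dropped with a warning naming
    the samples, mirroring the usual exclusion rule for shallow samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.sum(axis=1)
    shallow = table.index[totals < depth].tolist()
    if shallow:
        warnings.warn(
            f"excluded {len(shallow)} sample(s) below depth {depth}: {shallow}"
        )
    kept = table.loc[totals >= depth]
    out = np.vstack([rarefy(row, depth, rng) for row in kept.to_numpy()])
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def bray_curtis(abundance_matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows: sum|x-y| / sum(x+y), in [0, 1]."""
    X = abundance_matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative abundances")
    zero = abundance_matrix.index[X.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(list(abundance_matrix.index.astype(str)), d)


def _permanova_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    """Pseudo-F from squared distances: SS_T and within-group SS partition."""
    n = d2.shape[0]
    a = len(uniq)
    iu = np.triu_indices(n, 1)
    ss_t = d2[iu].sum() / n
    ss_w = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    if ss_w <= 1e-300:
        return math.inf
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F statistic partitions the total sum of squared distances
    into among- and within-group components; the p-value comes from free
    permutation of the sample labels with the +1 correction, so it can
    never be exactly zero.  With ``exhaustive=True`` all distinct label
    assignments are enumerated instead (feasible for small designs only)
    and the p-value is the exact fraction of assignments with F at least
    as large as observed.
    """
    labels = np.asarray(groups)
    if len(labels) != dist.n:
        raise ValueError("group labels do not match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    d2 = dist.data**2
    f_obs = _permanova_f(d2, labels, uniq)
    group_sizes = dict(zip((str(u) for u in uniq), (int(c) for c in counts)))

    if exhaustive:
        # Enumerate distinct assignments of positions to groups.
        n = len(labels)
        positions = list(range(n))
        ge = 0
        total = 0
        for assignment in _distinct_assignments(positions, uniq, counts):
            f_p = _permanova_f(d2, assignment, uniq)
            total += 1
            if f_p >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(f_obs, ge / total, total, group_sizes, exhaustive=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm, uniq) >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return PermanovaResult(f_obs, p, n_perm, group_sizes)


def _distinct_assignments(positions, uniq, counts):
    """Yield every distinct labeling of positions with the given group sizes."""
    n = len(positions)
    first_count = int(counts[0])
    if len(uniq) == 1:
        yield np.full(n, uniq[0])
        return
    for chosen in itertools.combinations(range(n), first_count):
        rest_pos = [p for k, p in enumerate(positions) if k not in set(chosen)]
        for sub in _distinct_assignments(rest_pos, uniq[1:], counts[1:]):
            out = np.empty(n, dtype=uniq.dtype)
            out[list(chosen)] = uniq[0]
            rest_idx = [k for k in range(n) if k not in set(chosen)]
            out[rest_idx] = sub
            yield out


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    ``d2``'s rows and columns are permuted simultaneously; the one-sided
    (greater) p-value uses the +1 correction.  ``exhaustive=True``
    enumerates all n! permutations (small n only) and returns the exact
    fraction with r at least as large as observed.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices have mismatched labels")
    n = d1.n
    if n < 4:
        raise ValueError("need at least 4 entities")
    x = d1.condensed()
    if x.std() == 0 or d2.condensed().std() == 0:
        raise ValueError("undefined correlation: zero variance in a distance matrix")

    def corr(perm: np.ndarray) -> float:
        y = squareform(d2.data[np.ix_(perm, perm)], checks=False)
        return float(np.corrcoef(x, y)[0, 1])

    ident = np.arange(n)
    r_obs = corr(ident)
    if exhaustive:
        rs = [corr(np.array(p)) for p in itertools.permutations(range(n))]
        ge = sum(1 for r in rs if r >= r_obs - 1e-12)
        return r_obs, ge / len(rs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ge = sum(1 for _ in range(n_perm) if corr(rng.permutation(n)) >= r_obs - 1e-12)
    return r_obs, (1 + ge) / (1 + n_perm)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gower_distance(
    trait_table: pd.DataFrame, categorical: list[str] | None = None
) -> DistanceMatrix:
    """Gower dissimilarity over mixed numeric/categorical traits.

    Per pair, the mean over jointly observed traits of |x-y|/range for
    numeric traits and a 0/1 mismatch for categorical ones; all traits
    equally weighted, missing values handled by pairwise deletion.
    """
    if trait_table.shape[1] == 0:
        raise ValueError("trait table has no columns")
    if categorical is None:
        categorical = [
            c for c in trait_table.columns
            if not pd.api.types.is_numeric_dtype(trait_table[c])
        ]
    labels = list(trait_table.index.astype(str))
    n = len(labels)
    contrib = np.zeros((n, n))
    weight = np.zeros((n, n))
    for col in trait_table.columns:
        vals = trait_table[col]
        obs = vals.notna().to_numpy()
        both = np.outer(obs, obs)
        if col in categorical:
            arr = vals.to_numpy(dtype=object)
            diff = (arr[:, None] != arr[None, :]).astype(float)
        else:
            arr = vals.to_numpy(dtype=float)
            rng_ = np.nanmax(arr) - np.nanmin(arr)
            if rng_ == 0 or np.isnan(rng_):
                diff = np.zeros((n, n))
            else:
                diff = np.abs(arr[:, None] - arr[None, :]) / rng_
        diff = np.where(both, np.nan_to_num(diff), 0.0)
        contrib += diff
        weight += both
    if (weight[~np.eye(n, dtype=bool)] == 0).any():
        bad = np.argwhere((weight == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"no jointly observed trait for pair ({labels[bad[0]]}, {labels[bad[1]]})"
        )
    d = contrib / weight
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, (d + d.T) / 2)


def cophenetic_distance(tree: str | dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distances from a newick tree."""
    if isinstance(tree, str):
        try:
            tree = dendropy.Tree.get(data=tree, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(tips)
    d = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[tips[j]])
    return DistanceMatrix(tips, d)


def define_core_otus(
    species_table: pd.DataFrame,
    cutoff: float,
    species: str = "",
    stage: str | None = None,
) -> CoreOTUSet:
    """Core OTUs of one host species at a detection-frequency cutoff.

    ``species_table`` holds the species' root-tip samples (rows) by OTUs
    (columns).  An OTU is core when it is detected (count > 0) in at least
    ``cutoff`` of the samples; the comparison is made on exact rationals so
    that e.g. 4/8 samples at cutoff 0.5 is unambiguously core.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff {cutoff} outside (0, 1]")
    n_samples = species_table.shape[0]
    if n_samples < 2:
        raise ValueError("need at least 2 samples to define core OTUs")
    detected = (species_table > 0).sum(axis=0)
    cut = Fraction(cutoff).limit_denominator(10**6)
    core = [
        otu for otu, k in detected.items() if Fraction(int(k), n_samples) >= cut
    ]
    total = float(species_table.to_numpy().sum())
    core_reads = float(species_table[core].to_numpy().sum()) if core else 0.0
    coverage = core_reads / total if total > 0 else 0.0
    return CoreOTUSet(species, cutoff, frozenset(map(str, core)), coverage,
                      n_samples=n_samples, stage=stage)


def classify_host_specificity(
    adjusted_pvals,
    species: str = "",
    alpha: float = 0.05,
    dependent_fraction: float = 0.9,
    stage: str | None = None,
) -> HostSpecificityCall:
    """Classify a species' fungal community by how many other hosts it differs from.

    ``adjusted_pvals`` are the FDR-adjusted PERMANOVA p-values of the focal
    species against each of the other hosts.  The community is host-specific
    when it differs significantly from every other host, host-dependent when
    it differs from more than ``dependent_fraction`` of them (ceil of 0.9*38
    is 35, matching "at least 35 of 38"), and nonspecific otherwise.
    """
    p = np.asarray(adjusted_pvals, dtype=float)
    n_other = p.size
    if n_other < 1:
        raise ValueError("need at least one comparison")
    k = int((p < alpha).sum())
    threshold = math.ceil(dependent_fraction * n_other)
    if k == n_other:
        call = "host-specific"
    elif k >= threshold:
        call = "host-dependent"
    else:
        call = "nonspecific"
    return HostSpecificityCall(species, k, n_other, call, stage=stage)
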