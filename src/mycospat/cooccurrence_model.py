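"""Random-Forest prediction of pair co-occurrence from fungal predictors.

Compares predictor sets — single species-level dissimilarities (relative
abundance RA, phylogeny PL, functional traits FT, fungal richness RICH,
community composition COMM) against per-OTU modified-relative-abundance
(MRA) profiles — for classifying plant pairs as spatially aggregated or
segregated.  Each repetition draws a stratified 80/20 train/validation
split, rebalances the training classes by random over/under-sampling,
fits a 1000-tree random forest on the observed labels and again on
label-shuffled training data (the null branch), and scores both on the
untouched validation fold with ROC AUC.  Predictor sets are compared by
Wilcoxon tests (observed vs shuffled, FDR-adjusted) and one-way ANOVA
with Tukey HSD compact letters on the observed AUC distributions.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .community_stats import DistanceMatrix, bh_fdr, bray_curtis
from .mra import MRAProfile

__all__ = [
    "PairFeatureTable",
    "ModelResult",
    "build_features",
    "balance_classes",
    "roc_auc",
    "run_repetition",
    "evaluate_predictors",
    "compare_models",
]

SCALAR_PREDICTORS = ("RA", "PL", "FT", "RICH", "COMM")


@dataclass
class PairFeatureTable:
    """Feature matrix over labeled species pairs (aggregated vs segregated)."""

    predictor_set: str
    features: pd.DataFrame  # index: "spA--spB" pair keys
    labels: pd.Series       # "aggregated" | "segregated", same index

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels indices differ")
        if self.features.index.has_duplicates:
            raise ValueError("duplicate pairs in feature table")
        bad = set(self.labels.unique()) - {"aggregated", "segregated"}
        if bad:
            raise ValueError(f"non-binary labels: {bad}")


@dataclass
class ModelResult:
    predictor_set: str
    auc_observed: np.ndarray
    auc_shuffled: np.ndarray
    wilcoxon_p: float | None = None
    wilcoxon_p_fdr: float | None = None
    tukey_letter: str | None = None


def _pair_key(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}--{b}"


def build_features(
    predictor_set: str,
    pair_classes: dict[tuple[str, str], str],
    species_ra: dict[str, float] | None = None,
    phylo_dist: DistanceMatrix | None = None,
    trait_dist: DistanceMatrix | None = None,
    richness: dict[str, float] | None = None,
    community: pd.DataFrame | None = None,
    mra_profiles: dict[tuple[str, str], MRAProfile] | None = None,
    mra_side: str = "shared",
) -> PairFeatureTable:
    """Assemble the feature table for one predictor set.

    Scalar sets give one dissimilarity column: RA = |relative-abundance
    difference| of the two plant species, PL = cophenetic distance, FT =
    Gower distance, RICH = |fungal OTU richness difference|, COMM =
    Bray-Curtis between species-pooled root fungal communities.  MRA sets
    give one column per core OTU present on the requested side in any
    pair, with 0 for OTUs absent from a pair's profile.  Pairs classed
    "none" are excluded; pairs missing a required input are dropped with
    a warning.
    """
    pairs = [(a, b) for (a, b), c in sorted(pair_classes.items())
             if c in ("aggregated", "segregated")]
    labels, keys, rows = [], [], []
    comm_bc = None
    if predictor_set == "COMM":
        if community is None:
            raise ValueError("COMM requires species-pooled communities")
        comm_bc = bray_curtis(community)

    if predictor_set in SCALAR_PREDICTORS:
        for a, b in pairs:
            try:
                if predictor_set == "RA":
                    val = abs(species_ra[a] - species_ra[b])
                elif predictor_set == "PL":
                    val = phylo_dist[a, b]
                elif predictor_set == "FT":
                    val = trait_dist[a, b]
                elif predictor_set == "RICH":
                    val = abs(richness[a] - richness[b])
                else:
                    val = comm_bc[a, b]
            except (KeyError, ValueError, TypeError):
                warnings.warn(f"pair ({a}, {b}) dropped: missing {predictor_set} input")
                continue
            keys.append(_pair_key(a, b))
            rows.append({predictor_set: val})
            labels.append(pair_classes[(a, b)])
        feats = pd.DataFrame(rows, index=keys)
    elif predictor_set.startswith("MRA"):
        if mra_profiles is None:
            raise ValueError("MRA predictor sets require MRA profiles")
        all_otus = sorted({
            o for p in mra_profiles.values()
            for o in (p.shared if mra_side == "shared" else p.unique)
        })
        for a, b in pairs:
            prof = mra_profiles.get((a, b)) or mra_profiles.get((b, a))
            if prof is None:
                warnings.warn(f"pair ({a}, {b}) dropped: no MRA profile")
                continue
            side = prof.shared if mra_side == "shared" else prof.unique
            keys.append(_pair_key(a, b))
            rows.append({o: side.get(o, 0.0) for o in all_otus})
            labels.append(pair_classes[(a, b)])
        feats = pd.DataFrame(rows, index=keys, columns=all_otus).fillna(0.0)
    else:
        raise ValueError(f"unknown predictor set {predictor_set!r}")

    return PairFeatureTable(predictor_set, feats, pd.Series(labels, index=keys))


def balance_classes(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Rebalance a binary training set to a 1:1 class ratio.

    Random oversampling of the minority class (with replacement) and
    undersampling of the majority (without), both to the mean class size —
    a plain-resampling counterpart of the "both" strategy used for
    imbalanced binary classification (no kernel smoothing).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    target = int(round(len(labels) / 2))
    parts = []
    for c in sorted(classes):
        idx = np.flatnonzero((labels == c).to_numpy())
        if len(idx) >= target:
            take = rng.choice(idx, size=target, replace=False)
        else:
            take = rng.choice(idx, size=target, replace=True)
        parts.append(take)
    sel = np.concatenate(parts)
    return features.iloc[sel].reset_index(drop=True), labels.iloc[sel].reset_index(drop=True)


def roc_auc(scores, labels, positive: str = "aggregated") -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _stratified_split(labels: pd.Series, test_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified index split; at least one test row per class."""
    test_idx = []
    for c in sorted(labels.unique()):
        idx = np.flatnonzero((labels == c).to_numpy())
        n_test = max(1, int(round(test_frac * len(idx))))
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


def run_repetition(
    table: PairFeatureTable,
    seed: int | np.random.Generator = 0,
    n_trees: int = 1000,
    test_frac: float = 0.2,
    max_features: str | float = "sqrt",
) -> tuple[float, float]:
    """One modeling repetition: observed-label and shuffled-label AUCs.

    Stratified 80/20 split; the training fold is rebalanced and used to
    fit two random forests — one on observed labels, one on labels
    shuffled within the training fold (the random-guess null).  Both are
    scored on the untouched validation fold.
    """
    if len(table.labels) < 10:
        raise ValueError("need at least 10 labeled pairs")
    if table.labels.nunique() != 2:
        raise ValueError("both classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train, test = _stratified_split(table.labels, test_frac, rng)
    X_tr = table.features.iloc[train]
    y_tr = table.labels.iloc[train]
    X_te = table.features.iloc[test]
    y_te = table.labels.iloc[test]

    Xb, yb = balance_classes(X_tr, y_tr, rng)
    y_shuf = yb.iloc[rng.permutation(len(yb))].reset_index(drop=True)

    rf_seed = int(rng.integers(0, 2**31 - 1))
    aucs = []
    for y_fit in (yb, y_shuf):
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features=max_features,
            min_samples_leaf=1, random_state=rf_seed, n_jobs=1,
        )
        rf.fit(Xb.to_numpy(), y_fit.to_numpy())
        pos = list(rf.classes_).index("aggregated")
        scores = rf.predict_proba(X_te.to_numpy())[:, pos]
        aucs.append(roc_auc(scores, y_te.to_numpy()))
    return aucs[0], aucs[1]


def evaluate_predictors(
    tables: dict[str, PairFeatureTable],
    n_rep: int = 100,
    seed: int = 0,
    n_trees: int = 1000,
) -> dict[str, ModelResult]:
    """Run n_rep repetitions per predictor set with independent substream seeds."""
    if n_rep < 2:
        raise ValueError("need at least 2 repetitions")
    results = {}
    for name, table in tables.items():
        ss = np.random.SeedSequence([seed, zlib.crc32(name.encode()) % 2**31])
        child_seeds = ss.spawn(n_rep)
        obs = np.empty(n_rep)
        shuf = np.empty(n_rep)
        for r in range(n_rep):
            rng = np.random.default_rng(child_seeds[r])
            obs[r], shuf[r] = run_repetition(table, rng, n_trees=n_trees)
        results[name] = ModelResult(name, obs, shuf)
    return results


def _compact_letters(names: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb over a pairwise decision matrix.

    Groups sharing a letter are not significantly different.
    """
    # start with one letter group containing everything, then split on
    # each significant pair
    groups: list[set[str]] = [set(names)]
    for a, b in sorted(different):
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in new_groups:
            if not any(g < h for h in new_groups if g is not h) and g not in groups:
                groups.append(g)
    groups.sort(key=lambda g: sorted(names.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for k, g in enumerate(groups):
        for n in g:
            letters[n] += alphabet[k]
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def compare_models(
    results: dict[str, ModelResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Compare predictor sets: observed-vs-shuffled Wilcoxon and Tukey letters.

    Per set, a two-sided Wilcoxon rank-sum of observed vs shuffled AUCs,
    FDR-adjusted across sets; across sets, one-way ANOVA on observed AUCs
    followed by Tukey HSD, summarized as compact letters (sets sharing a
    letter are not significantly different at ``alpha``).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 predictor sets")
    n_reps = {len(r.auc_observed) for r in results.values()}
    if len(n_reps) != 1:
        raise ValueError("predictor sets have unequal repetition counts")
    names = list(results)
    pvals = []
    for n in names:
        r = results[n]
        if np.array_equal(r.auc_observed, r.auc_shuffled):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(
                r.auc_observed, r.auc_shuffled, alternative="two-sided"
            ).pvalue)
        pvals.append(p)
    p_fdr = bh_fdr(pvals)

    values = np.concatenate([results[n].auc_observed for n in names])
    group = np.concatenate([[n] * len(results[n].auc_observed) for n in names])
    if all(np.allclose(results[n].auc_observed, results[names[0]].auc_observed)
           for n in names):
        different: set[tuple[str, str]] = set()
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(
            *[results[n].auc_observed for n in names]
        ).pvalue)
        tk = pairwise_tukeyhsd(values, group, alpha=alpha)
        different = set()
        res = tk.summary().data[1:]
        for row in res:
            if bool(row[-1]):
                different.add((str(row[0]), str(row[1])))
    letters = _compact_letters(names, different)

    rows = []
    for k, n in enumerate(names):
        r = results[n]
        r.wilcoxon_p = pvals[k]
        r.wilcoxon_p_fdr = float(p_fdr[k])
        r.tukey_letter = letters[n]
        rows.append({
            "predictor_set": n,
            "mean_auc_observed": float(r.auc_observed.mean()),
            "mean_auc_shuffled": float(r.auc_shuffled.mean()),
            "wilcoxon_p": pvals[k],
            "wilcoxon_p_fdr": float(p_fdr[k]),
            "anova_p": anova_p,
            "tukey_letter": letters[n],
        })
    return pd.DataFrame(rows)
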