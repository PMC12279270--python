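"""Alpha-diversity panel, Aitchison beta-diversity, ordination and
permutation tests.

Alpha diversity covers Shannon (natural log), inverse Simpson, classic Chao1
and Faith's phylogenetic diversity (including the path to the root).
Beta diversity is the Aitchison distance (Euclidean distance between CLR
sample vectors); ordination is classical PCoA (default) or non-metric MDS
initialised from the PCoA solution; group separation and dispersion are
tested by label permutation (pseudo-F PERMANOVA and a betadisper-style
one-way F on distances to group centroids).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import FeatureTable


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def shannon(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return np.nan
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def inverse_simpson(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return np.nan
    p = counts / total
    return float(1.0 / (p**2).sum())


def chao1(counts: np.ndarray) -> float:
    """Classic Chao1: ``S_obs + F1^2 / (2 F2)``.

    When no doubletons exist the bias-corrected form
    ``S_obs + F1 (F1 - 1) / 2`` is used; with no singletons the estimate is
    simply the observed richness.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        return np.nan
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return float(s_obs + f1 * (f1 - 1) / 2.0)
    return float(s_obs + f1 * f1 / (2.0 * f2))


def faith_pd(observed: Sequence[str], tree: TreeNode) -> float:
    """Total branch length of the subtree spanning the observed leaves and
    the root."""
    observed = [o for o in observed]
    if not observed:
        return np.nan
    nodes: set[int] = set()
    lengths = 0.0
    seen: set[int] = set()
    for name in observed:
        node = tree.find(name)
        while node.parent is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            lengths += node.length or 0.0
            node = node.parent
    return float(lengths)


def alpha_diversity(
    counts: FeatureTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample Shannon, inverse Simpson, Chao1 and (with a tree) Faith PD.

    Empty samples are reported as missing. Counts must be integer-valued;
    Faith PD requires the tree to cover every observed ASV.
    """
    mat = counts.data.to_numpy(dtype=float)
    if not np.allclose(mat, np.round(mat)):
        raise ValueError("alpha diversity requires integer counts")
    rows = {}
    tips = {t.name for t in tree.tips()} if tree is not None else set()
    if tree is not None:
        uncovered = [f for f in counts.feature_ids if f not in tips]
        present_any = counts.data.sum(axis=1) > 0
        bad = [f for f in uncovered if present_any.loc[f]]
        if bad:
            raise ValueError(f"tree does not cover observed ASVs: {bad}")
    for j, sample in enumerate(counts.sample_ids):
        col = mat[:, j]
        row = {
            "shannon": shannon(col),
            "inverse_simpson": inverse_simpson(col),
            "chao1": chao1(col),
        }
        if tree is not None:
            obs = [f for f, v in zip(counts.feature_ids, col) if v > 0]
            row["faith_pd"] = faith_pd(obs, tree)
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity and ordination
# ---------------------------------------------------------------------------


def aitchison_distance(clr: FeatureTable) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed sample vectors."""
    if clr.kind != "clr_values":
        raise ValueError("aitchison_distance expects a CLR table")
    coords = clr.data.to_numpy(dtype=float).T  # samples x features
    return DistanceMatrix(squareform(pdist(coords)), ids=clr.sample_ids)


@dataclasses.dataclass
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame  # samples x axes
    eigenvalue_fractions: np.ndarray | None = None  # pcoa only
    stress: float | None = None  # nmds only


def ordinate(
    dm: DistanceMatrix, method: str = "pcoa", k: int = 2, seed: int = 0
) -> OrdinationResult:
    """Classical PCoA or non-metric MDS of a distance matrix.

    PCoA is classical scaling of the Gower-centered matrix with axes ordered
    by eigenvalue; NMDS minimises stress iteratively starting from the PCoA
    configuration with a fixed seed. ``k`` beyond the matrix rank is
    truncated with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=len(dm.ids))
    eigvals = res.eigvals.to_numpy()
    positive = int((eigvals > max(eigvals.max(), 1.0) * 1e-12).sum())
    kk = min(k, max(positive, 1))
    if kk < k:
        import warnings

        warnings.warn(f"requested {k} axes but rank is {positive}; truncating")
    coords = res.samples.iloc[:, :kk].copy()
    coords.index = list(dm.ids)
    coords.columns = [f"axis_{i + 1}" for i in range(kk)]
    if method == "pcoa":
        total = eigvals[eigvals > 0].sum()
        frac = np.where(eigvals[:kk] > 0, eigvals[:kk] / total, 0.0)
        return OrdinationResult("pcoa", coords, eigenvalue_fractions=frac)
    if method == "nmds":
        from sklearn.manifold import MDS

        mds = MDS(
            n_components=kk,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            random_state=seed,
            normalized_stress=True,
        )
        emb = mds.fit_transform(dm.data, init=coords.to_numpy())
        out = pd.DataFrame(emb, index=list(dm.ids),
                           columns=[f"axis_{i + 1}" for i in range(kk)])
        return OrdinationResult("nmds", out, stress=float(mds.stress_))
    raise ValueError(f"unknown ordination method: {method!r}")


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Distance-based pseudo-F from the squared-distance partition."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    a = n_groups
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _distinct_assignment_count(group_sizes: Sequence[int]) -> int:
    n = sum(group_sizes)
    total = math.factorial(n)
    for g in group_sizes:
        total //= math.factorial(g)
    return total


def _enumerate_assignments(codes: np.ndarray, n_groups: int):
    """Yield every distinct assignment of the multiset of labels."""
    n = len(codes)
    sizes = [int((codes == g).sum()) for g in range(n_groups)]

    def rec(remaining: tuple[int, ...], sizes_left: list[int], group: int):
        if group == n_groups - 1:
            out = np.empty(n, dtype=int)
            for i in remaining:
                out[i] = group
            yield list(remaining), out
            return
        for chosen in itertools.combinations(remaining, sizes_left[group]):
            rest = tuple(i for i in remaining if i not in set(chosen))
            for _, partial in rec(rest, sizes_left, group + 1):
                for i in chosen:
                    partial[i] = group
                yield chosen, partial

    for _, assignment in rec(tuple(range(n)), sizes, 0):
        yield assignment


def _permutation_p(
    d2_or_values,
    codes: np.ndarray,
    n_groups: int,
    stat_fn,
    n_permutations: int,
    seed: int | None,
) -> tuple[float, float, int, str]:
    observed = stat_fn(d2_or_values, codes, n_groups)
    sizes = [int((codes == g).sum()) for g in range(n_groups)]
    n_assign = _distinct_assignment_count(sizes)
    if n_assign <= 10 * n_permutations:
        count = 0
        total = 0
        for assignment in _enumerate_assignments(codes, n_groups):
            total += 1
            if stat_fn(d2_or_values, assignment, n_groups) >= observed - 1e-12:
                count += 1
        return observed, count / total, total, "exact"
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if stat_fn(d2_or_values, perm, n_groups) >= observed - 1e-12:
            count += 1
    return observed, (1 + count) / (1 + n_permutations), n_permutations, "permutation"


def _codes(dm_ids: Sequence[str], groups: Mapping[str, str] | pd.Series):
    labels = pd.Series(groups).loc[list(dm_ids)]
    uniq = sorted(labels.unique())
    codes = labels.map({g: i for i, g in enumerate(uniq)}).to_numpy()
    return codes, uniq


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Distance-based one-factor PERMANOVA.

    The pseudo-F partitions the summed squared distances within and between
    groups. The p-value comes from complete enumeration of distinct label
    assignments when their number is at most ``10 * n_permutations``
    (identity included, no add-one), otherwise from random label
    permutations with the add-one convention.
    """
    codes, uniq = _codes(dm.ids, groups)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = [int((codes == g).sum()) for g in range(len(uniq))]
    if min(sizes) < 2:
        raise ValueError(f"every group needs >= 2 samples, got sizes {sizes}")
    d2 = np.asarray(dm.data) ** 2
    f, p, nperm, method = _permutation_p(
        d2, codes, len(uniq), _pseudo_f, n_permutations, seed
    )
    return PermutationTestResult(f, p, nperm, seed, method)


def _dispersion_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(values)
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    scale = float(np.abs(values).max()) ** 2 + 1e-300
    if sst <= scale * 1e-20:  # all distances equal: no dispersion contrast
        return 0.0
    ssb = 0.0
    for g in range(n_groups):
        sub = values[codes == g]
        ssb += len(sub) * (sub.mean() - grand) ** 2
    ssw = sst - ssb
    if ssw <= sst * 1e-12:
        return np.inf
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def dispersion_test(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Betadisper-style homogeneity-of-dispersion test.

    Each sample's distance to its group centroid is computed in the PCoA
    coordinate space spanned by all positive-eigenvalue axes; a one-way F on
    those distances is assessed by permuting group labels over the fixed
    distances.
    """
    codes, uniq = _codes(dm.ids, groups)
    if len(uniq) < 2:
        raise ValueError("dispersion test needs >= 2 groups")
    sizes = [int((codes == g).sum()) for g in range(len(uniq))]
    if min(sizes) < 2:
        raise ValueError(f"every group needs >= 2 samples, got sizes {sizes}")
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=len(dm.ids))
    eig = res.eigvals.to_numpy()
    keep = eig > max(abs(eig).max(), 1.0) * 1e-12
    coords = res.samples.to_numpy()[:, keep]
    dist = np.empty(len(codes))
    for g in range(len(uniq)):
        idx = np.flatnonzero(codes == g)
        centroid = coords[idx].mean(axis=0)
        dist[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p, nperm, method = _permutation_p(
            dist, codes, len(uniq), _dispersion_f, n_permutations, seed
        )
    return PermutationTestResult(f, p, nperm, seed, method)
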