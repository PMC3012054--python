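"""Shared information-theoretic and enrichment statistics.

Everything downstream of motif scanning runs through here: maximum-entropy
(equal-population) discretization of quantitative profiles, plug-in mutual
information in bits, empirical randomization tests with the strict
"beats every null draw" significance rule, jackknife robustness, and exact
hypergeometric enrichment with Bonferroni correction.

The permutation null for a binary presence profile against class labels is
sampled exactly: under a uniform permutation of the labels, the per-class
carrier counts follow a multivariate hypergeometric distribution, so null MI
values are drawn from that distribution directly instead of materializing
label permutations. Statistics that are not a function of the joint table
alone (e.g. positional bias) permute labels explicitly elsewhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from scipy.stats import hypergeom

__all__ = [
    "derive_seed",
    "discretize",
    "mutual_information",
    "ShuffleTest",
    "shuffle_test",
    "conditional_mi_test",
    "robustness",
    "hypergeom_tail",
    "EnrichmentCell",
    "class_enrichment",
]

_LOG2 = np.log(2.0)
_P_FLOOR = 1e-300


def derive_seed(master: int, *parts) -> int:
    """Derive a reproducible sub-seed (< 2^31) from a master seed and labels.

    Every source of randomness in the package draws its seed through this
    function, so a single master seed makes a whole run reproducible while
    keeping the per-component streams independent.
    """
    key = f"{master}|" + "|".join(str(p) for p in parts)
    h = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def discretize(values, n_bins: int) -> np.ndarray:
    """Equal-population (maximum-entropy) binning of quantitative values.

    Values are ranked ascending with ties broken by input position (stable
    sort) and split into ``n_bins`` contiguous bins whose sizes differ by at
    most one, larger bins first. Returns the bin index of each input value
    (0 = smallest values). This makes no assumption about the distribution of
    the measurements, which is why it suits arbitrary proteomic data.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if n_bins > n:
        raise ValueError(f"n_bins ({n_bins}) exceeds number of values ({n})")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite value in quantitative profile")
    order = np.argsort(values, kind="stable")
    q, r = divmod(n, n_bins)
    sizes = np.full(n_bins, q, dtype=np.int64)
    sizes[:r] += 1  # larger bins first
    classes = np.empty(n, dtype=np.int64)
    classes[order] = np.repeat(np.arange(n_bins), sizes)
    return classes


def _mi_from_joint(counts: np.ndarray) -> float:
    """Plug-in MI in bits from a 2-D contingency table of counts."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(p, p) - xlogy(p, px * py)
    return float(terms.sum() / _LOG2)


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two class-index vectors, in bits.

    MI = sum_ab p(a,b) log2[p(a,b) / (p(a) p(b))], with 0 log 0 := 0.
    Symmetric and non-negative.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("profiles have different lengths")
    if x.size == 0:
        raise ValueError("empty profiles")
    cx = int(x.max()) + 1
    cy = int(y.max()) + 1
    joint = np.bincount(x * cy + y, minlength=cx * cy).reshape(cx, cy)
    return _mi_from_joint(joint)


def _mi_binary_vs_classes(k: np.ndarray, class_sizes: np.ndarray, K) -> np.ndarray:
    """Vectorized MI (bits) of a binary profile vs classes from carrier counts.

    ``k``: (..., C) carriers per class; ``class_sizes``: (C,); ``K``: total
    carriers, scalar or broadcastable. Used for both observed values and the
    sampled permutation null.
    """
    k = np.asarray(k, dtype=float)
    n_c = np.asarray(class_sizes, dtype=float)
    N = n_c.sum()
    K = np.asarray(K, dtype=float)
    if K.ndim < k.ndim - 1:
        K = K.reshape(K.shape + (1,) * (k.ndim - 1 - K.ndim))
    miss = n_c - k
    K_ = K[..., None] if K.ndim == k.ndim - 1 else K
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = xlogy(k, k * N) - xlogy(k, K_ * n_c)
        t2 = xlogy(miss, miss * N) - xlogy(miss, (N - K_) * n_c)
    return (t1 + t2).sum(axis=-1) / (N * _LOG2)


@dataclass
class ShuffleTest:
    """Result of an empirical randomization test of an MI value.

    ``passed`` uses the strict rule: the observed MI must exceed every one of
    the ``n_rand`` null values. ``empirical_p`` uses the (1 + #null >= obs) /
    (1 + n_rand) estimator, so it can never be zero.
    """

    observed_mi: float
    z_score: float
    empirical_p: float
    passed: bool
    n_rand: int
    seed: int


def _summarize_null(observed: float, null: np.ndarray, n_rand: int, seed: int) -> ShuffleTest:
    mean = float(null.mean())
    sd = float(null.std())
    z = 0.0 if sd == 0 else (observed - mean) / sd
    n_ge = int(np.count_nonzero(null >= observed - 1e-15))
    p = (1 + n_ge) / (1 + n_rand)
    passed = bool(observed > null.max() + 1e-15)
    return ShuffleTest(float(observed), z, p, passed, n_rand, seed)


def shuffle_test(motif_present, behavior, n_rand: int = 10000, seed: int = 0) -> ShuffleTest:
    """Randomization test of MI between a binary presence profile and classes.

    The null distribution is that of MI under uniform permutations of the
    behavior labels (sampled exactly via the multivariate hypergeometric
    distribution of per-class carrier counts). A motif is deemed significant
    (``passed``) only if its MI is greater than all ``n_rand`` null values.
    """
    present = np.asarray(motif_present, dtype=bool)
    behavior = np.asarray(behavior, dtype=np.int64)
    if present.shape != behavior.shape:
        raise ValueError("profiles have different lengths")
    C = int(behavior.max()) + 1
    class_sizes = np.bincount(behavior, minlength=C)
    K = int(present.sum())
    k_obs = np.bincount(behavior[present], minlength=C)
    observed = float(_mi_binary_vs_classes(k_obs, class_sizes, K))
    rng = np.random.default_rng(seed)
    if K == 0 or K == present.size:
        null = np.zeros(n_rand)
    else:
        draws = rng.multivariate_hypergeometric(class_sizes, K, size=n_rand)
        null = _mi_binary_vs_classes(draws, class_sizes, K)
    return _summarize_null(observed, null, n_rand, seed)


def conditional_mi_test(candidate, behavior, given, n_rand: int = 1000, seed: int = 0) -> ShuffleTest:
    """Test whether ``candidate`` carries behavior information beyond ``given``.

    The statistic is the conditional mutual information
    CMI = sum_g p(g) MI(candidate; behavior | given = g); the null permutes
    behavior labels independently within each stratum of ``given``, so a
    candidate that merely restates an already-accepted profile scores zero.
    Used as the redundancy filter during discovery.
    """
    cand = np.asarray(candidate, dtype=bool)
    behavior = np.asarray(behavior, dtype=np.int64)
    given = np.asarray(given, dtype=bool)
    if not (cand.shape == behavior.shape == given.shape):
        raise ValueError("profiles have different lengths")
    N = cand.size
    C = int(behavior.max()) + 1
    rng = np.random.default_rng(seed)
    observed = 0.0
    null = np.zeros(n_rand)
    for g in (False, True):
        stratum = given == g
        n_g = int(stratum.sum())
        if n_g == 0:
            continue
        w = n_g / N
        beh_g = behavior[stratum]
        sizes_g = np.bincount(beh_g, minlength=C)
        K_g = int(cand[stratum].sum())
        k_obs = np.bincount(beh_g[cand[stratum]], minlength=C)
        observed += w * float(_mi_binary_vs_classes(k_obs, sizes_g, K_g))
        if 0 < K_g < n_g:
            draws = rng.multivariate_hypergeometric(sizes_g, K_g, size=n_rand)
            null += w * _mi_binary_vs_classes(draws, sizes_g, K_g)
    return _summarize_null(observed, null, n_rand, seed)


def robustness(
    motif,
    proteome,
    behavior,
    n_trials: int = 10,
    keep_fraction: float = 2 / 3,
    n_rand: int = 1000,
    seed: int = 0,
) -> int:
    """Jackknife robustness score in 0..n_trials (default 0..10).

    Each trial keeps a random ``keep_fraction`` subset of the analysis
    universe, restricts the motif profile to that subset, and reruns the
    strict randomization test; the score is the number of trials passed.
    Subsets that empty a behavior class are resampled (up to 100 attempts,
    then the trial counts as a failure).
    """
    from .motif import build_profile  # local import to avoid a cycle

    if not (0 < keep_fraction < 1):
        raise ValueError("keep_fraction must be in (0, 1)")
    profile = build_profile(proteome, motif, behavior.ids)
    present = profile.present
    classes = behavior.classes
    C = int(classes.max()) + 1
    n = classes.size
    m = int(np.floor(keep_fraction * n))
    score = 0
    for trial in range(n_trials):
        rng = np.random.default_rng(derive_seed(seed, "robustness", trial))
        subset = None
        for _attempt in range(100):
            idx = rng.choice(n, size=m, replace=False)
            if len(np.unique(classes[idx])) == C:
                subset = idx
                break
        if subset is None:
            continue
        t = shuffle_test(
            present[subset], classes[subset], n_rand=n_rand, seed=derive_seed(seed, "robustness-test", trial)
        )
        if t.passed:
            score += 1
    return score


def hypergeom_tail(k: int, K: int, n: int, N: int, tail: str = "upper") -> float:
    """Exact hypergeometric tail: upper = P(X >= k), lower = P(X <= k).

    ``X`` counts successes when drawing ``n`` items from a universe of ``N``
    containing ``K`` successes.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if tail == "upper":
        return float(hypergeom.sf(k - 1, N, K, n))
    if tail == "lower":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class EnrichmentCell:
    """Per-class over/under-representation of a motif (one heatmap cell).

    ``signed_score`` is -log10(p_over) when over-representation is the smaller
    tail (positive values = over-represented) and +log10(p_under) otherwise
    (negative values = under-represented). ``significant`` applies a
    Bonferroni factor of (number of classes x 2 tails).
    """

    class_index: int
    p_over: float
    p_under: float
    signed_score: float
    significant: bool


def class_enrichment(profile, behavior, alpha: float = 0.05) -> list[EnrichmentCell]:
    """Hypergeometric over/under-representation of carriers in every class."""
    present = np.asarray(profile.present, dtype=bool)
    classes = behavior.classes
    C = behavior.n_classes
    N = classes.size
    K = int(present.sum())
    bonferroni = 2 * C
    cells = []
    for c in range(C):
        in_class = classes == c
        n = int(in_class.sum())
        k = int(present[in_class].sum())
        p_over = hypergeom_tail(k, K, n, N, "upper")
        p_under = hypergeom_tail(k, K, n, N, "lower")
        if p_over <= p_under:
            score = -np.log10(max(p_over, _P_FLOOR))
        else:
            score = np.log10(max(p_under, _P_FLOOR))
        significant = min(p_over, p_under) * bonferroni < alpha
        cells.append(EnrichmentCell(c, p_over, p_under, float(score), bool(significant)))
    return cells
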