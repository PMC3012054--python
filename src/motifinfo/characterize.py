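"""Post-discovery motif characterization.

Covers positional bias along the normalized linear sequence, motif-motif
co-occurrence and co-localization, domain co-occurrence and the domain overlap
z-score (positive = domain signature, negative = the motif lies apart from the
domain), flat term enrichment, disorder scoring, and similarity to a catalog
of known motifs. All randomized p-values use the same strict empirical
machinery as discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats
from .motif import ALPHABET, Motif, MotifProfile, encode_sequence, get_encoded

_MIN_INSTANCES = 20
_MIN_CO_CARRIERS = 20


# ---------------------------------------------------------------------------
# shared helper: MI between instance-level labels with explicit label shuffles


def _label_shuffle_mi(x: np.ndarray, labels: np.ndarray, n_rand: int, seed: int):
    """Observed MI(x; labels) plus a null from n_rand label permutations.

    Used where the statistic lives on instances rather than proteins, so the
    exact table-sampling shortcut does not apply.
    """
    observed = stats.mutual_information(x, labels)
    rng = np.random.default_rng(seed)
    cx = int(x.max()) + 1
    cy = int(labels.max()) + 1
    n = x.size
    perms = rng.permuted(np.tile(labels, (n_rand, 1)), axis=1)
    flat = (np.arange(n_rand)[:, None] * (cx * cy) + x[None, :] * cy + perms).ravel()
    joint = np.bincount(flat, minlength=n_rand * cx * cy).reshape(n_rand, cx, cy)
    nn = float(n)
    p = joint / nn
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    from scipy.special import xlogy

    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(p, p) - xlogy(p, px * py)
    null = terms.sum(axis=(1, 2)) / np.log(2.0)
    return stats._summarize_null(observed, null, n_rand, seed)


@dataclass
class PositionalBias:
    """MI between normalized instance position and host-protein class.

    ``histogram_targets`` / ``histogram_others`` count instances in 10
    normalized-position bins, split into proteins of significantly
    over-represented ("target") classes versus all other proteins.
    ``insufficient`` marks an abstention when fewer than 20 instances exist.
    """

    mi_bits: float | None
    z_score: float | None
    empirical_p: float | None
    histogram_targets: np.ndarray
    histogram_others: np.ndarray
    insufficient: bool = False


def _instance_table(profile: MotifProfile, proteome):
    """Flatten instances: (host protein index in profile order, start)."""
    prot_idx = []
    starts = []
    for i, inst in enumerate(profile.instances):
        for s in inst:
            prot_idx.append(i)
            starts.append(int(s))
    return np.asarray(prot_idx, dtype=np.int64), np.asarray(starts, dtype=np.int64)


def positional_bias(
    profile: MotifProfile,
    behavior,
    proteome,
    n_pos_bins: int = 10,
    n_rand: int = 10000,
    seed: int = 0,
) -> PositionalBias:
    """Test whether motif instance position is informative of behavior.

    Position is normalized to sequence length as start / (L - w + 1), the
    number of valid start offsets, then binned into ``n_pos_bins`` equal-width
    bins; the null shuffles host-class labels across instances. Abstains
    (``insufficient=True``) below 20 instances.
    """
    w = profile.motif.width
    prot_idx, starts = _instance_table(profile, proteome)
    lengths = np.array([len(proteome.sequence(pid)) for pid in profile.ids], dtype=np.int64)
    if prot_idx.size:
        norm = starts / (lengths[prot_idx] - w + 1)
        bins = np.minimum((norm * n_pos_bins).astype(np.int64), n_pos_bins - 1)
        labels = behavior.classes[prot_idx]
    else:
        bins = np.zeros(0, dtype=np.int64)
        labels = np.zeros(0, dtype=np.int64)
    target_classes = {
        c.class_index
        for c in stats.class_enrichment(profile, behavior)
        if c.significant and c.signed_score > 0
    }
    is_target = np.isin(labels, sorted(target_classes)) if labels.size else np.zeros(0, bool)
    hist_t = np.bincount(bins[is_target], minlength=n_pos_bins)
    hist_o = np.bincount(bins[~is_target], minlength=n_pos_bins)
    if prot_idx.size < _MIN_INSTANCES:
        return PositionalBias(None, None, None, hist_t, hist_o, insufficient=True)
    t = _label_shuffle_mi(bins, labels, n_rand, seed)
    return PositionalBias(t.observed_mi, t.z_score, t.empirical_p, hist_t, hist_o)


@dataclass
class MotifInteraction:
    """Pairwise motif relationship: co-occurrence (presence MI over the
    proteome) and co-localization (distance-binned MI among co-carriers)."""

    motif_a: Motif
    motif_b: Motif
    cooccurrence_mi: float
    cooccurrence_p: float
    direction: str  # "co-occur" | "co-avoid"
    colocalized: bool
    colocalization_p: float | None


def cooccurrence(profile_a: MotifProfile, profile_b: MotifProfile, n_rand: int = 10000, seed: int = 0):
    """MI between two binary presence profiles with a permutation null.

    Returns (mi_bits, empirical_p, direction); direction is "co-occur" when
    the observed joint-presence count exceeds its independence expectation,
    otherwise "co-avoid".
    """
    a = np.asarray(profile_a.present, dtype=bool)
    b = np.asarray(profile_b.present, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles over different universes")
    t = stats.shuffle_test(a, b.astype(np.int64), n_rand=n_rand, seed=seed)
    N = a.size
    joint = int((a & b).sum())
    expected = a.sum() * b.sum() / N
    direction = "co-occur" if joint > expected else "co-avoid"
    return t.observed_mi, t.empirical_p, direction


def colocalization(
    profile_a: MotifProfile,
    profile_b: MotifProfile,
    behavior,
    n_dist_bins: int = 3,
    n_rand: int = 10000,
    seed: int = 0,
):
    """Test whether the distance between two motifs is informative of behavior.

    For each protein carrying both motifs, the distance is the minimum
    |start_a - start_b| over instance pairs; distances are split into
    ``n_dist_bins`` equally populated bins and their MI with the host class is
    tested by shuffling class labels among co-carrying proteins. Returns
    (mi_bits, empirical_p) or (None, None) below 20 co-carriers.
    """
    co = np.flatnonzero(np.asarray(profile_a.present) & np.asarray(profile_b.present))
    if co.size < _MIN_CO_CARRIERS:
        return None, None
    dists = np.array(
        [
            int(np.min(np.abs(profile_a.instances[i][:, None] - profile_b.instances[i][None, :])))
            for i in co
        ],
        dtype=np.int64,
    )
    bins = stats.discretize(dists.astype(float), n_dist_bins)
    labels = behavior.classes[co]
    t = _label_shuffle_mi(bins, labels, n_rand, seed)
    return t.observed_mi, t.empirical_p


def interaction(
    profile_a: MotifProfile,
    profile_b: MotifProfile,
    behavior,
    n_rand: int = 10000,
    alpha: float = 0.01,
    seed: int = 0,
) -> MotifInteraction:
    """Full pairwise relationship used by the interaction map output."""
    mi, p, direction = cooccurrence(profile_a, profile_b, n_rand, stats.derive_seed(seed, "cooc"))
    cmi, cp = colocalization(profile_a, profile_b, behavior, 3, n_rand, stats.derive_seed(seed, "coloc"))
    colocalized = cp is not None and cp < alpha
    return MotifInteraction(profile_a.motif, profile_b.motif, mi, p, direction, colocalized, cp)


# ---------------------------------------------------------------------------
# domains


@dataclass
class DomainReport:
    """Per-domain co-occurrence p and positional overlap z for one motif."""

    domain_name: str
    cooccurrence_p: float
    overlap_z: float | None
    n_carriers_overlap: int


def _intersecting_start_count(intervals, L: int, w: int) -> int:
    """Number of width-w start offsets whose window intersects any interval."""
    ranges = []
    for a, b in intervals:
        lo = max(0, a - w + 1)
        hi = min(L - w, b - 1)
        if lo <= hi:
            ranges.append((lo, hi + 1))  # half-open
    merged = []
    for lo, hi in sorted(ranges):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return sum(hi - lo for lo, hi in merged)


def domain_report(profile: MotifProfile, domains, proteome) -> list[DomainReport]:
    """Per-domain co-occurrence and overlap statistics, ranked by p ascending.

    Co-occurrence: upper hypergeometric tail of the motif-carrier / domain-
    carrier intersection in the analysis universe. Overlap z: over all motif
    instances in proteins carrying the domain, compares the number of
    instances intersecting a domain interval with its expectation under
    uniform random placement of each instance within its protein
    (z = (sum O_i - sum p_i) / sqrt(sum p_i (1 - p_i))). Positive z marks a
    domain signature, negative z a motif lying apart from the domain.
    """
    w = profile.motif.width
    universe = set(profile.ids)
    carriers = profile.carrier_ids()
    N = len(profile.ids)
    K = len(carriers)
    reports = []
    for name in domains.domain_names():
        dom_carriers = domains.carriers(name) & universe
        n = len(dom_carriers)
        if n == 0:
            continue
        k = len(carriers & dom_carriers)
        p_co = stats.hypergeom_tail(k, K, n, N, "upper")
        obs = 0.0
        exp = 0.0
        var = 0.0
        n_overlap_carriers = 0
        for pid, starts in zip(profile.ids, profile.instances):
            if len(starts) == 0 or pid not in dom_carriers:
                continue
            n_overlap_carriers += 1
            L = len(proteome.sequence(pid))
            ivs = domains.intervals_of(pid, name)
            c = _intersecting_start_count(ivs, L, w)
            m = L - w + 1
            p_i = c / m
            for s in starts:
                hit = any(s < b and s + w > a for a, b in ivs)
                obs += 1.0 if hit else 0.0
                exp += p_i
                var += p_i * (1.0 - p_i)
        z = None if var == 0 else (obs - exp) / np.sqrt(var)
        reports.append(DomainReport(name, p_co, z, n_overlap_carriers))
    reports.sort(key=lambda r: (r.cooccurrence_p, r.domain_name))
    return reports


# ---------------------------------------------------------------------------
# terms


def term_enrichment(carriers: set, terms, universe: set, alpha: float = 0.05):
    """Upper-tail hypergeometric enrichment of motif carriers in each term.

    Bonferroni-corrects over the number of terms tested; returns
    (term_id, p, corrected_p) ranked by p ascending.
    """
    if not carriers <= universe:
        raise ValueError("carriers must be a subset of the universe")
    N = len(universe)
    K = len(carriers)
    n_tests = len(terms.terms)
    out = []
    for term, members in terms.terms.items():
        members = members & universe
        n = len(members)
        if n == 0:
            continue
        k = len(carriers & members)
        p = stats.hypergeom_tail(k, K, n, N, "upper")
        out.append((term, p, min(1.0, p * n_tests)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# disorder


def _instance_disorder_flags(profile: MotifProfile, mask, proteome) -> np.ndarray:
    """Per-instance flag: >50% of the instance's residues lie in disorder."""
    w = profile.motif.width
    flags = []
    for pid, starts in zip(profile.ids, profile.instances):
        if len(starts) == 0:
            continue
        ivs = mask.intervals.get(pid, [])
        for s in starts:
            covered = sum(max(0, min(s + w, b) - max(s, a)) for a, b in ivs)
            flags.append(covered * 2 > w)
    return np.asarray(flags, dtype=bool)


def disorder_score(profile: MotifProfile, mask, proteome) -> float:
    """Fraction of motif instances lying in disordered regions.

    An instance counts as disordered when more than half of its residues fall
    inside (merged) disorder intervals. Raises on zero instances.
    """
    flags = _instance_disorder_flags(profile, mask, proteome)
    if flags.size == 0:
        raise ValueError("disorder score requires at least one motif instance")
    return float(flags.mean())


def kmer_disorder_percentile(motif_score: float, motif_width: int, mask, proteome) -> float:
    """Percentile of a motif's disorder score among all same-width exact k-mers.

    Every width-w window of canonical residues in the proteome contributes one
    instance to its k-mer; each k-mer's score is the fraction of its instances
    with >50% disordered residues. Returns 100 x (fraction of k-mers scoring
    below the motif, counting ties as half).
    """
    enc = get_encoded(proteome)
    w = motif_width
    disordered = np.zeros(enc.total + 1, dtype=np.int64)
    for pid, ivs in mask.intervals.items():
        try:
            i = enc.ids.index(pid)
        except ValueError:
            continue
        off = enc.starts[i]
        for a, b in ivs:
            disordered[off + a] += 1
            disordered[off + b] -= 1
    per_residue = np.cumsum(disordered[:-1]) > 0
    cum = np.concatenate([[0], np.cumsum(per_residue)])
    valid = enc.valid_starts(w).copy()
    codes = enc.codes.astype(np.int64)
    kmer_code = np.zeros(enc.total, dtype=np.int64)
    ok = np.ones(enc.total, dtype=bool)
    for j in range(w):
        shifted = np.full(enc.total, 20, dtype=np.int64)
        shifted[: enc.total - j] = codes[j:]
        ok &= shifted < 20
        kmer_code = kmer_code * 20 + np.where(shifted < 20, shifted, 0)
    valid &= ok
    idx = np.flatnonzero(valid)
    cover = cum[idx + w] - cum[idx]
    flag = cover * 2 > w
    uniq, inv = np.unique(kmer_code[idx], return_inverse=True)
    n_inst = np.bincount(inv)
    n_dis = np.bincount(inv, weights=flag.astype(float))
    scores = n_dis / n_inst
    less = int(np.count_nonzero(scores < motif_score - 1e-12))
    equal = int(np.count_nonzero(np.abs(scores - motif_score) <= 1e-12))
    return 100.0 * (less + 0.5 * equal) / scores.size


# ---------------------------------------------------------------------------
# known-motif similarity


_WILDCARD_CONTRIBUTION = 0.05


def motif_similarity(motif_a: Motif, motif_b: Motif) -> float:
    """Alignment-free similarity of two degenerate motifs, in [0, 1].

    Scans all ungapped relative offsets with at least 2 aligned positions; the
    score of an offset is the mean over aligned positions of the Jaccard index
    |A n B| / |A u B| of the two allowed-sets, except that any aligned
    position involving a wildcard contributes a fixed 0.05 (so wildcard-heavy
    patterns cannot match everything). Returns the maximum over offsets.
    Symmetric; equals 1 only for set-identical, wildcard-free alignments.
    """
    wa, wb = motif_a.width, motif_b.width
    best = 0.0
    for offset in range(-(wb - 2), wa - 1):
        scores = []
        for j in range(wa):
            jb = j - offset
            if 0 <= jb < wb:
                sa, sb = motif_a.sets[j], motif_b.sets[jb]
                if len(sa) == 20 or len(sb) == 20:
                    scores.append(_WILDCARD_CONTRIBUTION)
                else:
                    scores.append(len(sa & sb) / len(sa | sb))
        if len(scores) >= 2:
            best = max(best, sum(scores) / len(scores))
    return best


def best_match(motif: Motif, catalog, threshold: float = 0.5):
    """Best-scoring catalog entry above ``threshold``.

    ``catalog`` is an iterable of (name, Motif, context) triples as loaded by
    :func:`motifinfo.io.read_known_motifs`. Returns (name, pattern-string,
    score) or None. Ties break on catalog order.
    """
    best_entry = None
    best_score = threshold
    for name, cat_motif, _context in catalog:
        s = motif_similarity(motif, cat_motif)
        if s > best_score:
            best_score = s
            best_entry = (name, str(cat_motif), s)
    return best_entry
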