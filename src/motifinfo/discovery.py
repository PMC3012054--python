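"""Two-step motif discovery: exhaustive k-mer seeding scored by mutual
information, then greedy degenerate refinement, strict randomization gating,
jackknife robustness, and a conditional-MI redundancy filter.

The search is deterministic given the configuration's master seed: proposal
order in the greedy refinement is fixed (position ascending, residue
alphabetical), seed k-mers are ranked by MI with lexicographic tie-breaks, and
every randomized test derives its seed from the master seed and a component
label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

from . import stats
from .motif import ALPHABET, Motif, MotifProfile, build_profile, get_encoded, pwm_from_instances

logger = logging.getLogger("motifinfo")

_EPS = 1e-12
_FULL = frozenset(ALPHABET)


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the discovery pipeline.

    ``k_values`` are the seed k-mer widths explored (motif width is fixed at
    seed width; multi-width discovery comes from iterating k). ``n_rand``
    permutations back the strict significance rule (a motif must beat every
    null draw). ``max_degeneracy_per_position`` bounds allowed-set growth
    during refinement (the interior wildcard is exempt).
    """

    k_values: tuple[int, ...] = (3, 4, 5)
    min_carrier_proteins: int = 10
    n_rand: int = 10000
    seed: int = 0
    max_refine_passes: int = 10
    max_degeneracy_per_position: int = 5
    max_motifs: int = 50
    redundancy_n_rand: int = 1000
    robustness_floor: int = 6
    robustness_trials: int = 10
    robustness_n_rand: int = 1000

    def __post_init__(self):
        self.k_values = tuple(sorted(int(k) for k in self.k_values))
        if not self.k_values or any(k < 2 or k > 10 for k in self.k_values):
            raise ValueError("k_values must lie in [2, 10]")
        for name in (
            "min_carrier_proteins",
            "n_rand",
            "max_refine_passes",
            "max_degeneracy_per_position",
            "redundancy_n_rand",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_motifs < 0:
            raise ValueError("max_motifs must be >= 0")

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if f.name == "k_values":
                    v = ",".join(str(k) for k in v)
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path) -> "DiscoveryConfig":
        kwargs = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "k_values":
                    kwargs[key] = tuple(int(k) for k in value.split(",") if k)
                else:
                    kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class MotifResult:
    """A reported motif with its statistics and characterization hooks."""

    motif: Motif
    mi: float
    test: stats.ShuffleTest
    robustness: int
    enrichment: list[stats.EnrichmentCell]
    profile: MotifProfile
    seed_kmer: str
    pwm: np.ndarray | None = None
    robust_enough: bool = True


# ---------------------------------------------------------------------------
# seed enumeration


class _SeedIndex:
    """Exact k-mer carrier index over the analysis universe.

    Maps every k-mer (over canonical residues) to the set of carrier proteins,
    built once per width with vectorized window encoding.
    """

    def __init__(self, enc, universe_rows: np.ndarray, k: int):
        self.k = k
        n_univ = universe_rows.size
        row_of_prot = np.full(enc.n, -1, dtype=np.int64)
        row_of_prot[universe_rows] = np.arange(n_univ)
        codes = enc.codes.astype(np.int64)
        valid = enc.valid_starts(k) & (row_of_prot[enc.prot_of_pos] >= 0)
        kmer_code = np.zeros(enc.total, dtype=np.int64)
        ok = np.ones(enc.total, dtype=bool)
        for j in range(k):
            shifted = np.full(enc.total, 20, dtype=np.int64)
            shifted[: enc.total - j] = codes[j:]
            ok &= shifted < 20
            kmer_code = kmer_code * 20 + np.where(shifted < 20, shifted, 0)
        valid &= ok
        idx = np.flatnonzero(valid)
        prot_rows = row_of_prot[enc.prot_of_pos[idx]]
        # deduplicate (kmer, protein) pairs
        pair_key = kmer_code[idx] * np.int64(n_univ) + prot_rows
        uniq_pairs = np.unique(pair_key)
        self.pair_codes = uniq_pairs // n_univ
        self.pair_rows = (uniq_pairs % n_univ).astype(np.int64)
        self.uniq_codes, self.code_starts = np.unique(self.pair_codes, return_index=True)
        self.code_ends = np.append(self.code_starts[1:], self.pair_codes.size)
        self.n_univ = n_univ

    def carrier_counts(self) -> np.ndarray:
        return self.code_ends - self.code_starts

    def carriers_of(self, code: int) -> np.ndarray:
        """Universe row indices of proteins carrying the exact k-mer."""
        i = np.searchsorted(self.uniq_codes, code)
        return self.pair_rows[self.code_starts[i] : self.code_ends[i]]

    @staticmethod
    def decode(code: int, k: int) -> str:
        out = []
        for _ in range(k):
            out.append(ALPHABET[code % 20])
            code //= 20
        return "".join(reversed(out))

    @staticmethod
    def encode(kmer: str) -> int:
        code = 0
        for a in kmer:
            code = code * 20 + ALPHABET.index(a)
        return code


def _universe_rows(enc, behavior) -> np.ndarray:
    index = {pid: i for i, pid in enumerate(enc.ids)}
    return np.array([index[pid] for pid in behavior.ids], dtype=np.int64)


def _ranked_seeds(proteome, behavior, config):
    """Internal: [(kmer, mi, carriers_row_indices)] ranked by MI desc, ties lexicographic."""
    enc = get_encoded(proteome)
    rows = _universe_rows(enc, behavior)
    classes = behavior.classes
    C = behavior.n_classes
    class_sizes = np.bincount(classes, minlength=C)
    ranked = []
    for k in config.k_values:
        if int(np.int64(20) ** k) * rows.size >= np.iinfo(np.int64).max:
            raise ValueError(f"k={k} too large for the seed index on this proteome")
        idx = _SeedIndex(enc, rows, k)
        counts = idx.carrier_counts()
        keep = np.flatnonzero(counts >= config.min_carrier_proteins)
        if keep.size == 0:
            continue
        # per-kmer carriers-per-class via segment bincount
        class_of_pair = classes[idx.pair_rows]
        seg = np.repeat(np.arange(idx.uniq_codes.size), counts)
        kmat = np.zeros((keep.size, C), dtype=np.int64)
        keep_mask = np.zeros(idx.uniq_codes.size, dtype=bool)
        keep_mask[keep] = True
        sel = keep_mask[seg]
        seg_keep = np.searchsorted(keep, seg[sel])
        np.add.at(kmat, (seg_keep, class_of_pair[sel]), 1)
        mis = stats._mi_binary_vs_classes(kmat, class_sizes, counts[keep].astype(float))
        for pos, code_i in enumerate(keep):
            code = int(idx.uniq_codes[code_i])
            ranked.append(
                (
                    _SeedIndex.decode(code, k),
                    float(mis[pos]),
                    idx.pair_rows[idx.code_starts[code_i] : idx.code_ends[code_i]],
                )
            )
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def enumerate_seeds(proteome, behavior, config: DiscoveryConfig) -> list[tuple[str, float]]:
    """Score every abundant exact k-mer by MI with the behavior profile.

    A k-mer is abundant when it occurs in at least ``min_carrier_proteins``
    distinct proteins of the analysis universe. Returns (kmer, MI bits) sorted
    by MI descending with lexicographic tie-breaks.
    """
    return [(kmer, mi) for kmer, mi, _ in _ranked_seeds(proteome, behavior, config)]


# ---------------------------------------------------------------------------
# greedy refinement


class _RefineEngine:
    """Fast MI evaluation of single-position set changes on a fixed proteome."""

    def __init__(self, enc, universe_rows, behavior):
        self.enc = enc
        self.rows = universe_rows
        self.row_of_prot = np.full(enc.n, -1, dtype=np.int64)
        self.row_of_prot[universe_rows] = np.arange(universe_rows.size)
        self.in_universe = self.row_of_prot[enc.prot_of_pos] >= 0
        self.classes = behavior.classes
        self.C = behavior.n_classes
        self.class_sizes = np.bincount(self.classes, minlength=self.C).astype(float)

    @staticmethod
    def _table(s: frozenset) -> np.ndarray:
        t = np.zeros(21, dtype=bool)
        for a in s:
            t[ALPHABET.index(a)] = True
        return t

    def base_windows(self, sets: list[frozenset], j: int) -> tuple[np.ndarray, np.ndarray]:
        """Window starts matching every position except ``j``, and the residue
        codes those windows expose at position ``j``."""
        enc = self.enc
        w = len(sets)
        m = enc.valid_starts(w) & self.in_universe
        m = m.copy()
        for p in range(w):
            if p == j:
                continue
            lookup = self._table(sets[p])[enc.codes]
            if p == 0:
                m &= lookup
            else:
                m[: enc.total - p] &= lookup[p:]
        idx = np.flatnonzero(m)
        res_j = enc.codes[idx + j]
        return idx, res_j

    def mi_of_candidate(self, idx, res_j, candidate: frozenset) -> float:
        hit = self._table(candidate)[res_j]
        prots = self.enc.prot_of_pos[idx[hit]]
        rows = np.unique(self.row_of_prot[prots])
        K = rows.size
        k_c = np.bincount(self.classes[rows], minlength=self.C)
        return float(stats._mi_binary_vs_classes(k_c, self.class_sizes, float(K)))

    def mi_of_motif(self, sets: list[frozenset]) -> float:
        idx, res_j = self.base_windows(sets, 0)
        return self.mi_of_candidate(idx, res_j, sets[0])


def _proposals(sets: list[frozenset], j: int, config: DiscoveryConfig):
    """Fixed-order proposals at position j: residue additions (alphabetical),
    removals (alphabetical), then the full wildcard for interior positions."""
    s = sets[j]
    w = len(sets)
    out = []
    terminal = j == 0 or j == w - 1
    if len(s) < 20 and len(s) + 1 <= config.max_degeneracy_per_position:
        if not (terminal and len(s) + 1 == 20):  # never create a terminal wildcard
            for a in ALPHABET:
                if a not in s:
                    out.append(s | {a})
    if len(s) >= 2:
        for a in sorted(s):
            out.append(s - {a})
    if 0 < j < w - 1 and len(s) != 20:
        out.append(_FULL)
    return [frozenset(p) for p in out]


def refine(
    seed: Motif,
    proteome,
    behavior,
    config: DiscoveryConfig,
    return_trajectory: bool = False,
):
    """Greedy degenerate refinement of a seed motif.

    Repeatedly sweeps positions left to right; at each position the single
    set change (residue addition bounded by ``max_degeneracy_per_position``,
    residue removal, or interior wildcard) with the largest strict MI increase
    is accepted. Terminates when a full pass accepts nothing or after
    ``max_refine_passes`` passes. The returned motif's MI is never below the
    seed's.
    """
    enc = get_encoded(proteome)
    rows = _universe_rows(enc, behavior)
    engine = _RefineEngine(enc, rows, behavior)
    sets = list(seed.sets)
    cur_mi = engine.mi_of_motif(sets)
    trajectory = [cur_mi]
    w = len(sets)
    for _pass in range(config.max_refine_passes):
        accepted = False
        for j in range(w):
            idx, res_j = engine.base_windows(sets, j)
            best_set = None
            best_mi = cur_mi
            for cand in _proposals(sets, j, config):
                mi = engine.mi_of_candidate(idx, res_j, cand)
                if mi > best_mi + _EPS:
                    best_mi = mi
                    best_set = cand
            if best_set is not None:
                sets[j] = best_set
                cur_mi = best_mi
                trajectory.append(cur_mi)
                accepted = True
        if not accepted:
            break
    refined = Motif(sets)
    if return_trajectory:
        return refined, trajectory
    return refined


# ---------------------------------------------------------------------------
# redundancy + pipeline


def filter_redundant(accepted, candidate: MotifResult, proteome, behavior, config) -> bool:
    """Keep a candidate only if it is conditionally informative given every
    already-accepted motif (conditional-MI randomization test, strict rule,
    short-circuiting on the first failure)."""
    for i, a in enumerate(accepted):
        t = stats.conditional_mi_test(
            candidate.profile.present,
            behavior.classes,
            a.profile.present,
            n_rand=config.redundancy_n_rand,
            seed=stats.derive_seed(config.seed, "redundancy", str(candidate.motif), i),
        )
        if not t.passed:
            return False
    return True


def discover(proteome, behavior, config: DiscoveryConfig) -> list[MotifResult]:
    """Run the full discovery pipeline and return reported motifs.

    Pipeline: enumerate seeds -> strict randomization gate on each seed in
    rank order -> greedy refinement -> strict re-test of the refined motif
    against a fresh null -> redundancy filter against accepted motifs ->
    jackknife robustness -> per-class enrichment. Stops at ``max_motifs``.
    Results are sorted by MI descending; fully deterministic given the config.
    """
    if config.max_motifs == 0:
        return []
    enc = get_encoded(proteome)
    rows = _universe_rows(enc, behavior)
    classes = behavior.classes
    n_univ = rows.size
    ranked = _ranked_seeds(proteome, behavior, config)
    logger.info("discovery: %d abundant seed k-mers", len(ranked))
    results: list[MotifResult] = []
    seen_motifs: set[Motif] = set()
    n_gated = 0
    for rank, (kmer, _mi, carrier_rows) in enumerate(ranked):
        if len(results) >= config.max_motifs:
            break
        present = np.zeros(n_univ, dtype=bool)
        present[carrier_rows] = True
        gate = stats.shuffle_test(
            present, classes, n_rand=config.n_rand, seed=stats.derive_seed(config.seed, "seed-gate", kmer)
        )
        if not gate.passed:
            continue
        n_gated += 1
        seed_motif = Motif([frozenset(a) for a in kmer])
        refined = refine(seed_motif, proteome, behavior, config)
        if refined in seen_motifs:
            continue
        profile = build_profile(proteome, refined, behavior.ids)
        retest = stats.shuffle_test(
            profile.present,
            classes,
            n_rand=config.n_rand,
            seed=stats.derive_seed(config.seed, "refined-gate", str(refined)),
        )
        if not retest.passed:
            continue
        candidate = MotifResult(
            motif=refined,
            mi=retest.observed_mi,
            test=retest,
            robustness=0,
            enrichment=[],
            profile=profile,
            seed_kmer=kmer,
        )
        if not filter_redundant(results, candidate, proteome, behavior, config):
            seen_motifs.add(refined)
            continue
        candidate.robustness = stats.robustness(
            refined,
            proteome,
            behavior,
            n_trials=config.robustness_trials,
            n_rand=config.robustness_n_rand,
            seed=stats.derive_seed(config.seed, "robustness", str(refined)),
        )
        candidate.robust_enough = candidate.robustness >= config.robustness_floor
        candidate.enrichment = stats.class_enrichment(profile, behavior)
        candidate.pwm = pwm_from_instances(profile, proteome) if profile.n_instances() else None
        results.append(candidate)
        seen_motifs.add(refined)
        logger.info(
            "accepted motif %s (MI=%.4f bits, z=%.1f, robustness=%d/%d)",
            refined,
            candidate.mi,
            retest.z_score,
            candidate.robustness,
            config.robustness_trials,
        )
    logger.info(
        "discovery: %d seeds passed the gate, %d motifs reported", n_gated, len(results)
    )
    results.sort(key=lambda r: (-r.mi, str(r.motif)))
    return results
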