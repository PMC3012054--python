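"""Synthetic proteomes with planted ground truth.

Generates i.i.d.-residue proteomes, behavior class assignments, planted motif
instances at a chosen penetrance and positional mode, co-occurring motif pairs
at controlled spacing, synthetic domains, and quantitative behaviors coupled
to motif presence. Every generator is deterministic per seed and records an
exact :class:`SyntheticTruth` so recovery can be scored without re-deriving
anything from the emitted sequences.

Planted instances overwrite sequence content in place (lengths never change),
so recorded positions are exact. Proteins that happen to match a planted motif
by chance are recorded separately as "incidental" carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BehaviorProfile, DomainAnnotations, Proteome
from .motif import ALPHABET, Motif, build_profile

_MIN_LENGTH = 20  # 2 x the maximum supported motif width


@dataclass
class PlantedMotif:
    motif: Motif
    carrier_ids: set[str]
    instance_positions: dict[str, int]
    target_class: int
    penetrance: float
    incidental_ids: set[str] = field(default_factory=set)


@dataclass
class PlantedPair:
    motif_a: Motif
    motif_b: Motif
    carrier_ids: set[str]
    positions: dict[str, tuple[int, int]]
    distances: dict[str, int]
    target_class: int


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything planted into a synthetic proteome."""

    planted: list[PlantedMotif] = field(default_factory=list)
    pair_truth: list[PlantedPair] = field(default_factory=list)
    domain_truth: DomainAnnotations | None = None


def random_proteome(
    n: int,
    length_mean: int = 400,
    length_sd: int = 100,
    residue_freqs=None,
    seed: int = 0,
) -> Proteome:
    """I.i.d.-residue proteome with truncated-normal lengths (min 20).

    ``residue_freqs`` is a length-20 probability vector over the alphabetical
    amino-acid order (default uniform).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if residue_freqs is None:
        freqs = np.full(20, 1 / 20)
    else:
        freqs = np.asarray(residue_freqs, dtype=float)
        if freqs.shape != (20,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ValueError("residue_freqs must be 20 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    width = len(str(n - 1))
    entries = []
    alphabet = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    for i in range(n):
        L = 0
        while L < _MIN_LENGTH:
            L = int(round(rng.normal(length_mean, length_sd)))
        codes = rng.choice(20, size=L, p=freqs)
        seq = alphabet[codes].tobytes().decode("ascii")
        entries.append((f"P{i:0{width}d}", seq))
    return Proteome(entries)


def random_class_profile(
    proteome: Proteome, class_sizes, seed: int = 0, labels=None
) -> BehaviorProfile:
    """Randomly partition the proteome into classes of the given sizes.

    ``class_sizes`` must sum to the proteome size; assignment is a uniform
    random permutation. Returned ids follow proteome entry order.
    """
    sizes = np.asarray(class_sizes, dtype=np.int64)
    n = len(proteome)
    if sizes.sum() != n:
        raise ValueError(f"class sizes sum to {sizes.sum()}, proteome has {n}")
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(sizes.size), sizes)
    rng.shuffle(assignment)
    if labels is None:
        labels = [f"class{c}" for c in range(sizes.size)]
    return BehaviorProfile(list(proteome.ids), assignment, labels)


def _mutable(proteome: Proteome) -> list[tuple[str, list[str]]]:
    return [(pid, list(proteome.sequence(pid))) for pid in proteome.ids]


def _concrete_instance(motif: Motif, rng) -> str:
    return "".join(sorted(s)[rng.integers(len(s))] for s in motif.sets)


def _draw_start(L: int, w: int, mode: str, rng) -> int:
    n_starts = L - w + 1
    if mode == "uniform":
        return int(rng.integers(n_starts))
    edge = max(1, n_starts // 10)
    if mode == "nterm":
        return int(rng.integers(edge))
    if mode == "cterm":
        return int(n_starts - 1 - rng.integers(edge))
    raise ValueError(f"unknown position_mode {mode!r}")


def plant_motif(
    proteome: Proteome,
    class_assignment: BehaviorProfile,
    motif: Motif,
    target_class: int,
    penetrance: float,
    position_mode: str = "uniform",
    seed: int = 0,
) -> tuple[Proteome, SyntheticTruth]:
    """Plant one concrete instance of ``motif`` into target-class proteins.

    Each target-class protein independently becomes a carrier with probability
    ``penetrance``; residues are sampled uniformly from each allowed-set and
    overwrite the sequence at a start drawn per ``position_mode`` (``nterm`` =
    first 10% of valid starts, ``cterm`` = last 10%). Returns a new proteome
    plus the exact truth record, including incidental (chance) carriers.
    """
    if not (0 < penetrance <= 1):
        raise ValueError("penetrance must be in (0, 1]")
    rng = np.random.default_rng(seed)
    w = motif.width
    class_of = dict(zip(class_assignment.ids, class_assignment.classes))
    entries = _mutable(proteome)
    carrier_ids: set[str] = set()
    positions: dict[str, int] = {}
    for pid, seq in entries:
        if class_of.get(pid) != target_class:
            continue
        if rng.random() >= penetrance:
            continue
        L = len(seq)
        if L < w:
            continue  # too short; skipped
        s = _draw_start(L, w, position_mode, rng)
        seq[s : s + w] = _concrete_instance(motif, rng)
        carrier_ids.add(pid)
        positions[pid] = s
    new = Proteome([(pid, "".join(seq)) for pid, seq in entries])
    profile = build_profile(new, motif)
    incidental = profile.carrier_ids() - carrier_ids
    truth = SyntheticTruth(
        planted=[PlantedMotif(motif, carrier_ids, positions, target_class, penetrance, incidental)]
    )
    return new, truth


def plant_pair(
    proteome: Proteome,
    class_assignment: BehaviorProfile,
    motif_a: Motif,
    motif_b: Motif,
    target_class: int,
    spacing: int,
    jitter: int = 0,
    penetrance: float = 1.0,
    seed: int = 0,
) -> tuple[Proteome, SyntheticTruth]:
    """Plant a co-occurring motif pair with |start_b - start_a| = spacing +- jitter.

    Motif b is placed downstream of motif a; the distance between start
    offsets is ``spacing`` plus a uniform integer jitter in [-jitter, jitter].
    """
    if not (0 < penetrance <= 1):
        raise ValueError("penetrance must be in (0, 1]")
    if spacing < motif_a.width:
        raise ValueError("spacing must be >= width of motif_a (no overlap)")
    rng = np.random.default_rng(seed)
    wa, wb = motif_a.width, motif_b.width
    class_of = dict(zip(class_assignment.ids, class_assignment.classes))
    entries = _mutable(proteome)
    carrier_ids: set[str] = set()
    positions: dict[str, tuple[int, int]] = {}
    distances: dict[str, int] = {}
    for pid, seq in entries:
        if class_of.get(pid) != target_class:
            continue
        if rng.random() >= penetrance:
            continue
        L = len(seq)
        d = spacing + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        if L < d + wb:
            continue
        sa = int(rng.integers(L - d - wb + 1))
        sb = sa + d
        seq[sa : sa + wa] = _concrete_instance(motif_a, rng)
        seq[sb : sb + wb] = _concrete_instance(motif_b, rng)
        carrier_ids.add(pid)
        positions[pid] = (sa, sb)
        distances[pid] = d
    new = Proteome([(pid, "".join(seq)) for pid, seq in entries])
    truth = SyntheticTruth(
        pair_truth=[PlantedPair(motif_a, motif_b, carrier_ids, positions, distances, target_class)]
    )
    return new, truth


def plant_domains(
    proteome: Proteome, carrier_ids, coverage: float, seed: int = 0, name: str = "SynDom"
) -> DomainAnnotations:
    """Give each carrier one domain interval of length floor(coverage * L)."""
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    rng = np.random.default_rng(seed)
    intervals: dict[str, list] = {}
    for pid in proteome.ids:
        if pid not in carrier_ids:
            continue
        L = len(proteome.sequence(pid))
        dlen = max(1, int(np.floor(coverage * L)))
        start = int(rng.integers(L - dlen + 1))
        intervals[pid] = [(name, start, start + dlen)]
    return DomainAnnotations(intervals)


def make_quantitative(
    class_assignment: BehaviorProfile,
    carrier_ids,
    effect: float,
    noise_sd: float,
    seed: int = 0,
) -> dict[str, float]:
    """Quantitative values coupled to motif presence.

    value = -effect (carriers) or 0 (non-carriers), plus N(0, noise_sd) noise,
    so carriers concentrate in the low bins after equal-population
    discretization — the shape of a short-half-life association.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    values = {}
    for pid in class_assignment.ids:
        base = -effect if pid in carrier_ids else 0.0
        values[pid] = float(base + rng.normal(0.0, noise_sd))
    return values
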