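"""Degenerate fixed-width protein motifs and fast proteome scanning.

A motif is an ordered list of allowed amino-acid sets, one per position, written
in the conventional dialect: a bare residue letter for a singleton set, ``.`` for
any residue, and ``[KR]`` for a multi-residue set. Matching is exact set
membership at every position — no regex quantifiers, no gaps. Non-canonical
residues (X, U, B, Z, O, J, ``*``) are retained in sequences but match nothing,
not even the wildcard, so ambiguity codes can never create motif instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 20 canonical residues in alphabetical order; defines PWM column order
#: and the integer encoding used by the scanner.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_CODE = {a: i for i, a in enumerate(ALPHABET)}
#: Code assigned to every non-canonical character; matches no allowed-set.
NON_CANONICAL = 20

_FULL_SET = frozenset(ALPHABET)

# byte-value -> code lookup for fast sequence encoding
_BYTE_CODE = np.full(256, NON_CANONICAL, dtype=np.uint8)
for _a, _i in AA_TO_CODE.items():
    _BYTE_CODE[ord(_a)] = _i


class MotifParseError(ValueError):
    """Raised when a motif pattern string cannot be parsed; carries the column."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


class Motif:
    """A fixed-width degenerate motif: one allowed residue set per position."""

    __slots__ = ("sets", "_tables", "_hash")

    def __init__(self, sets: Iterable[Iterable[str]]):
        sets = tuple(frozenset(s) for s in sets)
        if len(sets) < 2:
            raise ValueError("motif width must be >= 2")
        for j, s in enumerate(sets):
            if not s:
                raise ValueError(f"empty allowed-set at position {j}")
            bad = s - _FULL_SET
            if bad:
                raise ValueError(f"non-canonical residues {sorted(bad)} at position {j}")
        if len(sets[0]) == 20 or len(sets[-1]) == 20:
            raise ValueError("terminal motif positions may not be wildcards")
        self.sets = sets
        self._tables = None
        self._hash = None

    @property
    def width(self) -> int:
        return len(self.sets)

    def is_wildcard(self, j: int) -> bool:
        return len(self.sets[j]) == 20

    @property
    def degeneracy(self) -> int:
        """Product of allowed-set sizes over positions."""
        d = 1
        for s in self.sets:
            d *= len(s)
        return d

    def member_tables(self) -> np.ndarray:
        """(width, 21) boolean lookup: tables[j, code] == residue allowed at j.

        Column 20 (non-canonical) is always False, including at wildcards.
        """
        if self._tables is None:
            t = np.zeros((self.width, 21), dtype=bool)
            for j, s in enumerate(self.sets):
                for a in s:
                    t[j, AA_TO_CODE[a]] = True
            self._tables = t
        return self._tables

    def __str__(self) -> str:
        out = []
        for s in self.sets:
            if len(s) == 20:
                out.append(".")
            elif len(s) == 1:
                out.append(next(iter(s)))
            else:
                out.append("[" + "".join(sorted(s)) + "]")
        return "".join(out)

    def __repr__(self) -> str:
        return f"Motif({str(self)!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Motif) and self.sets == other.sets

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(self.sets)
        return self._hash


def parse_motif(pattern: str) -> Motif:
    """Parse a motif string like ``"SP.[RK]"`` into a :class:`Motif`.

    Raises :class:`MotifParseError` with a 0-based column index on empty
    brackets, unbalanced brackets, or characters outside the canonical
    alphabet / ``.`` / ``[...]``.
    """
    sets: list[frozenset[str]] = []
    i = 0
    n = len(pattern)
    while i < n:
        c = pattern[i]
        if c == ".":
            sets.append(_FULL_SET)
            i += 1
        elif c == "[":
            j = pattern.find("]", i + 1)
            if j < 0:
                raise MotifParseError("unbalanced '['", i)
            inner = pattern[i + 1 : j]
            if not inner:
                raise MotifParseError("empty bracket set", i + 1)
            for k, a in enumerate(inner):
                if a not in _FULL_SET:
                    raise MotifParseError(f"unknown residue {a!r}", i + 1 + k)
            sets.append(frozenset(inner))
            i = j + 1
        elif c == "]":
            raise MotifParseError("unbalanced ']'", i)
        elif c in _FULL_SET:
            sets.append(frozenset(c))
            i += 1
        else:
            raise MotifParseError(f"unknown character {c!r}", i)
    if len(sets) < 2:
        raise MotifParseError("motif must have width >= 2", 0)
    try:
        return Motif(sets)
    except ValueError as e:
        raise MotifParseError(str(e), 0) from e


@dataclass
class MotifProfile:
    """Presence/absence of a motif across an ordered protein universe.

    ``present[i]`` is True iff protein ``ids[i]`` contains at least one exact
    match; ``instances[i]`` lists all (overlapping) 0-based start offsets.
    """

    motif: Motif
    ids: list[str]
    present: np.ndarray
    instances: list[np.ndarray]

    @property
    def n_carriers(self) -> int:
        return int(self.present.sum())

    def carrier_ids(self) -> set[str]:
        return {pid for pid, p in zip(self.ids, self.present) if p}

    def n_instances(self) -> int:
        return int(sum(len(s) for s in self.instances))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an uppercase amino-acid string as uint8 codes (non-canonical -> 20)."""
    return _BYTE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class EncodedProteome:
    """Concatenated integer encoding of a proteome for vectorized scanning.

    Built lazily once per proteome and cached; all scan-heavy operations
    (profile building, seed enumeration, greedy refinement) share it.
    """

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        self.ids = list(ids)
        self.n = len(self.ids)
        lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        self.lengths = lengths
        self.starts = np.concatenate([[0], np.cumsum(lengths)])  # n+1 offsets
        self.total = int(self.starts[-1])
        self.codes = (
            np.concatenate([encode_sequence(s) for s in sequences])
            if self.total
            else np.zeros(0, dtype=np.uint8)
        )
        # protein index and within-protein offset of every global position
        self.prot_of_pos = np.repeat(np.arange(self.n), lengths)
        self.local_pos = np.arange(self.total) - self.starts[self.prot_of_pos]
        self._valid_cache: dict[int, np.ndarray] = {}

    def valid_starts(self, w: int) -> np.ndarray:
        """Boolean over global positions: True where a width-w window fits in-protein."""
        if w not in self._valid_cache:
            max_start = self.lengths[self.prot_of_pos] - w
            self._valid_cache[w] = self.local_pos <= max_start
        return self._valid_cache[w]

    def match_mask(self, tables: np.ndarray) -> np.ndarray:
        """Boolean over global positions: width-w window starting there matches."""
        w = tables.shape[0]
        m = tables[0][self.codes]
        for j in range(1, w):
            mj = tables[j][self.codes]
            m[: self.total - j] &= mj[j:]
            if j:
                m[self.total - j :] = False
        m &= self.valid_starts(w)
        return m

    def presence(self, tables: np.ndarray) -> np.ndarray:
        """Per-protein presence (bool, length n) for the given member tables."""
        m = self.match_mask(tables)
        present = np.zeros(self.n, dtype=bool)
        present[self.prot_of_pos[m]] = True
        return present

    def profile(self, motif: Motif) -> MotifProfile:
        m = self.match_mask(motif.member_tables())
        hits = np.flatnonzero(m)
        prots = self.prot_of_pos[hits]
        local = hits - self.starts[prots]
        present = np.zeros(self.n, dtype=bool)
        present[prots] = True
        bounds = np.searchsorted(prots, np.arange(self.n + 1))
        instances = [local[bounds[i] : bounds[i + 1]] for i in range(self.n)]
        return MotifProfile(motif, list(self.ids), present, instances)


def get_encoded(proteome) -> EncodedProteome:
    """Return (and cache on the proteome) its :class:`EncodedProteome`."""
    enc = getattr(proteome, "_encoded", None)
    if enc is None:
        enc = EncodedProteome(proteome.ids, [proteome.sequence(i) for i in proteome.ids])
        proteome._encoded = enc
    return enc


def scan_sequence(sequence: str, motif: Motif) -> np.ndarray:
    """All 0-based start offsets of exact matches of ``motif`` in ``sequence``.

    Overlapping matches are all reported; empty when the sequence is shorter
    than the motif.
    """
    w = motif.width
    L = len(sequence)
    if L < w:
        return np.zeros(0, dtype=np.int64)
    codes = encode_sequence(sequence.upper())
    tables = motif.member_tables()
    m = tables[0][codes[: L - w + 1]].copy()
    for j in range(1, w):
        m &= tables[j][codes[j : L - w + 1 + j]]
    return np.flatnonzero(m).astype(np.int64)


def build_profile(proteome, motif: Motif, id_order: Sequence[str] | None = None) -> MotifProfile:
    """Presence and instance offsets of ``motif`` across ``proteome``.

    ``id_order`` restricts and orders the universe (default: proteome entry
    order). Deterministic; unknown ids raise KeyError.
    """
    enc = get_encoded(proteome)
    full = enc.profile(motif)
    if id_order is None:
        return full
    index = {pid: i for i, pid in enumerate(enc.ids)}
    try:
        rows = [index[pid] for pid in id_order]
    except KeyError as e:
        raise KeyError(f"protein id {e.args[0]!r} not in proteome") from None
    return MotifProfile(
        motif,
        list(id_order),
        full.present[rows],
        [full.instances[r] for r in rows],
    )


def pwm_from_instances(profile: MotifProfile, proteome) -> np.ndarray:
    """(width, 20) position-weight matrix over all motif instances.

    Every instance (including overlapping ones) contributes one count per
    position; rows are normalized to sum to 1. Raises on zero instances.
    Instances covering non-canonical residues contribute nothing at those
    positions, and the affected rows are renormalized over what was observed.
    """
    w = profile.motif.width
    counts = np.zeros((w, 20), dtype=float)
    n_inst = 0
    for pid, starts in zip(profile.ids, profile.instances):
        if len(starts) == 0:
            continue
        codes = encode_sequence(proteome.sequence(pid))
        for s in starts:
            win = codes[s : s + w]
            ok = win < 20
            counts[np.arange(w)[ok], win[ok]] += 1
            n_inst += 1
    if n_inst == 0:
        raise ValueError("PWM requires at least one motif instance")
    row_sums = counts.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return counts / row_sums


def motif_degeneracy(motif: Motif) -> int:
    """Product over positions of allowed-set sizes (``"SP.[RK]"`` -> 40)."""
    return motif.degeneracy
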