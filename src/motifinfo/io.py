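"""Reading and writing the external formats: FASTA proteomes, TSV behavior
profiles, interval annotations (domains / disorder), flat term maps, known-motif
catalogs, and all result tables.

Conventions: TSVs are tab-separated UTF-8 with ``#`` comment lines ignored;
all coordinates are 0-based half-open; sequences are uppercased on load.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO

from . import stats
from .motif import ALPHABET, Motif, parse_motif

logger = logging.getLogger("motifinfo")

_ALLOWED_CHARS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ*")


class Proteome:
    """Ordered map of protein id -> amino-acid sequence.

    Entry order is stable and defines the index order of every downstream
    profile and statistic. Non-canonical characters (X, U, B, Z, O, J, ``*``)
    are retained but never matched by any motif position.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.ids: list[str] = []
        self._seqs: dict[str, str] = {}
        for pid, seq in entries:
            if not pid:
                raise ValueError("empty protein id")
            if pid in self._seqs:
                raise ValueError(f"duplicate protein id {pid!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - _ALLOWED_CHARS
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in protein {pid!r}")
            self.ids.append(pid)
            self._seqs[pid] = seq

    def sequence(self, pid: str) -> str:
        return self._seqs[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._seqs

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Proteome)
            and self.ids == other.ids
            and all(self._seqs[i] == other._seqs[i] for i in self.ids)
        )

    def lengths(self) -> np.ndarray:
        return np.array([len(self._seqs[i]) for i in self.ids], dtype=np.int64)


class BehaviorProfile:
    """Per-protein class assignment: the target of mutual information.

    Built either from discrete labels (first-appearance order defines class
    indices) or from quantitative values split into equally populated bins.
    Protein order follows the proteome entry order.
    """

    def __init__(self, ids, classes, class_labels, source="discrete", bin_edges=None):
        self.ids = list(ids)
        self.classes = np.asarray(classes, dtype=np.int64)
        self.class_labels = list(class_labels)
        self.source = source
        self.bin_edges = bin_edges
        if len(self.ids) != self.classes.size:
            raise ValueError("ids and classes have different lengths")
        C = len(self.class_labels)
        if C < 2:
            raise ValueError("behavior profile needs at least 2 classes")
        counts = np.bincount(self.classes, minlength=C)
        if self.classes.min() < 0 or self.classes.max() >= C:
            raise ValueError("class index out of range")
        if (counts == 0).any():
            empty = [self.class_labels[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"empty behavior classes: {empty}")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.classes, minlength=self.n_classes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BehaviorProfile)
            and self.ids == other.ids
            and np.array_equal(self.classes, other.classes)
            and self.class_labels == other.class_labels
        )


@dataclass
class DomainAnnotations:
    """Per-protein named domain intervals, 0-based half-open; may overlap."""

    intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def domain_names(self) -> list[str]:
        names = {name for ivs in self.intervals.values() for name, _, _ in ivs}
        return sorted(names)

    def carriers(self, domain_name: str) -> set[str]:
        return {
            pid
            for pid, ivs in self.intervals.items()
            if any(name == domain_name for name, _, _ in ivs)
        }

    def intervals_of(self, pid: str, domain_name: str) -> list[tuple[int, int]]:
        return [(s, e) for name, s, e in self.intervals.get(pid, []) if name == domain_name]


@dataclass
class DisorderMask:
    """Per-protein disordered intervals, merged and sorted on construction."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @staticmethod
    def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in sorted(intervals):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    def __post_init__(self):
        self.intervals = {pid: self.merge(ivs) for pid, ivs in self.intervals.items()}


@dataclass
class TermMap:
    """Flat term -> protein-set annotation map (GO/Pfam style, no ontology)."""

    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)


def _tsv_rows(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_fasta(path) -> Proteome:
    """Load a FASTA proteome; the header token up to the first whitespace is
    the protein id. Duplicate ids, empty records, and characters that are
    neither letters nor ``*`` are hard errors."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append((rec.id, str(rec.seq)))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return Proteome(entries)


def write_fasta(proteome: Proteome, path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in proteome.ids:
            seq = proteome.sequence(pid)
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_behavior(path, mode: str, proteome: Proteome, n_bins: int = 10) -> BehaviorProfile:
    """Load a two-column TSV (protein id, label-or-value) behavior profile.

    ``mode="discrete"`` maps distinct labels to class indices in first-
    appearance order; ``mode="quantitative"`` bins values into ``n_bins``
    equally populated classes (bin 0 = smallest values). Ids absent from the
    proteome are dropped with a logged count; the retained proteins are
    reordered to proteome entry order.
    """
    if mode not in ("discrete", "quantitative"):
        raise ValueError(f"unknown mode {mode!r}")
    raw: dict[str, str] = {}
    order: list[str] = []
    n_dropped = 0
    for lineno, cols in _tsv_rows(path):
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        pid, value = cols[0], cols[1]
        if pid not in proteome:
            n_dropped += 1
            continue
        if pid in raw:
            raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        raw[pid] = value
        order.append(pid)
    if n_dropped:
        logger.info("behavior file %s: dropped %d ids absent from proteome", path, n_dropped)
    ids = [pid for pid in proteome.ids if pid in raw]
    if mode == "discrete":
        labels: list[str] = []
        label_index: dict[str, int] = {}
        for pid in order:  # first-appearance order in the file
            lab = raw[pid]
            if lab not in label_index:
                label_index[lab] = len(labels)
                labels.append(lab)
        if len(labels) < 2:
            raise ValueError("behavior profile has fewer than 2 distinct classes")
        classes = [label_index[raw[pid]] for pid in ids]
        return BehaviorProfile(ids, classes, labels, source="discrete")
    values = []
    for pid in ids:
        try:
            v = float(raw[pid])
        except ValueError:
            raise ValueError(f"non-numeric value {raw[pid]!r} for protein {pid!r}")
        values.append(v)
    if n_bins > len(ids):
        raise ValueError(f"n_bins ({n_bins}) exceeds number of proteins ({len(ids)})")
    classes = stats.discretize(values, n_bins)
    values = np.asarray(values)
    edges = [float(np.max(values[classes == b])) for b in range(n_bins - 1)]
    labels = [f"bin{b}" for b in range(n_bins)]
    return BehaviorProfile(ids, classes, labels, source=f"quantized({n_bins})", bin_edges=edges)


def read_intervals(path, proteome: Proteome, kind: str):
    """Load TSV intervals (protein_id, name-or-blank, start, end), 0-based
    half-open. ``kind="domain"`` -> :class:`DomainAnnotations`;
    ``kind="disorder"`` -> :class:`DisorderMask` (overlaps merged)."""
    if kind not in ("domain", "disorder"):
        raise ValueError(f"unknown interval kind {kind!r}")
    per_protein: dict[str, list] = {}
    for lineno, cols in _tsv_rows(path):
        if len(cols) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
        pid, name, start, end = cols[0], cols[1], int(cols[2]), int(cols[3])
        if pid not in proteome:
            raise ValueError(f"{path}:{lineno}: unknown protein id {pid!r}")
        L = len(proteome.sequence(pid))
        if not (0 <= start < end <= L):
            raise ValueError(
                f"{path}:{lineno}: interval [{start},{end}) out of bounds for "
                f"protein {pid!r} of length {L}"
            )
        if kind == "domain":
            if not name:
                raise ValueError(f"{path}:{lineno}: domain name must be non-empty")
            per_protein.setdefault(pid, []).append((name, start, end))
        else:
            per_protein.setdefault(pid, []).append((start, end))
    if kind == "domain":
        return DomainAnnotations(per_protein)
    return DisorderMask(per_protein)


def read_terms(path, proteome: Proteome) -> TermMap:
    """Load a flat TSV term map: (term_id, protein_id[, term_name]) rows."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, cols in _tsv_rows(path):
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
        term, pid = cols[0], cols[1]
        if pid not in proteome:
            raise ValueError(f"{path}:{lineno}: unknown protein id {pid!r}")
        sets.setdefault(term, set()).add(pid)
        if len(cols) > 2 and cols[2]:
            names[term] = cols[2]
    if any(not s for s in sets.values()):
        raise ValueError("empty term set")
    return TermMap({t: frozenset(s) for t, s in sets.items()}, names)


def read_known_motifs(path) -> list[tuple[str, Motif, str]]:
    """Load a known-motif catalog TSV: (name, pattern, context-tag) rows."""
    catalog = []
    for lineno, cols in _tsv_rows(path):
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected (name, pattern[, context])")
        name, pattern = cols[0], cols[1]
        context = cols[2] if len(cols) > 2 else ""
        try:
            motif = parse_motif(pattern)
        except Exception as e:
            raise ValueError(f"{path}:{lineno}: bad motif pattern {pattern!r}: {e}")
        catalog.append((name, motif, context))
    return catalog


def _fmt(x, digits=6):
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.{digits}g}"
    return str(x)


def write_results(results, out_dir, class_labels=None) -> list[str]:
    """Write discovery results deterministically into ``out_dir``.

    Produces ``motifs.tsv`` (motif, MI, z, empirical p, robustness, carriers),
    ``heatmap.tsv`` (motifs x classes signed enrichment scores with
    significance flags), ``instances.tsv`` (motif, protein, start) and one
    ``pwm/<motif>.tsv`` per motif (20 alphabetical residue columns, rows
    summing to 1). Reruns on identical results are byte-identical.
    """
    from .motif import pwm_from_instances  # noqa: F401  (signature reference)

    os.makedirs(out_dir, exist_ok=True)
    written = []

    path = os.path.join(out_dir, "motifs.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("motif\tmi_bits\tz_score\tempirical_p\trobustness\tn_carriers\tseed_kmer\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        str(r.motif),
                        _fmt(r.mi),
                        _fmt(r.test.z_score),
                        _fmt(r.test.empirical_p),
                        str(r.robustness),
                        str(r.profile.n_carriers),
                        r.seed_kmer,
                    ]
                )
                + "\n"
            )
    written.append(path)

    path = os.path.join(out_dir, "heatmap.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        if results:
            C = len(results[0].enrichment)
            labels = class_labels if class_labels is not None else [f"class{c}" for c in range(C)]
            header = ["motif"]
            for lab in labels:
                header += [f"score[{lab}]", f"sig[{lab}]"]
            fh.write("\t".join(header) + "\n")
            for r in results:
                row = [str(r.motif)]
                for cell in r.enrichment:
                    flag = ""
                    if cell.significant:
                        flag = "over" if cell.signed_score > 0 else "under"
                    row += [_fmt(cell.signed_score), flag]
                fh.write("\t".join(row) + "\n")
        else:
            fh.write("motif\n")
    written.append(path)

    path = os.path.join(out_dir, "instances.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("motif\tprotein_id\tstart\n")
        for r in results:
            for pid, starts in zip(r.profile.ids, r.profile.instances):
                for s in starts:
                    fh.write(f"{r.motif}\t{pid}\t{int(s)}\n")
    written.append(path)

    pwm_dir = os.path.join(out_dir, "pwm")
    os.makedirs(pwm_dir, exist_ok=True)
    for r in results:
        if r.pwm is None:
            continue
        path = os.path.join(pwm_dir, f"{r.motif}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("position\t" + "\t".join(ALPHABET) + "\n")
            for j, row in enumerate(r.pwm):
                fh.write(str(j) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        written.append(path)
    return written
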