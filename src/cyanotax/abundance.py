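"""Metagenomic read recruitment and length-normalised relative abundance.

Reads are recruited to genomes by exact canonical k-mer matching: a read's
score against a genome is the fraction of the read's k-mers present in that
genome, and the read is assigned to the top-scoring genome(s) provided the
score reaches ``min_fraction``.  Ties are split fractionally and equally,
so a read from a segment shared verbatim by two genomes contributes half a
count to each.  Per-sample abundances are mapped-read counts divided by
genome length and closed to sum to one.

k-mers are canonicalised as the minimum of a k-mer and its reverse
complement, so both strands recruit identically.  For k <= 31 k-mers are
packed into 64-bit integers and all scoring is vectorised; larger (odd) k
fall back to a string-keyed path.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import SequenceSet

log = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-minimum) 2-bit packed k-mer codes of one sequence.

    Positions whose window contains a non-ACGT base are dropped.
    """
    a = _encode(seq)
    n = len(a)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes, valid = _codes_with_validity(a, k)
    return codes[valid]


def _codes_with_validity(a: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    valid_base = a < 4
    a4 = np.where(valid_base, a, 0).astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    win = np.lib.stride_tricks.sliding_window_view(a4, k)
    forward = (win * powers).sum(axis=1, dtype=np.uint64)
    rc = (np.uint64(3) - a4)[::-1]
    rwin = np.lib.stride_tricks.sliding_window_view(rc, k)
    reverse = (rwin * powers).sum(axis=1, dtype=np.uint64)[::-1]
    canonical = np.minimum(forward, reverse)
    valid = np.lib.stride_tricks.sliding_window_view(valid_base, k).all(axis=1)
    return canonical, valid


def _canonical_strings(seq: str, k: int) -> list[str]:
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        rc = kmer.translate(_COMPLEMENT)[::-1]
        out.append(min(kmer, rc))
    return out


@dataclass
class KmerIndex:
    """Sorted canonical k-mer sets per genome (both strands represented)."""

    k: int
    genome_ids: list[str]
    genome_lengths: dict[str, int]
    _packed: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _strings: dict[str, frozenset[str]] = field(default_factory=dict,
                                                repr=False)

    @property
    def packed(self) -> bool:
        return self.k <= 31

    def n_kmers(self, genome_id: str) -> int:
        if self.packed:
            return len(self._packed[genome_id])
        return len(self._strings[genome_id])

    def genomes_with(self, kmer: str) -> set[str]:
        """Genome ids containing a k-mer (given in either orientation)."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer must have length {self.k}")
        if self.packed:
            code = _canonical_codes(kmer, self.k)
            if len(code) == 0:
                return set()
            return {g for g in self.genome_ids
                    if _sorted_contains(self._packed[g], code)[0]}
        rc = kmer.translate(_COMPLEMENT)[::-1]
        canon = min(kmer, rc)
        return {g for g in self.genome_ids if canon in self._strings[g]}


def _sorted_contains(sorted_arr: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Boolean membership of ``values`` in a sorted unique array."""
    if len(sorted_arr) == 0:
        return np.zeros(len(values), dtype=bool)
    pos = np.searchsorted(sorted_arr, values)
    pos = np.minimum(pos, len(sorted_arr) - 1)
    return sorted_arr[pos] == values


def build_kmer_index(genomes: Mapping[str, SequenceSet],
                     k: int = 31) -> KmerIndex:
    """Index the canonical k-mers of each genome.

    ``k`` must be odd (so no k-mer is its own reverse complement) and lie
    in [15, 63].  Genomes shorter than ``k`` are excluded with a warning.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not 15 <= k <= 63:
        raise ValueError("k must lie in [15, 63]")
    ids = []
    lengths = {}
    packed: dict[str, np.ndarray] = {}
    strings: dict[str, frozenset[str]] = {}
    for gid in sorted(genomes):
        contigs = genomes[gid]
        total = sum(len(rec) for rec in contigs)
        if total < k:
            log.warning("genome %s shorter than k=%d; excluded from index",
                        gid, k)
            continue
        ids.append(gid)
        lengths[gid] = total
        if k <= 31:
            parts = [_canonical_codes(rec.residues, k) for rec in contigs]
            packed[gid] = np.unique(np.concatenate(parts)) if parts else \
                np.empty(0, dtype=np.uint64)
        else:
            pool: set[str] = set()
            for rec in contigs:
                pool.update(_canonical_strings(rec.residues, k))
            strings[gid] = frozenset(pool)
    if not ids:
        raise ValueError("no genome long enough to index")
    return KmerIndex(k=k, genome_ids=ids, genome_lengths=lengths,
                     _packed=packed, _strings=strings)


@dataclass(frozen=True)
class ReadAssignment:
    """Fractional assignment of one read to genomes (empty = unassigned)."""

    read_id: str
    weights: dict[str, float]

    @property
    def assigned(self) -> bool:
        return bool(self.weights)


def recruit_reads(reads: SequenceSet, index: KmerIndex,
                  min_fraction: float = 0.5) -> list[ReadAssignment]:
    """Assign reads to genomes by shared canonical k-mer fraction.

    The per-genome score of a read is the number of its k-mer positions
    whose canonical k-mer occurs in the genome, divided by the total number
    of k-mer positions (L - k + 1).  The read is split equally over all
    genomes attaining the maximal score when that score is at least
    ``min_fraction``; otherwise it is unassigned.
    """
    k = index.k
    read_list = list(reads)
    if not read_list:
        return []
    if index.packed:
        counts, n_positions = _score_packed(read_list, index)
    else:
        counts, n_positions = _score_strings(read_list, index)
    assignments = []
    genome_ids = index.genome_ids
    best = counts.max(axis=1)
    for r, rec in enumerate(read_list):
        npos = n_positions[r]
        if npos == 0 or best[r] == 0 or best[r] / npos < min_fraction:
            assignments.append(ReadAssignment(rec.id, {}))
            continue
        winners = [genome_ids[g] for g in np.flatnonzero(counts[r] == best[r])]
        w = 1.0 / len(winners)
        assignments.append(ReadAssignment(rec.id, {g: w for g in winners}))
    return assignments


def _score_packed(read_list, index: KmerIndex) -> tuple[np.ndarray, np.ndarray]:
    k = index.k
    # One pass over the concatenated reads (joined on N so windows never span
    # two reads), then one sorted-membership query per genome.
    seqs = [rec.residues for rec in read_list]
    concat = "N".join(seqs)
    starts = np.cumsum([0] + [len(s) + 1 for s in seqs[:-1]])
    n_positions = np.array([max(len(s) - k + 1, 0) for s in seqs])
    a = _encode(concat)
    if len(a) < k:
        return (np.zeros((len(seqs), len(index.genome_ids)), dtype=np.int64),
                n_positions)
    codes, valid = _codes_with_validity(a, k)
    pos = np.flatnonzero(valid)
    codes = codes[pos]
    read_idx = np.searchsorted(starts, pos, side="right") - 1
    counts = np.zeros((len(seqs), len(index.genome_ids)), dtype=np.int64)
    for g, gid in enumerate(index.genome_ids):
        hit = _sorted_contains(index._packed[gid], codes)
        if hit.any():
            counts[:, g] = np.bincount(read_idx[hit], minlength=len(seqs))
    return counts, n_positions


def _score_strings(read_list, index: KmerIndex) -> tuple[np.ndarray, np.ndarray]:
    k = index.k
    counts = np.zeros((len(read_list), len(index.genome_ids)), dtype=np.int64)
    n_positions = np.zeros(len(read_list), dtype=np.int64)
    for r, rec in enumerate(read_list):
        n_positions[r] = max(len(rec.residues) - k + 1, 0)
        for canon in _canonical_strings(rec.residues, k):
            for g, gid in enumerate(index.genome_ids):
                if canon in index._strings[gid]:
                    counts[r, g] += 1
    return counts, n_positions


@dataclass
class AbundanceMatrix:
    """Genome x sample relative abundances plus per-sample assigned counts.

    Each column with at least one assigned read sums to one; columns with no
    assigned reads are all-zero and listed in ``empty_samples``.
    """

    abundance: pd.DataFrame
    assigned_reads: pd.Series
    empty_samples: list[str] = field(default_factory=list)

    def validate(self, tol: float = 1e-9) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        sums = self.abundance.sum(axis=0)
        for sample in self.abundance.columns:
            if sample in self.empty_samples:
                if sums[sample] != 0:
                    raise ValueError(f"empty sample {sample} has mass")
            elif abs(sums[sample] - 1.0) > tol:
                raise ValueError(
                    f"sample {sample} abundances sum to {sums[sample]}")

    def write(self, path: str | Path) -> None:
        self.abundance.to_csv(path, sep="\t")


def relative_abundance(assignments: Mapping[str, Iterable[ReadAssignment]],
                       genome_lengths: Mapping[str, int]) -> AbundanceMatrix:
    """Length-normalised, per-sample-closed relative abundances.

    For each sample: raw counts are the summed fractional weights per
    genome, divided by genome length (reads per base), then closed so the
    column sums to one.  Samples with zero assigned reads yield an all-zero
    column and are flagged.
    """
    genome_ids = sorted(genome_lengths)
    for gid in genome_ids:
        if genome_lengths[gid] <= 0:
            raise ValueError(f"genome {gid} has non-positive length")
    samples = list(assignments)
    table = pd.DataFrame(0.0, index=genome_ids, columns=samples)
    assigned = pd.Series(0.0, index=samples)
    empty = []
    for sample in samples:
        raw = dict.fromkeys(genome_ids, 0.0)
        total = 0.0
        for assignment in assignments[sample]:
            for gid, w in assignment.weights.items():
                raw[gid] += w
                total += w
        assigned[sample] = total
        if total == 0:
            empty.append(sample)
            log.warning("sample %s: no assigned reads", sample)
            continue
        norm = np.array([raw[g] / genome_lengths[g] for g in genome_ids])
        table[sample] = norm / norm.sum()
    matrix = AbundanceMatrix(table, assigned, empty)
    matrix.validate()
    return matrix
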