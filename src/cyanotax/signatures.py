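"""Pairwise genomic signatures: AAI, genome-to-genome distance, 16S identity.

Three whole-genome signatures drive taxon delimitation:

* **AAI** — average amino acid identity: the unweighted mean percent identity
  over reciprocal-best-hit (RBH) protein pairs between two proteomes.
* **GGD** — a genome-to-genome distance expressed as percent similarity, in
  the digital DNA-DNA hybridisation family: one genome is fragmented into
  1 kb windows, each window is locally aligned to the other genome, and GGD
  is 100 x (sum of identities) / (sum of HSP columns), symmetrised over both
  directions.
* **16S identity** — percent identity of the small-subunit rRNA genes under a
  global alignment with free end gaps (terminal-gap columns excluded).

The module also provides Tajima-Nei nucleotide distances on a multiple
alignment and the concatenation of per-marker protein alignments into a
supermatrix (genomes missing any marker are excluded).

Scoring conventions (declared for reproducibility): proteins are aligned
locally under BLOSUM62 with affine gaps (open 11, extend 1); nucleotides
with match +2 / mismatch -3 and gaps open 5 / extend 2.  Internal gap
columns count as mismatches in all identity computations.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import Alphabet, SequenceRecord, SequenceSet

log = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Nucleotide scoring used for GGD windows and 16S alignment.
NUC_MATCH, NUC_MISMATCH, NUC_GAP_OPEN, NUC_GAP_EXTEND = 2, -3, 5, 2


class AAIUndefinedError(ValueError):
    """Raised when no reciprocal-best-hit pair exists between two proteomes."""


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _nucleotide_local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = NUC_MATCH
    aligner.mismatch_score = NUC_MISMATCH
    aligner.open_gap_score = -float(NUC_GAP_OPEN)
    aligner.extend_gap_score = -float(NUC_GAP_EXTEND)
    return aligner


def _nucleotide_endsfree_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NUC_MATCH
    aligner.mismatch_score = NUC_MISMATCH
    aligner.open_gap_score = -float(NUC_GAP_OPEN)
    aligner.extend_gap_score = -float(NUC_GAP_EXTEND)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass(frozen=True)
class ProteinAlignment:
    """Best local alignment between two protein sequences."""

    identity_percent: float
    aln_length: int
    coverage_a: float
    coverage_b: float
    score: float


def align_protein_pair(a: SequenceRecord, b: SequenceRecord,
                       aligner: PairwiseAligner | None = None
                       ) -> ProteinAlignment | None:
    """Locally align two proteins; ``None`` if no positive-scoring segment.

    Identity is computed over aligned columns with internal gaps counted as
    mismatches; coverage is the aligned span divided by sequence length.
    """
    if len(a.residues) == 0 or len(b.residues) == 0:
        raise ValueError("cannot align empty sequence")
    if aligner is None:
        aligner = _protein_aligner()
    alignments = aligner.align(a.residues, b.residues)
    score = alignments.score
    if score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    blocks = aln.aligned
    span_a = int(blocks[0][-1][1] - blocks[0][0][0])
    span_b = int(blocks[1][-1][1] - blocks[1][0][0])
    return ProteinAlignment(
        identity_percent=100.0 * counts.identities / columns,
        aln_length=int(columns),
        coverage_a=span_a / len(a.residues),
        coverage_b=span_b / len(b.residues),
        score=float(score),
    )


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit protein pair contributing to AAI."""

    id_a: str
    id_b: str
    identity_percent: float
    aln_length: int
    coverage_a: float
    coverage_b: float


def _best_hit(scores: Mapping[str, ProteinAlignment]) -> str | None:
    """Best target id by score, then alignment length, then lexicographic id."""
    best = None
    for target, aln in scores.items():
        if best is None:
            best = (target, aln)
            continue
        key = (aln.score, aln.aln_length)
        best_key = (best[1].score, best[1].aln_length)
        if key > best_key or (key == best_key and target < best[0]):
            best = (target, aln)
    return best[0] if best else None


def find_rbh_pairs(proteome_a: SequenceSet, proteome_b: SequenceSet,
                   min_identity: float = 30.0,
                   min_coverage: float = 0.7) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes.

    A pair (x, y) is retained iff y is x's best-scoring hit in B and x is
    y's best in A, the identity is at least ``min_identity`` percent, and
    the coverage of the shorter sequence is at least ``min_coverage``.
    """
    if len(proteome_a) == 0 or len(proteome_b) == 0:
        raise ValueError("proteomes must be non-empty")
    aligner = _protein_aligner()
    hits_a: dict[str, dict[str, ProteinAlignment]] = {}
    hits_b: dict[str, dict[str, ProteinAlignment]] = {}
    for x in proteome_a:
        for y in proteome_b:
            aln = align_protein_pair(x, y, aligner)
            if aln is None:
                continue
            hits_a.setdefault(x.id, {})[y.id] = aln
            hits_b.setdefault(y.id, {})[x.id] = aln
    pairs: list[OrthologPair] = []
    for x_id in sorted(hits_a):
        y_id = _best_hit(hits_a[x_id])
        if y_id is None or _best_hit(hits_b[y_id]) != x_id:
            continue
        aln = hits_a[x_id][y_id]
        shorter_cov = (aln.coverage_a
                       if len(proteome_a[x_id]) <= len(proteome_b[y_id])
                       else aln.coverage_b)
        if aln.identity_percent >= min_identity and shorter_cov >= min_coverage:
            pairs.append(OrthologPair(x_id, y_id, aln.identity_percent,
                                      aln.aln_length, aln.coverage_a,
                                      aln.coverage_b))
    return pairs


def compute_aai(proteome_a: SequenceSet, proteome_b: SequenceSet,
                min_identity: float = 30.0, min_coverage: float = 0.7) -> float:
    """Average amino acid identity: unweighted mean over RBH pair identities.

    Raises :class:`AAIUndefinedError` when no RBH pair passes the filters;
    AAI is then recorded as missing, never as zero.
    """
    pairs = find_rbh_pairs(proteome_a, proteome_b, min_identity, min_coverage)
    if not pairs:
        raise AAIUndefinedError("AAI undefined: no reciprocal-best-hit pairs")
    return float(np.mean([p.identity_percent for p in pairs]))


# ---------------------------------------------------------------------------
# Genome-to-genome distance


@dataclass(frozen=True)
class GGDResult:
    percent: float
    has_homology: bool


def _concat_with_breaks(contigs: SequenceSet, k: int) -> str:
    # contigs are joined on a run of N so no seed spans a contig boundary
    return ("N" * k).join(rec.residues for rec in contigs)


def _seed_index(target: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        kmer = target[j:j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    return index


def _windows(contigs: SequenceSet, window: int, min_len: int) -> list[str]:
    out = []
    for rec in contigs:
        s = rec.residues
        for i in range(0, len(s), window):
            w = s[i:i + window]
            if len(w) >= min_len:
                out.append(w)
    return out


def _one_way_ggd(query: SequenceSet, target: str,
                 index: dict[str, list[int]], aligner: PairwiseAligner,
                 window: int, min_hsp_len: int, min_hsp_identity: float,
                 seed_k: int, seed_step: int, margin: int,
                 diag_bucket: int) -> tuple[float, float]:
    """Sum of identities and of HSP columns for query windows against target."""
    total_id = 0.0
    total_cols = 0.0
    for w in _windows(query, window, min_hsp_len):
        votes: Counter[int] = Counter()
        for i in range(0, len(w) - seed_k + 1, seed_step):
            for j in index.get(w[i:i + seed_k], ()):
                votes[(j - i) // diag_bucket] += 1
        if not votes:
            continue
        bucket = votes.most_common(1)[0][0]
        start = max(0, bucket * diag_bucket - margin)
        end = min(len(target), (bucket + 1) * diag_bucket + len(w) + margin)
        region = target[start:end]
        if not region:
            continue
        alignments = aligner.align(w, region)
        if alignments.score <= 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        if columns < min_hsp_len:
            continue
        identity = 100.0 * counts.identities / columns
        if identity < min_hsp_identity:
            continue
        total_id += counts.identities
        total_cols += columns
    return total_id, total_cols


def compute_ggd(genome_a: SequenceSet, genome_b: SequenceSet,
                window: int = 1000, min_hsp_len: int = 100,
                min_hsp_identity: float = 50.0, seed_k: int = 13,
                seed_step: int = 4, margin: int = 100,
                diag_bucket: int = 64) -> GGDResult:
    """Genome-to-genome distance as a percent similarity.

    Each genome is fragmented into non-overlapping ``window``-bp windows;
    each window is locally aligned to the other genome (anchored to its best
    shared-seed diagonal region), HSPs shorter than ``min_hsp_len`` or below
    ``min_hsp_identity`` percent identity are discarded, and the one-way
    value is 100 x (sum of identities) / (sum of HSP columns).  The result
    is the mean of both directions.  If no HSP survives in either direction
    the value is 0 with ``has_homology=False``.
    """
    if len(genome_a) == 0 or len(genome_b) == 0:
        raise ValueError("genomes must be non-empty")
    aligner = _nucleotide_local_aligner()
    values = []
    for query, subject in ((genome_a, genome_b), (genome_b, genome_a)):
        target = _concat_with_breaks(subject, seed_k)
        index = _seed_index(target, seed_k)
        tid, tcols = _one_way_ggd(query, target, index, aligner, window,
                                  min_hsp_len, min_hsp_identity, seed_k,
                                  seed_step, margin, diag_bucket)
        if tcols > 0:
            values.append(100.0 * tid / tcols)
    if not values:
        return GGDResult(0.0, has_homology=False)
    return GGDResult(float(np.mean(values)), has_homology=True)


# ---------------------------------------------------------------------------
# 16S rRNA identity


def sixteen_s_identity(a: SequenceRecord, b: SequenceRecord,
                       min_length: int = 500) -> float:
    """Percent identity of two 16S genes under ends-free global alignment.

    Terminal-gap columns are excluded from the denominator; internal gap
    columns count as mismatches.  Fragments shorter than ``min_length`` bp
    are rejected.
    """
    for rec in (a, b):
        if len(rec.residues) < min_length:
            raise ValueError(
                f"fragment too short: record {rec.id!r} has "
                f"{len(rec.residues)} bp (< {min_length})")
    aligner = _nucleotide_endsfree_aligner()
    aln = aligner.align(a.residues, b.residues)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    first, last = 0, len(s1)
    while first < last and (s1[first] == "-" or s2[first] == "-"):
        first += 1
    while last > first and (s1[last - 1] == "-" or s2[last - 1] == "-"):
        last -= 1
    columns = last - first
    if columns == 0:
        return 0.0
    matches = sum(1 for i in range(first, last) if s1[i] == s2[i])
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# Tajima-Nei distances on a multiple alignment

_VALID_BASES = frozenset("ACGT")


def _tajima_nei_pair(x: str, y: str) -> float:
    """Tajima-Nei (equal-input) distance between two aligned rows.

    Columns where either row is a gap or an ambiguous base are excluded.
    Returns NaN when the proportion of differences reaches the validity
    limit of the correction (log argument non-positive).
    """
    pairs = [(c1, c2) for c1, c2 in zip(x, y)
             if c1 in _VALID_BASES and c2 in _VALID_BASES]
    n = len(pairs)
    if n == 0:
        return math.nan
    diffs = [(c1, c2) for c1, c2 in pairs if c1 != c2]
    p = len(diffs) / n
    if p == 0.0:
        return 0.0
    base_counts: Counter[str] = Counter()
    for c1, c2 in pairs:
        base_counts[c1] += 1
        base_counts[c2] += 1
    g = {b: base_counts[b] / (2 * n) for b in "ACGT"}
    pair_counts: Counter[frozenset[str]] = Counter(
        frozenset(d) for d in diffs)
    h = 0.0
    bases = "ACGT"
    for i in range(4):
        for j in range(i + 1, 4):
            x_ij = pair_counts[frozenset((bases[i], bases[j]))] / n
            if x_ij and g[bases[i]] > 0 and g[bases[j]] > 0:
                h += x_ij ** 2 / (2.0 * g[bases[i]] * g[bases[j]])
    b_coef = 0.5 * (1.0 - sum(v ** 2 for v in g.values()) + p ** 2 / h)
    arg = 1.0 - p / b_coef
    if arg <= 0.0:
        return math.nan
    return -b_coef * math.log(arg)


def tajima_nei_distance(alignment: SequenceSet) -> pd.DataFrame:
    """Symmetric Tajima-Nei distance matrix over an aligned nucleotide set."""
    lengths = {len(rec.residues) for rec in alignment}
    if len(lengths) > 1:
        raise ValueError("alignment rows must all have equal length")
    ids = alignment.ids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        d = _tajima_nei_pair(alignment[a].residues, alignment[b].residues)
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


# ---------------------------------------------------------------------------
# Marker concatenation


@dataclass
class MarkerAlignmentSet:
    """Per-gene aligned protein sets keyed by unique gene name."""

    genes: dict[str, SequenceSet]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker set must be non-empty")
        for name, aln in self.genes.items():
            widths = {len(rec.residues) for rec in aln}
            if len(widths) > 1:
                raise ValueError(f"gene {name!r}: rows have unequal lengths")

    @property
    def presence(self) -> dict[str, set[str]]:
        """genome id -> set of genes in which it is present."""
        out: dict[str, set[str]] = {}
        for name, aln in self.genes.items():
            for rec in aln:
                out.setdefault(rec.id, set()).add(name)
        return out


@dataclass(frozen=True)
class Supermatrix:
    alignment: SequenceSet
    coordinates: dict[str, tuple[int, int]]  # gene -> (start, end), 0-based
    excluded: list[str]


def concatenate_markers(markers: MarkerAlignmentSet,
                        genome_ids: Iterable[str] | None = None) -> Supermatrix:
    """Concatenate per-marker alignments into a supermatrix.

    Only genomes present in every marker are retained; the rest are listed
    in ``excluded``.  Column coordinates of each gene are reported so tree
    builders can partition the supermatrix.
    """
    presence = markers.presence
    all_genes = set(markers.genes)
    candidates = list(genome_ids) if genome_ids is not None else sorted(presence)
    kept = [g for g in candidates if presence.get(g, set()) == all_genes]
    excluded = [g for g in candidates if g not in set(kept)]
    if not kept:
        raise ValueError("no genome carries the complete marker set")
    coords: dict[str, tuple[int, int]] = {}
    parts: dict[str, list[str]] = {g: [] for g in kept}
    offset = 0
    for name, aln in markers.genes.items():
        width = len(next(iter(aln)).residues)
        coords[name] = (offset, offset + width)
        offset += width
        for g in kept:
            parts[g].append(aln[g].residues)
    records = SequenceSet(
        SequenceRecord(g, "".join(parts[g]), Alphabet.protein) for g in kept)
    return Supermatrix(records, coords, excluded)


# ---------------------------------------------------------------------------
# Signature matrix container


@dataclass
class SignatureMatrices:
    """Symmetric genome x genome matrices of AAI%, GGD% and 16S identity%.

    Diagonals are exactly 100; missing entries (no 16S gene, AAI undefined)
    are NaN.  Pairs with no detectable nucleotide homology carry GGD 0 and
    are listed in ``no_homology_pairs``.
    """

    genome_ids: list[str]
    aai: pd.DataFrame
    ggd: pd.DataFrame
    s16: pd.DataFrame
    no_homology_pairs: set[frozenset[str]] = field(default_factory=set)

    def validate(self, tol: float = 0.1) -> None:
        for name, mat in (("aai", self.aai), ("ggd", self.ggd),
                          ("s16", self.s16)):
            arr = mat.to_numpy(dtype=float)
            if list(mat.index) != self.genome_ids or \
                    list(mat.columns) != self.genome_ids:
                raise ValueError(f"{name}: index/columns must be genome_ids")
            diag = np.diag(arr)
            if not np.all(np.isclose(diag[np.isfinite(diag)], 100.0)):
                raise ValueError(f"{name}: diagonal must equal 100")
            finite = np.isfinite(arr)
            if np.any((arr[finite] < 0) | (arr[finite] > 100)):
                raise ValueError(f"{name}: entries must lie in [0, 100]")
            asym = np.nanmax(np.abs(arr - arr.T)) if finite.any() else 0.0
            if asym > tol:
                raise ValueError(f"{name}: asymmetry {asym:.3f} exceeds {tol}")

    def write(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mat in (("aai", self.aai), ("ggd", self.ggd),
                          ("s16", self.s16)):
            mat.to_csv(directory / f"{prefix}{name}.tsv", sep="\t")


def _blank_matrix(ids: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 100.0)
    return mat


def compute_signature_matrices(
        proteomes: Mapping[str, SequenceSet],
        genomes: Mapping[str, SequenceSet],
        s16_genes: Mapping[str, SequenceRecord] | None = None,
        min_identity: float = 30.0, min_coverage: float = 0.7,
        ggd_window: int = 1000) -> SignatureMatrices:
    """All-vs-all AAI, GGD and 16S identity over a genome collection.

    ``s16_genes`` may omit genomes lacking an annotated 16S gene; the
    corresponding matrix entries stay NaN (missing, not zero).
    """
    ids = sorted(genomes)
    if sorted(proteomes) != ids:
        raise ValueError("proteomes and genomes must cover the same ids")
    s16_genes = s16_genes or {}
    aai = _blank_matrix(ids)
    ggd = _blank_matrix(ids)
    s16 = _blank_matrix(ids)
    no_homology: set[frozenset[str]] = set()
    for a, b in combinations(ids, 2):
        try:
            aai.loc[a, b] = aai.loc[b, a] = compute_aai(
                proteomes[a], proteomes[b], min_identity, min_coverage)
        except AAIUndefinedError:
            log.warning("AAI undefined for pair (%s, %s)", a, b)
        res = compute_ggd(genomes[a], genomes[b], window=ggd_window)
        ggd.loc[a, b] = ggd.loc[b, a] = res.percent
        if not res.has_homology:
            no_homology.add(frozenset((a, b)))
        if a in s16_genes and b in s16_genes:
            s16.loc[a, b] = s16.loc[b, a] = sixteen_s_identity(
                s16_genes[a], s16_genes[b])
    matrices = SignatureMatrices(ids, aai, ggd, s16, no_homology)
    matrices.validate()
    return matrices
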