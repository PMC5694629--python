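"""Synthetic genomes, proteomes, 16S genes, trees, reads and metadata.

Every pipeline stage is testable without downloads: this module plants a
known species/genus partition (via controlled sequence identities evolved
down a generated tree) and known ecogenomic groups (via a log-linear
abundance model with sign-patterned environmental effects), and emits the
ground truth alongside the data.

Divergence is simulated by per-site substitution at a rate chosen so that
pairwise identities land on the requested bands; protein and nucleotide
divergence are simulated independently at consistent band levels, and the
16S gene evolves at a fixed fraction (default 1/5) of the genomic
substitution rate, mirroring its relative conservation — the 98.8% species
band then co-occurs with the 95% AAI band.  All generators are
seed-deterministic and emit their truth objects.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Alphabet, SequenceRecord, SequenceSet, write_fasta

_NUC = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Environmental effect templates (beta, per z-scored parameter) for the
#: three planted ecogenomic groups.  Strong effects have |beta| = 1; the
#: copiotroph group repeats the cold-water sign pattern with uniformly
#: stronger magnitudes, and the warm-water group inverts the nutrient signs.
BETA_TEMPLATES: dict[str, dict[str, float]] = {
    "LT": {"temperature": -1.0, "nitrate": 0.5, "nitrite": 0.5,
           "phosphate": 0.5, "silicate": 0.25, "depth": 0.25,
           "min_generation_time": 0.25, "salinity": -0.5, "oxygen": -0.5,
           "cell_density": -0.5, "autotroph_density": -0.25},
    "LTC": {"temperature": -1.0, "nitrate": 1.0, "nitrite": 1.0,
            "phosphate": 1.0, "silicate": 0.5, "depth": 0.5,
            "min_generation_time": 0.5, "salinity": -1.0, "oxygen": -1.0,
            "cell_density": -1.0, "autotroph_density": -1.0},
    "HTO": {"temperature": 1.0, "nitrate": -1.0, "nitrite": -1.0,
            "phosphate": -1.0, "silicate": 0.0, "depth": 0.0,
            "min_generation_time": 0.0, "salinity": 0.0, "oxygen": 0.0,
            "cell_density": 0.5, "autotroph_density": 1.0},
}


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to every generated dataset."""

    species_of: dict[str, str] = field(default_factory=dict)
    genus_of: dict[str, str] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)
    beta: pd.DataFrame | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    protein_bands: tuple[float, float, float] | None = None
    nucleotide_bands: tuple[float, float, float] | None = None


# ---------------------------------------------------------------------------
# Sequence evolution


def random_sequence(length: int, alphabet: Alphabet, rng: np.random.Generator,
                    record_id: str = "seq") -> SequenceRecord:
    chars = _NUC if Alphabet(alphabet) is Alphabet.nucleotide else _AA
    residues = "".join(rng.choice(list(chars), size=length))
    return SequenceRecord(record_id, residues, alphabet)


def _substitute(residues: str, rate: float, alphabet: Alphabet,
                rng: np.random.Generator,
                exact_count: bool = False) -> tuple[str, int]:
    """Substitute sites at ``rate`` to a uniform alternative residue.

    With ``exact_count`` the number of substituted sites is fixed to
    round(rate * length) (sites drawn without replacement), pinning the
    realized identity to the target; otherwise each site mutates
    independently with probability ``rate``.
    """
    chars = _NUC if alphabet is Alphabet.nucleotide else _AA
    arr = list(residues)
    if exact_count:
        n_subs = min(int(round(rate * len(arr))), len(arr))
        sites = rng.choice(len(arr), size=n_subs, replace=False)
    else:
        sites = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in sites:
        current = arr[i]
        alternatives = [c for c in chars if c != current]
        arr[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(arr), len(sites)


def _apply_indels(residues: str, indel_rate: float,
                  rng: np.random.Generator, alphabet: Alphabet) -> str:
    if indel_rate <= 0:
        return residues
    chars = _NUC if alphabet is Alphabet.nucleotide else _AA
    out = []
    i = 0
    while i < len(residues):
        if rng.random() < indel_rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append("".join(rng.choice(list(chars), size=length)))
        out.append(residues[i])
        i += 1
    return "".join(out) or residues[:1]


def evolve_sequences(ancestor: SequenceSet, target_identity: float,
                     indel_rate: float = 0.0, seed: int = 0,
                     rng: np.random.Generator | None = None,
                     exact_count: bool = False
                     ) -> tuple[SequenceSet, dict[str, float]]:
    """Evolve every record toward a target percent identity.

    Substitutions hit sites at rate 1 - identity/100 and always change the
    residue (uniform over alternatives); indels, if enabled, are geometric
    with mean length 2.  ``exact_count`` fixes the number of substituted
    sites to round(rate x length), pinning realized identity to the target
    (used by the clade simulator so planted identities respect their bands
    on every run).  The realized identity of each record (percent of
    ancestral sites left unchanged, before indels) is returned alongside.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    if rng is None:
        rng = np.random.default_rng(seed)
    rate = 1.0 - target_identity / 100.0
    evolved = SequenceSet()
    realized: dict[str, float] = {}
    for rec in ancestor:
        mutated, n_subs = _substitute(rec.residues, rate, rec.alphabet, rng,
                                      exact_count)
        realized[rec.id] = 100.0 * (len(rec.residues) - n_subs) / len(rec.residues)
        mutated = _apply_indels(mutated, indel_rate, rng, rec.alphabet)
        evolved.add(SequenceRecord(rec.id, mutated, rec.alphabet))
    return evolved, realized


def realized_identity(a: SequenceSet, b: SequenceSet) -> float:
    """Positional identity between two indel-free sets sharing record ids.

    Serves as the generator-side oracle for AAI and nucleotide identity:
    since simulated substitutions never shift coordinates, the planted
    identity of a pair is simply the fraction of matching positions,
    averaged over records.
    """
    values = []
    for rec in a:
        other = b[rec.id]
        if len(rec.residues) != len(other.residues):
            raise ValueError(f"record {rec.id!r}: lengths differ (indels?)")
        matches = sum(c1 == c2 for c1, c2 in zip(rec.residues, other.residues))
        values.append(100.0 * matches / len(rec.residues))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Hierarchical clade simulation


@dataclass
class CladeScene:
    """A simulated clade: genomes, proteomes, 16S genes, tree and truth."""

    genomes: dict[str, SequenceSet]
    proteomes: dict[str, SequenceSet]
    s16: dict[str, SequenceRecord]
    newick: str
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        written = []
        for sub in ("genomes", "proteomes"):
            (outdir / sub).mkdir(parents=True, exist_ok=True)
        for gid, contigs in self.genomes.items():
            path = outdir / "genomes" / f"{gid}.fasta"
            write_fasta(contigs, path)
            written.append(path)
        for gid, prots in self.proteomes.items():
            path = outdir / "proteomes" / f"{gid}.faa"
            write_fasta(prots, path)
            written.append(path)
        path = outdir / "s16.fasta"
        write_fasta(SequenceSet(self.s16.values()), path)
        written.append(path)
        path = outdir / "tree.nwk"
        path.write_text(self.newick + "\n")
        written.append(path)
        path = outdir / "truth_taxonomy.tsv"
        ids = sorted(self.truth.species_of)
        pd.DataFrame({
            "species": [self.truth.species_of[g] for g in ids],
            "genus": [self.truth.genus_of[g] for g in ids],
        }, index=pd.Index(ids, name="genome_id")).to_csv(path, sep="\t")
        written.append(path)
        return written


def _edge_identities(bands: tuple[float, float, float]
                     ) -> tuple[float, float, float]:
    """Per-edge identity shares so pairwise identities land on the bands.

    Identity is (approximately) multiplicative along tree paths, so a
    within-species pair (leaf-leaf) needs each leaf edge to carry
    sqrt(band) of identity, and deeper edges carry the remaining ratios.
    """
    species_b, genus_b, between_b = (b / 100.0 for b in bands)
    if not species_b > genus_b > between_b > 0:
        raise ValueError("identity bands must be strictly nested "
                         "(species > genus > between-genus)")
    leaf = math.sqrt(species_b)
    species_edge = math.sqrt(genus_b / species_b)
    genus_edge = math.sqrt(between_b / genus_b)
    return leaf, species_edge, genus_edge


def _branch_length(identity_share: float) -> float:
    return max(-math.log(identity_share), 1e-9)


def make_clade(n_genera: int = 3, species_per_genus: int = 2,
               genomes_per_species: int = 2,
               protein_bands: tuple[float, float, float] = (97.0, 85.0, 55.0),
               nucleotide_bands: tuple[float, float, float] = (97.0, 80.0, 55.0),
               s16_rate_fraction: float = 0.2, seed: int = 0,
               genome_length: int = 8000, n_proteins: int = 16,
               protein_length: int = 150, s16_length: int = 1200) -> CladeScene:
    """Simulate a clade with a planted species/genus partition.

    Sequences evolve down a generated tree whose genus and species nodes
    are clades, with per-edge substitution rates arranged so that pairwise
    identities fall on the requested bands: within species, between species
    of one genus, and between genera.  The emitted truth object records the
    partition and the bands; planted pairwise identities can be recovered
    exactly with :func:`realized_identity`.
    """
    if min(n_genera, species_per_genus, genomes_per_species) < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    p_leaf, p_sp, p_gen = _edge_identities(protein_bands)
    n_leaf, n_sp, n_gen = _edge_identities(nucleotide_bands)

    def s16_share(nuc_share: float) -> float:
        return 1.0 - s16_rate_fraction * (1.0 - nuc_share)

    root_prot = SequenceSet(
        random_sequence(protein_length, Alphabet.protein, rng, f"p{j:03d}")
        for j in range(n_proteins))
    root_gen = SequenceSet([random_sequence(genome_length,
                                            Alphabet.nucleotide, rng,
                                            "chromosome")])
    root_16s = SequenceSet([random_sequence(s16_length, Alphabet.nucleotide,
                                            rng, "16S")])

    genomes: dict[str, SequenceSet] = {}
    proteomes: dict[str, SequenceSet] = {}
    s16: dict[str, SequenceRecord] = {}
    truth = SyntheticTruth(seed=seed, protein_bands=protein_bands,
                           nucleotide_bands=nucleotide_bands)
    genus_subtrees = []
    for gi in range(1, n_genera + 1):
        gen_prot, _ = evolve_sequences(root_prot, 100 * p_gen, rng=rng, exact_count=True)
        gen_gen, _ = evolve_sequences(root_gen, 100 * n_gen, rng=rng, exact_count=True)
        gen_16s, _ = evolve_sequences(root_16s, 100 * s16_share(n_gen), rng=rng, exact_count=True)
        species_subtrees = []
        for si in range(1, species_per_genus + 1):
            sp_prot, _ = evolve_sequences(gen_prot, 100 * p_sp, rng=rng, exact_count=True)
            sp_gen, _ = evolve_sequences(gen_gen, 100 * n_sp, rng=rng, exact_count=True)
            sp_16s, _ = evolve_sequences(gen_16s, 100 * s16_share(n_sp),
                                         rng=rng, exact_count=True)
            leaves = []
            for ki in range(1, genomes_per_species + 1):
                gid = f"g{gi:02d}s{si:02d}n{ki:02d}"
                prot, _ = evolve_sequences(sp_prot, 100 * p_leaf, rng=rng, exact_count=True)
                gen, _ = evolve_sequences(sp_gen, 100 * n_leaf, rng=rng, exact_count=True)
                gene16, _ = evolve_sequences(sp_16s, 100 * s16_share(n_leaf),
                                             rng=rng, exact_count=True)
                genomes[gid] = SequenceSet(
                    SequenceRecord(f"{gid}_chr", rec.residues,
                                   Alphabet.nucleotide) for rec in gen)
                proteomes[gid] = prot
                rec16 = next(iter(gene16))
                s16[gid] = SequenceRecord(gid, rec16.residues,
                                          Alphabet.nucleotide)
                truth.species_of[gid] = f"g{gi:02d}_s{si:02d}"
                truth.genus_of[gid] = f"g{gi:02d}"
                leaves.append(f"{gid}:{_branch_length(n_leaf):.6f}")
            species_subtrees.append(_join_newick(
                leaves, _branch_length(n_sp)))
        genus_subtrees.append(_join_newick(species_subtrees,
                                           _branch_length(n_gen)))
    newick = _join_newick(genus_subtrees, 0.0).rsplit(":", 1)[0] + ";"
    _assert_bands(proteomes, truth)
    return CladeScene(genomes, proteomes, s16, newick, truth)


def _join_newick(children: list[str], parent_edge: float) -> str:
    if len(children) == 1:
        # collapse unary node: extend the single child's terminal edge
        label, length = children[0].rsplit(":", 1)
        return f"{label}:{float(length) + parent_edge:.6f}"
    return f"({','.join(children)}):{parent_edge:.6f}"


def _assert_bands(proteomes: Mapping[str, SequenceSet],
                  truth: SyntheticTruth) -> None:
    """Planted identities must respect the partition bands on every run."""
    species_b, genus_b, _ = truth.protein_bands
    ids = sorted(proteomes)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident = realized_identity(proteomes[a], proteomes[b])
            if truth.species_of[a] == truth.species_of[b]:
                ok = ident > (species_b + genus_b) / 2
            elif truth.genus_of[a] == truth.genus_of[b]:
                ok = (genus_b - 10) < ident < (species_b + genus_b) / 2
            else:
                ok = ident < genus_b - 10
            if not ok:
                raise AssertionError(
                    f"planted identity {ident:.1f} for pair ({a}, {b}) "
                    "violates its partition band")


# ---------------------------------------------------------------------------
# Environmental tables and communities


def make_env_table(n_samples: int = 40, seed: int = 0) -> pd.DataFrame:
    """Sample x parameter table with an oceanic temperature-nutrient pattern.

    Temperature follows a gradient across samples; nitrate, nitrite,
    phosphate and silicate decrease with temperature (cold waters are
    nutrient-rich); salinity, oxygen, depth, cell densities and minimum
    generation time carry independent noise.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    samples = [f"sample_{i:03d}" for i in range(1, n_samples + 1)]
    temp = np.linspace(2.0, 30.0, n_samples) + rng.normal(0, 0.5, n_samples)
    z = (temp - temp.mean()) / temp.std()

    def nutrient(scale: float, noise: float) -> np.ndarray:
        return np.clip(scale * (1.2 - 0.8 * z) + rng.normal(0, noise,
                                                            n_samples), 0.0,
                       None)

    env = pd.DataFrame({
        "temperature": temp,
        "nitrate": nutrient(5.0, 1.2),
        "nitrite": nutrient(0.5, 0.12),
        "phosphate": nutrient(0.8, 0.2),
        "silicate": nutrient(3.0, 0.8),
        "salinity": rng.normal(35.0, 1.0, n_samples),
        "oxygen": rng.normal(250.0, 20.0, n_samples),
        "depth": rng.uniform(5.0, 200.0, n_samples),
        "cell_density": rng.lognormal(11.0, 0.5, n_samples),
        "autotroph_density": rng.lognormal(9.0, 0.5, n_samples),
        "min_generation_time": rng.normal(10.0, 2.0, n_samples),
    }, index=pd.Index(samples, name="sample_id"))
    return env


def planted_abundance(env: pd.DataFrame, beta: pd.DataFrame, sigma: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Log-linear abundance model closed to one per sample.

    log a_gs = sum_p beta_gp z(env_ps) + eps_gs with eps ~ Normal(0, sigma).
    """
    z = (env - env.mean()) / env.std(ddof=0)
    z = z.fillna(0.0)
    params = [p for p in beta.columns if p in z.columns]
    loga = beta[params].to_numpy() @ z[params].to_numpy().T
    loga = loga + rng.normal(0.0, sigma, loga.shape)
    a = np.exp(loga)
    a = a / a.sum(axis=0, keepdims=True)
    return pd.DataFrame(a, index=beta.index, columns=env.index)


def simulate_community(genomes: Mapping[str, SequenceSet], env: pd.DataFrame,
                       truth: SyntheticTruth, reads_per_sample: int = 4000,
                       read_length: int = 100, error_rate: float = 0.0,
                       seed: int = 0
                       ) -> tuple[dict[str, SequenceSet], pd.DataFrame]:
    """Draw shotgun reads from a planted community composition.

    Reads are drawn multinomially with probability proportional to
    abundance x genome length, from uniform positions and either strand,
    with substitution errors at ``error_rate``.  Returns per-sample read
    sets and the planted abundance matrix (columns closed to one).
    """
    if reads_per_sample < 100:
        raise ValueError("need at least 100 reads per sample")
    if truth.beta is None:
        raise ValueError("truth must carry a beta matrix")
    rng = np.random.default_rng(seed)
    gids = list(truth.beta.index)
    lengths = {g: sum(len(rec) for rec in genomes[g]) for g in gids}
    planted = planted_abundance(env, truth.beta, truth.noise_sigma, rng)
    concat = {g: "".join(rec.residues for rec in genomes[g]) for g in gids}
    comp = str.maketrans("ACGTN", "TGCAN")
    reads_by_sample: dict[str, SequenceSet] = {}
    for sample in env.index:
        weights = planted[sample].to_numpy() * np.array(
            [lengths[g] for g in gids], dtype=float)
        p = weights / weights.sum()
        counts = rng.multinomial(reads_per_sample, p)
        records = SequenceSet()
        r = 0
        for g, n_reads in zip(gids, counts):
            seq = concat[g]
            max_start = max(len(seq) - read_length, 0)
            starts = rng.integers(0, max_start + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            for start, flip in zip(starts, strands):
                read = seq[start:start + read_length]
                if flip:
                    read = read.translate(comp)[::-1]
                if error_rate > 0:
                    read, _ = _substitute(read, error_rate,
                                          Alphabet.nucleotide, rng)
                r += 1
                records.add(SequenceRecord(f"{sample}_r{r:06d}", read,
                                           Alphabet.nucleotide))
        reads_by_sample[sample] = records
    return reads_by_sample, planted


@dataclass
class CommunityScene:
    """A simulated metagenome survey with planted ecogenomic groups."""

    genomes: dict[str, SequenceSet]
    env: pd.DataFrame
    reads_by_sample: dict[str, SequenceSet]
    planted_abundance: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        written = []
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        for gid, contigs in self.genomes.items():
            path = outdir / "genomes" / f"{gid}.fasta"
            write_fasta(contigs, path)
            written.append(path)
        for sample, reads in self.reads_by_sample.items():
            path = outdir / "reads" / f"{sample}.fasta"
            write_fasta(reads, path)
            written.append(path)
        for name, frame in (("env.tsv", self.env),
                            ("abundance_planted.tsv", self.planted_abundance),
                            ("truth_beta.tsv", self.truth.beta)):
            path = outdir / name
            frame.to_csv(path, sep="\t")
            written.append(path)
        path = outdir / "truth_groups.tsv"
        ids = sorted(self.truth.group_of)
        pd.DataFrame({"group": [self.truth.group_of[g] for g in ids]},
                     index=pd.Index(ids, name="genome_id")).to_csv(path,
                                                                   sep="\t")
        written.append(path)
        return written


def make_ecogroup_scene(n_per_group: int = 10, n_samples: int = 40,
                        genome_length: int = 5000,
                        reads_per_sample: int = 4000, read_length: int = 100,
                        error_rate: float = 0.0, sigma: float = 0.2,
                        seed: int = 0) -> CommunityScene:
    """Simulate the default ecogroup study: 3 sign-patterned groups of
    genomes surveyed across an environmental gradient.

    Genomes are independent random sequences (so k-mer recruitment is
    unambiguous); per-genome environmental effects follow the group's
    template in :data:`BETA_TEMPLATES` and abundances follow the
    log-linear model with noise ``sigma`` on the log scale.
    """
    rng = np.random.default_rng(seed)
    env = make_env_table(n_samples, seed=int(rng.integers(2 ** 31)))
    genomes: dict[str, SequenceSet] = {}
    truth = SyntheticTruth(noise_sigma=sigma, seed=seed)
    rows = []
    index = []
    for group, template in BETA_TEMPLATES.items():
        for i in range(1, n_per_group + 1):
            gid = f"{group}_{i:02d}"
            genomes[gid] = SequenceSet([random_sequence(
                genome_length, Alphabet.nucleotide, rng, f"{gid}_chr")])
            truth.group_of[gid] = group
            rows.append([template.get(p, 0.0) for p in env.columns])
            index.append(gid)
    truth.beta = pd.DataFrame(rows, index=index, columns=env.columns)
    reads, planted = simulate_community(
        genomes, env, truth, reads_per_sample=reads_per_sample,
        read_length=read_length, error_rate=error_rate,
        seed=int(rng.integers(2 ** 31)))
    return CommunityScene(genomes, env, reads, planted, truth)
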