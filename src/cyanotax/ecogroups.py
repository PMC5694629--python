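"""Ecogenomic group inference from abundance-environment correlations.

Each genome's ecological niche is summarised by its profile of Spearman
rank correlations between per-sample relative abundance and measured
environmental parameters (temperature, nutrient concentrations, salinity,
oxygen, depth, cell densities, ...).  Profiles are compared by Manhattan
distance and clustered with complete linkage; the dendrogram cut into k
groups yields the ecogenomic groups.  All correlations enter the
clustering regardless of significance — weak associations are still
ecologically informative — while Benjamini-Hochberg q-values are reported
alongside for annotation.

Groups are named from sign rules on their mean correlations: a warm-water
nutrient-averse group (positive temperature rho, negative nutrient rho) is
the High Temperature Oligotroph; cold-water nutrient-associated groups are
ranked by the strength of their nutrient correlation into Low Temperature
Copiotroph (stronger) and Low Temperature (weaker).

Samples themselves are ordinated by non-metric multidimensional scaling of
Bray-Curtis dissimilarities between their genome abundance columns.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import braycurtis, pdist, squareform
from sklearn.manifold import smacof

from .abundance import AbundanceMatrix

log = logging.getLogger(__name__)

#: Canonical environmental parameter vocabulary.
ENV_PARAMETERS = ["temperature", "nitrate", "nitrite", "phosphate",
                  "silicate", "salinity", "oxygen", "depth", "cell_density",
                  "autotroph_density", "min_generation_time"]

NUTRIENT_PARAMETERS = ("nitrate", "nitrite", "phosphate")

GROUP_LOW_TEMP = "Low Temperature"
GROUP_LOW_TEMP_COPIOTROPH = "Low Temperature Copiotroph"
GROUP_HIGH_TEMP_OLIGOTROPH = "High Temperature Oligotroph"
GROUP_UNNAMED = "unnamed"


def validate_env_table(env: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Check a sample x parameter table; drop parameters too sparse to use.

    At least three samples are required; a parameter enters correlation
    analysis only with at least ``min_obs`` non-missing values.
    """
    if env.shape[0] < 3:
        raise ValueError("environmental table needs at least 3 samples")
    keep = [c for c in env.columns if env[c].notna().sum() >= min_obs]
    dropped = set(env.columns) - set(keep)
    if dropped:
        log.warning("parameters dropped (<%d observations): %s", min_obs,
                    sorted(dropped))
    return env[keep]


# ---------------------------------------------------------------------------
# Spearman correlation profiles


@dataclass
class CorrelationProfile:
    """Genome x parameter Spearman rho with p, BH q and n per cell."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_obs: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for g in self.rho.index:
            for param in self.rho.columns:
                rows.append((g, param, self.rho.loc[g, param],
                             self.p.loc[g, param], self.q.loc[g, param],
                             int(self.n_obs.loc[g, param])))
        return pd.DataFrame(rows, columns=["genome", "parameter", "rho",
                                           "p", "q", "n"])

    def write(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided permutation p-value by full enumeration (n < 10 only)."""
    n = len(x)
    if n >= 10:
        raise ValueError("exact permutation p only available for n < 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    observed = abs(rho)
    count = 0
    total = 0
    for perm in permutations(ry):
        ry_p = np.asarray(perm)
        r = float(np.mean(rx * (ry_p - ry_p.mean()) / ry_p.std()))
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_profile(abundance: AbundanceMatrix | pd.DataFrame,
                     env: pd.DataFrame,
                     p_method: str = "t") -> CorrelationProfile:
    """Correlate every genome's abundance with every parameter.

    Correlations use pairwise-complete samples with average ranks for
    ties; two-sided p-values come from the t approximation (``p_method
    = "exact"`` switches to full permutation enumeration, n < 10 only).
    Cells with a constant vector or fewer than 3 paired observations are
    recorded as missing.  q-values are Benjamini-Hochberg adjusted across
    all computed cells jointly.
    """
    table = abundance.abundance if isinstance(abundance, AbundanceMatrix) \
        else abundance
    shared = [s for s in table.columns if s in env.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared sample ids")
    env = validate_env_table(env.loc[shared])
    genomes = list(table.index)
    params = list(env.columns)
    rho = pd.DataFrame(np.nan, index=genomes, columns=params)
    pval = pd.DataFrame(np.nan, index=genomes, columns=params)
    nobs = pd.DataFrame(0, index=genomes, columns=params)
    for param in params:
        y_all = env[param]
        mask = y_all.notna().to_numpy()
        y = y_all.to_numpy(dtype=float)[mask]
        nonmiss = [shared[i] for i in np.flatnonzero(mask)]
        for g in genomes:
            x = table.loc[g, nonmiss].to_numpy(dtype=float)
            nobs.loc[g, param] = len(x)
            if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r, p = stats.spearmanr(x, y)
            if math.isnan(r):
                continue
            if p_method == "exact":
                p = _spearman_exact_p(x, y, r)
            elif p_method != "t":
                raise ValueError(f"unknown p_method {p_method!r}")
            rho.loc[g, param] = r
            pval.loc[g, param] = p
    flat = pval.to_numpy().ravel()
    qflat = bh_adjust(flat)
    q = pd.DataFrame(qflat.reshape(pval.shape), index=genomes, columns=params)
    return CorrelationProfile(rho=rho, p=pval, q=q, n_obs=nobs)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    NaN entries pass through unchanged and do not count toward the number
    of tests.  Values outside [0, 1] raise ``ValueError``.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    valid = ~np.isnan(flat)
    vals = flat[valid]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out_flat = out.ravel()
    out_flat[valid] = q
    return out_flat.reshape(p.shape)


# ---------------------------------------------------------------------------
# Ecogroup clustering and naming


@dataclass
class EcoGroupAssignment:
    """Genome-to-group mapping with optional rule-derived group names."""

    group_of: dict[str, str]
    linkage_matrix: np.ndarray
    genome_order: list[str]
    names: dict[str, str] = field(default_factory=dict)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)

    def named_group_of(self) -> dict[str, str]:
        return {g: self.names.get(grp, GROUP_UNNAMED)
                for g, grp in self.group_of.items()}

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.group_of)
        return pd.DataFrame({
            "group": [self.group_of[g] for g in ids],
            "name": [self.names.get(self.group_of[g], GROUP_UNNAMED)
                     for g in ids],
        }, index=pd.Index(ids, name="genome_id"))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def ecogroup_cluster(profiles: CorrelationProfile, k: int = 3,
                     method: str = "complete") -> EcoGroupAssignment:
    """Cluster correlation profiles into k ecogenomic groups.

    Manhattan distances between genome rho vectors feed complete-linkage
    agglomeration; the dendrogram is cut into ``k`` groups.  Missing rho
    cells are imputed as 0 (no association) and flagged.  Genomes are
    processed in identifier order so the result is input-order invariant.
    """
    rho = profiles.rho.sort_index()
    genomes = list(rho.index)
    if not 1 <= k <= len(genomes):
        raise ValueError(f"k={k} out of range for {len(genomes)} genomes")
    all_missing = rho.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"all-missing profile row(s): {list(rho.index[all_missing])}")
    imputed = [(g, param) for g in genomes for param in rho.columns
               if math.isnan(rho.loc[g, param])]
    filled = rho.fillna(0.0).to_numpy(dtype=float)
    if len(genomes) == 1:
        return EcoGroupAssignment({genomes[0]: "group_01"},
                                  np.empty((0, 4)), genomes,
                                  imputed_cells=imputed)
    z = linkage(pdist(filled, metric="cityblock"), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    clusters: dict[int, set[str]] = {}
    for g, lab in zip(genomes, labels):
        clusters.setdefault(int(lab), set()).add(g)
    ordered = sorted(clusters.values(), key=min)
    group_of = {}
    for i, members in enumerate(ordered, start=1):
        for g in members:
            group_of[g] = f"group_{i:02d}"
    return EcoGroupAssignment(group_of, z, genomes, imputed_cells=imputed)


def name_groups(assignment: EcoGroupAssignment,
                profiles: CorrelationProfile,
                temperature_param: str = "temperature",
                nutrient_params: Sequence[str] = NUTRIENT_PARAMETERS
                ) -> EcoGroupAssignment:
    """Name groups from the signs of their mean correlations.

    Per group, T-bar is the mean temperature rho and N-bar the mean rho
    over the nutrient parameters.  T-bar > 0 with N-bar < 0 names the High
    Temperature Oligotroph (the strongest such group if several qualify);
    groups with T-bar < 0 and N-bar > 0 are ranked by |N-bar|, the
    strongest being the Low Temperature Copiotroph and the next the Low
    Temperature group.  Anything failing all rules stays unnamed.
    """
    rho = profiles.rho
    nutrients = [p for p in nutrient_params if p in rho.columns]
    groups = sorted(set(assignment.group_of.values()))
    tbar: dict[str, float] = {}
    nbar: dict[str, float] = {}
    for grp in groups:
        members = [g for g, gr in assignment.group_of.items() if gr == grp]
        t = rho.loc[members, temperature_param].mean() \
            if temperature_param in rho.columns else math.nan
        n = rho.loc[members, nutrients].to_numpy(dtype=float)
        tbar[grp] = float(t) if not math.isnan(t) else 0.0
        nbar[grp] = float(np.nanmean(n)) if n.size else 0.0
    names: dict[str, str] = {}
    hot = [g for g in groups if tbar[g] > 0 and nbar[g] < 0]
    if hot:
        strongest = max(hot, key=lambda g: tbar[g] - nbar[g])
        names[strongest] = GROUP_HIGH_TEMP_OLIGOTROPH
    cold = [g for g in groups if tbar[g] < 0 and nbar[g] > 0]
    cold.sort(key=lambda g: abs(nbar[g]), reverse=True)
    if len(cold) >= 2:
        names[cold[0]] = GROUP_LOW_TEMP_COPIOTROPH
        names[cold[1]] = GROUP_LOW_TEMP
    elif len(cold) == 1:
        names[cold[0]] = GROUP_LOW_TEMP
    return EcoGroupAssignment(assignment.group_of, assignment.linkage_matrix,
                              assignment.genome_order, names,
                              assignment.imputed_cells)


# ---------------------------------------------------------------------------
# Sample ordination


def bray_curtis(a: Sequence[float] | np.ndarray,
                b: Sequence[float] | np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) between two columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the same genome order")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(braycurtis(a, b))


def sample_dissimilarity(abundance: AbundanceMatrix | pd.DataFrame
                         ) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between sample columns."""
    table = abundance.abundance if isinstance(abundance, AbundanceMatrix) \
        else abundance
    samples = list(table.columns)
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            d = bray_curtis(table[a].to_numpy(), table[b].to_numpy())
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


@dataclass(frozen=True)
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"nmds{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _classical_mds_init(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centring eigendecomposition as deterministic init."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    comps = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if comps.shape[1] < dims:
        comps = np.pad(comps, ((0, 0), (0, dims - comps.shape[1])))
    return comps


def nmds_embed(dissimilarity: pd.DataFrame | np.ndarray, dims: int = 2,
               seed: int = 0, max_iter: int = 300, tol: float = 1e-6,
               n_init: int = 8) -> NMDSResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Iterative majorisation (SMACOF) with monotone regression on the
    dissimilarity ranks.  One restart starts from the classical-scaling
    configuration (deterministic); the remaining ``n_init - 1`` restarts
    are random, seeded from ``seed``.  The configuration with the lowest
    stress is returned; stress lies in [0, 1].
    """
    if isinstance(dissimilarity, pd.DataFrame):
        labels = [str(c) for c in dissimilarity.columns]
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    n = d.shape[0]
    if not 1 <= dims < n:
        raise ValueError(f"dims={dims} out of range for {n} points")
    rng = np.random.default_rng(seed)
    inits = [_classical_mds_init(d, dims)]
    inits += [rng.standard_normal((n, dims)) for _ in range(max(n_init - 1, 0))]
    best: tuple[float, np.ndarray] | None = None
    for init in inits:
        coords, stress = smacof(d, metric=False, n_components=dims,
                                init=init, n_init=1, max_iter=max_iter,
                                eps=tol, normalized_stress=True)
        if best is None or stress < best[0]:
            best = (float(stress), coords)
    return NMDSResult(coordinates=best[1], stress=best[0], labels=labels)
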