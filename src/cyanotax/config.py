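"""Run configuration: thresholds, knobs and seeds, serialisable to text."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .taxonomy import Thresholds


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    The delimitation cut-offs default to the community values (species:
    AAI >= 95, GGD >= 70, 16S >= 98.8; genus: AAI >= 70); the genome
    inclusion filter to completeness >= 90% and < 500 contigs.  The config
    is serialised into every output directory for reproducibility.
    """

    aai_species: float = 95.0
    ggd_species: float = 70.0
    s16_species: float = 98.8
    aai_genus: float = 70.0
    min_completeness: float = 90.0
    max_contigs: int = 500
    kmer_k: int = 31
    min_fraction: float = 0.5
    n_groups: int = 3
    linkage_method: str = "complete"
    nmds_dims: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("aai_species", "ggd_species", "s16_species", "aai_genus",
                     "min_completeness"):
            value = getattr(self, name)
            if not 0 <= value <= 100:
                raise ValueError(f"{name}={value} must lie in [0, 100]")

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(aai_species=self.aai_species,
                          ggd_species=self.ggd_species,
                          s16_species=self.s16_species,
                          aai_genus=self.aai_genus)

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value.strip())
        return cls(**kwargs)
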