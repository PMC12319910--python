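"""Run configuration for the end-to-end gradient pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All tunable pipeline parameters, with the study's standard defaults.

    threshold_fraction
        Fraction of off-diagonal entries retained per connectivity row (0.10).
    alpha
        Diffusion anisotropy parameter of the embedding (0.5).
    n_components / n_aligned / n_analyzed
        Components computed, Procrustes-aligned, and analyzed in the
        manifold (10 / 10 / 3).
    n_perm / n_rotations
        Sign-flip permutations and spin rotations (1000 each).
    fdr_alpha
        Significance level for FDR-controlled families (0.05).
    seed
        Master seed; every source of randomness derives from it.
    """

    threshold_fraction: float = 0.10
    alpha: float = 0.5
    n_components: int = 10
    n_aligned: int = 10
    n_analyzed: int = 3
    n_perm: int = 1000
    n_rotations: int = 1000
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.n_analyzed != 3:
            raise ValueError("the manifold analysis is defined on exactly 3 gradients")
        if self.n_aligned > self.n_components:
            raise ValueError("cannot align more components than are computed")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        loaded.update(overrides)
        return cls(**loaded)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **{k: v for k, v in kw.items() if v is not None})
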