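"""Pipeline configuration and its default parameter values."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class PipelineConfig:
    """All tunables of the pseudotime pipeline.

    Defaults: k = 50
    neighbours for cell classification, branching threshold at the 80th
    nonlinearity percentile, tip threshold 0.9, adaptive alignment
    neighbourhoods in [40, 100], and a two-dimensional diffusion-map
    embedding.
    """

    k: int = 50
    delta_b_percentile: float = 0.80
    delta_t: float = 0.9
    kmin: int = 40
    kmax: int = 100
    D: int = 2
    d: int = 1
    root: str | None = None
    seed: int = 0

    # preprocessing toggles
    normalize: bool = True        # size-factor normalisation
    log1p: bool = False
    use_diffusion: bool = True    # bypass -> treat input rows as coordinates
    pca_predim: int | None = None
    diffusion_sigma: float | None = None

    # branch clustering
    candidate_branches: tuple[int, int] = (2, 8)
    tighten_by_tips: bool = True
    n_branches: int | None = None  # bypass silhouette selection
    n_anchor: int | None = None    # default: min(k, branch size)

    # scoring / solver options
    consistency_norm: str = "full"
    eig_raw: bool = False

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0.0 < self.delta_b_percentile < 1.0:
            raise ValueError("delta_b_percentile must be in (0, 1)")
        if self.kmin > self.kmax:
            raise ValueError(f"kmin={self.kmin} exceeds kmax={self.kmax}")
        if self.kmin < self.d + 2:
            raise ValueError("kmin must be at least d + 2")
        if self.D < 1 or self.d < 1 or self.d >= max(self.D, 2):
            raise ValueError("need 1 <= d < D")
        lo, hi = self.candidate_branches
        if lo < 2 or hi < lo:
            raise ValueError("candidate branch range must satisfy 2 <= lo <= hi")
        if self.consistency_norm not in ("full", "pairs"):
            raise ValueError("consistency_norm must be 'full' or 'pairs'")

    def as_dict(self) -> dict:
        return asdict(self)
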