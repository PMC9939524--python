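"""Run configuration: geometric constants and score weights.

All defaults are the published operating point of the method: a 0.6 Å
voxel grid with a 1.4 Å water probe, a 5 Å heavy-atom cutoff defining the
interaction interface, seed points separated by more than 5 Å, 10 Å patch
spheres, 1 Å geodesic-histogram bins, 512 visibility rays with a 0.3 Å
blocking tolerance, and order-15 Zernike descriptors (72 invariants per
feature).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

FEATURES = ("shape", "electrostatic", "visibility", "hbond", "hydrophobicity")


@dataclass(frozen=True)
class ScoreWeights:
    """Trainable weights of the patch distance, patch score and interface score.

    ``feature_w`` weights the per-feature descriptor distances inside the
    patch distance (order: shape, electrostatic potential, visibility,
    hydrogen-bond donor/acceptor, hydrophobicity).  ``patch_w`` = (w_P, w_R,
    w_A) weights patch distance, seed RMSD and patch-position-histogram
    distance in the matching objective.  ``ppi_k`` = (k_P, k_R, k_A, k_S)
    weights the averaged terms plus the size difference in the final
    interface score.  Defaults are the grid-search-trained values.
    """

    feature_w: tuple[float, float, float, float, float] = (1.0, 0.1, 1.0, 0.3, 1.6)
    patch_w: tuple[float, float, float] = (0.7, 0.9, 1.7)
    ppi_k: tuple[float, float, float, float] = (0.6, 0.1, 0.2, 0.1)

    def __post_init__(self) -> None:
        for group in (self.feature_w, self.patch_w, self.ppi_k):
            if any(w < 0 for w in group):
                raise ValueError("score weights must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """All geometric constants of the pipeline, in Å unless noted."""

    grid_spacing: float = 0.6
    probe_radius: float = 1.4
    interface_cutoff: float = 5.0
    seed_separation: float = 5.0
    patch_radius: float = 10.0
    app_bin_width: float = 1.0
    app_n_bins: int = 50
    n_rays: int = 512
    ray_length: float = 20.0
    block_tol: float = 0.3
    zernike_order: int = 15
    zernike_dim: int = 64
    patch_scale_margin: float = 1.25
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    version: str = "1"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        w = d.pop("weights", None)
        weights = ScoreWeights(
            feature_w=tuple(w["feature_w"]),
            patch_w=tuple(w["patch_w"]),
            ppi_k=tuple(w["ppi_k"]),
        ) if w else ScoreWeights()
        return cls(weights=weights, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


DEFAULT_CONFIG = RunConfig()
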