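"""Pipeline defaults shared across filtrations, vectorisation and classification.

All length units are the simulation's dimensionless cell-diameter-scaled units
(cell radius 0.5, domain [0, 50] x [0, 50]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class ImageSpecConfig:
    birth_range: tuple[float, float]
    pers_range: tuple[float, float]
    resolution: tuple[int, int]
    sigma: float


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults for the full featurisation / classification pipeline.

    eps_tumour : fixed linkage radius for tumour complexes (radial filtration
        and intersection-based constructions); selected by a coarse sweep.
    eps_macrophage_zigzag : linkage radius for macrophage zigzag complexes.
    basepoint, radial_R : radial-filtration basepoint and maximum radius.
    vr_max_eps_* : truncation radius for VR filtrations, matched to the
        persistence-image window so truncated features fall outside the image.
    times : end times (hours) at which classifiers are trained.
    window_snapshots : number of snapshots in a dynamic (vineyard/zigzag)
        window; the window ends at t - 10 and is sampled every 10 h.
    """

    eps_tumour: float = 0.7
    eps_macrophage_zigzag: float = 2.0
    basepoint: tuple[float, float] = (25.0, 25.0)
    radial_R: float = 35.0
    vr_max_eps_tumour: float = 5.0
    vr_max_eps_macrophage: float = 10.0
    times: tuple[int, ...] = (250, 300, 350, 400, 450, 500)
    window_snapshots: int = 10
    snapshot_interval: int = 10

    # persistence-image windows; sigma is half a pixel width for VR images
    vr_image_tumour: ImageSpecConfig = field(
        default_factory=lambda: ImageSpecConfig((0.0, 5.0), (0.0, 5.0), (20, 20), 0.125)
    )
    vr_image_macrophage: ImageSpecConfig = field(
        default_factory=lambda: ImageSpecConfig((0.0, 10.0), (0.0, 10.0), (20, 20), 0.25)
    )
    radial_image: ImageSpecConfig = field(
        default_factory=lambda: ImageSpecConfig((0.0, 35.0), (0.0, 8.0), (35, 8), 0.5)
    )
    vineyard_image: ImageSpecConfig = field(
        default_factory=lambda: ImageSpecConfig((0.5, 10.5), (0.0, 10.0), (10, 20), 0.5)
    )
    zigzag_image: ImageSpecConfig = field(
        default_factory=lambda: ImageSpecConfig((-0.5, 18.5), (0.5, 19.5), (19, 19), 0.5)
    )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in (
            "vr_image_tumour",
            "vr_image_macrophage",
            "radial_image",
            "vineyard_image",
            "zigzag_image",
        ):
            if key in raw:
                spec = raw[key]
                raw[key] = ImageSpecConfig(
                    tuple(spec["birth_range"]),
                    tuple(spec["pers_range"]),
                    tuple(spec["resolution"]),
                    spec["sigma"],
                )
        for key in ("basepoint", "times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


DEFAULT_CONFIG = PipelineConfig()
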