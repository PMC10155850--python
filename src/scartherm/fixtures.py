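"""Fixture generation: config files, perturbed material sets, and masks.

These generators are the only place randomness enters the package, and
every one is deterministic under a fixed seed.  They exist to support
testing and sensitivity analysis:

* ``default_config`` writes the study's canonical configuration file;
* ``perturbed_materials`` writes N config variants whose thermophysical
  closure values (and optionally optics) are jittered by a stated
  relative amount, for sensitivity studies of the temperature targets;
* ``masks`` writes synthetic binary collagen masks hitting requested
  target fractions exactly (positive-pixel counts are rounded to the
  nearest integer), for exercising the histology metric.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RunConfig
from .histology import SegmentationMask

__all__ = ["generate_fixtures", "synthetic_mask", "perturbed_configs"]


def synthetic_mask(fraction: float, shape=(100, 100), seed: int = 0) -> SegmentationMask:
    """Random binary mask whose positive fraction is round(f*N)/N."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    n_pos = int(round(fraction * n))
    flat = np.zeros(n, dtype=bool)
    flat[rng.choice(n, size=n_pos, replace=False)] = True
    return SegmentationMask(flat.reshape(shape))


def perturbed_configs(n: int = 5, rel: float = 0.1, seed: int = 0,
                      perturb_optics: bool = False) -> list[RunConfig]:
    """Config variants with closure values jittered by +-``rel`` (uniform)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        cfg = RunConfig()
        for key in ("rho", "c", "k"):
            cfg.data["closure"][key] *= float(1.0 + rel * rng.uniform(-1, 1))
        cfg.data["solver"]["h_W_per_m2K"] *= float(1.0 + rel * rng.uniform(-1, 1))
        if perturb_optics:
            for mat in cfg.data["materials"].values():
                for key in ("mu_a", "mu_s"):
                    mat[key] *= float(1.0 + rel * rng.uniform(-1, 1))
        out.append(cfg)
    return out


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0, **kwargs) -> list[Path]:
    """Write fixture files of the requested kind and return their paths.

    kind : {"default_config", "perturbed_materials", "masks"}
        masks accepts ``fractions`` (default: the untreated-scar and
        normal-skin collagen reference levels 0.84 and 0.56) and
        ``shape``; perturbed_materials accepts ``n`` and ``rel``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if kind == "default_config":
        path = out_dir / "default_config.yaml"
        RunConfig().save(path)
        paths.append(path)
    elif kind == "perturbed_materials":
        cfgs = perturbed_configs(kwargs.get("n", 5), kwargs.get("rel", 0.1), seed)
        for i, cfg in enumerate(cfgs):
            path = out_dir / f"perturbed_{i:02d}.yaml"
            cfg.save(path)
            paths.append(path)
    elif kind == "masks":
        from PIL import Image

        fractions = kwargs.get("fractions", (0.84, 0.56))
        shape = kwargs.get("shape", (100, 100))
        for frac in fractions:
            mask = synthetic_mask(frac, shape, seed)
            path = out_dir / f"mask_{int(round(frac * 100)):03d}pct.png"
            Image.fromarray(mask.data.astype(np.uint8) * 255, mode="L").save(path)
            paths.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
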