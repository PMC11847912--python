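"""On-disk round trip for synthetic cohorts.

Layout written under a cohort directory::

    responses.csv      one row per response (RESPONSE_COLUMNS schema)
    images.csv         generative ground truth per image
    config.yaml        echo of the SyntheticConfig
    wound_images/      one 8-bit RGB PNG per image (optional)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .cohort import IMAGE_COLUMNS, RESPONSE_COLUMNS, Cohort
from .config import SyntheticConfig

_RESPONSE_DTYPES = {"postop_day": int, "ssi48": int}
_IMAGE_DTYPES = {"pus_count": int, "render_seed": int}


def write_cohort(
    cohort: Cohort,
    directory: str | Path,
    *,
    overwrite: bool = False,
    render_images: bool = True,
) -> Path:
    """Write a cohort to ``directory``; refuses to clobber unless ``overwrite``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    targets = [directory / "responses.csv", directory / "images.csv", directory / "config.yaml"]
    clashes = [t for t in targets if t.exists()]
    if clashes and not overwrite:
        raise FileExistsError(f"refusing to overwrite existing cohort files: {clashes[0]}")

    cohort.responses.to_csv(directory / "responses.csv", index=False)
    cohort.images.to_csv(directory / "images.csv", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)

    if render_images and len(cohort.images):
        img_dir = directory / "wound_images"
        img_dir.mkdir(exist_ok=True)
        for image_id in cohort.images["image_id"]:
            out = img_dir / f"{image_id}.png"
            if out.exists() and not overwrite:
                raise FileExistsError(f"refusing to overwrite {out}")
            synth = cohort.render_image(image_id)
            arr = np.clip(np.rint(synth.pixels * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="RGB").save(out)
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    responses = pd.read_csv(
        directory / "responses.csv", dtype=str, keep_default_na=False
    )
    missing = set(RESPONSE_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"responses.csv missing columns: {sorted(missing)}")
    for col, typ in _RESPONSE_DTYPES.items():
        responses[col] = responses[col].astype(typ)
    images = pd.read_csv(directory / "images.csv", dtype=str, keep_default_na=False)
    if len(images):
        missing = set(IMAGE_COLUMNS) - set(images.columns)
        if missing:
            raise ValueError(f"images.csv missing columns: {sorted(missing)}")
        for col in ("erythema_intensity", "skin_tone"):
            images[col] = images[col].astype(float)
        for col, typ in _IMAGE_DTYPES.items():
            images[col] = images[col].astype(typ)
    else:
        images = pd.DataFrame(columns=IMAGE_COLUMNS)
    with open(directory / "config.yaml") as fh:
        config = SyntheticConfig.from_dict(yaml.safe_load(fh))
    return Cohort(responses=responses[list(RESPONSE_COLUMNS)], images=images, config=config)
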