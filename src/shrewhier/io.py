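"""On-disk interchange formats.

Spike and event tables travel as CSV with documented headers; image banks as
directories of 8-bit grayscale PNGs with a JSON manifest; feature banks as
HDF5 with datasets ``/features``, ``/pc_basis``, ``/pc_mean``, ``/pc_scores``
and a ``layer`` attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .synthetic.features import FeatureBank
from .synthetic.images import ImageBank

__all__ = [
    "write_spikes_csv",
    "read_spikes_csv",
    "write_events_csv",
    "read_events_csv",
    "write_feature_bank",
    "read_feature_bank",
    "write_image_bank",
    "read_image_bank",
]

SPIKE_COLUMNS = ["unit_id", "area", "time_s", "amplitude"]
EVENT_COLUMNS = ["stim_id", "stim_class", "onset_s", "duration_s", "params_json"]


def write_spikes_csv(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes[SPIKE_COLUMNS].to_csv(path, index=False)


def read_spikes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    if "params_json" not in out:
        extra = [c for c in out.columns if c not in EVENT_COLUMNS]
        out["params_json"] = [
            json.dumps({c: row[c] for c in extra}, default=_json_default) for _, row in out.iterrows()
        ]
    out[EVENT_COLUMNS].to_csv(path, index=False)


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_events_csv(path: str | Path, expand_params: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if expand_params and "params_json" in df:
        params = df["params_json"].map(json.loads).apply(pd.Series)
        df = pd.concat([df.drop(columns=["params_json"]), params], axis=1)
    return df


def write_feature_bank(bank: FeatureBank, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layer"] = bank.layer_name
        f.create_dataset("image_ids", data=bank.image_ids)
        f.create_dataset("features", data=bank.features, compression="gzip")
        f.create_dataset("pc_basis", data=bank.pc_basis)
        f.create_dataset("pc_mean", data=bank.pc_mean)
        f.create_dataset("pc_scores", data=bank.pc_scores)


def read_feature_bank(path: str | Path) -> FeatureBank:
    with h5py.File(path, "r") as f:
        return FeatureBank(
            layer_name=str(f.attrs["layer"]),
            image_ids=f["image_ids"][...],
            features=f["features"][...],
            pc_basis=f["pc_basis"][...],
            pc_mean=f["pc_mean"][...],
            pc_scores=f["pc_scores"][...],
        )


def write_image_bank(bank: ImageBank, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, img_id in enumerate(bank.image_ids):
        name = f"img_{int(img_id):05d}.png"
        arr = np.clip(bank.pixels[i] * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / name)
        manifest.append(
            dict(
                id=int(img_id),
                file=name,
                category=str(bank.category[i]),
                family=int(bank.family[i]),
                partner_id=int(bank.partner_id[i]),
                n_repeats=int(bank.n_repeats),
            )
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_image_bank(directory: str | Path) -> ImageBank:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    ids, pixels, category, family, partner = [], [], [], [], []
    for entry in manifest:
        ids.append(entry["id"])
        pixels.append(np.asarray(Image.open(directory / entry["file"]), dtype=float) / 255.0)
        category.append(entry["category"])
        family.append(entry["family"])
        partner.append(entry["partner_id"])
    return ImageBank(
        image_ids=np.asarray(ids),
        pixels=np.stack(pixels),
        category=np.asarray(category, dtype=object),
        family=np.asarray(family),
        partner_id=np.asarray(partner),
        n_repeats=int(manifest[0]["n_repeats"]) if manifest else 1,
    )
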