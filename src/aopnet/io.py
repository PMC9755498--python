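"""On-disk dataset layout: PNG images, indexed PNG masks, manifest CSV.

Layout of a dataset directory::

    images/<image_id>.png   8-bit grayscale frame
    masks/<image_id>.png    indexed PNG, 0 background / 1 PS / 2 FH
    manifest.csv            per-image ground truth and generator parameters

The manifest stores the exact key points (Ut/Lt = superior/inferior PS
endpoints, Tp = tangent point), the analytic AoP, and the generating
ellipse parameters, so a directory round-trips to in-memory samples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import AoPKeyPoints, Point2D
from .synthetic import PhantomSpec, SyntheticSample

__all__ = ["save_dataset", "load_dataset", "save_mask_png", "load_mask_png"]

_PALETTE = [0, 0, 0, 255, 80, 80, 80, 160, 255] + [0] * (256 * 3 - 9)

MANIFEST_COLUMNS = [
    "image_id", "patient_id",
    "Ut_x", "Ut_y", "Lt_x", "Lt_y", "Tp_x", "Tp_y", "aop_deg",
    "height", "width",
    "ps_cx", "ps_cy", "ps_semi_major", "ps_semi_minor", "ps_theta",
    "fh_cx", "fh_cy", "fh_semi_major", "fh_semi_minor", "fh_theta",
    "speckle_sigma", "blur_sigma", "fan_angle_deg", "seed",
]


def save_mask_png(mask: np.ndarray, path) -> None:
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_PALETTE)
    im.save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("P"), dtype=np.uint8)


def save_dataset(samples: list[SyntheticSample], out_dir) -> None:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img8 = np.clip((s.image + 1.0) * 127.5, 0, 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / "images" / f"{s.image_id}.png")
        save_mask_png(s.mask, out / "masks" / f"{s.image_id}.png")
        k = s.gt_keypoints
        sp = s.spec
        rows.append({
            "image_id": s.image_id, "patient_id": s.patient_id,
            "Ut_x": k.Up.x, "Ut_y": k.Up.y, "Lt_x": k.Lp.x, "Lt_y": k.Lp.y,
            "Tp_x": k.Tp.x, "Tp_y": k.Tp.y, "aop_deg": s.gt_aop_deg,
            "height": sp.image_size[0], "width": sp.image_size[1],
            "ps_cx": sp.ps_center[0], "ps_cy": sp.ps_center[1],
            "ps_semi_major": sp.ps_axes[0], "ps_semi_minor": sp.ps_axes[1],
            "ps_theta": sp.ps_theta,
            "fh_cx": sp.fh_center[0], "fh_cy": sp.fh_center[1],
            "fh_semi_major": sp.fh_axes[0], "fh_semi_minor": sp.fh_axes[1],
            "fh_theta": sp.fh_theta,
            "speckle_sigma": sp.speckle_sigma, "blur_sigma": sp.blur_sigma,
            "fan_angle_deg": sp.fan_angle_deg, "seed": sp.seed,
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out / "manifest.csv", index=False)


def load_dataset(in_dir) -> list[SyntheticSample]:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    samples = []
    for _, r in manifest.iterrows():
        image_id = str(r["image_id"])
        img8 = np.asarray(
            Image.open(src / "images" / f"{image_id}.png").convert("L"), dtype=np.float32
        )
        image = (img8 / 127.5 - 1.0).astype(np.float32)
        mask = load_mask_png(src / "masks" / f"{image_id}.png")
        spec = PhantomSpec(
            image_size=(int(r["height"]), int(r["width"])),
            ps_center=(float(r["ps_cx"]), float(r["ps_cy"])),
            ps_axes=(float(r["ps_semi_major"]), float(r["ps_semi_minor"])),
            ps_theta=float(r["ps_theta"]),
            fh_center=(float(r["fh_cx"]), float(r["fh_cy"])),
            fh_axes=(float(r["fh_semi_major"]), float(r["fh_semi_minor"])),
            fh_theta=float(r["fh_theta"]),
            speckle_sigma=float(r["speckle_sigma"]),
            blur_sigma=float(r["blur_sigma"]),
            fan_angle_deg=float(r["fan_angle_deg"]),
            seed=int(r["seed"]),
        )
        keypoints = AoPKeyPoints(
            Up=Point2D(float(r["Ut_x"]), float(r["Ut_y"])),
            Lp=Point2D(float(r["Lt_x"]), float(r["Lt_y"])),
            Tp=Point2D(float(r["Tp_x"]), float(r["Tp_y"])),
        )
        samples.append(
            SyntheticSample(
                image=image, mask=mask, gt_keypoints=keypoints,
                gt_aop_deg=float(r["aop_deg"]), spec=spec,
                patient_id=str(r["patient_id"]), image_id=image_id,
            )
        )
    return samples
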