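"""End-to-end orchestration: phantoms -> crop -> DRR -> preprocess ->
package -> split -> train -> evaluate -> angle sweep.

A single YAML config with per-stage sections drives the run; every
artifact is listed in a JSON manifest with its stage, inputs and the seed
in force, and any prefix/subset of stages can be re-run against existing
artifacts.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml
from skimage.transform import resize

from . import drr, eval_metrics, phantom, recon_gan, volume_roi, xray_prep
from .types import CTVolume, PairedSample

__all__ = ["PipelineConfig", "run_pipeline", "assemble_samples", "STAGES"]

log = logging.getLogger("vert2ct")

STAGES = (
    "phantoms",
    "crop",
    "drr",
    "preprocess",
    "package",
    "split",
    "train",
    "evaluate",
    "angle_sweep",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "vert2ct_run"
    phantom: dict = field(default_factory=dict)
    drr: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    gan: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if "transfer_function" not in self.drr:
            raise ValueError(
                "config is missing drr.transfer_function (six [intensity, "
                "opacity] control points)"
            )
        # constructing the value objects validates every stage up front
        self.tf()
        self.gan_config()
        if self.phantom.get("n_cases", 4) < 2:
            raise ValueError("phantom.n_cases must be >= 2 (train/test split)")

    def tf(self) -> drr.OpacityTransferFunction:
        pts = tuple(tuple(p) for p in self.drr["transfer_function"])
        return drr.OpacityTransferFunction(pts)

    def gan_config(self) -> recon_gan.GanConfig:
        g = dict(self.gan)
        weights = g.pop("loss_weights", None)
        kwargs = dict(seed=self.seed, **g)
        if weights is not None:
            kwargs["loss_weights"] = recon_gan.LossWeights(**weights)
        return recon_gan.GanConfig(**kwargs)

    def intensity_scale(self) -> float:
        return float(self.drr.get("intensity_scale", 2500.0))


class _Manifest:
    def __init__(self, path: str, seed: int):
        self.path = path
        self.seed = seed
        self.entries = []
        if os.path.exists(path):
            with open(path) as fh:
                self.entries = json.load(fh)

    def add(self, stage: str, artifact: str, inputs=()):
        self.entries.append(
            {
                "stage": stage,
                "artifact": artifact,
                "inputs": list(inputs),
                "seed": self.seed,
            }
        )
        with open(self.path, "w") as fh:
            json.dump(self.entries, fh, indent=1)


def _case_ids(cfg: PipelineConfig):
    n = cfg.phantom.get("n_cases", 4)
    return [f"case_{i:04d}" for i in range(n)]


def run_pipeline(config, stages=None, log_dir: str | None = None) -> str:
    """Execute the configured stages; returns the artifacts directory.

    ``config`` is a path to a YAML file, a dict, or a PipelineConfig.  A
    failing stage raises with the stage name; artifacts of completed
    stages are retained.
    """
    if isinstance(config, PipelineConfig):
        cfg = config
        cfg.validate()
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = PipelineConfig.from_yaml(config)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = _Manifest(os.path.join(out, "manifest.json"), cfg.seed)

    tf = cfg.tf()
    scale = cfg.intensity_scale()
    gan_cfg = cfg.gan_config()
    size = gan_cfg.volume_size
    geom = drr.ProjectionGeometry(
        image_size=(size, size),
        intensity_scale=scale,
        step_mm=float(cfg.drr.get("step_mm", 1.0)),
    )
    ids = _case_ids(cfg)

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            log.info("stage %s: start", stage)
            _run_stage(stage, cfg, out, manifest, tf, geom, scale, gan_cfg, ids)
            log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def assemble_samples(
    case_dirs,
    size: int,
    scale: float = 2500.0,
    tf: drr.OpacityTransferFunction | None = None,
    lateral_angle_deg: float = 90.0,
) -> list[PairedSample]:
    """In-memory crop → DRR → preprocess → resize for a list of phantom
    case directories; one PairedSample per case."""
    geom = drr.ProjectionGeometry(image_size=(size, size), intensity_scale=scale)
    samples = []
    for d in case_dirs:
        vol = volume_roi.read_volume(os.path.join(d, "ct.nii.gz"))
        mask = volume_roi.read_mask(os.path.join(d, "mask.nii.gz"))
        cvol, _ = volume_roi.crop_to_mask(vol, mask)
        ant, lat = drr.make_biplanar(cvol, tf, lateral_angle_deg, geom)
        x1 = xray_prep.preprocess_xray(ant.pixels, out_size=size).pixels
        x2 = xray_prep.preprocess_xray(lat.pixels, out_size=size).pixels
        samples.append(
            PairedSample(
                ct=_norm_resize(cvol, size, scale),
                xray1=x1,
                xray2=x2,
                case_id=os.path.basename(d),
            )
        )
    return samples


def _norm_resize(vol: CTVolume, size: int, scale: float) -> np.ndarray:
    data = np.clip(np.asarray(vol.data, dtype=np.float64) / scale, 0, 1)
    if data.shape != (size, size, size):
        data = np.clip(resize(data, (size, size, size), order=1,
                              anti_aliasing=False), 0, 1)
    return data


def _run_stage(stage, cfg, out, manifest, tf, geom, scale, gan_cfg, ids):
    size = gan_cfg.volume_size
    ph_dir = os.path.join(out, "phantoms")
    crop_dir = os.path.join(out, "cropped")
    drr_dir = os.path.join(out, "drr")
    prep_dir = os.path.join(out, "preprocessed")
    h5_dir = os.path.join(out, "cases")
    split_csv = os.path.join(out, "split.csv")

    if stage == "phantoms":
        spec_kwargs = {
            k: v
            for k, v in cfg.phantom.items()
            if k in phantom.PhantomSpec.__dataclass_fields__
        }
        if "volume_shape" in spec_kwargs:
            spec_kwargs["volume_shape"] = tuple(spec_kwargs["volume_shape"])
        base = phantom.PhantomSpec(**spec_kwargs)
        dirs = phantom.generate_cohort(
            cfg.phantom.get("n_cases", 4),
            cfg.phantom.get("spec_ranges"),
            seed=cfg.seed,
            out_dir=ph_dir,
            base_spec=base,
        )
        for d in dirs:
            manifest.add("phantoms", d)

    elif stage == "crop":
        for cid in ids:
            src = os.path.join(ph_dir, cid)
            vol = volume_roi.read_volume(os.path.join(src, "ct.nii.gz"))
            mask = volume_roi.read_mask(os.path.join(src, "mask.nii.gz"))
            cvol, cmask = volume_roi.crop_to_mask(vol, mask)
            dst = os.path.join(crop_dir, cid)
            os.makedirs(dst, exist_ok=True)
            volume_roi.write_volume(cvol, os.path.join(dst, "ct.nii.gz"))
            volume_roi.write_mask(
                cmask,
                os.path.join(dst, "mask.nii.gz"),
                voxel_size=cvol.voxel_size_mm,
                origin=cvol.origin_mm,
            )
            manifest.add("crop", dst, [src])

    elif stage == "drr":
        angle = float(cfg.drr.get("lateral_angle_deg", 90.0))
        mode = cfg.drr.get("mode", "composite")
        for cid in ids:
            vol = volume_roi.read_volume(os.path.join(crop_dir, cid, "ct.nii.gz"))
            ant, lat = drr.make_biplanar(vol, tf, angle, geom, mode)
            dst = os.path.join(drr_dir, cid)
            os.makedirs(dst, exist_ok=True)
            for name, img in ((f"{cid}_anterior.png", ant), (f"{cid}_lateral.png", lat)):
                drr.save_png(img, os.path.join(dst, name))
                manifest.add("drr", os.path.join(dst, name), [crop_dir])

    elif stage == "preprocess":
        import imageio.v3 as iio

        out_size = int(cfg.preprocess.get("out_size", size))
        for cid in ids:
            dst = os.path.join(prep_dir, cid)
            os.makedirs(dst, exist_ok=True)
            for view in ("anterior", "lateral"):
                raw = iio.imread(os.path.join(drr_dir, cid, f"{cid}_{view}.png"))
                img = xray_prep.preprocess_xray(
                    raw,
                    out_size=out_size,
                    threshold=cfg.preprocess.get(
                        "threshold", xray_prep.DEFAULT_THRESHOLD
                    ),
                )
                drr.save_png(img, os.path.join(dst, f"{cid}_{view}.png"))
                manifest.add("preprocess", os.path.join(dst, f"{cid}_{view}.png"))

    elif stage == "package":
        import imageio.v3 as iio

        os.makedirs(h5_dir, exist_ok=True)
        for cid in ids:
            vol = volume_roi.read_volume(os.path.join(crop_dir, cid, "ct.nii.gz"))
            ct = _norm_resize(vol, size, scale)
            x1 = iio.imread(
                os.path.join(prep_dir, cid, f"{cid}_anterior.png")
            ).astype(np.float64) / 255.0
            x2 = iio.imread(
                os.path.join(prep_dir, cid, f"{cid}_lateral.png")
            ).astype(np.float64) / 255.0
            path = os.path.join(h5_dir, f"{cid}.h5")
            xray_prep.package_case(ct, x1, x2, path, scale)
            manifest.add("package", path)

    elif stage == "split":
        split = xray_prep.split_cases(
            ids, cfg.split.get("train_frac", 0.8), seed=cfg.seed
        )
        with open(split_csv, "w") as fh:
            fh.write("case_id,partition\n")
            for cid in split.train_ids:
                fh.write(f"{cid},train\n")
            for cid in split.test_ids:
                fh.write(f"{cid},test\n")
        manifest.add("split", split_csv)

    elif stage == "train":
        train_ids = _read_split(split_csv)["train"]
        samples = [
            xray_prep.read_case(os.path.join(h5_dir, f"{cid}.h5"), cid)
            for cid in train_ids
        ]
        result = recon_gan.train(samples, gan_cfg, log_dir=os.path.join(out, "train"))
        manifest.add("train", result.log_path or "")
        for c in result.checkpoints:
            manifest.add("train", c)

    elif stage == "evaluate":
        model = _load_model(out, gan_cfg)
        test_ids = _read_split(split_csv)["test"]
        pairs = []
        for cid in test_ids:
            s = xray_prep.read_case(os.path.join(h5_dir, f"{cid}.h5"), cid)
            pairs.append((s.ct, model.predict_volume(s.xray1, s.xray2)))
        report = eval_metrics.evaluate_pairs(
            pairs, eval_metrics.IntensityScale(scale)
        )
        path = os.path.join(out, "metrics.csv")
        eval_metrics.report_frame(report).to_csv(path)
        manifest.add("evaluate", path)

    elif stage == "angle_sweep":
        model = _load_model(out, gan_cfg)
        test_ids = _read_split(split_csv)["test"]
        cases = []
        for cid in test_ids:
            vol = volume_roi.read_volume(os.path.join(crop_dir, cid, "ct.nii.gz"))
            cases.append(
                CTVolume(_norm_resize(vol, size, scale) * scale, vol.voxel_size_mm)
            )
        angles = tuple(cfg.eval.get("angles", (90.0, 85.0, 80.0, 75.0)))
        report = eval_metrics.angle_sweep(
            lambda x1, x2: model.predict_volume(x1, x2),
            cases,
            angles=angles,
            tf=tf,
            geom=geom,
            scale=eval_metrics.IntensityScale(scale),
            out_size=size,
        )
        path = os.path.join(out, "angle_sweep.csv")
        eval_metrics.report_frame(report).to_csv(path)
        manifest.add("angle_sweep", path)


def _read_split(path) -> dict:
    if not os.path.exists(path):
        raise FileNotFoundError(f"split manifest {path} not found; run 'split' first")
    out = {"train": [], "test": []}
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, part = line.strip().split(",")
            out[part].append(cid)
    return out


def _load_model(out, gan_cfg) -> recon_gan.TwoViewFusionGenerator:
    train_dir = os.path.join(out, "train")
    ckpts = sorted(
        f for f in os.listdir(train_dir) if f.endswith(".npz")
    ) if os.path.isdir(train_dir) else []
    if not ckpts:
        raise FileNotFoundError("no generator checkpoint found; run 'train' first")
    G = recon_gan.build_generator(gan_cfg)
    with np.load(os.path.join(train_dir, ckpts[-1])) as data:
        G.load_state_arrays([data[f"arr_{i}"] for i in range(len(data.files))])
    return G
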