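"""End-to-end pipeline driver: synth -> preprocess -> patch/augment ->
train -> evaluate, with per-stage caching and a structural/hyperparameter
ablation runner.

Each stage writes its outputs under the run directory and records a hash
of its resolved configuration (chained with the upstream hash) in
``manifest.json``; re-running with an unchanged config is a no-op for
every stage whose hash and outputs are intact.  The global seed fans out
to the synthetic generator, the weight init and the training shuffle, so
two runs with the same config produce identical manifests.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np

from masegnet.metrics import evaluate
from masegnet.model import ModelConfig, build_model, load_checkpoint
from masegnet.preprocess import (
    AugmentSpec,
    PreprocessConfig,
    augment,
    extract_patches,
    preprocess,
    preprocess_mask,
)
from masegnet.synth import SynthConfig, generate_dataset
from masegnet.train import TrainConfig, train

__all__ = ["RunConfig", "run_pipeline", "run_ablation", "STRUCTURAL_GRID"]


def _from_dict(cls, payload: dict):
    """Strict dataclass construction: unknown keys are an error, list
    values for tuple fields are coerced."""
    if not isinstance(payload, dict):
        raise TypeError(f"expected mapping for {cls.__name__}, got {payload!r}")
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in payload:
            continue
        v = payload[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    """One resolved experiment: data scale, all stage parameters, seed."""

    n_train: int = 8
    n_test: int = 2
    image_size: int = 512
    seed: int = 0
    threshold: float = 0.5
    synth: SynthConfig = SynthConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    model: ModelConfig = ModelConfig()
    train: TrainConfig = TrainConfig()

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        for key, sub in (("synth", SynthConfig),
                         ("preprocess", PreprocessConfig),
                         ("model", ModelConfig),
                         ("train", TrainConfig)):
            if key in payload:
                payload[key] = _from_dict(sub, payload[key])
        return _from_dict(cls, payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def resolved(self) -> "RunConfig":
        """Fan the global seed out to every stochastic stage and align the
        synthetic image size and the preprocessing target size."""
        synth = dataclasses.replace(
            self.synth, seed=self.seed, image_size=self.image_size)
        pre = dataclasses.replace(self.preprocess,
                                  target_size=self.image_size)
        model = dataclasses.replace(self.model, seed=self.seed + 1)
        train_cfg = dataclasses.replace(self.train, seed=self.seed + 2)
        return dataclasses.replace(self, synth=synth, preprocess=pre,
                                   model=model, train=train_cfg)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_hash(payload, upstream: str = "") -> str:
    text = upstream + json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages: dict[str, dict] = {}
        if path.exists():
            self.stages = json.loads(path.read_text()).get("stages", {})

    def fresh(self, stage: str, h: str, outputs: list[Path]) -> bool:
        rec = self.stages.get(stage)
        return (rec is not None and rec.get("hash") == h
                and all(Path(o).exists() for o in rec.get("outputs", [])))

    def record(self, stage: str, h: str, outputs: list[Path],
               stats: dict | None = None) -> None:
        self.stages[stage] = {
            "hash": h,
            "outputs": [str(o) for o in outputs],
            "stats": stats or {},
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(
            json.dumps({"stages": self.stages}, indent=2) + "\n")


def _fail(stage: str, err: Exception):
    raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 progress: bool = False) -> dict:
    """Run (or resume) the full pipeline under ``out_dir``.

    Returns the manifest dict; the resolved config is written beside the
    outputs for provenance.  Stage stats include the patch bookkeeping
    (patches per image, train/test patch counts, count after x4
    augmentation).
    """
    cfg = config.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, default=str) + "\n")
    manifest = _Manifest(out / "manifest.json")

    # stage 1: synthetic data ------------------------------------------------
    h_synth = _stage_hash({"synth": asdict(cfg.synth),
                           "n_train": cfg.n_train, "n_test": cfg.n_test})
    data_dir = out / "data"
    if not manifest.fresh("synth", h_synth, [data_dir / "manifest.json"]):
        try:
            generate_dataset(cfg.n_train, cfg.n_test, cfg.synth, data_dir,
                             overwrite=True)
        except Exception as e:  # noqa: BLE001
            _fail("synth", e)
        manifest.record("synth", h_synth, [data_dir / "manifest.json"],
                        {"n_train": cfg.n_train, "n_test": cfg.n_test})

    # stage 2: preprocessing -------------------------------------------------
    h_pre = _stage_hash(asdict(cfg.preprocess), h_synth)
    pre_path = out / "preprocessed.npz"
    if not manifest.fresh("preprocess", h_pre, [pre_path]):
        import imageio.v3 as iio

        data_manifest = json.loads((data_dir / "manifest.json").read_text())
        arrays = {}
        try:
            entries = data_manifest["entries"]
            iterator = entries
            if progress:
                from tqdm import tqdm
                iterator = tqdm(entries, desc="preprocess")
            for entry in iterator:
                img = iio.imread(data_dir / entry["image"])
                msk = iio.imread(data_dir / entry["mask"]) > 127
                gray = preprocess(img, cfg.preprocess)
                mask = preprocess_mask(msk.astype(np.uint8), cfg.preprocess,
                                       crop_like=img)
                arrays[f"{entry['id']}_gray"] = gray.astype(np.float32)
                arrays[f"{entry['id']}_mask"] = mask
        except Exception as e:  # noqa: BLE001
            _fail("preprocess", e)
        np.savez_compressed(pre_path, **arrays)
        manifest.record("preprocess", h_pre, [pre_path],
                        {"n_images": len(arrays) // 2})

    # stage 3: patches + augmentation ---------------------------------------
    h_patch = _stage_hash({"patch_size": cfg.preprocess.patch_size}, h_pre)
    patch_path = out / "patches.npz"
    if not manifest.fresh("patch", h_patch, [patch_path]):
        data_manifest = json.loads((data_dir / "manifest.json").read_text())
        with np.load(pre_path) as pre:
            splits = {"train": ([], []), "test": ([], [])}
            p = cfg.preprocess.patch_size
            for entry in data_manifest["entries"]:
                gray = pre[f"{entry['id']}_gray"]
                mask = pre[f"{entry['id']}_mask"]
                gp, mp = extract_patches(gray, p), extract_patches(mask, p)
                splits[entry["split"]][0].extend(gp.patches)
                splits[entry["split"]][1].extend(mp.patches)
        n_img_patches = (cfg.image_size // p) ** 2
        train_p, train_m = splits["train"]
        test_p, test_m = splits["test"]
        n_train_patches, n_test_patches = len(train_p), len(test_p)
        from masegnet.preprocess import PatchSet
        tp = PatchSet(train_p, [(0, 0)] * len(train_p),
                      (cfg.image_size, cfg.image_size), p)
        tm = PatchSet(train_m, [(0, 0)] * len(train_m),
                      (cfg.image_size, cfg.image_size), p)
        aug_p, aug_m = augment(tp, tm, AugmentSpec())
        stats = {
            "patches_per_image": n_img_patches,
            "n_train_patches": n_train_patches,
            "n_test_patches": n_test_patches,
            "n_train_patches_augmented": len(aug_p),
        }
        np.savez_compressed(
            patch_path,
            train_patches=np.stack(aug_p.patches) if len(aug_p) else
            np.zeros((0, p, p), np.float32),
            train_masks=np.stack(aug_m.patches) if len(aug_m) else
            np.zeros((0, p, p), np.uint8),
            test_patches=np.stack(test_p) if test_p else
            np.zeros((0, p, p), np.float32),
            test_masks=np.stack(test_m) if test_m else
            np.zeros((0, p, p), np.uint8),
        )
        manifest.record("patch", h_patch, [patch_path], stats)

    # stage 4: training ------------------------------------------------------
    h_train = _stage_hash({"model": asdict(cfg.model),
                           "train": asdict(cfg.train)}, h_patch)
    ckpt_path = out / "model.npz"
    hist_path = out / "history.csv"
    if not manifest.fresh("train", h_train, [ckpt_path, hist_path]):
        with np.load(patch_path) as data:
            train_patches = list(data["train_patches"])
            train_masks = list(data["train_masks"])
        model = build_model(cfg.model)
        try:
            model, history = train(model, train_patches, train_masks,
                                   cfg.train, checkpoint_path=ckpt_path)
        except Exception as e:  # noqa: BLE001
            _fail("train", e)
        history.to_csv(hist_path)
        manifest.record("train", h_train, [ckpt_path, hist_path],
                        {"epochs": len(history),
                         "final_train_loss": history.train_loss[-1],
                         "final_val_loss": history.val_loss[-1],
                         "final_lr": history.learning_rate[-1]})

    # stage 5: evaluation ----------------------------------------------------
    h_eval = _stage_hash({"threshold": cfg.threshold}, h_train)
    report_path = out / "report.json"
    if not manifest.fresh("evaluate", h_eval, [report_path]):
        model = load_checkpoint(ckpt_path)
        data_manifest = json.loads((data_dir / "manifest.json").read_text())
        with np.load(pre_path) as pre:
            test_imgs = [pre[f"{e['id']}_gray"]
                         for e in data_manifest["entries"]
                         if e["split"] == "test"]
            test_msks = [pre[f"{e['id']}_mask"]
                         for e in data_manifest["entries"]
                         if e["split"] == "test"]
        try:
            report = evaluate(model, test_imgs, test_msks,
                              threshold=cfg.threshold,
                              patch_size=cfg.preprocess.patch_size)
        except Exception as e:  # noqa: BLE001
            _fail("evaluate", e)
        report.to_json(report_path)
        manifest.record("evaluate", h_eval, [report_path],
                        {"dice": report.dice, "iou": report.iou,
                         "auc": report.auc, "accuracy": report.accuracy})

    return {"stages": manifest.stages}


# ablation ------------------------------------------------------------------

# the four structural variants: AG on/off x bottleneck 512/256
STRUCTURAL_GRID = [
    {"label": "Unet + CBAM + AG with 512 as a bottleneck (Proposed)",
     "model": {"use_ag": True, "base_filters": 32, "bottleneck_filters": 512}},
    {"label": "Unet + CBAM with 512 as a bottleneck",
     "model": {"use_ag": False, "base_filters": 32, "bottleneck_filters": 512}},
    {"label": "Unet + CBAM + AG with 256 as a bottleneck",
     "model": {"use_ag": True, "base_filters": 16, "bottleneck_filters": 256}},
    {"label": "Unet + CBAM with 256 as a bottleneck",
     "model": {"use_ag": False, "base_filters": 16, "bottleneck_filters": 256}},
]


def run_ablation(config: RunConfig, grid: list[dict], out_dir: str | Path
                 ) -> list[dict]:
    """Train/evaluate one pipeline per grid row; rows override model,
    train or preprocess fields.  Writes ``ablation.csv`` (label, Dice,
    IoU, parameter count) and returns the rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(grid):
        spec = dict(spec)
        label = spec.pop("label", f"config_{i}")
        overrides = {}
        for key in ("model", "train", "preprocess"):
            if key in spec:
                base = asdict(getattr(config, key))
                base.update(spec.pop(key))
                sub_cls = {"model": ModelConfig, "train": TrainConfig,
                           "preprocess": PreprocessConfig}[key]
                overrides[key] = _from_dict(sub_cls, base)
        if spec:
            raise ValueError(f"unknown ablation row keys: {sorted(spec)}")
        cfg_i = dataclasses.replace(config, **overrides)
        run_pipeline(cfg_i, out / f"ablation_{i}")
        report = json.loads((out / f"ablation_{i}" / "report.json").read_text())
        from masegnet.nn import count_parameters
        n_params = count_parameters(build_model(cfg_i.resolved().model))
        rows.append({"label": label, "dice": report["dice"],
                     "iou": report["iou"], "parameters": n_params})
    with open(out / "ablation.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["label", "dice", "iou",
                                                "parameters"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
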