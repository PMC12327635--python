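"""End-to-end workflow: generate/load -> tile -> train members -> predict ->
ensemble-search -> evaluate -> render.

Every stage persists its artifacts under the output directory and a
manifest records seeds, configuration and content hashes, so each number
in the final report is recomputable from the persisted intermediates with
the metrics module alone. Non-training stages are bit-reproducible under a
fixed seed; training reproducibility additionally requires a single BLAS
thread.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import metrics
from .ensemble import EnsembleWeights, ensemble_predict, search_weights
from .legend import DEFAULT_LEGEND
from .losses import LossParams
from .raster import LabelMask, SceneRaster, read_mask, read_scene, render_map, \
    write_mask, write_probability_map, write_scene
from .simulate import DEFAULT_FRACTIONS, SceneSpec, generate_scene
from .tiling import TileSet, augment, patchify, split_tiles, stitch
from .unet import MEMBER_PRESETS, ModelConfig, TrainConfig, UNet, build_unet, \
    predict_probabilities, train_model

log = logging.getLogger("mangroveseg.pipeline")


@dataclass
class MemberSpec:
    """One ensemble member: a named depth/width preset or explicit sizes."""

    name: str
    encoder_depth: int | None = None
    base_width: int | None = None

    def model_config(self, num_classes: int, seed: int) -> ModelConfig:
        if self.encoder_depth is None or self.base_width is None:
            if self.name not in MEMBER_PRESETS:
                raise ValueError(
                    f"member {self.name!r} has no sizes and is not a preset"
                )
            preset = MEMBER_PRESETS[self.name]
            depth = self.encoder_depth or preset["encoder_depth"]
            width = self.base_width or preset["base_width"]
        else:
            depth, width = self.encoder_depth, self.base_width
        return ModelConfig(
            num_classes=num_classes, encoder_depth=depth, base_width=width, seed=seed
        )


@dataclass
class PipelineConfig:
    # scene: either synthesized from these parameters or loaded from paths
    height: int = 256
    width: int = 256
    class_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    color_sd: float = 10.0
    texture_scale: float = 12.0
    image_path: str | None = None
    mask_path: str | None = None
    # tiling
    tile_size: int = 64
    augment_total: int | None = 60
    split_ratio: float = 0.75
    # members and training
    members: list[MemberSpec] = field(
        default_factory=lambda: [MemberSpec("M3"), MemberSpec("M10"), MemberSpec("M12")]
    )
    epochs: int = 8
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss: str = "focal+dice"
    loss_params: LossParams = field(default_factory=LossParams)
    # ensemble search
    grid_step: float = 0.1
    objective: str = "mean_iou"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("member list must be non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "members" in d:
            d["members"] = [
                MemberSpec(**m) if isinstance(m, dict) else MemberSpec(str(m))
                for m in d["members"]
            ]
        if "loss_params" in d and isinstance(d["loss_params"], dict):
            d["loss_params"] = LossParams(**d["loss_params"])
        if "class_fractions" in d:
            d["class_fractions"] = tuple(d["class_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_fractions"] = list(self.class_fractions)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _tiles_npz(path: Path, tiles: TileSet) -> None:
    np.savez_compressed(
        path,
        images=np.stack(tiles.images),
        masks=np.stack(tiles.masks),
        origins=np.asarray(tiles.origins, dtype=np.int64),
        tile_size=np.int64(tiles.tile_size),
    )


def load_tiles(path: str | Path) -> TileSet:
    with np.load(Path(path)) as d:
        return TileSet(
            images=list(d["images"]),
            masks=list(d["masks"]),
            origins=[tuple(o) for o in d["origins"]],
            tile_size=int(d["tile_size"]),
        )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the run report (also persisted as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "hashes": {}}
    t0 = time.time()

    def stage_done(name: str, **info) -> None:
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 2), **info}
        log.info("stage %-16s done (%.1fs elapsed)", name, time.time() - t0)

    try:
        # 1. scene ----------------------------------------------------------
        if config.image_path and config.mask_path:
            scene = read_scene(config.image_path)
            mask = read_mask(config.mask_path)
        else:
            spec = SceneSpec(
                height=config.height, width=config.width,
                class_fractions=config.class_fractions,
                color_sd=config.color_sd, texture_scale=config.texture_scale,
                seed=config.seed,
            )
            scene, mask = generate_scene(spec)
        write_scene(out / "scene.tif", scene)
        write_mask(out / "labels.tif", mask)
        render_map(out / "labels_rendered.png", mask)
        stage_done("generate", shape=list(scene.shape))

        # 2. tile / augment / split ----------------------------------------
        base_tiles = patchify(scene, mask, config.tile_size)
        tiles = base_tiles
        if config.augment_total and config.augment_total > len(base_tiles):
            tiles = augment(base_tiles, seed=config.seed, total=config.augment_total)
        split = split_tiles(tiles, ratio=config.split_ratio, seed=config.seed)
        train_set = tiles.subset(list(split.train_indices))
        val_set = tiles.subset(list(split.val_indices))
        _tiles_npz(out / "tiles.npz", tiles)
        (out / "split.json").write_text(json.dumps(asdict(split), indent=2))
        stage_done("tile", n_tiles=len(tiles), n_train=len(train_set),
                   n_val=len(val_set))

        # 3. train members --------------------------------------------------
        num_classes = mask.legend.num_classes
        member_probs_val: list[np.ndarray] = []
        member_ids: list[str] = []
        reports: dict[str, metrics.MetricReport] = {}
        val_masks = np.concatenate([m.ravel() for m in val_set.masks])
        for k, mspec in enumerate(config.members):
            mcfg = mspec.model_config(num_classes, seed=config.seed + k)
            tcfg = TrainConfig(
                epochs=config.epochs, batch_size=config.batch_size,
                learning_rate=config.learning_rate, loss=config.loss,
                loss_params=config.loss_params, seed=config.seed + 100 + k,
            )
            model = build_unet(mcfg)
            log.info("training member %s (depth %d, width %d)", mspec.name,
                     mcfg.encoder_depth, mcfg.base_width)
            model, history = train_model(model, train_set, val_set, tcfg,
                                         log=log.debug)
            model.save(out / f"{mspec.name}.ckpt.npz")
            history.to_csv(out / f"{mspec.name}_history.csv")
            # stitched full-scene probability map from the grid tiles
            grid_probs = predict_probabilities(model, base_tiles,
                                               batch_size=config.batch_size)
            full = stitch(grid_probs, base_tiles.origins, scene.shape)
            write_probability_map(out / f"{mspec.name}_probs.tif",
                                  np.nan_to_num(full, nan=0.0))
            # held-out evaluation + search input: validation-tile pixels
            val_probs = predict_probabilities(model, val_set,
                                              batch_size=config.batch_size)
            flat = np.concatenate([p.reshape(-1, num_classes) for p in val_probs])
            member_probs_val.append(flat)
            member_ids.append(mspec.name)
            reports[mspec.name] = metrics.evaluate(
                metrics.hard_labels(flat), val_masks, num_classes,
                class_names=mask.legend.names,
            )
            stage_done(f"train:{mspec.name}",
                       final_train_loss=history.train_loss[-1],
                       val_mean_iou=reports[mspec.name].mean_iou)

        # 4. ensemble weight search on the held-out validation pixels -------
        result = search_weights(member_probs_val, val_masks,
                                grid_step=config.grid_step,
                                objective=config.objective,
                                member_ids=tuple(member_ids))
        result.best.to_json(out / "weights.json", objective=result.objective,
                            grid_step=result.grid_step, score=result.best_score,
                            evaluations=result.evaluations)
        stage_done("ensemble-search", weights=list(result.best.weights),
                   score=result.best_score, evaluations=result.evaluations)

        # 5. ensemble evaluation + full-scene map ---------------------------
        em_val = ensemble_predict(member_probs_val, result.best)
        reports["EM"] = metrics.evaluate(metrics.hard_labels(em_val), val_masks,
                                         num_classes, class_names=mask.legend.names)
        metrics.write_report_table(out / "report.csv", reports)
        # rendered map from the stitched member maps
        from .raster import read_probability_map
        full_members = [read_probability_map(out / f"{m}_probs.tif")
                        for m in member_ids]
        em_full = ensemble_predict(full_members, result.best)
        em_mask = LabelMask(metrics.hard_labels(em_full), mask.legend)
        write_mask(out / "ensemble_map.tif", em_mask)
        render_map(out / "ensemble_map.png", em_mask)
        stage_done("evaluate", ensemble_mean_iou=reports["EM"].mean_iou,
                   ensemble_oa=reports["EM"].oa)

        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["hashes"][f.name] = _sha256(f)
        report = {
            "members": {m: reports[m].to_dict() for m in member_ids},
            "ensemble": reports["EM"].to_dict(),
            "weights": {m: w for m, w in zip(member_ids, result.best.weights)},
            "search": {"objective": result.objective,
                       "grid_step": result.grid_step,
                       "score": result.best_score,
                       "evaluations": result.evaluations},
        }
        manifest["report"] = report
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return report
    except Exception as exc:
        failed = next(
            (s for s in ("generate", "tile", "train", "ensemble-search", "evaluate")
             if s not in manifest["stages"] and not any(
                 k.startswith(s) for k in manifest["stages"])),
            "unknown",
        )
        manifest["failed_stage"] = failed
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale three-member demo: synthetic 256x256 scene, 64-px tiles."""
    return PipelineConfig(seed=seed)
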