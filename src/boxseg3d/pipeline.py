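"""Three-stage weakly-supervised training pipeline and baselines.

Stage 1 turns each ground-truth mask into a bounding box (the only use the
reference labels get during training) and runs CRF inference to obtain a
pseudo-mask per case. Stage 2 partitions the training set into K disjoint
subsets, trains one network per subset on its pseudo-masks (class-weighted
cross-entropy), then predicts every training image with every network; the
union of the pseudo-mask and the K predictions, refined by the same CRF
machinery, becomes the fusion mask, and the per-voxel count of foreground
votes (background reset to K+1) becomes the voxel-wise weight map. Stage 3
trains the final network on the fusion masks with the voxel-wise weighted
cross-entropy. A fully-supervised baseline trained on the true masks serves
as the comparison ceiling, and K=0 ablates stage 2 (pseudo-masks train the
final model directly).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .preprocessing import VolumeImage, clip_and_normalize
from .phantoms import PhantomSpec, generate_dataset
from .weak_labels import BoundingBox3D, box_from_mask, box_to_mask
from .crf import CRFParams, LabelMarginals, convcrf_infer, unary_from_box, generate_pseudo_mask
from .losses import ClassWeights, validate_weight_map
from .segmodel import (
    NetworkConfig,
    TrainConfig,
    LossSpec,
    SegmentationModel,
    train_model,
    predict_mask,
)
from . import io as bio

__all__ = [
    "PipelineConfig",
    "GroupTrainingResult",
    "FusionOutput",
    "PipelineResult",
    "partition_dataset",
    "group_train",
    "fuse_masks",
    "build_weight_map",
    "run_weak_pipeline",
    "train_fully_supervised",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config block for the whole run (data, CRF, model, training)."""

    K: int = 3                     # number of group-training subsets; 0 ablates stage 2
    margin_d: int = 5              # bounding-box margin, voxels
    loss: str = "vwce"             # final-stage loss: ce | wce | vwce
    seed: int = 0
    hu_min: float = -200.0
    hu_max: float = 500.0
    crf: CRFParams = field(default_factory=CRFParams)
    fusion_crf: CRFParams | None = None  # None: reuse the stage-1 CRF parameters
    net: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    class_weights: ClassWeights = field(default_factory=ClassWeights)

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.loss not in ("ce", "wce", "vwce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.loss == "vwce" and self.K == 0:
            raise ValueError("vwce needs stage-2 weight maps; use wce/ce with K=0")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GroupTrainingResult:
    models: list[SegmentationModel]
    predictions: list[list[np.ndarray]]  # per image: K binary masks
    subset_assignment: np.ndarray        # image index -> subset index


@dataclass
class FusionOutput:
    fusion_masks: list[np.ndarray]
    weight_maps: list[np.ndarray]


@dataclass
class PipelineResult:
    final_model: SegmentationModel
    boxes: list[BoundingBox3D]
    pseudo_masks: list[np.ndarray]
    group: GroupTrainingResult | None
    fusion: FusionOutput | None
    manifest: dict


def desk_scale_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Reference desk-scale study configuration.

    48^3 phantoms, depth-3 UNet with 4 base channels, K=3 groups, d=5 boxes,
    VWCE final loss, 30 epochs of Adam at lr 3e-3 with 0.95/epoch decay.
    Sized so the full three-arm comparison (weak, ablation, fully-supervised)
    runs in minutes on one CPU core. Keyword overrides replace whole fields.
    """
    base = dict(
        K=3,
        margin_d=5,
        loss="vwce",
        seed=seed,
        net=NetworkConfig(depth=3, base_channels=4, in_shape=(48, 48, 48)),
        train=TrainConfig(lr_init=3e-3, epochs=30, batch_size=4, seed=seed),
    )
    base.update(overrides)
    return PipelineConfig(**base)


def partition_dataset(n_images: int, K: int, seed: int) -> np.ndarray:
    """Random disjoint cover of range(n_images) into K subsets of near-equal size.

    Returns the subset index of every image; subset sizes differ by at most 1.
    """
    if not 1 <= K <= n_images:
        raise ValueError(f"K must be in [1, {n_images}], got {K}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    assignment = np.empty(n_images, dtype=np.int64)
    assignment[order] = np.arange(n_images) % K
    return assignment


def group_train(
    samples: list[tuple[VolumeImage, np.ndarray]],
    pseudo_masks: list[np.ndarray],
    K: int,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    class_weights: ClassWeights = ClassWeights(),
    seed: int | None = None,
) -> GroupTrainingResult:
    """Stage 2: one WCE-trained network per subset, then all-by-all prediction.

    Each training image contributes to exactly one network; afterwards every
    network predicts every image, giving K binary masks per image.
    """
    if len(pseudo_masks) != len(samples):
        raise ValueError("need one pseudo mask per sample")
    n = len(samples)
    seed = train_cfg.seed if seed is None else seed
    assignment = partition_dataset(n, K, seed)
    models: list[SegmentationModel] = []
    for k in range(K):
        idx = np.flatnonzero(assignment == k)
        subset = [(samples[i][0], pseudo_masks[i]) for i in idx]
        cfg_k = replace(train_cfg, seed=seed + 1000 * (k + 1))
        try:
            model, hist = train_model(
                subset, LossSpec(kind="wce", class_weights=class_weights), net_cfg, cfg_k
            )
        except Exception as exc:  # pragma: no cover - defensive context tagging
            raise RuntimeError(f"group training failed for subset {k}") from exc
        logger.info("subset %d/%d: %d images, final loss %.1f", k + 1, K, len(subset), hist[-1])
        models.append(model)
    predictions = [
        [predict_mask(m, img) for m in models] for img, _ in samples
    ]
    return GroupTrainingResult(models=models, predictions=predictions, subset_assignment=assignment)


def fuse_masks(
    image: VolumeImage,
    pseudo_mask: np.ndarray,
    predictions: list[np.ndarray],
    crf_params: CRFParams,
) -> np.ndarray:
    """Fusion mask: CRF-refined union of the pseudo-mask and all predictions.

    The voxelwise OR of the pseudo-mask and the K predictions plays the role
    the box interior played in stage 1: it becomes the foreground-prior
    region of the unary, and mean-field inference trims it against the image
    evidence.
    """
    shape = np.asarray(pseudo_mask).shape
    union = np.asarray(pseudo_mask) > 0
    for p in predictions:
        p = np.asarray(p)
        if p.shape != shape:
            raise ValueError(f"prediction shape {p.shape} != pseudo-mask shape {shape}")
        union = union | (p > 0)
    if not union.any():
        return np.zeros(shape, dtype=np.uint8)
    unary = unary_from_box(union.astype(np.uint8), crf_params)
    marg = convcrf_infer(image, unary, crf_params)
    return (marg.foreground > 0.5).astype(np.uint8)


def build_weight_map(
    pseudo_mask: np.ndarray,
    predictions: list[np.ndarray],
    K: int,
) -> np.ndarray:
    """Voxel-wise confidence weights: v = PM + P1 + ... + PK, v[v == 0] = K+1.

    A voxel marked foreground by j of the K+1 masks gets weight j (agreement
    strength); a voxel no mask marks gets K+1, the confident-background
    weight.
    """
    if len(predictions) != K:
        raise ValueError(f"expected {K} predictions, got {len(predictions)}")
    v = (np.asarray(pseudo_mask) > 0).astype(np.int64)
    for p in predictions:
        p = np.asarray(p)
        if p.shape != v.shape:
            raise ValueError("prediction shape mismatch")
        v = v + (p > 0)
    v[v == 0] = K + 1
    return validate_weight_map(v, k=K)


def _prepare(dataset, hu_min: float, hu_max: float) -> list[tuple[VolumeImage, np.ndarray]]:
    """Normalize a dataset of PhantomSample-likes or (image, mask) pairs."""
    out = []
    for item in dataset:
        if hasattr(item, "image"):
            img, msk = item.image, item.gt_mask
        else:
            img, msk = item
        out.append((clip_and_normalize(img, hu_min, hu_max), np.asarray(msk)))
    return out


def run_weak_pipeline(
    dataset,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    pseudo_masks: list[np.ndarray] | None = None,
) -> PipelineResult:
    """Execute stages 1-3 on a training dataset of (image, gt_mask) cases.

    Ground-truth masks are used only to derive the bounding boxes. With
    ``out_dir`` every intermediate artifact (boxes, pseudo/fusion masks,
    weight maps) is persisted along with a manifest carrying the config hash
    and per-stage timings; partial artifacts survive a failed stage.
    ``pseudo_masks`` short-circuits stage 1 with precomputed masks (e.g. when
    several ablation arms share the same stage-1 output).
    """
    samples = _prepare(dataset, config.hu_min, config.hu_max)
    n = len(samples)
    manifest: dict = {"config_hash": config.hash(), "n_images": n, "stages": {}, "artifacts": {}}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def persist(stage: str, name_fmt: str, arrays, writer) -> None:
        if out is None:
            return
        paths = []
        for i, arr in enumerate(arrays):
            p = out / name_fmt.format(i=i)
            writer(arr, p)
            paths.append(p.name)
        manifest["artifacts"][stage] = paths
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # ---- stage 1: boxes -> pseudo masks ----------------------------------
    t0 = time.perf_counter()
    try:
        boxes = [box_from_mask(msk, config.margin_d) for _, msk in samples]
        if pseudo_masks is not None:
            if len(pseudo_masks) != n:
                raise ValueError("need one precomputed pseudo mask per case")
            pseudo = [np.asarray(p) for p in pseudo_masks]
        else:
            pseudo = [
                generate_pseudo_mask(img, box, config.crf)
                for (img, _), box in zip(samples, boxes)
            ]
    except Exception as exc:
        raise RuntimeError("stage 1 (pseudo-mask generation) failed") from exc
    manifest["stages"]["stage1_seconds"] = round(time.perf_counter() - t0, 2)
    if out is not None:
        for i, box in enumerate(boxes):
            box.save(out / f"case_{i:03d}_box.json", case_id=f"case_{i:03d}")
        manifest["artifacts"]["boxes"] = [f"case_{i:03d}_box.json" for i in range(n)]
    persist("pseudo_masks", "case_{i:03d}_pseudo.nii.gz", pseudo, lambda a, p: bio.save_mask(a, p))

    # ---- stage 2: group training + fusion --------------------------------
    group = None
    fusion = None
    targets = pseudo
    weight_maps = None
    if config.K >= 1:
        t0 = time.perf_counter()
        try:
            group = group_train(
                samples, pseudo, config.K, config.net, config.train,
                class_weights=config.class_weights, seed=config.seed,
            )
            fparams = config.fusion_crf if config.fusion_crf is not None else config.crf
            fusion_masks = [
                fuse_masks(img, pm, preds, fparams)
                for (img, _), pm, preds in zip(samples, pseudo, group.predictions)
            ]
            weight_maps = [
                build_weight_map(pm, preds, config.K)
                for pm, preds in zip(pseudo, group.predictions)
            ]
            fusion = FusionOutput(fusion_masks=fusion_masks, weight_maps=weight_maps)
            targets = fusion_masks
        except Exception as exc:
            raise RuntimeError("stage 2 (group training / fusion) failed") from exc
        manifest["stages"]["stage2_seconds"] = round(time.perf_counter() - t0, 2)
        manifest["subset_sizes"] = np.bincount(group.subset_assignment, minlength=config.K).tolist()
        persist("fusion_masks", "case_{i:03d}_fusion.nii.gz", fusion_masks, lambda a, p: bio.save_mask(a, p))
        persist(
            "weight_maps", "case_{i:03d}_vmap.nii.gz", weight_maps,
            lambda a, p: bio.save_mask_int(a, p),
        )

    # ---- stage 3: final model ---------------------------------------------
    t0 = time.perf_counter()
    spec = LossSpec(
        kind=config.loss,
        class_weights=config.class_weights,
        weight_maps=weight_maps if config.loss == "vwce" else None,
    )
    try:
        final_model, history = train_model(
            [(img, t) for (img, _), t in zip(samples, targets)],
            spec, config.net, replace(config.train, seed=config.seed + 7000),
        )
    except Exception as exc:
        raise RuntimeError("stage 3 (final training) failed") from exc
    manifest["stages"]["stage3_seconds"] = round(time.perf_counter() - t0, 2)
    manifest["final_loss"] = round(history[-1], 6)
    manifest["tag"] = "weakly_supervised"
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        final_model=final_model,
        boxes=boxes,
        pseudo_masks=pseudo,
        group=group,
        fusion=fusion,
        manifest=manifest,
    )


def run_desk_study(
    seed: int = 1,
    n_train: int = 12,
    n_test: int = 6,
    margins: tuple[int, ...] = (0, 5, 10),
    config: PipelineConfig | None = None,
) -> dict:
    """Full desk-scale comparison study on seeded phantoms.

    Generates disjoint training/test phantom sets, measures the quality of
    every weak-label stage on the training set (box masks and pseudo-masks
    per margin, fusion masks for the pipeline margin), trains the three arms
    — weak K=3/VWCE, weak K=0/WCE ablation, fully-supervised WCE — and
    evaluates them on the held-out phantoms with and without
    largest-component post-processing. Returns a flat dict of named means
    plus the problem sizes used. Deterministic under ``seed``.
    """
    from .evaluation import dsc, evaluate_pairs

    config = config if config is not None else desk_scale_config(seed)
    spec = PhantomSpec()
    train = generate_dataset(n_train, spec, seed=(seed * 1000 + 1) % 2**31)
    test = generate_dataset(n_test, spec, seed=(seed * 1000 + 2) % 2**31)
    tr = _prepare(train, config.hu_min, config.hu_max)
    te = _prepare(test, config.hu_min, config.hu_max)

    out: dict = {"n_train": n_train, "n_test": n_test}
    pseudo_for_pipeline: list[np.ndarray] | None = None
    for d in margins:
        box_dscs, pseudo_dscs = [], []
        pseudos = []
        for img, gt in tr:
            box = box_from_mask(gt, d)
            box_dscs.append(dsc(box_to_mask(box, gt.shape), gt))
            pm = generate_pseudo_mask(img, box, config.crf)
            pseudos.append(pm)
            pseudo_dscs.append(dsc(pm, gt))
        out[f"dsc_train_box_d{d}"] = float(np.mean(box_dscs))
        out[f"dsc_train_pseudo_d{d}"] = float(np.mean(pseudo_dscs))
        if d == config.margin_d:
            pseudo_for_pipeline = pseudos

    weak = run_weak_pipeline(train, config, pseudo_masks=pseudo_for_pipeline)
    if weak.fusion is not None:
        out[f"dsc_train_fusion_d{config.margin_d}"] = float(
            np.mean([dsc(fm, gt) for fm, (_, gt) in zip(weak.fusion.fusion_masks, tr)])
        )

    ablation_cfg = replace(config, K=0, loss="wce")
    ablation = run_weak_pipeline(train, ablation_cfg, pseudo_masks=pseudo_for_pipeline)
    fullsup, _ = train_fully_supervised(
        train, config.net, config.train, class_weights=config.class_weights,
        hu_min=config.hu_min, hu_max=config.hu_max,
    )

    for tag, model in (
        ("weak_k3_vwce", weak.final_model),
        ("weak_k0_wce", ablation.final_model),
        ("fullsup", fullsup),
    ):
        pairs = {f"case_{i:03d}": (predict_mask(model, img), gt) for i, (img, gt) in enumerate(te)}
        raw = evaluate_pairs(pairs)
        post = evaluate_pairs(pairs, postprocess=True)
        out[f"dsc_test_{tag}"] = raw.summary["mean_dsc"]
        out[f"dsc_test_{tag}_postprocessed"] = post.summary["mean_dsc"]
        if "mean_hd" in raw.summary:
            out[f"hd_test_{tag}"] = raw.summary["mean_hd"]
        if "mean_hd" in post.summary:
            out[f"hd_test_{tag}_postprocessed"] = post.summary["mean_hd"]
        out[f"_per_case_{tag}"] = {
            "raw": raw.per_case,
            "postprocessed": post.per_case,
        }
    return out


def train_fully_supervised(
    dataset,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    class_weights: ClassWeights = ClassWeights(),
    loss: str = "wce",
    hu_min: float = -200.0,
    hu_max: float = 500.0,
    out_dir: str | Path | None = None,
) -> tuple[SegmentationModel, dict]:
    """Baseline: train on the true pixel-wise masks (comparison ceiling)."""
    samples = _prepare(dataset, hu_min, hu_max)
    model, history = train_model(
        samples, LossSpec(kind=loss, class_weights=class_weights), net_cfg, train_cfg
    )
    manifest = {"tag": "fully_supervised", "final_loss": round(history[-1], 6), "n_images": len(samples)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return model, manifest
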