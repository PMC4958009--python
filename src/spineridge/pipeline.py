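"""End-to-end orchestration: image -> preprocessed mask -> backbone ->
boundary -> spine candidates -> Hu features -> TSVM filtering and
classification -> report + overlay artifacts."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import boundary as boundary_mod
from . import io_preprocess as iop
from .config import PipelineConfig
from .density_ridge import BackboneConfig, extract_backbone
from .errors import ValidationError
from .hu_features import feature_vector
from .spines import (
    SpineReport,
    detect_spines,
    filter_pseudo,
    measure_dendrite,
    measure_spine,
)
from .synthgen import SPINE_CLASSES, make_shape_dataset
from .tsvm import (
    MulticlassModel,
    TSVMModel,
    TrainingSet,
    predict_multiclass,
    train_kernel,
    train_multiclass,
)

log = logging.getLogger("spineridge")


def preprocess(img: iop.GrayImage, cfg: PipelineConfig):
    """Denoise + morphology chain.

    Returns (enhanced GrayImage, backbone BinaryMask, spine BinaryMask,
    threshold). The backbone mask goes through opening (or top-hat) and a
    strict majority vote so thin protrusions cannot disturb ridge
    extraction; the spine mask skips the opening (which would erase
    1-2 px wide spine necks) and uses a lenient majority vote that only
    removes isolated noise pixels. Both use the same intensity threshold.
    """
    den = iop.median_filter(img, cfg.median_window)
    if cfg.pde_iterations > 0:
        den = iop.enhance_pde(den, cfg.pde_iterations, cfg.pde_conductance, cfg.pde_dt)
    se = iop.StructuringElement(cfg.se_shape, cfg.se_size)
    opened = iop.top_hat(den, se) if cfg.use_top_hat else iop.opening(den, se)
    if cfg.binarize_method == "fixed":
        t = cfg.fixed_threshold
    else:
        t = iop.otsu_threshold(den)
    t = min(max(t, 1e-6), 1.0 - 1e-6)
    mask_bb = iop.majority(iop.binarize(opened, "fixed", t), cfg.majority_n)
    # the median erases 1-px-wide necks, so the spine mask binarizes the
    # unsmoothed image; the lenient majority vote removes impulse noise
    mask_sp = iop.majority(iop.binarize(img, "fixed", t), cfg.spine_majority_n)
    return den, mask_bb, mask_sp, t


def backbone_config(cfg: PipelineConfig) -> BackboneConfig:
    return BackboneConfig(
        bandwidth_px=cfg.bandwidth_px,
        ridge_step=cfg.ridge_step,
        theta_fraction=cfg.theta_fraction,
        spur_max_len=cfg.spur_max_len,
        junction_radius=cfg.junction_radius,
        max_samples=cfg.max_samples,
    )


def _overlay_png(path, img: iop.GrayImage, backbone=None, bnd=None, pseudo=None):
    """RGB overlay: backbone purple, boundary red, pseudo-spines circled."""
    import imageio.v3 as iio

    rgb = np.stack([img.pixels] * 3, axis=-1)
    H, W = img.pixels.shape

    def paint(pts, color):
        p = np.round(np.atleast_2d(pts)).astype(int)
        ok = (p[:, 0] >= 0) & (p[:, 0] < H) & (p[:, 1] >= 0) & (p[:, 1] < W)
        rgb[p[ok, 0], p[ok, 1]] = color

    if backbone is not None:
        for c in backbone.curves:
            paint(c.points, (0.6, 0.1, 0.9))
    if bnd is not None:
        paint(bnd.left[bnd.valid], (1.0, 0.1, 0.1))
        paint(bnd.right[bnd.valid], (1.0, 0.1, 0.1))
    if pseudo:
        from skimage.draw import circle_perimeter

        for region in pseudo:
            r, c = np.round(region.pixels.mean(axis=0)).astype(int)
            rad = int(np.ceil(np.linalg.norm(
                region.pixels - region.pixels.mean(axis=0), axis=1).max() + 2))
            rr, cc = circle_perimeter(r, c, max(rad, 3), shape=(H, W))
            rgb[rr, cc] = (0.6, 0.1, 0.9)
    iio.imwrite(str(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def run_pipeline(cfg: PipelineConfig, img: iop.GrayImage | None = None,
                 write_artifacts: bool = True):
    """Run the full cascade; returns (SpineReport, artifacts dict).

    ``img`` may be passed directly (tests); otherwise ``cfg.input`` is
    loaded. With model paths configured, pseudo-spines are filtered out and
    survivors are classified mushroom/stubby/thin.
    """
    t0 = time.time()
    if img is None:
        if not cfg.input:
            raise ValidationError("no input image configured")
        img = iop.load_image(cfg.input, pixel_size_um=cfg.pixel_size_um)
    img = iop.GrayImage(img.pixels, pixel_size_um=cfg.pixel_size_um)

    enhanced, mask, spine_mask, thr = preprocess(img, cfg)
    log.info("preprocess: %d foreground px, threshold %.3f (%.2fs)",
             int(mask.pixels.sum()), thr, time.time() - t0)
    if not mask.pixels.any():
        raise ValidationError("backbone stage: preprocessed mask is empty")

    backbone = extract_backbone(mask, backbone_config(cfg))
    # ridge fragments shorter than a plausible side-dendrite are spine
    # remnants: drop them so the boundary stage cannot absorb the spines
    backbone.curves = [c for c in backbone.curves
                       if c.arc_length() >= cfg.min_branch_px]
    if not backbone.curves:
        raise ValidationError("backbone stage: no ridge curves found")
    log.info("backbone: %d curves, %.1f px", len(backbone.curves),
             backbone.total_length_px())

    alpha = cfg.alpha
    if alpha is None:
        alpha = boundary_mod.suggest_alpha(img, backbone, sigma_d=cfg.sigma_d,
                                           max_halfwidth=cfg.max_halfwidth)
    bnd = boundary_mod.locate_boundary(enhanced, backbone, alpha,
                                       max_halfwidth=cfg.max_halfwidth,
                                       sigma_d=cfg.sigma_d)
    log.info("boundary: alpha=%.3f, %d/%d valid points", alpha,
             int(bnd.valid.sum()), bnd.valid.size)

    # the dendrite region subtracted before spine detection is bounded at
    # the binarization threshold (so polygon and mask edges coincide) plus
    # a sub-pixel radial margin that swallows rasterization slivers
    bnd_mask = boundary_mod.locate_boundary(enhanced, backbone, thr,
                                            max_halfwidth=cfg.max_halfwidth,
                                            sigma_d=cfg.sigma_d)
    dmask = boundary_mod.dendrite_mask(
        mask.shape, boundary_mod.expand_boundary(bnd_mask, cfg.boundary_margin_px)
    )

    # the subtraction region extends boundary_margin_px beyond the marched
    # rails, so the attachment gap is measured from the region edge
    candidates = detect_spines(spine_mask, dmask, bnd_mask,
                               min_area=cfg.min_area,
                               max_gap=cfg.max_gap + cfg.boundary_margin_px,
                               min_protrusion=cfg.min_protrusion_px)
    for region in candidates:
        measure_spine(region, cfg.pixel_size_um)
    log.info("spines: %d candidates", len(candidates))

    pseudo = []
    if cfg.binary_model:
        model = TSVMModel.load(cfg.binary_model)
        feats = np.array([feature_vector(r) for r in candidates]) if candidates else None
        spines_true, pseudo = filter_pseudo(candidates, model, feats)
    else:
        spines_true = candidates
    if cfg.multiclass_model and spines_true:
        mc = MulticlassModel.load(cfg.multiclass_model)
        feats = np.array([feature_vector(r) for r in spines_true])
        for region, lab in zip(spines_true, predict_multiclass(mc, feats)):
            region.label = lab

    report = SpineReport.from_spines(measure_dendrite(backbone, cfg.pixel_size_um),
                                     spines_true)
    artifacts = {}
    if write_artifacts:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv")
        report.to_json(out / "report.json")
        with open(out / "backbone.json", "w") as fh:
            payload = backbone.to_dict(cfg.pixel_size_um)
            payload["boundary"] = bnd.to_dict(cfg.pixel_size_um)
            json.dump(payload, fh, sort_keys=True)
        _overlay_png(out / "overlay.png", img, backbone, bnd, pseudo)
        artifacts = {
            "report_csv": str(out / "report.csv"),
            "report_json": str(out / "report.json"),
            "backbone_json": str(out / "backbone.json"),
            "overlay_png": str(out / "overlay.png"),
        }
    log.info("pipeline done in %.2fs: %d spines kept, %d pseudo",
             time.time() - t0, len(spines_true), len(pseudo))
    return report, artifacts


def train_models(cfg: PipelineConfig, n_per_class: int = 200,
                 dataset=None, out_dir=None, holdout_fraction: float = 0.25):
    """Train the pseudo-vs-true binary TSVM and the 3-class model.

    ``dataset`` is (images, labels) of binary shape masks; by default a
    seeded synthetic shape dataset of ``n_per_class`` per class is used.
    Returns (binary model, multiclass model, summary dict) and writes JSON
    models + a training summary when ``out_dir`` is given.
    """
    if dataset is None:
        images, labels, _ = make_shape_dataset(n_per_class, seed=cfg.seed)
    else:
        images, labels = dataset
        if len(images) == 0:
            raise ValidationError("empty training dataset")
    labels = list(labels)
    for cls in SPINE_CLASSES + ("pseudo",):
        if labels.count(cls) < 2:
            raise ValidationError(f"class {cls!r} missing from training data")
    feats = np.array([feature_vector(im) for im in images])
    labels_arr = np.array(labels)

    # deterministic stratified holdout
    rng = np.random.default_rng(cfg.seed)
    test_idx = np.zeros(len(labels), dtype=bool)
    for cls in set(labels):
        idx = np.flatnonzero(labels_arr == cls)
        k = max(1, int(round(holdout_fraction * idx.size)))
        test_idx[rng.permutation(idx)[:k]] = True
    Xtr, ytr = feats[~test_idx], labels_arr[~test_idx]
    Xte, yte = feats[test_idx], labels_arr[test_idx]

    # holdout models measure generalization; the deployed models are then
    # refit on the full dataset
    is_true_tr = ytr != "pseudo"
    binary_ho = train_kernel(TrainingSet(A=Xtr[is_true_tr], B=Xtr[~is_true_tr]),
                             c1=cfg.c1, c2=cfg.c2, gamma_k=cfg.gamma_k,
                             standardize=True)
    mc_ho = train_multiclass(Xtr[is_true_tr], ytr[is_true_tr], c1=cfg.c1,
                             c2=cfg.c2, gamma_k=cfg.gamma_k,
                             classes=list(SPINE_CLASSES), standardize=True)

    from .tsvm import predict_batch

    bin_pred = predict_batch(binary_ho, Xte)
    bin_acc = float(np.mean((bin_pred == 1) == (yte != "pseudo")))
    sel = yte != "pseudo"
    mc_pred = np.array(predict_multiclass(mc_ho, Xte[sel]))
    mc_acc = float(np.mean(mc_pred == yte[sel]))

    is_true = labels_arr != "pseudo"
    binary = train_kernel(TrainingSet(A=feats[is_true], B=feats[~is_true]),
                          c1=cfg.c1, c2=cfg.c2, gamma_k=cfg.gamma_k,
                          standardize=True)
    mc = train_multiclass(feats[is_true], labels_arr[is_true], c1=cfg.c1,
                          c2=cfg.c2, gamma_k=cfg.gamma_k,
                          classes=list(SPINE_CLASSES), standardize=True)
    summary = {
        "n_train": int((~test_idx).sum()),
        "n_test": int(test_idx.sum()),
        "per_class_train": {c: int((ytr == c).sum()) for c in sorted(set(labels))},
        "binary_holdout_accuracy": bin_acc,
        "multiclass_holdout_accuracy": mc_acc,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        binary.save(out / "binary_tsvm.json")
        mc.save(out / "multiclass_tsvm.json")
        with open(out / "training_summary.json", "w") as fh:
            json.dump(summary, fh, sort_keys=True, indent=1)
    return binary, mc, summary
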