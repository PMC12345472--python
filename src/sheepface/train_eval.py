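"""Multi-task adversarial training, hyper-parameter search and evaluation.

Each training iteration plays one round of a min-max game: the correlation
head takes ``adversarial_ratio`` gradient-*ascent* steps on the squared batch
correlation between the identity and age codes (finding the most correlated
projections), after which every other parameter takes one SGD descent step on
the joint objective ``L_id + alpha * L_grow + beta * rho^2``.  The encoder is
thereby pushed to make the two codes uncorrelated along whatever directions
the adversary can find.

Evaluation covers closed-set identification (nearest class vector on the
unit-normalized identity code), the verification error-rate suite, per-age
group breakdowns, and leakage diagnostics quantifying how much age
information remains in each code.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import metrics, nn, objectives
from .backbone import PRESETS, Backbone, build_backbone
from .decoupling import CorrModule, Decoupler, correlation_objective
from .nn import tensor as F
from .synthetic_faces import (AugmentPolicy, DatasetManifest, LabeledFaceImage,
                              ManifestRecord, load_png)

AGE_GROUPS_DEFAULT = ((1, 3), (4, 6), (7, 9), (10, 12))


@dataclasses.dataclass
class TrainingConfig:
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 20
    alpha: float = objectives.DEFAULT_ALPHA
    beta: float = objectives.DEFAULT_BETA
    adversarial_ratio: int = 1
    seed: int = 0
    preset: str = "fe_net_tiny"
    cosface_s: float = objectives.DEFAULT_SCALE
    cosface_b: float = objectives.DEFAULT_MARGIN
    age_dim: int = 128
    attention: str = "ecbam"        # none | cbam | ecbam
    decouple_mode: str = "mlp"      # none | linear | mlp
    use_bkcca: bool = True
    corr_lr_mult: float = 10.0
    corr_prior_strength: float = 1e-4
    corr_pairs: int = 8
    corr_closed_form: bool = True   # exact inner maximization of the projections
    residual_fit_weight: float = 1.0  # drives r = MLP_res(x_age) toward E[x | x_age]
    residual_lr_mult: float = 10.0    # faster optimizer group for the residual map
    augment_online: bool = True       # apply the augmentation policy per batch
    scale_jitter: float = 0.3         # random rescale range for train batches
    age_code_purity_weight: float = 0.0  # experimental: penalize identity content in x_age
    warmup_epochs: float = 1.0
    cosine_decay: bool = True
    val_subset: int = 256   # per-epoch validation sample; full val on final epoch

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.adversarial_ratio < 1:
            raise ValueError("adversarial_ratio must be at least 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# -- data container -----------------------------------------------------

@dataclasses.dataclass
class Cohort:
    """In-memory image cohort with split bookkeeping and an access audit."""

    images: np.ndarray          # (N, 3, H, W) float32
    labels: np.ndarray          # (N,) int class index
    ages: np.ndarray            # (N,) int months
    splits: np.ndarray          # (N,) str
    boxes: np.ndarray           # (N, 4) int
    class_names: list
    access_log: set = dataclasses.field(default_factory=set)

    def indices(self, split: str) -> np.ndarray:
        self.access_log.add(split)
        if split == "all":
            return np.arange(len(self.splits))
        return np.where(self.splits == split)[0]

    @classmethod
    def from_images(cls, images: list[LabeledFaceImage],
                    records: list[ManifestRecord]) -> "Cohort":
        class_names = sorted({r.sheep_id for r in records})
        lut = {c: i for i, c in enumerate(class_names)}
        return cls(
            images=np.stack([im.pixels for im in images]),
            labels=np.array([lut[r.sheep_id] for r in records]),
            ages=np.array([r.age_months for r in records]),
            splits=np.array([r.split for r in records]),
            boxes=np.array([r.box for r in records]),
            class_names=class_names,
        )

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest, root: str | Path) -> "Cohort":
        root = Path(root)
        class_names = sorted({r.sheep_id for r in manifest.records})
        lut = {c: i for i, c in enumerate(class_names)}
        return cls(
            images=np.stack([load_png(root / r.path) for r in manifest.records]),
            labels=np.array([lut[r.sheep_id] for r in manifest.records]),
            ages=np.array([r.age_months for r in manifest.records]),
            splits=np.array([r.split for r in manifest.records]),
            boxes=np.array([r.box for r in manifest.records]),
            class_names=class_names,
        )


# -- model --------------------------------------------------------------

class SheepFaceModel(nn.Module):
    """Backbone + decoupler + CosFace head + age regressor + correlation head."""

    def __init__(self, cfg: TrainingConfig, n_classes: int):
        super().__init__()
        self.cfg = cfg
        preset = PRESETS[cfg.preset]
        root = np.random.SeedSequence(cfg.seed)
        s_back, s_dec, s_head, s_corr = (int(s.generate_state(1)[0]) % (2 ** 31)
                                         for s in root.spawn(4))
        self.backbone: Backbone = build_backbone(cfg.preset, seed=s_back)
        rng_dec = np.random.default_rng(s_dec)
        self.decoupler = Decoupler(rng_dec, preset.embed_dim, age_dim=cfg.age_dim,
                                   attention=cfg.attention, mode=cfg.decouple_mode)
        rng_head = np.random.default_rng(s_head)
        self.head = objectives.CosFaceHead(rng_head, n_classes, preset.embed_dim,
                                           s=cfg.cosface_s, b=cfg.cosface_b)
        self.age_reg = objectives.AgeRegressor(rng_head, cfg.age_dim)
        rng_corr = np.random.default_rng(s_corr)
        self.corr = CorrModule(rng_corr, preset.embed_dim, cfg.age_dim,
                               n_pairs=cfg.corr_pairs,
                               prior_strength=cfg.corr_prior_strength)

    def encoder_parameters(self):
        corr_ids = {id(p) for p in self.corr.parameters()}
        return [p for p in self.parameters() if id(p) not in corr_ids]

    def forward(self, batch):
        fmap, x = self.backbone(batch)
        return self.decoupler(fmap, x)

    def embed(self, images: np.ndarray, batch_size: int = 64):
        """Eval-mode codes for a stack of images; returns (x_id, x_age)."""
        self.eval()
        ids, ages = [], []
        with nn.no_grad():
            for start in range(0, len(images), batch_size):
                bundle = self.forward(images[start:start + batch_size])
                ids.append(bundle.x_id.data.copy())
                ages.append(bundle.x_age.data.copy())
        return np.concatenate(ids), np.concatenate(ages)

    def classify(self, x_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-class-vector prediction on unit codes; returns (pred, score)."""
        w = self.head.weight.data
        wn = w / (np.linalg.norm(w, axis=1, keepdims=True) + 1e-8)
        xn = x_id / (np.linalg.norm(x_id, axis=1, keepdims=True) + 1e-8)
        cos = xn @ wn.T
        pred = cos.argmax(axis=1)
        return pred, cos[np.arange(len(pred)), pred]


# -- training -----------------------------------------------------------

class DivergenceError(RuntimeError):
    pass


def _rescale_image(img: np.ndarray, scale: float) -> np.ndarray:
    """Zoom a (3, H, W) image about its centre, crop/pad back to size."""
    from scipy import ndimage

    _, h, w = img.shape
    zoomed = ndimage.zoom(img, (1.0, scale, scale), order=1, mode="nearest")
    zh, zw = zoomed.shape[1:]
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        return np.ascontiguousarray(zoomed[:, top:top + h, left:left + w])
    out = np.empty_like(img)
    out[:] = zoomed[:, :1, :1].mean(axis=(1, 2), keepdims=True)
    top, left = (h - zh) // 2, (w - zw) // 2
    out[:, top:top + zh, left:left + zw] = zoomed
    return out


def _augment_batch(images: np.ndarray, rng: np.random.Generator,
                   policy: AugmentPolicy, scale_jitter: float = 0.0) -> np.ndarray:
    """Per-batch stochastic version of the four-way augmentation policy.

    Each image is left untouched or receives one of the photometric, noise or
    rotation transforms with equal probability — the same mix the static x4
    expansion produces, applied on the fly.  An independent random rescale
    (standard random-resized-crop-style scale jitter) is layered on half the
    images when ``scale_jitter`` > 0.
    """
    from scipy import ndimage

    out = images.copy()
    kinds = rng.integers(0, 4, size=len(images))
    for i, kind in enumerate(kinds):
        if kind == 1:
            gain = 1.0 + rng.uniform(-policy.gain_range, policy.gain_range)
            bias = rng.uniform(-policy.bias_range, policy.bias_range)
            out[i] = gain * out[i] + bias
        elif kind == 2:
            out[i] = out[i] + rng.normal(0.0, policy.noise_sigma,
                                         size=out[i].shape).astype(np.float32)
        elif kind == 3:
            theta = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
            out[i] = ndimage.rotate(out[i], theta, axes=(2, 1), reshape=False,
                                    order=1, mode="nearest")
        if scale_jitter and rng.uniform() < 0.5:
            s = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
            out[i] = _rescale_image(out[i], s)
    np.clip(out, 0.0, 1.0, out=out)
    return out


def train(data: Cohort, cfg: TrainingConfig,
          model: SheepFaceModel | None = None) -> tuple[SheepFaceModel, list[dict]]:
    """Train a model on the cohort's train split; returns (model, history).

    History records the epoch means of the three loss terms, the batch
    correlation magnitude and validation top-1 accuracy.  Fully seeded: the
    same config and cohort reproduce the same history.
    """
    train_idx = data.indices("train")
    val_idx = data.indices("val")
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and val splits must be nonempty")
    model = model or SheepFaceModel(cfg, n_classes=len(data.class_names))

    res_params = (model.decoupler.mlp_res.parameters()
                  if model.decoupler.mlp_res is not None else [])
    res_ids = {id(p) for p in res_params}
    main_params = [p for p in model.encoder_parameters() if id(p) not in res_ids]
    age_params = model.age_reg.parameters()
    head_ids = res_ids | {id(p) for p in age_params}
    main_params = [p for p in main_params if id(p) not in head_ids]
    enc_opt = nn.SGD([{"params": main_params},
                      {"params": res_params,
                       "lr": cfg.lr * cfg.residual_lr_mult},
                      # the linear age readout is a tiny convex fit; its own
                      # faster group keeps it converged despite the small alpha
                      {"params": age_params, "lr": cfg.lr * 100.0}],
                     lr=cfg.lr, momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay)
    corr_opt = nn.SGD([{"params": model.corr.parameters(),
                        "maximize": True,
                        "weight_decay": cfg.corr_prior_strength}],
                      lr=cfg.lr * cfg.corr_lr_mult, momentum=0.0)

    def lr_factor(progress: float) -> float:
        # linear warmup then cosine decay; stabilizes the scaled-margin loss
        if cfg.warmup_epochs > 0 and progress < cfg.warmup_epochs / cfg.epochs:
            return progress * cfg.epochs / cfg.warmup_epochs
        if not cfg.cosine_decay:
            return 1.0
        rest = ((progress - cfg.warmup_epochs / cfg.epochs)
                / max(1.0 - cfg.warmup_epochs / cfg.epochs, 1e-9))
        return 0.5 * (1.0 + np.cos(np.pi * min(rest, 1.0)))

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD47A]))
    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / cfg.batch_size)))
    step = 0
    history = []
    # replay buffer of recent (detached) codes: the closed-form CCA solve
    # needs more samples than kernel dimensions to estimate real correlation
    buf_id: list[np.ndarray] = []
    buf_age: list[np.ndarray] = []
    buf_cap = max(1, 512 // cfg.batch_size)
    aug_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA06]))
    aug_policy = AugmentPolicy()
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train_idx)
        sums = {"l_id": 0.0, "l_grow": 0.0, "l_corr": 0.0, "rho": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue
            factor = lr_factor(step / (steps_per_epoch * cfg.epochs))
            for opt in (enc_opt, corr_opt):
                for g in opt.groups:
                    g.setdefault("base_lr", g["lr"])
                    g["lr"] = g["base_lr"] * factor
            step += 1
            batch = data.images[idx]
            if cfg.augment_online:
                batch = _augment_batch(batch, aug_rng, aug_policy,
                                       cfg.scale_jitter)
            labels = data.labels[idx]
            ages = data.ages[idx]

            bundle = model.forward(batch)

            if cfg.use_bkcca:
                xid_d = bundle.x_id.detach()
                xage_d = bundle.x_age.detach()
                for _ in range(cfg.adversarial_ratio):
                    corr_opt.zero_grad()
                    u, v = model.corr.projections(xid_d, xage_d)
                    obj, _ = correlation_objective(u, v)
                    obj.backward()
                    corr_opt.step()
                if cfg.corr_closed_form:
                    # exact ridge-CCA solve for the projection vectors over
                    # the buffer; the SGD ascent keeps adapting the kernel maps
                    buf_id.append(xid_d.data.copy())
                    buf_age.append(xage_d.data.copy())
                    if len(buf_id) > buf_cap:
                        buf_id.pop(0)
                        buf_age.pop(0)
                    model.corr.solve_projections(np.concatenate(buf_id),
                                                 np.concatenate(buf_age))

            enc_opt.zero_grad()
            model.corr.zero_grad()
            l_id = objectives.cosface_loss(bundle.x_id, model.head, labels)
            l_grow = objectives.age_loss(bundle.x_age, model.age_reg, ages)
            if cfg.use_bkcca:
                u, v = model.corr.projections(bundle.x_id, bundle.x_age)
                l_corr, rho_val = correlation_objective(u, v)
            else:
                l_corr = nn.Tensor(np.zeros(()))
                rho_val = 0.0
            total = objectives.joint_loss(l_id, l_grow, l_corr,
                                          cfg.alpha, cfg.beta)
            if cfg.age_code_purity_weight and cfg.decouple_mode != "none":
                # growth features should describe growth, not identity:
                # penalize the spread of per-identity means of the age code
                onehot = np.zeros((len(labels), len(data.class_names)),
                                  dtype=np.float32)
                onehot[np.arange(len(labels)), labels] = 1.0
                counts = onehot.sum(axis=0)
                present = counts > 0
                weights = (onehot[:, present] / counts[present]).T
                class_means = F.matmul(nn.Tensor(weights), bundle.x_age)
                grand = bundle.x_age.mean(axis=0, keepdims=True)
                dev = class_means - grand
                total = total + cfg.age_code_purity_weight * \
                    (dev * dev).sum(axis=1).mean()
            if cfg.residual_fit_weight and model.decoupler.mlp_res is not None:
                # teach the residual map the age-conditional mean embedding:
                # the subtraction x - E[x|age] is what annihilates the age
                # component, so supervise r with per-age batch means
                target = np.empty_like(bundle.x.data)
                for a in np.unique(ages):
                    sel = ages == a
                    target[sel] = bundle.x.data[sel].mean(axis=0)
                r_fit = model.decoupler.mlp_res(bundle.x_age.detach())
                diff = r_fit - nn.Tensor(target)
                l_rec = 0.5 * (diff * diff).sum(axis=1).mean()
                total = total + cfg.residual_fit_weight * l_rec
            if not np.isfinite(total.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: l_id={float(l_id.data)} "
                    f"l_grow={float(l_grow.data)} l_corr={float(l_corr.data)}")
            total.backward()
            enc_opt.step()

            sums["l_id"] += float(l_id.data)
            sums["l_grow"] += float(l_grow.data)
            sums["l_corr"] += float(l_corr.data)
            sums["rho"] += rho_val
            n_batches += 1

        if (cfg.val_subset and len(val_idx) > cfg.val_subset
                and epoch < cfg.epochs - 1):
            vsel = rng.choice(val_idx, cfg.val_subset, replace=False)
        else:
            vsel = val_idx
        val_acc, val_loss = _validation_accuracy(model, data, vsel)
        history.append({
            "epoch": epoch,
            "l_id": sums["l_id"] / max(n_batches, 1),
            "l_grow": sums["l_grow"] / max(n_batches, 1),
            "l_corr": sums["l_corr"] / max(n_batches, 1),
            "rho": sums["rho"] / max(n_batches, 1),
            "val_acc": val_acc,
            "val_loss": val_loss,
        })
    return model, history


def _validation_accuracy(model: SheepFaceModel, data: Cohort,
                         idx: np.ndarray) -> tuple[float, float]:
    x_id, x_age = model.embed(data.images[idx])
    pred, _ = model.classify(x_id)
    acc = float((pred == data.labels[idx]).mean())
    with nn.no_grad():
        l_id = objectives.cosface_loss(nn.Tensor(x_id), model.head, data.labels[idx])
        l_grow = objectives.age_loss(nn.Tensor(x_age), model.age_reg, data.ages[idx])
    loss = float(l_id.data) + model.cfg.alpha * float(l_grow.data)
    return acc, loss


# -- grid search --------------------------------------------------------

def grid_search(data: Cohort, grid: dict, base_cfg: TrainingConfig,
                evaluator=None) -> tuple[TrainingConfig, list[dict]]:
    """Exhaustive search over ``grid``, selected by validation top-1 accuracy.

    ``grid`` maps TrainingConfig field names to candidate lists.  Ties break
    by lower validation loss, then smaller learning rate.  The test split is
    never read; the cohort's access audit verifies this.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    if evaluator is None:
        def evaluator(cfg, cohort):
            _, history = train(cohort, cfg)
            return history[-1]["val_acc"], history[-1]["val_loss"]

    keys = sorted(grid)
    combos = [()]
    for k in keys:
        combos = [c + (val,) for c in combos for val in grid[k]]

    before = set(data.access_log)
    results = []
    for combo in combos:
        cfg = dataclasses.replace(base_cfg, **dict(zip(keys, combo)))
        val_acc, val_loss = evaluator(cfg, data)
        results.append({**dict(zip(keys, combo)), "val_acc": val_acc,
                        "val_loss": val_loss, "lr": cfg.lr})
    if "test" in data.access_log - before:
        raise RuntimeError("grid search read the test split")
    best = max(results, key=lambda r: (r["val_acc"], -r["val_loss"], -r["lr"]))
    best_cfg = dataclasses.replace(
        base_cfg, **{k: best[k] for k in keys if k in best})
    return best_cfg, results


# -- evaluation ---------------------------------------------------------

def evaluate(model: SheepFaceModel, data: Cohort, split: str = "test",
             age_groups=AGE_GROUPS_DEFAULT) -> dict:
    """Full evaluation report on one split (identification + verification).

    Identification is nearest-class-vector on the unit-normalized identity
    code.  The mAP@0.5 computation uses each record's face crop box as the
    predicted box (a classification-only reduction: the IoU term is exact).
    """
    idx = data.indices(split)
    if len(idx) == 0:
        raise ValueError(f"empty split: {split}")
    x_id, x_age = model.embed(data.images[idx])
    labels = data.labels[idx]
    ages = data.ages[idx]
    pred, scores = model.classify(x_id)

    counts = metrics.confusion_counts(pred, labels)
    cls = metrics.classification_metrics(counts)
    top1 = float((pred == labels).mean())

    boxes = data.boxes[idx]
    preds_map = [(int(p), float(s), tuple(b)) for p, s, b in zip(pred, scores, boxes)]
    gts_map = [(int(t), tuple(b)) for t, b in zip(labels, boxes)]
    map_res = metrics.map_at_50(preds_map, gts_map)

    ver = verification_report(x_id, labels, counts)

    groups = []
    for lo, hi in age_groups:
        sel = (ages >= lo) & (ages <= hi)
        if not sel.any():
            groups.append({"ages": [lo, hi], "n": 0, "empty": True})
            continue
        gc = metrics.confusion_counts(pred[sel], labels[sel])
        gm = metrics.classification_metrics(gc)
        groups.append({"ages": [lo, hi], "n": int(sel.sum()),
                       "top1": float((pred[sel] == labels[sel]).mean()), **gm})

    # leakage diagnostics need age variation spanning the full 1-12 month
    # range; under the age-based protocol no single split provides that
    leak = decoupling_report(model, data, split="all")
    return {
        "split": split,
        "n": int(len(idx)),
        "top1": top1,
        **{k: cls[k] for k in ("precision", "recall", "f1", "accuracy")},
        "map50": map_res["map"],
        "eer_eq11": ver["eer_eq11"],
        "eer_roc": ver["eer_roc"],
        "far_curve": ver["far"],
        "frr_curve": ver["frr"],
        "thresholds": ver["thresholds"],
        "age_groups": groups,
        "leakage": leak,
    }


def verification_report(x_id: np.ndarray, labels: np.ndarray,
                        counts: metrics.ConfusionCounts,
                        max_pairs: int = 200_000, seed: int = 0) -> dict:
    """Cosine-similarity verification over all (sub-sampled) pairs."""
    xn = x_id / (np.linalg.norm(x_id, axis=1, keepdims=True) + 1e-8)
    n = len(xn)
    iu, ju = np.triu_indices(n, k=1)
    if len(iu) > max_pairs:
        keep = np.random.default_rng(seed).choice(len(iu), max_pairs, replace=False)
        iu, ju = iu[keep], ju[keep]
    sims = np.einsum("ij,ij->i", xn[iu], xn[ju])
    same = labels[iu] == labels[ju]
    eer, thr, far, frr = metrics.eer_roc(sims, same)
    return {
        "eer_eq11": metrics.eer_eq11(counts),
        "eer_roc": eer,
        "thresholds": thr.tolist(),
        "far": far.tolist(),
        "frr": frr.tolist(),
    }


def _crossfit_r2(features: np.ndarray, target: np.ndarray,
                 seed: int = 0, k: int = 5) -> tuple[float, bool]:
    """K-fold cross-fitted OLS R^2 of ``target`` given ``features``.

    Fitting and scoring on disjoint folds avoids the p/n optimism of
    in-sample OLS with wide feature matrices; five folds keep the fit sample
    large so coefficient noise does not deflate the estimate much either.
    Negative values are clipped to 0 and flagged.
    """
    n = len(target)
    k = min(k, n)
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    r2s = []
    for i in range(k):
        te = folds[i]
        tr = np.concatenate([folds[j] for j in range(k) if j != i])
        X_tr = np.column_stack([features[tr], np.ones(len(tr))])
        X_te = np.column_stack([features[te], np.ones(len(te))])
        coef, *_ = np.linalg.lstsq(X_tr, target[tr], rcond=None)
        resid = target[te] - X_te @ coef
        sst = ((target[te] - target[te].mean()) ** 2).sum()
        r2s.append(1.0 - resid @ resid / sst if sst > 0 else 0.0)
    r2 = float(np.mean(r2s))
    return (max(r2, 0.0), r2 < 0.0)


def decoupling_report(model: SheepFaceModel, data: Cohort, split: str = "all",
                      x_id: np.ndarray | None = None,
                      x_age: np.ndarray | None = None) -> dict:
    """Leakage diagnostics: how much age information remains in each code.

    Defaults to the full cohort: the age-based protocol confines each split
    to a 4-month window, which leaves too little age variance for the R^2
    regressions to be informative.
    """
    idx = data.indices(split)
    ages = data.ages[idx].astype(np.float64)
    if x_id is None or x_age is None:
        x_id, x_age = model.embed(data.images[idx])
    r2_age, flag_a = _crossfit_r2(x_age.astype(np.float64), ages)
    r2_id, flag_i = _crossfit_r2(x_id.astype(np.float64), ages)
    with nn.no_grad():
        u, v = model.corr.projections(x_id, x_age)
        _, max_abs_rho = correlation_objective(u, v)
    return {
        "r2_age_from_x_age": r2_age,
        "r2_age_from_x_id": r2_id,
        "abs_rho": max_abs_rho,
        "clipped": bool(flag_a or flag_i),
    }


# -- saliency -----------------------------------------------------------

def saliency_map(model: SheepFaceModel, image: np.ndarray,
                 target_class: int) -> tuple[np.ndarray, bool]:
    """Gradient-weighted class activation map at image resolution.

    Channel weights are the spatially averaged gradients of the target
    class's scaled cosine logit with respect to the final feature map; the
    weighted sum is rectified, bilinearly upsampled and max-normalized to
    [0, 1].  Returns (map, zero_gradient_flag).
    """
    if not 0 <= target_class < model.head.n_classes:
        raise ValueError("invalid target class")
    model.eval()
    batch = image[None] if image.ndim == 3 else image
    fmap, x = model.backbone(batch)
    bundle = model.decoupler(fmap, x)
    cos = model.head.cosines(bundle.x_id)
    logit = cos.sum(axis=0)  # batch of one
    onehot = np.zeros(model.head.n_classes, dtype=np.float32)
    onehot[target_class] = model.head.s
    (logit * onehot).sum().backward()
    grad = fmap.grad
    if grad is None or not np.any(grad):
        h, w = batch.shape[2:]
        return np.zeros((h, w), dtype=np.float64), True
    weights = grad[0].mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * fmap.data[0]).sum(axis=0), 0.0)
    cam = nn.bilinear_resize(cam.astype(np.float64), batch.shape[2], batch.shape[3])
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0:
        return np.zeros_like(cam), True
    return cam / peak, False


# -- checkpointing ------------------------------------------------------

def config_hash(cfg: TrainingConfig) -> str:
    import hashlib

    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_checkpoint(model: SheepFaceModel, path: str | Path,
                    history: list[dict] | None = None) -> None:
    """Single-archive checkpoint: parameters keyed by module path + metadata."""
    meta = {
        "config": model.cfg.to_dict(),
        "config_hash": config_hash(model.cfg),
        "preset": model.cfg.preset,
        "n_classes": model.head.n_classes,
        "history": history or [],
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> tuple[SheepFaceModel, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = TrainingConfig(**meta["config"])
    model = SheepFaceModel(cfg, n_classes=meta["n_classes"])
    model.load_state_dict(state)
    return model, meta
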