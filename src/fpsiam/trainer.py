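"""Pre-training loop, schedule, collapse diagnostics and checkpointing.

The entry point is the :class:`FPSiamModel` / :class:`PretrainResults`
pair: the model is built from an unlabelled frame array (or directory)
plus configuration, ``fit()`` runs seeded SGD pre-training and returns a
results object carrying the loss trajectory, learning-rate trace,
collapse diagnostics and a ``summary()`` table.  Free functions
(:func:`cosine_lr`, :func:`training_step`, :func:`collapse_metric`,
:func:`export_backbone`) expose the individual pieces.

Schedule: SGD with momentum and weight decay; the learning rate follows
per-step cosine annealing ``base_lr * (1 + cos(pi * t / T)) / 2`` for the
encoder, while the prediction head's group keeps the base rate fixed.
Weight decay applies to conv/fc weights only, never to biases or
batch-norm parameters.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .augment import AugmentationConfig, ViewPair, augment_pair, load_frames, normalize
from .backbone import BackboneSpec
from .heads import HeadConfig
from .loss import LossBreakdown, fpsiam_loss
from .model import FPSiamNetwork
from .nn import SGD, Module, Tensor
from .pyramid import PyramidConfig


@dataclass
class TrainConfig:
    batch_size: int = 256
    epochs: int = 200
    base_lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    pred_head_lr_fixed: bool = True
    seed: int = 0
    device: str = "cpu"
    log_every: int = 10
    checkpoint_every: int = 50

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch norm)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")


@dataclass
class CollapseMetrics:
    """Spread of l2-normalised representations across a batch.

    ``per_channel_std`` is the standard deviation of each channel of the
    normalised vectors across the batch, averaged over channels.  For
    healthy (non-collapsed) representations scattered on the unit sphere
    this sits near ``1/sqrt(dim)``; a collapsed encoder maps every input
    to one point and the value vanishes.
    """

    per_channel_std: float
    expected_nocollapse: float

    @property
    def ratio(self) -> float:
        return self.per_channel_std / self.expected_nocollapse


def cosine_lr(step_epoch: float, config: TrainConfig) -> float:
    """Cosine-annealed learning rate at a (fractional) epoch position."""
    if step_epoch < 0:
        raise ValueError("step_epoch must be >= 0")
    if step_epoch > config.epochs:
        warnings.warn(f"step_epoch {step_epoch} beyond epochs "
                      f"{config.epochs}; clamping", stacklevel=2)
        step_epoch = config.epochs
    return config.base_lr * 0.5 * (1.0 + np.cos(np.pi * step_epoch / config.epochs))


def _is_decay_param(name: str, p: Tensor) -> bool:
    # conv/fc weights are >=2-D; biases and batch-norm affine params are 1-D
    return p.data.ndim >= 2


def build_optimizer(network: FPSiamNetwork, config: TrainConfig) -> SGD:
    """Four parameter groups: encoder/prediction x decay/no-decay.

    Prediction-head groups are flagged ``fixed_lr`` when the config keeps
    their learning rate constant through annealing.
    """
    enc_decay, enc_plain, pred_decay, pred_plain = [], [], [], []
    for name, p in network.named_parameters():
        is_pred = name.startswith("prediction")
        if _is_decay_param(name, p):
            (pred_decay if is_pred else enc_decay).append(p)
        else:
            (pred_plain if is_pred else enc_plain).append(p)
    fixed = config.pred_head_lr_fixed
    groups = [
        {"name": "encoder_decay", "params": enc_decay,
         "weight_decay": config.weight_decay},
        {"name": "encoder_no_decay", "params": enc_plain, "weight_decay": 0.0},
        {"name": "prediction_decay", "params": pred_decay,
         "weight_decay": config.weight_decay, "fixed_lr": fixed},
        {"name": "prediction_no_decay", "params": pred_plain,
         "weight_decay": 0.0, "fixed_lr": fixed},
    ]
    return SGD(groups, lr=config.base_lr, momentum=config.momentum)


def apply_schedule(optimizer: SGD, step_epoch: float,
                   config: TrainConfig) -> float:
    """Set every non-fixed group to the cosine rate; returns that rate."""
    lr = cosine_lr(step_epoch, config)
    for group in optimizer.param_groups:
        group["lr"] = config.base_lr if group.get("fixed_lr") else lr
    return lr


def training_step(model: FPSiamNetwork, view_pair: ViewPair, optimizer: SGD,
                  lambda_weight: float = 0.5, eps: float = 0.0,
                  stop_gradient: bool = True) -> LossBreakdown:
    """One SGD step on one augmented batch; returns the loss breakdown."""
    optimizer.zero_grad()
    local, global_ = model.forward_views(Tensor(view_pair.view1),
                                         Tensor(view_pair.view2))
    total, breakdown = fpsiam_loss(local, global_, lambda_weight, eps=eps,
                                   stop_gradient=stop_gradient)
    if not np.isfinite(total.data):
        raise RuntimeError(
            "non-finite training loss; per-term values: "
            f"L_local={breakdown.L_local}, L_global={breakdown.L_global}, "
            f"lambda={breakdown.lambda_weight}")
    total.backward()
    optimizer.step()
    return breakdown


def collapse_metric(z: Union[np.ndarray, Tensor]) -> CollapseMetrics:
    """Per-channel std of l2-normalised representations, channel-averaged."""
    arr = z.data if isinstance(z, Tensor) else np.asarray(z, dtype=np.float64)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 8:
        raise ValueError(f"need a (batch >= 8, dim) array, got {arr.shape}")
    norms = np.linalg.norm(arr, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    zn = arr / norms
    std = float(zn.std(axis=0).mean())
    return CollapseMetrics(per_channel_std=std,
                           expected_nocollapse=1.0 / np.sqrt(arr.shape[1]))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: Union[str, Path], network: FPSiamNetwork,
                    optimizer: SGD, train_config: TrainConfig,
                    global_step: int, meta: Optional[Dict] = None) -> Path:
    path = Path(path)
    arrays = {f"model.{k}": v for k, v in network.state_dict().items()}
    opt_state = optimizer.state_dict()
    for i, v in enumerate(opt_state["velocities"]):
        if v is not None:
            arrays[f"optim.v{i}"] = v
    header = {
        "train_config": asdict(train_config),
        "backbone_spec": asdict(network.backbone_spec),
        "pyramid_config": asdict(network.pyramid_config),
        "head_config": asdict(network.head_config),
        "optim_groups": opt_state["groups"],
        "global_step": int(global_step),
        "meta": meta or {},
    }
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


def read_checkpoint(path: Union[str, Path]) -> Tuple[Dict, Dict[str, np.ndarray]]:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        arrays = {k: data[k] for k in data.files if k != "header"}
    return header, arrays


def export_backbone(model: Union[FPSiamNetwork, "FPSiamModel"],
                    path: Union[str, Path]) -> Path:
    """Write the backbone parameters only — the hand-off artefact.

    The pyramid and both heads exist solely for pre-training; downstream
    detectors consume the backbone weights alone.  Keys are the
    backbone's own ``state_dict`` names (no prefix), so the file loads
    directly via ``backbone.load_state_dict`` /
    ``BackboneSpec(init="checkpoint")``.
    """
    network = model.network if isinstance(model, FPSiamModel) else model
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = network.backbone.state_dict()
    forbidden = ("pyramid", "projection", "prediction")
    assert not any(k.startswith(forbidden) for k in state)
    np.savez(path, **state)
    return path


def load_exported_backbone(path: Union[str, Path], backbone: Module) -> Module:
    with np.load(Path(path)) as data:
        backbone.load_state_dict({k: data[k] for k in data.files})
    return backbone


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: int
    epoch: float
    lr: float
    L_local: float
    L_global: float
    L_total: float


class FPSiamModel:
    """Self-supervised pre-training model over an unlabelled frame corpus.

    Parameters
    ----------
    frames : array (n, 3, H, W) in [0, 1], or a directory of PNG/JPEG
        frames.
    backbone_spec, augment_config, pyramid_config, head_config,
    train_config : component configurations; sensible defaults are the
        published recipe (224-px crops, d=256, 2048-D projections, SGD
        0.05/0.9/1e-4, 200 epochs) — pass smaller configs for desk-scale
        runs.
    lambda_weight : local/global balance of the joint loss (default 0.5).
    """

    def __init__(self, frames: Union[np.ndarray, str, Path],
                 backbone_spec: Optional[BackboneSpec] = None,
                 augment_config: Optional[AugmentationConfig] = None,
                 pyramid_config: Optional[PyramidConfig] = None,
                 head_config: Optional[HeadConfig] = None,
                 train_config: Optional[TrainConfig] = None,
                 lambda_weight: float = 0.5, norm_eps: float = 0.0,
                 stop_gradient: bool = True):
        if isinstance(frames, (str, Path)):
            frames = load_frames(frames)
        self.frames = np.asarray(frames, dtype=np.float32)
        if self.frames.ndim != 4 or self.frames.shape[1] != 3:
            raise ValueError("frames must be (n, 3, H, W)")
        self.backbone_spec = backbone_spec or BackboneSpec()
        self.augment_config = augment_config or AugmentationConfig()
        self.train_config = train_config or TrainConfig()
        if not 0.0 <= lambda_weight <= 1.0:
            raise ValueError("lambda_weight outside [0, 1]")
        self.lambda_weight = lambda_weight
        self.norm_eps = norm_eps
        self.stop_gradient = stop_gradient
        seed = self.train_config.seed
        # seed propagates into backbone init as well
        self.backbone_spec.seed = seed
        self.network = FPSiamNetwork(self.backbone_spec, pyramid_config,
                                     head_config, seed=seed)
        self.optimizer = build_optimizer(self.network, self.train_config)
        self.global_step = 0
        self._history: List[StepRecord] = []
        self._collapse_trajectory: List[Tuple[int, float, float]] = []

    # -- configuration loading --------------------------------------------
    @classmethod
    def from_config(cls, config: Union[Dict, str, Path],
                    frames: Union[np.ndarray, str, Path, None] = None
                    ) -> "FPSiamModel":
        """Build from a YAML config path or an equivalent nested dict.

        Recognised blocks: ``data`` (``frames_dir``), ``augment``,
        ``backbone``, ``pyramid``, ``heads``, ``loss``, ``train``.
        """
        import yaml
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        config = dict(config or {})
        if frames is None:
            data_block = config.get("data", {})
            if "frames_dir" not in data_block:
                raise ValueError("no frames given and no data.frames_dir "
                                 "in the config")
            frames = data_block["frames_dir"]
        loss_block = config.get("loss", {})

        def build(cls_, block):
            return cls_(**config.get(block, {})) if config.get(block) is not None \
                else None

        def tupled(cfg_cls, block):
            kw = dict(config.get(block) or {})
            for k, v in kw.items():
                if isinstance(v, list):
                    kw[k] = tuple(v)
            return cfg_cls(**kw) if kw else None

        return cls(
            frames,
            backbone_spec=tupled(BackboneSpec, "backbone"),
            augment_config=tupled(AugmentationConfig, "augment"),
            pyramid_config=tupled(PyramidConfig, "pyramid"),
            head_config=tupled(HeadConfig, "heads"),
            train_config=tupled(TrainConfig, "train"),
            lambda_weight=loss_block.get("lambda_weight", 0.5),
            norm_eps=loss_block.get("norm_eps", 0.0),
        )

    # -- data order and augmentation streams -------------------------------
    def _epoch_order(self, epoch: int) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.train_config.seed, 7, epoch]))
        return rng.permutation(len(self.frames))

    def _step_rng(self, step: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.train_config.seed, 11, step]))

    def _steps_per_epoch(self) -> int:
        n = len(self.frames) // self.train_config.batch_size
        if n < 1:
            raise ValueError("corpus smaller than one batch")
        return n

    # -- fitting ------------------------------------------------------------
    def fit(self, max_steps: Optional[int] = None,
            log_csv: Union[str, Path, None] = None,
            checkpoint_dir: Union[str, Path, None] = None,
            collapse_every: Optional[int] = None,
            verbose: bool = False) -> "PretrainResults":
        """Run pre-training; returns a results object.

        ``max_steps`` caps the total number of optimisation steps (the
        full schedule still spans ``epochs``); by default the loop runs
        ``epochs`` full passes.  ``collapse_every`` records the collapse
        diagnostic every that many steps into the results' collapse
        trajectory.  Resuming via checkpoints continues the identical
        seeded data and augmentation streams.
        """
        cfg = self.train_config
        spe = self._steps_per_epoch()
        total_steps = cfg.epochs * spe
        if max_steps is not None:
            total_steps = min(total_steps, self.global_step + max_steps)
        csv_writer = None
        csv_fh = None
        if log_csv is not None:
            csv_fh = open(log_csv, "a", newline="")
            csv_writer = csv.writer(csv_fh)
            if csv_fh.tell() == 0:
                csv_writer.writerow(["step", "epoch", "lr", "L_local",
                                     "L_global", "L_total"])
        self.network.train()
        try:
            while self.global_step < total_steps:
                step = self.global_step
                epoch = step // spe
                order = self._epoch_order(epoch)
                pos = (step % spe) * cfg.batch_size
                batch = self.frames[order[pos:pos + cfg.batch_size]]
                pair = augment_pair(batch, self.augment_config,
                                    self._step_rng(step))
                epoch_frac = step / spe
                lr = apply_schedule(self.optimizer, epoch_frac, cfg)
                breakdown = training_step(
                    self.network, pair, self.optimizer, self.lambda_weight,
                    eps=self.norm_eps, stop_gradient=self.stop_gradient)
                self.global_step += 1
                rec = StepRecord(step=step, epoch=epoch_frac, lr=lr,
                                 L_local=breakdown.L_local,
                                 L_global=breakdown.L_global,
                                 L_total=breakdown.L_total)
                self._history.append(rec)
                if csv_writer is not None and \
                        (step % cfg.log_every == 0 or step == total_steps - 1):
                    csv_writer.writerow([rec.step, f"{rec.epoch:.4f}",
                                         f"{rec.lr:.6f}", rec.L_local,
                                         rec.L_global, rec.L_total])
                if collapse_every is not None and \
                        (step + 1) % collapse_every == 0:
                    z = self.training_representations()
                    self._collapse_trajectory.append(
                        (step + 1, collapse_metric(z["emb_local"]).ratio,
                         collapse_metric(z["emb_global"]).ratio))
                if verbose and step % cfg.log_every == 0:
                    print(f"step {step:6d} epoch {epoch_frac:7.2f} "
                          f"lr {lr:.4f} L {rec.L_total:+.4f}")
                if checkpoint_dir is not None and \
                        (step + 1) % (cfg.checkpoint_every * spe) == 0:
                    self.save(Path(checkpoint_dir) /
                              f"ckpt_step{step + 1:06d}.npz")
        finally:
            if csv_fh is not None:
                csv_fh.close()
        return PretrainResults(self)

    # -- persistence --------------------------------------------------------
    def save(self, path: Union[str, Path]) -> Path:
        return save_checkpoint(path, self.network, self.optimizer,
                               self.train_config, self.global_step,
                               meta={"lambda_weight": self.lambda_weight})

    def load(self, path: Union[str, Path]) -> "FPSiamModel":
        header, arrays = read_checkpoint(path)
        model_state = {k[len("model."):]: v for k, v in arrays.items()
                       if k.startswith("model.")}
        self.network.load_state_dict(model_state)
        velocities = []
        flat_params = [p for g in self.optimizer.param_groups
                       for p in g["params"]]
        for i in range(len(flat_params)):
            velocities.append(arrays.get(f"optim.v{i}"))
        self.optimizer.load_state_dict({"velocities": velocities,
                                        "groups": header["optim_groups"]})
        self.global_step = header["global_step"]
        return self

    # -- diagnostics --------------------------------------------------------
    def training_representations(self, frames: Optional[np.ndarray] = None
                                 ) -> Dict[str, np.ndarray]:
        """Train-mode z batches for collapse diagnostics.

        Runs one augmented forward exactly as a training step would (batch
        statistics in every BN), without touching the optimiser, and with
        running statistics snapshot-restored so the call has no side
        effects.  At random initialisation the projection's output BN
        spreads the batch, so the collapse metric starts near its
        ``1/sqrt(dim)`` reference; a collapsing run drives it to zero.
        """
        if frames is None:
            frames = self.frames[:self.train_config.batch_size]
        pair = augment_pair(frames, self.augment_config,
                            self._step_rng(self.global_step))
        net = self.network
        was_training = net.training
        buffers = {k: v.copy() for k, v in net.named_buffers()}
        net.train()
        try:
            from .backbone import extract_multiscale
            feats = extract_multiscale(net.backbone, Tensor(pair.view1))
            pyr = net.pyramid(feats)
            out = {"z_local": net.projection(pyr.m_local).data,
                   "z_global": net.projection(pyr.m_global).data,
                   "emb_local": net.projection.embed(pyr.m_local).data,
                   "emb_global": net.projection.embed(pyr.m_global).data}
        finally:
            owners = net._named_buffer_owners()
            for k, v in buffers.items():
                mod, local = owners[k]
                mod._buffers[local][...] = v
            net.train(was_training)
        return out

    def encode_frames(self, frames: Optional[np.ndarray] = None,
                      max_frames: int = 256) -> Dict[str, np.ndarray]:
        """Eval-mode representations of (un-augmented, normalised) frames."""
        if frames is None:
            frames = self.frames[:max_frames]
        x = normalize(np.asarray(frames, dtype=np.float32),
                      self.augment_config.normalize_mean,
                      self.augment_config.normalize_std)
        was_training = self.network.training
        self.network.eval()
        try:
            z = self.network.encode(Tensor(x))
        finally:
            self.network.train(was_training)
        return {"z_local": z.z_local.data, "z_global": z.z_global.data}


class PretrainResults:
    """Outcome of a pre-training run.

    Carries the per-step loss trajectory, the learning-rate trace and
    collapse diagnostics; ``summary()`` renders a short report and
    ``export_backbone()`` writes the downstream hand-off checkpoint.
    """

    def __init__(self, model: FPSiamModel):
        self.model = model
        self.history: List[StepRecord] = list(model._history)
        #: (step, local ratio, global ratio) samples recorded during fit
        self.collapse_trajectory: List[Tuple[int, float, float]] = \
            list(model._collapse_trajectory)

    # -- trajectory ---------------------------------------------------------
    @property
    def losses(self) -> np.ndarray:
        return np.array([r.L_total for r in self.history])

    @property
    def lrs(self) -> np.ndarray:
        return np.array([r.lr for r in self.history])

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame([asdict(r) for r in self.history])

    # -- diagnostics --------------------------------------------------------
    def collapse_metrics(self, frames: Optional[np.ndarray] = None
                         ) -> Dict[str, CollapseMetrics]:
        """Collapse diagnostics on a train-mode representation batch.

        Measured on the projection head's pre-whitening embeddings (the
        final fc output before its BN): the output BN standardises every
        training batch, so a collapsing encoder would look healthy at the
        head's output while its actual representation degenerates.
        """
        z = self.model.training_representations(frames)
        return {"local": collapse_metric(z["emb_local"]),
                "global": collapse_metric(z["emb_global"])}

    def export_backbone(self, path: Union[str, Path]) -> Path:
        return export_backbone(self.model.network, path)

    def summary(self) -> str:
        h = self.history
        cm = self.collapse_metrics()
        buf = io.StringIO()
        w = buf.write
        w("FPSiam pre-training results\n")
        w("=" * 60 + "\n")
        cfg = self.model.train_config
        w(f"frames: {len(self.model.frames)}   batch: {cfg.batch_size}   "
          f"steps run: {self.model.global_step}\n")
        w(f"schedule: SGD lr={cfg.base_lr} momentum={cfg.momentum} "
          f"wd={cfg.weight_decay}, cosine over {cfg.epochs} epochs"
          f"{' (prediction head fixed)' if cfg.pred_head_lr_fixed else ''}\n")
        w(f"lambda (local/global weight): {self.model.lambda_weight}\n")
        w("-" * 60 + "\n")
        if h:
            w(f"{'':<18}{'first':>12}{'last':>12}\n")
            w(f"{'L_total':<18}{h[0].L_total:>12.4f}{h[-1].L_total:>12.4f}\n")
            w(f"{'L_local':<18}{h[0].L_local:>12.4f}{h[-1].L_local:>12.4f}\n")
            w(f"{'L_global':<18}{h[0].L_global:>12.4f}{h[-1].L_global:>12.4f}\n")
            w(f"{'lr (encoder)':<18}{h[0].lr:>12.4f}{h[-1].lr:>12.4f}\n")
        w("-" * 60 + "\n")
        for level, m in cm.items():
            w(f"collapse metric ({level}): {m.per_channel_std:.4f} "
              f"(reference 1/sqrt(d) = {m.expected_nocollapse:.4f}, "
              f"ratio {m.ratio:.2f})\n")
        return buf.getvalue()
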