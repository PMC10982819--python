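"""Weakly supervised lymph-node diagnosis model.

The central idea: a patient is a *bag* of MRI-visible lymph nodes, and only
patient-level pathology is known — whether any resected node was metastatic
(binary label ``y``) and which fraction of resected nodes was metastatic
(proportion ``rho``). A per-node scorer (a small residual CNN on the T2
patch, optionally fused with size and ADC features through a perceptron)
is trained end-to-end through two pooling heads:

* multiple-instance head (max pooling): the most suspicious node's
  probability ``p_max`` is matched to ``y``;
* label-proportion head (average pooling): the mean probability ``p_avg``
  over the bag is matched to ``rho``.

The training loss is ``lambda_mil * BCE(p_max, y) + lambda_llp *
BCE(p_avg, rho)`` with soft-target binary cross-entropy on the proportion
head (a squared-error proportion head is available via
``proportion_loss="mse"``).

Three variants mirror increasing feature availability: ``M_I`` scores the
patch alone; ``M_IS`` fuses the intensity probability with the long/short
diameters and their ratio; ``M_ISA`` additionally fuses mean ADC.

The public shape follows the estimator convention of statistical modelling
packages: build a :class:`WisdomModel` from a cohort of bags, call
:meth:`~WisdomModel.fit`, and receive a :class:`WisdomResults` that scores,
predicts, stages and summarises. ``train_intensity_model`` /
``train_integrated_model`` are thin functional wrappers over the same
machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from ._nn import Adam, FusionMLP, IntensityNet
from .errors import ConfigurationError, FeatureContractError, TargetError
from .features import normalize_intensity
from .simulate import PatientBag
from .staging import Stage, count_to_stage

__all__ = [
    "VARIANTS",
    "WisdomConfig",
    "WeakSupervisionTargets",
    "BagScores",
    "WisdomModel",
    "WisdomResults",
    "PatientPrediction",
    "weak_supervision_loss",
    "score_bag",
    "predict_patient",
    "train_intensity_model",
    "train_integrated_model",
]

VARIANTS = ("M_I", "M_IS", "M_ISA")
_EPS = 1e-7  # probability clamp inside cross-entropies


@dataclass(frozen=True)
class WisdomConfig:
    """Training configuration.

    ``lambda_mil`` and ``lambda_llp`` weight the max-pooling (binary) and
    average-pooling (proportion) heads; they may not both be zero.
    ``epochs``/``lr``/``batch_bags`` drive the intensity CNN,
    ``fusion_epochs``/``fusion_lr`` the fusion perceptron. Mini-batches are
    whole bags. ``threshold_policy`` is ``"youden"`` (maximise J of
    ``p_max`` vs ``y`` on the training bags) or ``"fixed:<value>"``.
    """

    variant: str = "M_I"
    lambda_mil: float = 1.0
    lambda_llp: float = 1.0
    proportion_loss: str = "bce"
    epochs: int = 14
    lr: float = 3e-3
    batch_bags: int = 8
    fusion_epochs: int = 120
    fusion_lr: float = 2e-2
    fusion_hidden: int = 16
    val_fraction: float = 0.15
    patience: int = 10
    grad_clip: float = 5.0
    threshold_policy: str = "youden"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"WisdomConfig.variant: must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.lambda_mil < 0 or self.lambda_llp < 0:
            raise ConfigurationError(
                "WisdomConfig.lambda_mil/lambda_llp: must be non-negative"
            )
        if self.lambda_mil + self.lambda_llp <= 0:
            raise ConfigurationError(
                "WisdomConfig.lambda_mil/lambda_llp: at least one must be positive"
            )
        if self.proportion_loss not in ("bce", "mse"):
            raise ConfigurationError(
                f"WisdomConfig.proportion_loss: 'bce' or 'mse', got "
                f"{self.proportion_loss!r}"
            )
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigurationError(
                f"WisdomConfig.val_fraction: must be in [0, 1), got {self.val_fraction}"
            )
        if not (
            self.threshold_policy == "youden"
            or self.threshold_policy.startswith("fixed:")
        ):
            raise ConfigurationError(
                "WisdomConfig.threshold_policy: 'youden' or 'fixed:<tau>', got "
                f"{self.threshold_policy!r}"
            )

    def replace(self, **kw) -> "WisdomConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class WeakSupervisionTargets:
    """Patient-level supervision: binary label and metastatic proportion."""

    y: int
    rho: float

    def __post_init__(self):
        if self.y not in (0, 1):
            raise TargetError(f"WeakSupervisionTargets.y: must be 0/1, got {self.y}")
        if not 0.0 <= self.rho <= 1.0:
            raise TargetError(
                f"WeakSupervisionTargets.rho: must be in [0, 1], got {self.rho}"
            )
        if self.y == 0 and self.rho != 0.0:
            raise TargetError(
                f"WeakSupervisionTargets: y = 0 requires rho = 0, got rho = {self.rho}"
            )

    @classmethod
    def from_bag(cls, bag: PatientBag) -> "WeakSupervisionTargets":
        return cls(y=bag.y, rho=bag.rho)


@dataclass(frozen=True)
class BagScores:
    """Per-node probabilities of one bag plus both pooled summaries."""

    probs: np.ndarray
    p_max: float
    p_avg: float

    @classmethod
    def from_probs(cls, probs) -> "BagScores":
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise TargetError("BagScores: probs must be a non-empty 1-D array")
        if probs.min() < 0 or probs.max() > 1:
            raise TargetError("BagScores: probabilities must lie in [0, 1]")
        return cls(probs=probs, p_max=float(probs.max()), p_avg=float(probs.mean()))


def _bce(p: float, t: float) -> float:
    p = min(max(p, _EPS), 1.0 - _EPS)
    return -(t * np.log(p) + (1.0 - t) * np.log1p(-p))


def weak_supervision_loss(
    scores: BagScores,
    targets: WeakSupervisionTargets,
    lambda_mil: float = 1.0,
    lambda_llp: float = 1.0,
    proportion_loss: str = "bce",
) -> float:
    """The bag loss: ``lambda_mil*BCE(p_max, y) + lambda_llp*BCE(p_avg, rho)``.

    Cross-entropies clamp probabilities at 1e-7. With
    ``proportion_loss="mse"`` the second term becomes
    ``(p_avg - rho)**2``.
    """
    if lambda_mil < 0 or lambda_llp < 0 or lambda_mil + lambda_llp <= 0:
        raise ConfigurationError(
            "weak_supervision_loss: weights must be non-negative, not both zero"
        )
    mil = _bce(scores.p_max, float(targets.y))
    if proportion_loss == "bce":
        llp = _bce(scores.p_avg, targets.rho)
    elif proportion_loss == "mse":
        llp = (scores.p_avg - targets.rho) ** 2
    else:
        raise ConfigurationError(
            f"weak_supervision_loss: unknown proportion_loss {proportion_loss!r}"
        )
    return float(lambda_mil * mil + lambda_llp * llp)


def _bag_loss_grad(probs, y, rho, lam_mil, lam_llp, proportion_loss):
    """Loss of one bag and d(loss)/d(logit_i) through both pooling heads."""
    n = probs.size
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    p_max = p.max()
    p_avg = p.mean()
    i_max = int(np.argmax(p))
    loss = lam_mil * _bce(p_max, y)
    dz = np.zeros(n, dtype=np.float64)
    # d BCE(sigmoid(z), t) / dz = p - t at the pooled node
    dz[i_max] += lam_mil * (p_max - y)
    sig_prime = p * (1.0 - p)
    if proportion_loss == "bce":
        loss += lam_llp * _bce(p_avg, rho)
        davg = (p_avg - rho) / max(p_avg * (1.0 - p_avg), _EPS)
    else:
        loss += lam_llp * (p_avg - rho) ** 2
        davg = 2.0 * (p_avg - rho)
    dz += lam_llp * davg * sig_prime / n
    return loss, dz


def _sigmoid(z):
    from scipy.special import expit

    return expit(np.asarray(z, dtype=np.float64))


def _logit(p):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _youden_threshold(scores, labels):
    """Threshold maximising sensitivity + specificity - 1 on (scores, labels).

    Candidates are midpoints between consecutive distinct scores plus both
    outer extremes; ties prefer the lower (more sensitive) threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    cands = np.concatenate(
        [[uniq[0] - 1e-6], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-6]]
    )
    n_pos = max(int((labels == 1).sum()), 1)
    n_neg = max(int((labels == 0).sum()), 1)
    best_tau, best_j = 0.5, -np.inf
    for tau in cands:
        pred = scores >= tau
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_tau = j, float(tau)
    return float(np.clip(best_tau, _EPS, 1.0 - _EPS))


def _bag_patches(bag: PatientBag) -> np.ndarray:
    for node in bag.nodes:
        if node.patch is None:
            raise FeatureContractError(
                f"bag {bag.patient_id}: node {node.node_id} has no image patch; "
                "the intensity network requires rendered patches"
            )
    return np.stack(
        [normalize_intensity(n.patch).astype(np.float32) for n in bag.nodes]
    )[:, None, :, :]


def _check_contract(bags, variant):
    if variant == "M_ISA":
        for bag in bags:
            for node in bag.nodes:
                if node.mean_adc is None:
                    raise FeatureContractError(
                        f"variant M_ISA requires mean ADC on every node; "
                        f"node {node.node_id} of bag {bag.patient_id} has none"
                    )


def _fusion_features(bag, p_int, variant):
    """Raw (unstandardized) fusion input rows for one bag.

    Column 0 is the *logit* of the intensity probability — keeping the
    intensity evidence on its natural scale lets an identity-configured
    perceptron reproduce the intensity scorer exactly.
    """
    cols = [_logit(p_int)]
    cols.append(np.array([n.long_diam_mm for n in bag.nodes]))
    cols.append(np.array([n.short_diam_mm for n in bag.nodes]))
    cols.append(np.array([n.diam_ratio for n in bag.nodes]))
    if variant == "M_ISA":
        cols.append(np.array([n.mean_adc for n in bag.nodes]))
    return np.stack(cols, axis=1).astype(np.float32)


@dataclass
class PatientPrediction:
    """Per-patient inference output."""

    patient_id: str
    probs: np.ndarray
    k_hat: int
    patient_score: float
    stage_pred: Stage


class WisdomResults:
    """A fitted diagnosis model: scorers, decision threshold, diagnostics.

    Attributes
    ----------
    variant : str
        ``M_I``, ``M_IS`` or ``M_ISA``.
    intensity_net : IntensityNet
        The patch scorer (shared by all variants).
    fusion : FusionMLP or None
        The feature-fusion perceptron (``None`` for ``M_I``).
    tau : float
        Decision threshold for calling a node metastatic; fixed on the
        training bags only.
    loss_history : dict
        Per-epoch training/validation losses for each fitted component.
    """

    def __init__(
        self,
        variant,
        intensity_net,
        fusion,
        feature_mean,
        feature_scale,
        tau,
        config,
        loss_history,
        n_train_bags,
    ):
        self.variant = variant
        self.intensity_net = intensity_net
        self.fusion = fusion
        self.feature_mean = feature_mean
        self.feature_scale = feature_scale
        self.tau = float(tau)
        self.config = config
        self.loss_history = loss_history
        self.n_train_bags = n_train_bags

    # -- scoring ---------------------------------------------------------
    def intensity_probs(self, bag: PatientBag) -> np.ndarray:
        """Intensity-network probability for every node of the bag."""
        return _sigmoid(self.intensity_net.forward(_bag_patches(bag)))

    def score_bag(self, bag: PatientBag) -> BagScores:
        """Per-node metastatic probabilities plus max/average pooling."""
        _check_contract([bag], self.variant)
        p_int = self.intensity_probs(bag)
        if self.variant == "M_I":
            return BagScores.from_probs(np.clip(p_int, 0.0, 1.0))
        feats = _fusion_features(bag, p_int, self.variant)
        z = (feats - self.feature_mean) / self.feature_scale
        return BagScores.from_probs(
            np.clip(_sigmoid(self.fusion.forward(z.astype(np.float32))), 0.0, 1.0)
        )

    def predict(self, bag: PatientBag) -> PatientPrediction:
        """Node probabilities, metastatic-node count, score and N stage.

        ``k_hat`` counts nodes with probability >= tau; the patient-level
        ROC score is ``p_max`` (consistent with the MIL head); the stage is
        the staging map applied to ``k_hat``.
        """
        scores = self.score_bag(bag)
        k_hat = int((scores.probs >= self.tau).sum())
        return PatientPrediction(
            patient_id=bag.patient_id,
            probs=scores.probs,
            k_hat=k_hat,
            patient_score=scores.p_max,
            stage_pred=count_to_stage(k_hat),
        )

    def predict_cohort(self, bags) -> "pandas.DataFrame":
        import pandas as pd

        rows = []
        for bag in bags:
            pred = self.predict(bag)
            rows.append(
                {
                    "patient_id": bag.patient_id,
                    "patient_score": pred.patient_score,
                    "k_hat": pred.k_hat,
                    "stage_pred": str(pred.stage_pred),
                    "n_nodes": len(bag),
                }
            )
        return pd.DataFrame(rows)

    def evaluate(self, bags, seed: int = 0):
        """Full patient-level evaluation report against pathology truth."""
        from .metrics import evaluate_cohort

        return evaluate_cohort(self, bags, seed=seed)

    def summary(self) -> str:
        cfg = self.config
        hist = self.loss_history.get("intensity", [])
        lines = [
            "Weakly Supervised LN Diagnosis Model Results",
            "=" * 46,
            f"variant:            {self.variant}",
            f"training bags:      {self.n_train_bags}",
            f"loss weights:       lambda_mil={cfg.lambda_mil}, "
            f"lambda_llp={cfg.lambda_llp} ({cfg.proportion_loss} proportion head)",
            f"decision threshold: tau={self.tau:.4f} ({cfg.threshold_policy})",
            f"intensity epochs:   {len(hist)}",
        ]
        if hist:
            lines.append(
                f"intensity loss:     {hist[0]['train']:.4f} -> {hist[-1]['train']:.4f}"
                " (train, first -> last epoch)"
            )
        if self.fusion is not None:
            fh = self.loss_history.get("fusion", [])
            if fh:
                lines.append(
                    f"fusion loss:        {fh[0]['train']:.4f} -> "
                    f"{fh[-1]['train']:.4f} ({len(fh)} epochs)"
                )
        lines.append("=" * 46)
        return "\n".join(lines)


class WisdomModel:
    """Unfitted weakly supervised diagnosis model over a cohort of bags.

    Parameters
    ----------
    cohort : sequence of PatientBag
        Training bags; every bag must be non-empty and carry the features
        the chosen variant requires.
    config : WisdomConfig, optional
        Training configuration; ``config.variant`` selects ``M_I``,
        ``M_IS`` or ``M_ISA``.
    intensity_results : WisdomResults, optional
        A fitted ``M_I`` result whose intensity network is reused (and
        frozen) when fitting a fused variant. If omitted for ``M_IS`` /
        ``M_ISA``, the intensity stage is fitted first automatically.
    """

    def __init__(self, cohort, config: Optional[WisdomConfig] = None,
                 intensity_results: Optional[WisdomResults] = None):
        self.cohort = list(cohort)
        self.config = config or WisdomConfig()
        self.intensity_results = intensity_results
        if not self.cohort:
            raise ConfigurationError("WisdomModel: cohort is empty")
        _check_contract(self.cohort, self.config.variant)
        labels = {bag.y for bag in self.cohort}
        if len(labels) < 2:
            warnings.warn(
                "WisdomModel: all bags share the same binary label; "
                "supervision is degenerate",
                stacklevel=2,
            )

    # -- internals -------------------------------------------------------
    def _split(self, rng):
        n = len(self.cohort)
        idx = rng.permutation(n)
        n_val = int(round(self.config.val_fraction * n))
        if self.config.val_fraction > 0:
            n_val = max(n_val, 1)
        n_val = min(n_val, n - 1)
        return idx[n_val:], idx[:n_val]

    def _fit_intensity(self, rng):
        cfg = self.config
        net = IntensityNet(seed=int(rng.integers(2**31)))
        bags = self.cohort
        patches = [_bag_patches(b) for b in bags]
        ys = [float(b.y) for b in bags]
        rhos = [b.rho for b in bags]
        # prior-bias initialisation: start every node near the cohort's mean
        # metastatic proportion instead of 0.5, so the proportion head does
        # not dominate the first epochs
        prior = float(np.clip(np.mean(rhos), 0.02, 0.5))
        net.fc.b[...] = np.log(prior / (1.0 - prior))
        train_idx, val_idx = self._split(rng)
        opt = Adam(net.params(), lr=cfg.lr, clip_norm=cfg.grad_clip)
        history = []
        best = (np.inf, net.state(), 0)
        wait = 0
        for epoch in range(cfg.epochs):
            # step decay stabilises the max-pooling head late in training
            if epoch >= 0.85 * cfg.epochs:
                opt.lr = cfg.lr * 0.09
            elif epoch >= 0.6 * cfg.epochs:
                opt.lr = cfg.lr * 0.3
            order = rng.permutation(train_idx)
            train_loss = 0.0
            for start in range(0, order.size, cfg.batch_bags):
                batch = order[start : start + cfg.batch_bags]
                x = np.concatenate([patches[i] for i in batch])
                opt.zero_grad()
                logits = net.forward(x)
                probs = _sigmoid(logits)
                dz = np.zeros_like(logits, dtype=np.float64)
                pos = 0
                loss = 0.0
                for i in batch:
                    n_i = patches[i].shape[0]
                    li, gi = _bag_loss_grad(
                        probs[pos : pos + n_i], ys[i], rhos[i],
                        cfg.lambda_mil, cfg.lambda_llp, cfg.proportion_loss,
                    )
                    loss += li
                    dz[pos : pos + n_i] = gi
                    pos += n_i
                loss /= batch.size
                dz /= batch.size
                net.backward(dz.astype(np.float32))
                opt.step()
                train_loss += loss * batch.size
            train_loss /= max(order.size, 1)
            val_loss = self._eval_loss(net, patches, ys, rhos, val_idx)
            history.append({"epoch": epoch, "train": train_loss, "val": val_loss})
            monitor = val_loss if val_idx.size else train_loss
            if monitor < best[0] - 1e-5:
                best = (monitor, net.state(), epoch)
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        net.load_state(best[1])
        return net, history

    def _eval_loss(self, net, patches, ys, rhos, idx):
        if idx.size == 0:
            return float("nan")
        total = 0.0
        for i in idx:
            probs = _sigmoid(net.forward(patches[i]))
            scores = BagScores.from_probs(np.clip(probs, 0, 1))
            total += weak_supervision_loss(
                scores,
                WeakSupervisionTargets(int(ys[i]), rhos[i]),
                self.config.lambda_mil,
                self.config.lambda_llp,
                self.config.proportion_loss,
            )
        return total / idx.size

    def _fit_fusion(self, rng, intensity_net):
        cfg = self.config
        bags = self.cohort
        feats = []
        for bag in bags:
            p_int = _sigmoid(intensity_net.forward(_bag_patches(bag)))
            feats.append(_fusion_features(bag, p_int, cfg.variant))
        train_idx, val_idx = self._split(rng)
        stacked = np.concatenate([feats[i] for i in train_idx])
        mean = stacked.mean(axis=0)
        scale = np.maximum(stacked.std(axis=0), 1e-6)
        z = [((f - mean) / scale).astype(np.float32) for f in feats]
        mlp = FusionMLP(
            z[0].shape[1], hidden=cfg.fusion_hidden, seed=int(rng.integers(2**31))
        )
        # warm start at the intensity pass-through: the fused scorer begins
        # exactly where the intensity scorer left off and can only be pulled
        # away by the extra features reducing the weakly supervised loss
        mlp.init_near_identity(
            0, mean=float(mean[0]), scale=float(scale[0]),
            rng=np.random.default_rng(int(rng.integers(2**31))),
        )
        opt = Adam(mlp.params(), lr=cfg.fusion_lr, clip_norm=cfg.grad_clip)
        ys = [float(b.y) for b in bags]
        rhos = [b.rho for b in bags]
        history = []
        best = (np.inf, mlp.state())
        wait = 0
        batch_bags = max(cfg.batch_bags, 16)
        for epoch in range(cfg.fusion_epochs):
            order = rng.permutation(train_idx)
            train_loss = 0.0
            for start in range(0, order.size, batch_bags):
                batch = order[start : start + batch_bags]
                x = np.concatenate([z[i] for i in batch])
                opt.zero_grad()
                probs = _sigmoid(mlp.forward(x))
                dz = np.zeros(x.shape[0], dtype=np.float64)
                pos = 0
                loss = 0.0
                for i in batch:
                    n_i = z[i].shape[0]
                    li, gi = _bag_loss_grad(
                        probs[pos : pos + n_i], ys[i], rhos[i],
                        cfg.lambda_mil, cfg.lambda_llp, cfg.proportion_loss,
                    )
                    loss += li
                    dz[pos : pos + n_i] = gi
                    pos += n_i
                loss /= batch.size
                dz /= batch.size
                mlp.backward(dz.astype(np.float32))
                opt.step()
                train_loss += loss * batch.size
            train_loss /= max(order.size, 1)
            if val_idx.size:
                val_loss = 0.0
                for i in val_idx:
                    probs = _sigmoid(mlp.forward(z[i]))
                    scores = BagScores.from_probs(np.clip(probs, 0, 1))
                    val_loss += weak_supervision_loss(
                        scores, WeakSupervisionTargets(int(ys[i]), rhos[i]),
                        cfg.lambda_mil, cfg.lambda_llp, cfg.proportion_loss,
                    )
                val_loss /= val_idx.size
            else:
                val_loss = float("nan")
            history.append({"epoch": epoch, "train": train_loss, "val": val_loss})
            monitor = val_loss if val_idx.size else train_loss
            if monitor < best[0] - 1e-5:
                best = (monitor, mlp.state())
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        mlp.load_state(best[1])
        return mlp, mean, scale, history

    # -- fitting ---------------------------------------------------------
    def fit(self) -> WisdomResults:
        """Train the scorer(s) and fix the decision threshold.

        Reproducible for a fixed ``config.seed`` on a fixed build. Returns
        a :class:`WisdomResults`.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        loss_history = {}
        if self.intensity_results is not None:
            net = self.intensity_results.intensity_net
            loss_history["intensity"] = list(
                self.intensity_results.loss_history.get("intensity", [])
            )
        else:
            net, hist = self._fit_intensity(rng)
            loss_history["intensity"] = hist
        fusion = mean = scale = None
        if cfg.variant != "M_I":
            fusion, mean, scale, fhist = self._fit_fusion(rng, net)
            loss_history["fusion"] = fhist
        results = WisdomResults(
            variant=cfg.variant,
            intensity_net=net,
            fusion=fusion,
            feature_mean=mean,
            feature_scale=scale,
            tau=0.5,
            config=cfg,
            loss_history=loss_history,
            n_train_bags=len(self.cohort),
        )
        if cfg.threshold_policy.startswith("fixed:"):
            results.tau = float(cfg.threshold_policy.split(":", 1)[1])
        else:
            p_max = np.array([results.score_bag(b).p_max for b in self.cohort])
            y = np.array([b.y for b in self.cohort])
            if len(set(y.tolist())) < 2:
                results.tau = 0.5
            else:
                results.tau = _youden_threshold(p_max, y)
        return results


# -- functional wrappers over the estimator shape ------------------------

def score_bag(model: WisdomResults, bag: PatientBag) -> BagScores:
    """Score one bag with a fitted model (order-preserving per-node probs)."""
    return model.score_bag(bag)


def predict_patient(model: WisdomResults, bag: PatientBag):
    """Predict ``(probs, k_hat, patient_score, stage_pred)`` for one bag."""
    pred = model.predict(bag)
    return pred.probs, pred.k_hat, pred.patient_score, pred.stage_pred


def train_intensity_model(cohort, config: Optional[WisdomConfig] = None) -> WisdomResults:
    """Fit the intensity-only variant ``M_I`` on a cohort of bags."""
    config = (config or WisdomConfig()).replace(variant="M_I")
    return WisdomModel(cohort, config).fit()


def train_integrated_model(
    cohort, intensity_model: WisdomResults, config: WisdomConfig
) -> WisdomResults:
    """Fit a fused variant (``M_IS`` or ``M_ISA``) on top of a fitted ``M_I``."""
    if config.variant not in ("M_IS", "M_ISA"):
        raise ConfigurationError(
            f"train_integrated_model: variant must be M_IS or M_ISA, got "
            f"{config.variant!r}"
        )
    return WisdomModel(cohort, config, intensity_results=intensity_model).fit()
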