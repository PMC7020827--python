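"""SDAE-LSTM depth-of-anesthesia regressor.

Architecture 46-92-12-18-1: two sparse denoising autoencoders (46->92 and
92->12, sigmoid encoders) are pretrained greedily — the first on corrupted
feature vectors, the second on the first encoder's clean outputs — then an
LSTM (input 12, hidden 18) with a linear output head is trained on the
encoded window sequences against effect-site concentration labels, and
finally the whole stack is fine-tuned end to end.  Setting ``use_sdae=False``
gives the plain-LSTM ablation (46 -> LSTM -> 1).

Training is full-batch-free minibatch Adam with L2 weight decay; sequences
are cut into truncated-backpropagation chunks of ``seq_len`` windows.
Features and labels are z-scored internally and predictions returned on the
original label scale, so the output tracks effect-site concentration and
therefore *increases* with anesthetic depth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .features import FeatureMatrix

__all__ = [
    "NetworkSpec",
    "TrainedNetwork",
    "corrupt",
    "pretrain_sdae",
    "train",
    "predict",
    "SDAELSTMRegressor",
]


@dataclass
class NetworkSpec:
    """Hyperparameters of the SDAE-LSTM (the 46-92-12-18-1 stack)."""

    input_dim: int = 46
    sdae_dims: tuple[int, int] = (92, 12)
    lstm_hidden: int = 18
    output_dim: int = 1
    corruption_p: float = 0.3
    sparsity_target: float = 0.05
    sparsity_weight: float = 0.1
    seq_len: int = 64
    pretrain_epochs: int = 50
    lstm_epochs: int = 150
    finetune_epochs: int = 50
    lr_pretrain: float = 1e-2
    lr_lstm: float = 1e-2
    lr_finetune: float = 2e-3
    batch_size: int = 64
    weight_decay: float = 1e-5
    use_sdae: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, *self.sdae_dims, self.lstm_hidden, self.output_dim) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if not 0 <= self.corruption_p < 1:
            raise ValueError("corruption probability must lie in [0, 1)")
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity target must lie in (0, 1)")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity weight must be >= 0")


@dataclass
class TrainedNetwork:
    """A fitted SDAE-LSTM: spec, weights (including scalers) and loss logs."""

    spec: NetworkSpec
    params: dict
    training_log: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Serialize as an .npz archive with the spec as a JSON header."""
        arrays = dict(self.params)
        arrays["_spec_json"] = np.array(json.dumps(asdict(self.spec)))
        arrays["_log_json"] = np.array(json.dumps(self.training_log))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedNetwork":
        data = np.load(path, allow_pickle=False)
        spec_d = json.loads(str(data["_spec_json"]))
        spec_d["sdae_dims"] = tuple(spec_d["sdae_dims"])
        log = json.loads(str(data["_log_json"]))
        params = {k: data[k] for k in data.files if not k.startswith("_")}
        return cls(spec=NetworkSpec(**spec_d), params=params, training_log=log)


def corrupt(x: np.ndarray, p: float, seed: int | np.random.Generator) -> np.ndarray:
    """Masking corruption: each element independently zeroed with probability p."""
    if not 0 <= p < 1:
        raise ValueError(f"corruption probability must lie in [0, 1), got {p}")
    x = np.asarray(x, dtype=float)
    if p == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return x * (rng.random(x.shape) >= p)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    if isinstance(features, (list, tuple)):
        return np.vstack([_as_matrix(f) for f in features])
    return np.asarray(features, dtype=float)


def pretrain_sdae(features, spec: NetworkSpec | None = None) -> dict:
    """Greedy layerwise pretraining of the two denoising autoencoders.

    ``features`` is a feature matrix (or stack of per-subject matrices),
    assumed already standardized.  Returns encoder and decoder parameters
    for both layers (decoders are kept for diagnostics only).
    """
    spec = spec or NetworkSpec()
    X = _as_matrix(features)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    reg = SDAELSTMRegressor.from_spec(spec)
    rng = np.random.default_rng(spec.seed)
    return reg._pretrain(X, rng)[0]


def train(features_per_subject, labels_per_subject, spec: NetworkSpec | None = None) -> TrainedNetwork:
    """Train the full SDAE-LSTM on per-subject feature/label sequences."""
    spec = spec or NetworkSpec()
    mats = [_as_matrix(f) for f in features_per_subject]
    labs = [np.asarray(l, dtype=float) for l in labels_per_subject]
    if len(mats) < 1:
        raise ValueError("need at least one training subject")
    X = np.vstack(mats)
    y = np.concatenate(labs)
    subjects = np.concatenate([np.full(m.shape[0], i) for i, m in enumerate(mats)])
    reg = SDAELSTMRegressor.from_spec(spec).fit(X, y, subjects=subjects)
    return TrainedNetwork(spec=spec, params=reg.params_, training_log=reg.loss_log_)


def predict(net: TrainedNetwork, features) -> np.ndarray:
    """Stream a subject's windows (temporal order) through a trained network."""
    reg = SDAELSTMRegressor.from_spec(net.spec)
    reg._adopt(net.params)
    return reg.predict(_as_matrix(features))


class SDAELSTMRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the SDAE-LSTM.

    Parameters mirror :class:`NetworkSpec`.  ``fit(X, y, subjects=...)``
    expects one row per analysis window in temporal order within each
    subject; ``subjects`` marks sequence boundaries (a single sequence is
    assumed when omitted).  ``predict`` streams windows through the encoders
    and the recurrent layer in order, carrying state across the whole
    sequence, and is deterministic given the fitted weights.
    """

    def __init__(
        self,
        sdae_hidden: int = 92,
        sdae_code: int = 12,
        lstm_hidden: int = 18,
        corruption_p: float = 0.3,
        sparsity_target: float = 0.05,
        sparsity_weight: float = 0.1,
        seq_len: int = 64,
        pretrain_epochs: int = 50,
        lstm_epochs: int = 150,
        finetune_epochs: int = 50,
        lr_pretrain: float = 1e-2,
        lr_lstm: float = 1e-2,
        lr_finetune: float = 2e-3,
        batch_size: int = 64,
        weight_decay: float = 1e-5,
        use_sdae: bool = True,
        seed: int = 0,
    ):
        self.sdae_hidden = sdae_hidden
        self.sdae_code = sdae_code
        self.lstm_hidden = lstm_hidden
        self.corruption_p = corruption_p
        self.sparsity_target = sparsity_target
        self.sparsity_weight = sparsity_weight
        self.seq_len = seq_len
        self.pretrain_epochs = pretrain_epochs
        self.lstm_epochs = lstm_epochs
        self.finetune_epochs = finetune_epochs
        self.lr_pretrain = lr_pretrain
        self.lr_lstm = lr_lstm
        self.lr_finetune = lr_finetune
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.use_sdae = use_sdae
        self.seed = seed

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_spec(cls, spec: NetworkSpec) -> "SDAELSTMRegressor":
        return cls(
            sdae_hidden=spec.sdae_dims[0],
            sdae_code=spec.sdae_dims[1],
            lstm_hidden=spec.lstm_hidden,
            corruption_p=spec.corruption_p,
            sparsity_target=spec.sparsity_target,
            sparsity_weight=spec.sparsity_weight,
            seq_len=spec.seq_len,
            pretrain_epochs=spec.pretrain_epochs,
            lstm_epochs=spec.lstm_epochs,
            finetune_epochs=spec.finetune_epochs,
            lr_pretrain=spec.lr_pretrain,
            lr_lstm=spec.lr_lstm,
            lr_finetune=spec.lr_finetune,
            batch_size=spec.batch_size,
            weight_decay=spec.weight_decay,
            use_sdae=spec.use_sdae,
            seed=spec.seed,
        )

    def to_spec(self, input_dim: int = 46) -> NetworkSpec:
        return NetworkSpec(
            input_dim=input_dim,
            sdae_dims=(self.sdae_hidden, self.sdae_code),
            lstm_hidden=self.lstm_hidden,
            corruption_p=self.corruption_p,
            sparsity_target=self.sparsity_target,
            sparsity_weight=self.sparsity_weight,
            seq_len=self.seq_len,
            pretrain_epochs=self.pretrain_epochs,
            lstm_epochs=self.lstm_epochs,
            finetune_epochs=self.finetune_epochs,
            lr_pretrain=self.lr_pretrain,
            lr_lstm=self.lr_lstm,
            lr_finetune=self.lr_finetune,
            batch_size=self.batch_size,
            weight_decay=self.weight_decay,
            use_sdae=self.use_sdae,
            seed=self.seed,
        )

    # -- internals ------------------------------------------------------------

    @staticmethod
    def _validate_xy(X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (n_windows, n_features) array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is not None:
            y = np.asarray(y, dtype=float).ravel()
            if y.shape[0] != X.shape[0]:
                raise ValueError("X and y have inconsistent lengths")
            if not np.all(np.isfinite(y)):
                raise ValueError("y contains non-finite values")
        return X, y

    def _pretrain(self, Xz: np.ndarray, rng: np.random.Generator):
        """Greedy layerwise SDAE pretraining on standardized features."""
        logs = {}
        ae1 = nn.init_autoencoder(Xz.shape[1], self.sdae_hidden, rng)
        logs["sdae1"] = self._run_ae(ae1, Xz, rng)
        code1 = nn.sigmoid(Xz @ ae1["W1"] + ae1["b1"])  # clean-input encodings
        ae2 = nn.init_autoencoder(self.sdae_hidden, self.sdae_code, rng)
        logs["sdae2"] = self._run_ae(ae2, code1, rng)
        weights = {
            "enc1_W": ae1["W1"], "enc1_b": ae1["b1"],
            "dec1_W": ae1["W2"], "dec1_b": ae1["b2"],
            "enc2_W": ae2["W1"], "enc2_b": ae2["b1"],
            "dec2_W": ae2["W2"], "dec2_b": ae2["b2"],
        }
        for name, log in logs.items():
            tail = log[-max(2, len(log) // 10):]
            half = len(tail) // 2 or 1
            if np.mean(tail[half:]) > np.mean(tail[:half]) * 1.05:
                warnings.warn(
                    f"{name} reconstruction loss rose over the final epochs "
                    f"({tail[0]:.4g} -> {tail[-1]:.4g})",
                    stacklevel=2,
                )
        return weights, logs

    def _run_ae(self, ae: dict, X: np.ndarray, rng: np.random.Generator) -> list[float]:
        opt = nn.AdamState(ae, lr=self.lr_pretrain)
        n = X.shape[0]
        log = []
        for _ in range(self.pretrain_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                clean = X[idx]
                noisy = corrupt(clean, self.corruption_p, rng)
                loss, grads = nn.ae_loss_and_grads(
                    ae, clean, noisy,
                    sparsity_target=self.sparsity_target,
                    sparsity_weight=self.sparsity_weight,
                    weight_decay=self.weight_decay,
                )
                if not np.isfinite(loss):
                    raise RuntimeError("autoencoder pretraining diverged (non-finite loss)")
                opt.step(ae, grads)
                losses.append(loss)
            log.append(float(np.mean(losses)))
        return log

    @staticmethod
    def _chunks(X: np.ndarray, y: np.ndarray, subjects: np.ndarray, seq_len: int):
        """Cut each subject's sequence into truncated-BPTT chunks (>= 2 windows)."""
        chunks = []
        for s in dict.fromkeys(subjects.tolist()):  # preserve first-seen order
            idx = np.flatnonzero(subjects == s)
            for start in range(0, idx.size, seq_len):
                sl = idx[start : start + seq_len]
                if sl.size >= 2:
                    chunks.append((X[sl], y[sl]))
        if not chunks:
            raise ValueError("no usable training sequences (need >= 2 windows per subject)")
        return chunks

    def _run_sequence_phase(
        self, params: dict, chunks: list, epochs: int, lr: float, rng: np.random.Generator
    ) -> list[float]:
        opt = nn.AdamState(params, lr=lr)
        # batch chunks of equal length together (all but per-subject remainders
        # share seq_len, so batching is near-complete)
        by_len: dict[int, list] = {}
        for ch in chunks:
            by_len.setdefault(ch[0].shape[0], []).append(ch)
        log = []
        max_chunks = max(1, self.batch_size // 4)
        for _ in range(epochs):
            losses = []
            sizes = []
            for T, group in by_len.items():
                order = rng.permutation(len(group))
                for start in range(0, len(group), max_chunks):
                    batch = [group[i] for i in order[start : start + max_chunks]]
                    Xb = np.stack([b[0] for b in batch])
                    yb = np.stack([b[1] for b in batch])
                    loss, grads, _ = nn.sequence_loss_and_grads(
                        params, Xb, yb, weight_decay=self.weight_decay
                    )
                    if not np.isfinite(loss):
                        raise RuntimeError("sequence training diverged (non-finite loss)")
                    opt.step(params, grads)
                    losses.append(loss * Xb.shape[0] * T)
                    sizes.append(Xb.shape[0] * T)
            log.append(float(np.sum(losses) / np.sum(sizes)))
        return log

    # -- estimator API --------------------------------------------------------

    def fit(self, X, y, subjects=None):
        X, y = self._validate_xy(X, y)
        n, d = X.shape
        self.n_features_in_ = d
        subjects = np.zeros(n, dtype=int) if subjects is None else np.asarray(subjects)
        if subjects.shape[0] != n:
            raise ValueError("subjects must have one entry per window")

        rng = np.random.default_rng(self.seed)
        mu = X.mean(axis=0)
        sd = np.maximum(X.std(axis=0), 1e-8)
        Xz = (X - mu) / sd
        y_mu, y_sd = float(y.mean()), float(max(y.std(), 1e-8))
        yz = (y - y_mu) / y_sd

        self.loss_log_ = {}
        params: dict = {}
        if self.use_sdae:
            sdae, ae_logs = self._pretrain(Xz, rng)
            self.loss_log_.update(ae_logs)
            self.sdae_decoders_ = {k: sdae[k] for k in ("dec1_W", "dec1_b", "dec2_W", "dec2_b")}
            enc = {k: sdae[k] for k in ("enc1_W", "enc1_b", "enc2_W", "enc2_b")}
            code = nn.sigmoid(
                nn.sigmoid(Xz @ enc["enc1_W"] + enc["enc1_b"]) @ enc["enc2_W"] + enc["enc2_b"]
            )
            lstm_in = self.sdae_code
        else:
            enc = {}
            code = Xz
            lstm_in = d

        lstm = nn.init_lstm(lstm_in, self.lstm_hidden, rng)
        head_rng_scale = np.sqrt(1.0 / self.lstm_hidden)
        params = {
            "lstm_Wx": lstm["Wx"], "lstm_Wh": lstm["Wh"], "lstm_b": lstm["b"],
            "out_W": rng.normal(0.0, head_rng_scale, size=(self.lstm_hidden, 1)),
            "out_b": np.zeros(1),
        }

        # phase 2: recurrent layer on (encoded) sequences
        code_chunks = self._chunks(code, yz, subjects, self.seq_len)
        extra = 0 if self.use_sdae else self.finetune_epochs
        self.loss_log_["lstm"] = self._run_sequence_phase(
            params, code_chunks, self.lstm_epochs + extra, self.lr_lstm, rng
        )

        # phase 3: end-to-end fine-tuning through the encoders
        if self.use_sdae:
            params.update(enc)
            raw_chunks = self._chunks(Xz, yz, subjects, self.seq_len)
            self.loss_log_["finetune"] = self._run_sequence_phase(
                params, raw_chunks, self.finetune_epochs, self.lr_finetune, rng
            )

        params["feat_mu"] = mu
        params["feat_sd"] = sd
        params["label_mu"] = np.array([y_mu])
        params["label_sd"] = np.array([y_sd])
        self.params_ = params
        return self

    def _adopt(self, params: dict) -> None:
        """Install externally loaded weights (e.g. from TrainedNetwork.load)."""
        self.params_ = {k: np.asarray(v) for k, v in params.items()}
        self.n_features_in_ = self.params_["feat_mu"].shape[0]
        self.loss_log_ = {}

    def predict(self, X, subjects=None) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        X, _ = self._validate_xy(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        p = self.params_
        Xz = (X - p["feat_mu"]) / p["feat_sd"]
        if "enc1_W" in p:
            code = nn.sigmoid(
                nn.sigmoid(Xz @ p["enc1_W"] + p["enc1_b"]) @ p["enc2_W"] + p["enc2_b"]
            )
        else:
            code = Xz
        subjects = (
            np.zeros(X.shape[0], dtype=int) if subjects is None else np.asarray(subjects)
        )
        out = np.empty(X.shape[0])
        for s in dict.fromkeys(subjects.tolist()):
            idx = np.flatnonzero(subjects == s)
            H_all, _ = nn.lstm_forward(
                code[idx][None, :, :], p["lstm_Wx"], p["lstm_Wh"], p["lstm_b"]
            )
            out[idx] = (H_all[0] @ p["out_W"]).ravel() + p["out_b"]
        return out * p["label_sd"][0] + p["label_mu"][0]
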