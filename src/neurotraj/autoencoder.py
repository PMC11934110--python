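"""Sequence-to-sequence LSTM autoencoder for neural/behavioral time series.

The encoder is a stack of LSTM layers consuming one block of one modality
(``x`` of shape tau x input_dim) and producing a latent trajectory
``h_1..h_tau`` (tau x latent_dim); the recurrence is

    h_t = ENC(x_{t-1}, h_{t-1}),   t = 1..tau,   x_0 = 0,

so ``h_t`` depends only on the strict past of the input.  The final latent
embedding ``h_tau`` initializes the hidden and cell states of every decoder
layer; the decoder emits the output modality autoregressively,

    y_t = DEC(y_{t-1}, h_tau),     t = 1..tau',   y_0 = 0,

with teacher forcing (ground-truth ``y*_{t-1}`` fed back) during training and
its own previous output at inference.  When input and output modalities
coincide the model is a reconstruction autoencoder; otherwise it learns a
cross-modal translation (e.g. EEG -> fNIRS) and its latents form a joint
representation of the modality pair.

Training minimizes the RMSE of the decoded sequence with Adam plus l2
regularization; the learning rate and weight decay are grid-searched on a
held-out block split.  Everything runs on numpy with explicit
backpropagation through time; gradients are verified against finite
differences in the test suite, and all computation is in float64, so
identical seeds give bit-identical runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data_model import Modality, ModalityBlock, SessionRecord

__all__ = [
    "EncoderDecoderConfig",
    "LatentTrajectory",
    "Seq2SeqModel",
    "train_autoencoder",
    "grid_search_autoencoder",
    "encode",
    "decode",
    "extract_trajectories",
    "save_model",
    "load_model",
]


@dataclass
class EncoderDecoderConfig:
    input_modality: str = "eeg"
    output_modality: str = "eeg"
    input_dim: int = 32
    output_dim: int = 32
    tau_in: int = 7680
    tau_out: int = 7680
    n_layers_enc: int = 3
    n_layers_dec: int = 3
    latent_dim: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_dim", "output_dim", "tau_in", "tau_out",
                     "n_layers_enc", "n_layers_dec", "latent_dim",
                     "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")

    @property
    def is_unimodal(self) -> bool:
        return self.input_modality == self.output_modality

    @property
    def pair_name(self) -> str:
        if self.is_unimodal:
            return self.input_modality
        return f"{self.input_modality}->{self.output_modality}"


@dataclass
class LatentTrajectory:
    """Encoder hidden-state sequence h_1..h_tau with provenance."""

    states: np.ndarray  # tau x latent_dim
    subject_id: str = "unknown"
    block_index: int = -1
    modality_pair: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.float64)
        if self.states.ndim != 2:
            raise ValueError("latent states must be tau x latent_dim")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("latent states contain non-finite values")

    @property
    def final(self) -> np.ndarray:
        """Final latent embedding h_tau (last row of states)."""
        return self.states[-1]

    @property
    def tau(self) -> int:
        return self.states.shape[0]


# ---------------------------------------------------------------------------
# LSTM layer with explicit BPTT
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMLayer:
    """Single LSTM layer. Gate order in the stacked weight matrices: i, f, g, o."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.W = rng.uniform(-k, k, (in_dim, 4 * hidden))
        self.U = rng.uniform(-k, k, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden
        self.in_dim = in_dim

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b}

    def step(self, x, h, c):
        """One timestep; returns (h_new, c_new, cache)."""
        H = self.hidden
        a = x @ self.W + h @ self.U + self.b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        return h_new, c_new, (x, h, c, i, f, g, o, tanh_c)

    def forward(self, X, h0=None, c0=None):
        """Full sequence. X: (T, B, in_dim). Returns (H_seq, caches, h_T, c_T)."""
        T, B, _ = X.shape
        h = np.zeros((B, self.hidden)) if h0 is None else h0
        c = np.zeros((B, self.hidden)) if c0 is None else c0
        H_seq = np.empty((T, B, self.hidden))
        caches = []
        for t in range(T):
            h, c, cache = self.step(X[t], h, c)
            H_seq[t] = h
            caches.append(cache)
        return H_seq, caches, h, c

    def backward(self, dH_seq, caches):
        """BPTT. dH_seq: (T, B, hidden) upstream grad on each h_t.

        Returns (dX, grads, dh0, dc0)."""
        T, B, H = dH_seq.shape
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.empty((T, B, self.in_dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            dh = dH_seq[t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x.T @ da
            dU += h_prev.T @ da
            db += da.sum(axis=0)
            dX[t] = da @ self.W.T
            dh_next = da @ self.U.T
            dc_next = dc * f
        return dX, {"W": dW, "U": dU, "b": db}, dh_next, dc_next


class Seq2SeqModel:
    """Stacked-LSTM encoder/decoder with a linear output projection."""

    def __init__(self, config: EncoderDecoderConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.latent_dim
        self.enc_layers = [
            _LSTMLayer(config.input_dim if l == 0 else H, H, rng)
            for l in range(config.n_layers_enc)
        ]
        self.dec_layers = [
            _LSTMLayer(config.output_dim if l == 0 else H, H, rng)
            for l in range(config.n_layers_dec)
        ]
        k = 1.0 / np.sqrt(H)
        self.W_out = rng.uniform(-k, k, (H, config.output_dim))
        self.b_out = np.zeros(config.output_dim)

    # -- parameter bookkeeping ------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.enc_layers):
            for k, v in layer.params().items():
                out[f"enc{i}.{k}"] = v
        for i, layer in enumerate(self.dec_layers):
            for k, v in layer.params().items():
                out[f"dec{i}.{k}"] = v
        out["W_out"] = self.W_out
        out["b_out"] = self.b_out
        return out

    def set_param(self, name: str, value: np.ndarray) -> None:
        if name == "W_out":
            self.W_out = value
        elif name == "b_out":
            self.b_out = value
        else:
            head, key = name.split(".")
            layers = self.enc_layers if head.startswith("enc") else self.dec_layers
            setattr(layers[int(head[3:])], key, value)

    # -- forward --------------------------------------------------------------
    def _shift(self, X: np.ndarray) -> np.ndarray:
        """Lag a (T, B, D) sequence by one step, inserting zeros at t=0."""
        Xs = np.zeros_like(X)
        Xs[1:] = X[:-1]
        return Xs

    def encode_batch(self, X: np.ndarray, keep_cache: bool = False):
        """X: (B, T, input_dim) -> latent states (B, T, latent_dim)."""
        Xt = self._shift(np.transpose(X, (1, 0, 2)))  # h_t sees x_{t-1}
        caches_all = []
        seq = Xt
        for layer in self.enc_layers:
            seq, caches, _, _ = layer.forward(seq)
            caches_all.append(caches)
        states = np.transpose(seq, (1, 0, 2))
        return (states, caches_all) if keep_cache else states

    def decode_teacher(self, h_tau: np.ndarray, teacher: np.ndarray,
                       keep_cache: bool = False):
        """Teacher-forced decode. h_tau: (B, H); teacher: (B, T', out_dim)."""
        if teacher.shape[2] != self.config.output_dim:
            raise ValueError("teacher channel count does not match output_dim")
        Yin = self._shift(np.transpose(teacher, (1, 0, 2)))
        seq = Yin
        caches_all = []
        for layer in self.dec_layers:
            seq, caches, _, _ = layer.forward(seq, h0=h_tau.copy(), c0=h_tau.copy())
            caches_all.append(caches)
        Y = seq @ self.W_out + self.b_out
        Y = np.transpose(Y, (1, 0, 2))
        return (Y, seq, caches_all) if keep_cache else Y

    def decode_free(self, h_tau: np.ndarray, tau_out: int | None = None) -> np.ndarray:
        """Autoregressive decode (inference): feed back own outputs. (B, T', D)."""
        tau_out = tau_out or self.config.tau_out
        B = h_tau.shape[0]
        hs = [h_tau.copy() for _ in self.dec_layers]
        cs = [h_tau.copy() for _ in self.dec_layers]
        y_prev = np.zeros((B, self.config.output_dim))
        out = np.empty((B, tau_out, self.config.output_dim))
        for t in range(tau_out):
            inp = y_prev
            for l, layer in enumerate(self.dec_layers):
                hs[l], cs[l], _ = layer.step(inp, hs[l], cs[l])
                inp = hs[l]
            y_prev = hs[-1] @ self.W_out + self.b_out
            out[:, t] = y_prev
        return out

    # -- loss and gradients ---------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, Y_target: np.ndarray):
        """RMSE loss over a batch and gradients for every parameter.

        X: (B, T, in_dim); Y_target: (B, T', out_dim).
        """
        B = X.shape[0]
        states, enc_caches = self.encode_batch(X, keep_cache=True)
        h_tau = states[:, -1, :]
        Y_pred, dec_seq, dec_caches = self.decode_teacher(
            h_tau, Y_target, keep_cache=True
        )
        resid = Y_pred - Y_target
        mse = float(np.mean(resid**2))
        rmse = float(np.sqrt(mse))
        n = resid.size
        if rmse == 0.0:
            dY = np.zeros_like(resid)
        else:
            dY = resid / (n * rmse)

        grads = {k: np.zeros_like(v) for k, v in self.named_params().items()}
        dYt = np.transpose(dY, (1, 0, 2))  # (T', B, D)
        grads["W_out"] = np.einsum("tbh,tbd->hd", dec_seq, dYt)
        grads["b_out"] = dYt.sum(axis=(0, 1))
        dSeq = dYt @ self.W_out.T

        dh_tau = np.zeros_like(h_tau)
        for l in range(len(self.dec_layers) - 1, -1, -1):
            dSeq, g, dh0, dc0 = self.dec_layers[l].backward(dSeq, dec_caches[l])
            for k, v in g.items():
                grads[f"dec{l}.{k}"] = v
            dh_tau += dh0 + dc0  # both states were initialized from h_tau
        # dSeq now holds the grad w.r.t. the (shifted) decoder input — discarded,
        # since teacher forcing detaches it from the model.

        T = X.shape[1]
        dEnc_top = np.zeros((T, B, self.config.latent_dim))
        dEnc_top[-1] = dh_tau
        dcur = dEnc_top
        for l in range(len(self.enc_layers) - 1, -1, -1):
            dcur, g, _, _ = self.enc_layers[l].backward(dcur, enc_caches[l])
            for k, v in g.items():
                grads[f"enc{l}.{k}"] = v
        return rmse, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            if self.wd and not k.endswith("b") and not k.endswith("b_out"):
                g = g + self.wd * p  # l2 on weight matrices, not biases
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_autoencoder(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: EncoderDecoderConfig,
    verbose: bool = False,
) -> tuple[Seq2SeqModel, list[float]]:
    """Train a seq2seq model on (input, target) block pairs.

    Each pair is (tau x input_dim, tau' x output_dim); for unimodal training
    the target is the input itself.  Returns the model and the per-epoch
    mean training RMSE.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    config.validate()
    model = Seq2SeqModel(config)
    params = model.named_params()
    opt = _Adam(params, config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    X_all = np.stack([np.asarray(x, dtype=np.float64) for x, _ in pairs])
    Y_all = np.stack([np.asarray(y, dtype=np.float64) for _, y in pairs])
    n = len(pairs)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(X_all[idx], Y_all[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check input scaling"
                )
            opt.step(params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: RMSE {history[-1]:.5f}")
    return model, history


def evaluate_rmse(
    model: Seq2SeqModel,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    teacher: bool = True,
) -> float:
    """RMSE of a model on held-out pairs.

    With ``teacher`` (training-mode conditioning) the decoder sees the
    ground-truth previous sample at each step; without it the decoder runs
    free from ``h_tau`` alone, which isolates how much of the output the
    latent actually carries.
    """
    X = np.stack([np.asarray(x, dtype=np.float64) for x, _ in pairs])
    Y = np.stack([np.asarray(y, dtype=np.float64) for _, y in pairs])
    states = model.encode_batch(X)
    if teacher:
        pred = model.decode_teacher(states[:, -1, :], Y)
    else:
        pred = model.decode_free(states[:, -1, :], Y.shape[1])
    return float(np.sqrt(np.mean((pred - Y) ** 2)))


def grid_search_autoencoder(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: EncoderDecoderConfig,
    learning_rates: Sequence[float] = (1e-2, 1e-3, 1e-4),
    weight_decays: Sequence[float] = (0.0, 1e-5, 1e-4),
    val_fraction: float = 0.25,
) -> tuple[EncoderDecoderConfig, Seq2SeqModel, dict[tuple[float, float], float]]:
    """Grid-search (learning rate, weight decay) on a held-out block split.

    Blocks (not subjects) are split within the training set; the winning
    configuration is the pair minimizing held-out teacher-forced RMSE.
    """
    if len(pairs) < 2:
        raise ValueError("grid search needs at least 2 training pairs")
    rng = np.random.default_rng(config.seed + 2)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_pairs = [pairs[i] for i in train_idx]
    val_pairs = [pairs[i] for i in val_idx]
    table: dict[tuple[float, float], float] = {}
    best: tuple[float, float] | None = None
    best_model = None
    for lr in learning_rates:
        for wd in weight_decays:
            cfg = EncoderDecoderConfig(**{**asdict(config),
                                          "learning_rate": lr,
                                          "weight_decay": wd})
            try:
                model, _ = train_autoencoder(train_pairs, cfg)
                score = evaluate_rmse(model, val_pairs)
            except FloatingPointError:
                score = np.inf
                model = None
            table[(lr, wd)] = score
            if best is None or score < table[best]:
                best, best_model = (lr, wd), model
    assert best is not None and best_model is not None
    best_cfg = EncoderDecoderConfig(**{**asdict(config),
                                       "learning_rate": best[0],
                                       "weight_decay": best[1]})
    return best_cfg, best_model, table


# ---------------------------------------------------------------------------
# Public single-block operations
# ---------------------------------------------------------------------------

def encode(x: np.ndarray, model: Seq2SeqModel, subject_id: str = "unknown",
           block_index: int = -1) -> LatentTrajectory:
    """Encode one block (tau x input_dim) into its latent trajectory."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != model.config.input_dim:
        raise ValueError(
            f"input shape {x.shape} does not match input_dim {model.config.input_dim}"
        )
    states = model.encode_batch(x[None])[0]
    return LatentTrajectory(
        states=states,
        subject_id=subject_id,
        block_index=block_index,
        modality_pair=model.config.pair_name,
    )


def decode(h_tau: np.ndarray, model: Seq2SeqModel,
           teacher: np.ndarray | None = None,
           tau_out: int | None = None) -> np.ndarray:
    """Decode a final embedding into an output-modality sequence.

    With ``teacher`` given (training mode), step t is conditioned on the
    ground-truth value at t-1; without it the decoder feeds back its own
    previous output.
    """
    h_tau = np.asarray(h_tau, dtype=np.float64)
    if h_tau.shape != (model.config.latent_dim,):
        raise ValueError("h_tau length must equal latent_dim")
    if teacher is not None:
        teacher = np.asarray(teacher, dtype=np.float64)
        return model.decode_teacher(h_tau[None], teacher[None])[0]
    return model.decode_free(h_tau[None], tau_out)[0]


def extract_trajectories(
    sessions: Sequence[SessionRecord],
    model: Seq2SeqModel,
    transform: Callable[[ModalityBlock], np.ndarray] | None = None,
) -> list[LatentTrajectory]:
    """Encode every block of the model's input modality, one trajectory each.

    ``transform`` maps a block to the tau x input_dim matrix fed to the
    encoder (band filtering, standardization, downsampling); default uses
    the raw block data.
    """
    modality = Modality(model.config.input_modality)
    out: list[LatentTrajectory] = []
    for session in sessions:
        if modality not in session.blocks:
            raise ValueError(
                f"session {session.subject_id} has no {modality.value} blocks"
            )
        for blk in session.blocks[modality]:
            x = transform(blk) if transform is not None else blk.data
            out.append(encode(x, model, blk.subject_id, blk.block_index))
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: Seq2SeqModel, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.named_params())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), indent=2))


def load_model(path: str | Path) -> Seq2SeqModel:
    path = Path(path)
    config = EncoderDecoderConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = Seq2SeqModel(config)
    with np.load(path.with_suffix(".npz")) as data:
        for name in model.named_params():
            model.set_param(name, data[name].copy())
    return model
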