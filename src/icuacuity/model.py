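"""Acuity sequence model: network, training, thresholds, results.

The network follows the architecture sketch: the (time, value) channels of
each triplet pass through 1-D convolutions and the variable code through a
lookup embedding (row 0, the padding code, is fixed at zero); the three are
summed with a sinusoidal positional encoding, passed through two gated
selective state-space blocks, summarized by top-k pooling (L2-norm
selection over unmasked positions), mapped by an MLP to the model width,
added to a two-layer static embedding, and read out by nine independent
sigmoid heads: the four primary acuity states (discharge, stable, unstable,
deceased), the two transitions, and the three therapy onsets (MV, VP,
CRRT).

Training minimizes the sum of per-head class-weighted binary cross
entropies, with masked labels contributing nothing; the development split
is by patient, never by window. The interface is model/results:
:class:`AcuityModel` holds data + configuration, ``fit()`` returns an
:class:`AcuityResults` carrying validation probabilities, Youden
thresholds, training curves and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._autograd import Tensor, conv1d_same, embedding
from .encoding import Vocabulary, encode_observation, scale_events, scale_static
from .nn import (
    Adam,
    Linear,
    Module,
    SSMBlock,
    pool_with_selection,
    sinusoidal_positional_encoding,
    topk_pool,
    topk_selection,
)
from .phenotyping import LABEL_NAMES, LabeledWindow
from .records import StayRecord

__all__ = [
    "ModelConfig",
    "WindowDataset",
    "build_dataset",
    "AcuityNet",
    "AcuityModel",
    "AcuityResults",
    "train_model",
    "select_thresholds",
    "split_by_stay",
    "compute_class_weights",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The published description fixes the structure (two state-space blocks,
    top-k pooling, nine heads) but not the widths; the defaults below are
    this package's choices, sized so the network lands near one million
    parameters with most of the mass in the per-window MLPs.
    """

    L: int = 256
    D: int = 64
    n_blocks: int = 2
    state_dim: int = 16
    k: int = 8
    f: int = 6
    n_heads: int = 9
    conv_kernel: int = 5
    expand: int = 1
    dt_rank: int = 32
    ssm_conv_kernel: int = 4
    mlp_hidden: int = 4096
    static_hidden: int = 1024
    seed: int = 0
    lr: float = 1e-3
    epochs: int = 5
    batch_size: int = 32
    class_weight_cap: float = 100.0
    scan_chunk: int = 8

    def __post_init__(self) -> None:
        if self.k > self.L:
            raise ValueError("k must not exceed L")
        if min(self.D, self.state_dim, self.n_blocks) < 1:
            raise ValueError("D, state_dim and n_blocks must be >= 1")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd")


@dataclass
class WindowDataset:
    """Encoded labeled windows as dense arrays (N windows)."""

    times: np.ndarray  # (N, L) scaled hours
    values: np.ndarray  # (N, L) scaled values
    codes: np.ndarray  # (N, L) int codes, 0 = padding
    mask: np.ndarray  # (N, L) 1 = real event
    static: np.ndarray  # (N, f)
    labels: np.ndarray  # (N, 9) float 0/1
    label_mask: np.ndarray  # (N, 9) 1 = label defined
    stay_ids: np.ndarray  # (N,) str
    window_index: np.ndarray  # (N,) int
    pred_start: np.ndarray  # (N,) hours
    states: np.ndarray  # (N,) str

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def n_static(self) -> int:
        return self.static.shape[1]

    def subset(self, idx) -> "WindowDataset":
        return WindowDataset(
            self.times[idx],
            self.values[idx],
            self.codes[idx],
            self.mask[idx],
            self.static[idx],
            self.labels[idx],
            self.label_mask[idx],
            self.stay_ids[idx],
            self.window_index[idx],
            self.pred_start[idx],
            self.states[idx],
        )


def build_dataset(
    stays: list[StayRecord],
    windows: list[LabeledWindow],
    vocab: Vocabulary,
    L: int = 256,
) -> WindowDataset:
    """Encode labeled windows into a dense dataset.

    Events are outlier-filtered/scaled per the vocabulary before encoding;
    statics are min-max scaled with development ranges.
    """
    from .encoding import filter_outliers

    by_stay = {s.stay_id: s for s in stays}
    scaled_events: dict[str, list] = {}
    statics: dict[str, np.ndarray] = {}
    for sid, stay in by_stay.items():
        kept, _ = filter_outliers(stay.events, vocab)
        scaled_events[sid] = scale_events(kept, vocab)
        statics[sid] = scale_static(stay.static, vocab)
    N = len(windows)
    f = len(vocab.static_ranges)
    times = np.zeros((N, L))
    values = np.zeros((N, L))
    codes = np.zeros((N, L), dtype=np.int64)
    mask = np.zeros((N, L), dtype=np.int64)
    static = np.zeros((N, f))
    labels = np.zeros((N, len(LABEL_NAMES)))
    label_mask = np.ones((N, len(LABEL_NAMES)))
    stay_ids = np.empty(N, dtype=object)
    window_index = np.zeros(N, dtype=int)
    pred_start = np.zeros(N)
    states = np.empty(N, dtype=object)
    for i, w in enumerate(windows):
        evs = [
            e for e in scaled_events[w.stay_id] if w.obs_start <= e.time_hours < w.obs_end
        ]
        enc = encode_observation(evs, vocab, L)
        times[i], values[i], codes[i], mask[i] = enc.times, enc.values, enc.codes, enc.mask
        static[i] = statics[w.stay_id]
        labels[i] = [w.labels[name] for name in LABEL_NAMES]
        label_mask[i] = [w.mask[name] for name in LABEL_NAMES]
        stay_ids[i] = w.stay_id
        window_index[i] = w.window_index
        pred_start[i] = w.pred_start
        states[i] = w.state
    return WindowDataset(
        times, values, codes, mask, static, labels, label_mask,
        stay_ids.astype(str), window_index, pred_start, states.astype(str),
    )


class AcuityNet(Module):
    """The nine-head selective state-space network."""

    def __init__(self, config: ModelConfig, vocab_size: int):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = config.D
        K = config.conv_kernel
        bound = 1.0 / np.sqrt(K)
        self.time_conv_w = Tensor(rng.uniform(-bound, bound, (K, 1, D)), requires_grad=True)
        self.time_conv_b = Tensor(np.zeros(D), requires_grad=True)
        self.value_conv_w = Tensor(rng.uniform(-bound, bound, (K, 1, D)), requires_grad=True)
        self.value_conv_b = Tensor(np.zeros(D), requires_grad=True)
        emb = rng.standard_normal((vocab_size + 1, D)) * 0.1
        emb[0] = 0.0  # padding row stays zero
        self.code_embedding = Tensor(emb, requires_grad=True)
        self.blocks = [
            SSMBlock(
                D,
                config.expand * D,
                config.state_dim,
                config.dt_rank,
                config.ssm_conv_kernel,
                rng,
                scan_chunk=config.scan_chunk,
            )
            for _ in range(config.n_blocks)
        ]
        self.trunk1 = Linear(D, config.mlp_hidden, rng)
        self.trunk2 = Linear(config.mlp_hidden, D, rng)
        self.static1 = Linear(config.f, config.static_hidden, rng)
        self.static2 = Linear(config.static_hidden, D, rng)
        # start the static pathway near zero: the temporal pathway should
        # dominate until training finds genuinely predictive statics, and
        # an untrained wide static branch would otherwise inject large
        # random per-stay offsets (and spurious attribution mass)
        self.static1.weight.data *= 0.1
        self.static2.weight.data *= 0.1
        self.heads = [Linear(D, 1, rng) for _ in range(config.n_heads)]

    # ------------------------------------------------------------ pipeline
    def embed_triplets(self, times, values, codes) -> Tensor:
        """conv(time) + conv(value) + lookup(code) + positional encoding."""
        if np.any(codes > self.code_embedding.shape[0] - 1) or np.any(codes < 0):
            raise ValueError("variable code outside the fitted vocabulary")
        N, L = times.shape
        # causal convolutions: an event's embedding may depend on earlier
        # events but never on later ones (or on tail padding)
        t_emb = conv1d_same(
            Tensor(times[:, :, None]), self.time_conv_w, self.time_conv_b, causal=True
        )
        v_emb = conv1d_same(
            Tensor(values[:, :, None]), self.value_conv_w, self.value_conv_b, causal=True
        )
        c_emb = embedding(self.code_embedding, codes)
        pe = sinusoidal_positional_encoding(L, self.config.D)
        return t_emb + v_emb + c_emb + pe


    def backbone(self, emb: Tensor, *, sequential_scan: bool = False) -> Tensor:
        out = emb
        for block in self.blocks:
            out = block(out, sequential_scan=sequential_scan)
        return out

    def _stack_heads(self, fused: Tensor) -> Tensor:
        """Differentiable column-stack of the nine (N, 1) head outputs."""
        n_heads = len(self.heads)
        logits = None
        for j, head in enumerate(self.heads):
            sel = np.zeros((1, n_heads))
            sel[0, j] = 1.0
            term = head(fused) @ Tensor(sel)
            logits = term if logits is None else logits + term
        return logits

    def pool_selection_for(self, emb_data: np.ndarray, mask: np.ndarray):
        """Top-k selection computed at a fixed embedding.

        Used to freeze the pooling selection along an attribution path:
        top-k by norm is discontinuous in its input, so path methods hold
        the selection at the actual input's choice.
        """
        seq = self.backbone(Tensor(emb_data))
        return topk_selection(seq.data, mask, self.config.k)

    def head_logits_from_embedding(
        self,
        emb: Tensor,
        mask: np.ndarray,
        static: Tensor,
        *,
        sequential_scan: bool = False,
        pool_selection=None,
    ) -> Tensor:
        """Logits (N, 9) from a fused temporal embedding; the entry point
        for integrated-gradients attribution."""
        seq = self.backbone(emb, sequential_scan=sequential_scan)
        if pool_selection is None:
            pooled = topk_pool(seq, mask, self.config.k)
        else:
            pooled = pool_with_selection(seq, *pool_selection)
        temporal = self.trunk2(self.trunk1(pooled).silu())
        static_emb = self.static2(self.static1(static).silu())
        return self._stack_heads(temporal + static_emb)

    def forward(
        self, batch: WindowDataset, idx=None, *, sequential_scan: bool = False
    ) -> Tensor:
        """Head logits for a batch (padded tail trimmed per batch)."""
        if idx is None:
            idx = np.arange(len(batch))
        if batch.static.shape[1] != self.config.f:
            raise ValueError(
                f"static dimension {batch.static.shape[1]} != configured f={self.config.f}"
            )
        # round the trimmed length up to a multiple of 8: few distinct batch
        # shapes means the allocator can recycle identical buffers
        Lb = max(1, int(batch.mask[idx].sum(axis=1).max()))
        Lb = min(int(np.ceil(Lb / 8)) * 8, batch.mask.shape[1])
        times = batch.times[idx][:, :Lb]
        values = batch.values[idx][:, :Lb]
        codes = batch.codes[idx][:, :Lb]
        mask = batch.mask[idx][:, :Lb]
        emb = self.embed_triplets(times, values, codes)
        return self.head_logits_from_embedding(
            emb, mask, Tensor(batch.static[idx]), sequential_scan=sequential_scan
        )

    def predict_proba(self, dataset: WindowDataset, batch_size: int = 256) -> np.ndarray:
        """Per-window head probabilities, (N, 9), deterministic."""
        out = np.zeros((len(dataset), self.config.n_heads))
        for start in range(0, len(dataset), batch_size):
            idx = np.arange(start, min(start + batch_size, len(dataset)))
            logits = self.forward(dataset, idx)
            out[idx] = 1.0 / (1.0 + np.exp(-logits.data))
        return out


def compute_class_weights(
    labels: np.ndarray, label_mask: np.ndarray, cap: float = 100.0
) -> np.ndarray:
    """Per-head positive-class weights N_neg / N_pos on defined labels,
    capped; heads without positives get weight nan (frozen)."""
    n_heads = labels.shape[1]
    weights = np.full(n_heads, np.nan)
    for j in range(n_heads):
        m = label_mask[:, j] > 0
        pos = float(labels[m, j].sum())
        neg = float(m.sum() - pos)
        if pos > 0:
            weights[j] = min(neg / pos, cap) if neg > 0 else 1.0
    return weights


def split_by_stay(
    dataset: WindowDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level split: all of a stay's windows land on one side."""
    stays = np.unique(dataset.stay_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(stays)
    n_train = int(round(train_fraction * len(stays)))
    train_set = set(stays[:n_train])
    is_train = np.array([sid in train_set for sid in dataset.stay_ids])
    return np.where(is_train)[0], np.where(~is_train)[0]


def select_thresholds(probs: np.ndarray, labels: np.ndarray) -> float:
    """Youden-optimal threshold for one head.

    Maximizes J = sensitivity + specificity - 1 over all observed
    probability values (decision rule: positive iff p >= threshold), ties
    broken toward the lower threshold.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("threshold selection needs both classes present")
    candidates = np.unique(probs)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_thr, best_j = None, -np.inf
    for thr in candidates:  # ascending; strict > keeps the lowest tie
        pred = probs >= thr
        tp = np.sum(pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return best_thr


@dataclass
class AcuityResults:
    """Fitted-model results: probabilities, thresholds, curves, summary."""

    net: AcuityNet
    config: ModelConfig
    class_weights: np.ndarray
    thresholds: dict[str, float]
    val_probs: np.ndarray
    val_dataset: WindowDataset
    history: pd.DataFrame
    best_epoch: int

    def predict_proba(self, dataset: WindowDataset) -> np.ndarray:
        return self.net.predict_proba(dataset)

    def predict(self, dataset: WindowDataset) -> pd.DataFrame:
        """Per-window probabilities, thresholded binaries and decided state."""
        from .decision import decide_acuity_frame

        probs = self.predict_proba(dataset)
        frame = pd.DataFrame(probs, columns=[f"p_{n}" for n in LABEL_NAMES])
        frame.insert(0, "stay_id", dataset.stay_ids)
        frame.insert(1, "window_index", dataset.window_index)
        for j, name in enumerate(LABEL_NAMES):
            thr = self.thresholds.get(name)
            frame[f"b_{name}"] = (
                (probs[:, j] >= thr).astype(int) if thr is not None else 0
            )
        frame["state"] = decide_acuity_frame(frame)
        return frame

    def summary(self) -> str:
        from sklearn.metrics import average_precision_score, roc_auc_score

        lines = [
            "Acuity sequence model results",
            f"  parameters: {self.net.n_parameters():,}",
            f"  best epoch: {self.best_epoch}",
            f"  {'head':<20}{'weight':>8}{'thr':>8}{'AUROC':>8}{'AUPRC':>8}",
        ]
        for j, name in enumerate(LABEL_NAMES):
            m = self.val_dataset.label_mask[:, j] > 0
            y = self.val_dataset.labels[m, j]
            p = self.val_probs[m, j]
            if 0 < y.sum() < len(y):
                auroc = roc_auc_score(y, p)
                auprc = average_precision_score(y, p)
                auroc_s, auprc_s = f"{auroc:8.3f}", f"{auprc:8.3f}"
            else:
                auroc_s = auprc_s = "      --"
            w = self.class_weights[j]
            thr = self.thresholds.get(name)
            lines.append(
                f"  {name:<20}{w if np.isfinite(w) else float('nan'):>8.2f}"
                f"{(thr if thr is not None else float('nan')):>8.3f}{auroc_s}{auprc_s}"
            )
        return "\n".join(lines)


class AcuityModel:
    """Model object: encoded windows in, :class:`AcuityResults` out.

    ``fit`` performs the seeded 80/20 patient-level split (unless an
    explicit validation set is given), class-weighted training, and Youden
    threshold selection on the validation head probabilities.
    """

    def __init__(
        self,
        dataset: WindowDataset,
        config: ModelConfig | None = None,
        val_dataset: WindowDataset | None = None,
        vocab_size: int | None = None,
    ):
        self.config = config or ModelConfig()
        if self.config.f != dataset.n_static:
            self.config = replace(self.config, f=dataset.n_static)
        if val_dataset is None:
            tr, va = split_by_stay(dataset, 0.8, self.config.seed)
            self.train_dataset = dataset.subset(tr)
            self.val_dataset = dataset.subset(va)
        else:
            self.train_dataset = dataset
            self.val_dataset = val_dataset
        if vocab_size is None:
            vocab_size = int(
                max(self.train_dataset.codes.max(), self.val_dataset.codes.max())
            )
        self.vocab_size = vocab_size

    def fit(self, verbose: bool = False) -> AcuityResults:
        cfg = self.config
        net = AcuityNet(cfg, self.vocab_size)
        weights = compute_class_weights(
            self.train_dataset.labels, self.train_dataset.label_mask, cfg.class_weight_cap
        )
        frozen = ~np.isfinite(weights)
        if frozen.any():
            names = [LABEL_NAMES[j] for j in np.where(frozen)[0]]
            warnings.warn(f"heads frozen (no positive training labels): {names}")
        params = net.parameters()
        opt = Adam(params, lr=cfg.lr)
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(self.train_dataset)
        history = []
        best_state, best_val, best_epoch = None, np.inf, -1
        event_counts = self.train_dataset.mask.sum(axis=1)
        for epoch in range(cfg.epochs):
            # bucket windows of similar event count into the same batch so
            # padded compute follows the mean length, not the max; batch
            # order and within-length ties are shuffled each epoch
            order = np.lexsort((rng.random(n), event_counts))
            batches = [
                order[s : s + cfg.batch_size] for s in range(0, n, cfg.batch_size)
            ]
            batches = [batches[i] for i in rng.permutation(len(batches))]
            total_loss, n_batches = 0.0, 0
            for idx in batches:
                loss = self._loss(net, self.train_dataset, idx, weights, frozen)
                net.zero_grad()
                loss.backward()
                opt.step()
                net.code_embedding.data[0] = 0.0  # keep padding row frozen
                total_loss += float(loss.data)
                n_batches += 1
            val_loss = self._eval_loss(net, self.val_dataset, weights, frozen, cfg.batch_size)
            history.append(
                {"epoch": epoch, "train_loss": total_loss / max(n_batches, 1), "val_loss": val_loss}
            )
            if verbose:
                print(f"epoch {epoch}: train {history[-1]['train_loss']:.4f} val {val_loss:.4f}")
            if val_loss < best_val:
                best_val, best_epoch = val_loss, epoch
                best_state = net.state_dict()
        if best_state is not None:
            net.load_state_dict(best_state)
        val_probs = net.predict_proba(self.val_dataset)
        thresholds: dict[str, float] = {}
        for j, name in enumerate(LABEL_NAMES):
            m = self.val_dataset.label_mask[:, j] > 0
            y = self.val_dataset.labels[m, j]
            if 0 < y.sum() < len(y):
                thresholds[name] = select_thresholds(val_probs[m, j], y)
        return AcuityResults(
            net=net,
            config=cfg,
            class_weights=weights,
            thresholds=thresholds,
            val_probs=val_probs,
            val_dataset=self.val_dataset,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
        )

    # ------------------------------------------------------------- internals
    @staticmethod
    def _loss(net, dataset, idx, weights, frozen) -> Tensor:
        logits = net.forward(dataset, idx)
        y = dataset.labels[idx]
        m = dataset.label_mask[idx].astype(float)
        m[:, frozen] = 0.0
        w = np.where(np.isfinite(weights), weights, 1.0)
        elem_w = (y * (w - 1.0) + 1.0) * m
        denom = np.maximum(m.sum(axis=0), 1.0)
        # weighted BCE with logits: softplus(z) - y z, numerically stable
        elem = logits.softplus() - logits * y
        per_head = (elem * (elem_w / denom)).sum(axis=0)
        return per_head.sum()

    @classmethod
    def _eval_loss(cls, net, dataset, weights, frozen, batch_size) -> float:
        total = 0.0
        n = len(dataset)
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            loss = cls._loss(net, dataset, idx, weights, frozen)
            total += float(loss.data) * len(idx)
        return total / max(n, 1)


def permute_labels(
    dataset: WindowDataset, seed: int = 0, within_stays: bool = False
) -> WindowDataset:
    """Null-experiment copy of a dataset with permuted labels.

    The default global permutation shuffles (labels, label_mask) rows
    across all windows, destroying every feature-label association while
    preserving marginal label rates — the appropriate chance-level null.
    ``within_stays=True`` instead shuffles rows only inside each stay;
    note that this preserves per-stay outcome propensity, which remains
    genuinely predictable, so it is not a chance-level null.
    """
    rng = np.random.default_rng(seed)
    out = dataset.subset(np.arange(len(dataset)))
    if within_stays:
        for sid in np.unique(out.stay_ids):
            rows = np.where(out.stay_ids == sid)[0]
            perm = rng.permutation(rows)
            out.labels[rows] = dataset.labels[perm]
            out.label_mask[rows] = dataset.label_mask[perm]
    else:
        perm = rng.permutation(len(dataset))
        out.labels = dataset.labels[perm].copy()
        out.label_mask = dataset.label_mask[perm].copy()
    return out


def train_model(
    train: WindowDataset,
    val: WindowDataset | None,
    config: ModelConfig | None = None,
) -> AcuityResults:
    """Functional wrapper over :class:`AcuityModel`."""
    if val is None:
        return AcuityModel(train, config).fit()
    return AcuityModel(train, config, val_dataset=val).fit()
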