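"""Three-stream CNN–LSTM fusion classifier and its baselines.

The classifier fuses three input streams per MVC trial:

* **stream A** — the raw multichannel window (sEMG + strain), passed
  through two Conv1D+ReLU+MaxPool blocks whose feature maps feed an LSTM
  (64 hidden units by default) that models temporal dependencies;
* **stream B** — the nine engineered sEMG features (MVC-normalized),
  lifted to ``mapping_channels`` by a length-1 convolution (an affine map
  applied per feature);
* **stream C** — subject demographics (sex, age, grip strength), lifted
  the same way.

The three representations are concatenated, passed through dropout and a
dense ReLU layer, and classified by a softmax over {healthy, sarcopenia}.
Baselines: SVM and random forest on the feature + demographics table, and
raw-window-only CNN and LSTM networks sharing the same layer library.

Modality configurations restrict the raw stream to sEMG channels only,
strain channels only, or both; the single-modality configurations also
drop the auxiliary streams so they see *only* that signal, which is what
makes them a meaningful ablation of the fused model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from . import nn
from .cohort import CHANNEL_NAMES, Recording, SubjectProfile
from .features import FEATURE_NAMES, mvc_normalize, session_feature_table

__all__ = [
    "FusionModelConfig",
    "Dataset",
    "FusionNet",
    "TrainedModel",
    "build_dataset",
    "build_model",
    "train",
    "predict_proba",
    "train_baseline",
    "MODALITY_CHANNELS",
]

MODALITY_CHANNELS = {
    "both": ("br_semg", "br_strain", "fds_semg", "fds_strain"),
    "semg": ("br_semg", "fds_semg"),
    "strain": ("br_strain", "fds_strain"),
}

CLASS_NAMES = ("healthy", "sarcopenia")


@dataclass(frozen=True)
class FusionModelConfig:
    """Hyperparameters of the fusion network.

    The architecture facts fixed by design are the two conv blocks, ReLU
    activations and the 64-unit LSTM; the remaining values (filter
    counts, kernel and pool sizes, dropout, optimizer settings) are
    package defaults chosen for stable single-CPU training.
    """

    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 7, 4), (32, 7, 4))
    lstm_hidden: int = 64
    feature_stream_dim: int = 9
    demo_stream_dim: int = 3
    mapping_channels: int = 4
    dense_hidden: int = 32
    dropout: float = 0.3
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    downsample: int = 4          # decimation factor applied to raw windows
    modality: str = "both"       # "both" | "semg" | "strain"
    use_features: bool = True
    use_demo: bool = True
    arch: str = "cnn_lstm"       # "cnn_lstm" | "cnn" | "lstm"
    lstm_input_pool: int = 16    # extra pooling for the raw-LSTM baseline

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 2:
            raise ValueError("the spatial stream uses exactly 2 conv blocks")
        if self.lstm_hidden < 1:
            raise ValueError("lstm_hidden must be >= 1")
        if self.modality not in MODALITY_CHANNELS:
            raise ValueError(f"modality must be one of {list(MODALITY_CHANNELS)}")
        if self.arch not in ("cnn_lstm", "cnn", "lstm"):
            raise ValueError(f"unknown architecture {self.arch!r}")


@dataclass
class Dataset:
    """Aligned per-trial samples for the whole cohort.

    ``raw`` is (n, 4, L) over all four channels (modality selection
    happens at train time), ``features`` (n, 9) MVC-normalized engineered
    features, ``demographics`` (n, 3) = [sex01, age, grip_kg], ``labels``
    (n,) with 0=healthy 1=sarcopenia, ``subject_ids`` (n,) strings.
    """

    raw: np.ndarray
    features: np.ndarray
    demographics: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    sampling_rate: float = 250.0

    def __len__(self) -> int:
        return self.raw.shape[0]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            raw=self.raw[idx],
            features=self.features[idx],
            demographics=self.demographics[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            channel_names=self.channel_names,
            sampling_rate=self.sampling_rate,
        )


def build_dataset(
    recordings: list[Recording],
    profiles: list[SubjectProfile],
    feature_channel: str = "br_semg",
    downsample: int = 4,
) -> Dataset:
    """Assemble the per-trial training set from a cohort.

    One sample per MVC trial: the raw 4-channel trial window (decimated
    by ``downsample`` with an anti-aliasing FIR), the trial's nine
    MVC-normalized features on ``feature_channel`` (active window
    normalized by the whole-trial reference), and the subject's
    demographics.
    """
    raw_list, feat_list, demo_list, labels, subjects = [], [], [], [], []
    for rec, prof in zip(recordings, profiles):
        table = session_feature_table(rec, channels=(feature_channel,))
        active = table[table["kind"] == "active"]
        reference = table[table["kind"] == "trial"]
        norm = mvc_normalize(active, reference_table=reference)
        norm = norm.sort_values("trial")

        demo = [1.0 if prof.sex == "male" else 0.0, prof.age, prof.grip_strength]
        label = CLASS_NAMES.index(prof.group_label)
        for trial_idx, (start, stop) in enumerate(rec.trial_boundaries):
            window = np.stack(
                [rec.channels[name][start:stop] for name in CHANNEL_NAMES]
            )
            if downsample > 1:
                window = sps.decimate(window, downsample, axis=1, ftype="fir", zero_phase=True)
            raw_list.append(window)
            row = norm[norm["trial"] == trial_idx].iloc[0]
            feat_list.append(row[list(FEATURE_NAMES)].to_numpy(dtype=float))
            demo_list.append(demo)
            labels.append(label)
            subjects.append(prof.subject_id)
    return Dataset(
        raw=np.asarray(raw_list),
        features=np.asarray(feat_list),
        demographics=np.asarray(demo_list),
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.asarray(subjects),
        sampling_rate=recordings[0].sampling_rate / downsample,
    )


class FusionNet:
    """The assembled network; holds layers and the forward/backward pass."""

    def __init__(self, config: FusionModelConfig, n_raw_channels: int, raw_len: int,
                 rng: np.random.Generator):
        self.config = config
        self.n_raw_channels = n_raw_channels
        self.raw_len = raw_len
        c = config

        (f1, k1, p1), (f2, k2, p2) = c.conv_blocks
        length = raw_len
        self.layers_a: list = []
        if c.arch in ("cnn_lstm", "cnn"):
            self.conv1 = nn.Conv1D(n_raw_channels, f1, k1, rng)
            self.pool1 = nn.MaxPool1D(p1)
            self.conv2 = nn.Conv1D(f1, f2, k2, rng)
            self.pool2 = nn.MaxPool1D(p2)
            self.relu1, self.relu2 = nn.ReLU(), nn.ReLU()
            length = (length - k1 + 1) // p1
            length = (length - k2 + 1) // p2
            self.layers_a = [
                self.conv1, self.relu1, self.pool1,
                self.conv2, self.relu2, self.pool2,
            ]
            if c.arch == "cnn_lstm":
                self.temporal = nn.LSTM(f2, c.lstm_hidden, rng)
                a_dim = c.lstm_hidden
            else:
                self.temporal = nn.GlobalAvgPool1D()
                a_dim = f2
        else:  # raw LSTM baseline: pooled raw channels straight into the LSTM
            self.prepool = nn.AvgPool1D(c.lstm_input_pool)
            self.layers_a = [self.prepool]
            self.temporal = nn.LSTM(n_raw_channels, c.lstm_hidden, rng)
            a_dim = c.lstm_hidden

        concat_dim = a_dim
        self.map_feat = self.map_demo = None
        if c.use_features:
            self.map_feat = nn.Conv1D(1, c.mapping_channels, 1, rng)
            concat_dim += c.mapping_channels * c.feature_stream_dim
        if c.use_demo:
            self.map_demo = nn.Conv1D(1, c.mapping_channels, 1, rng)
            concat_dim += c.mapping_channels * c.demo_stream_dim

        self.dropout = nn.Dropout(c.dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.fc1 = nn.Dense(concat_dim, c.dense_hidden, rng)
        self.relu_fc = nn.ReLU()
        self.fc2 = nn.Dense(c.dense_hidden, 2, rng)
        self.concat_dim = concat_dim

    def params(self) -> list[nn.Param]:
        layers = list(self.layers_a) + [self.temporal, self.fc1, self.fc2]
        if self.map_feat is not None:
            layers.append(self.map_feat)
        if self.map_demo is not None:
            layers.append(self.map_demo)
        out: list[nn.Param] = []
        for layer in layers:
            out.extend(layer.params())
        return out

    def forward(self, raw, feat, demo, train: bool = False) -> np.ndarray:
        """Logits for a batch; caches intermediates for backward."""
        h = raw
        for layer in self.layers_a:
            h = layer.forward(h)
        a = self.temporal.forward(h)

        parts = [a]
        self._splits = [a.shape[1]]
        if self.map_feat is not None:
            fb = self.map_feat.forward(feat[:, None, :])  # (B, m, 9)
            self._feat_shape = fb.shape
            parts.append(fb.reshape(fb.shape[0], -1))
            self._splits.append(parts[-1].shape[1])
        if self.map_demo is not None:
            db = self.map_demo.forward(demo[:, None, :])
            self._demo_shape = db.shape
            parts.append(db.reshape(db.shape[0], -1))
            self._splits.append(parts[-1].shape[1])

        concat = np.concatenate(parts, axis=1)
        self.embedding_ = concat  # post-concatenation activations (for t-SNE)
        h = self.dropout.forward(concat, train=train)
        h = self.relu_fc.forward(self.fc1.forward(h))
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc2.backward(dlogits)
        g = self.fc1.backward(self.relu_fc.backward(g))
        g = self.dropout.backward(g)

        offsets = np.cumsum([0] + self._splits)
        ga = g[:, offsets[0]:offsets[1]]
        pos = 1
        if self.map_feat is not None:
            gf = g[:, offsets[pos]:offsets[pos + 1]].reshape(self._feat_shape)
            self.map_feat.backward(gf)
            pos += 1
        if self.map_demo is not None:
            gd = g[:, offsets[pos]:offsets[pos + 1]].reshape(self._demo_shape)
            self.map_demo.backward(gd)

        h = self.temporal.backward(ga)
        for layer in reversed(self.layers_a):
            h = layer.backward(h)


@dataclass
class TrainedModel:
    """A trained network plus the fold-local standardization statistics."""

    net: FusionNet
    config: FusionModelConfig
    training_history: list[dict]
    raw_mean: np.ndarray
    raw_std: np.ndarray
    feat_mean: np.ndarray
    feat_std: np.ndarray
    demo_mean: np.ndarray
    demo_std: np.ndarray
    channel_idx: np.ndarray
    input_spec: dict = field(default_factory=dict)

    def weight_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.net.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()


def build_model(
    config: FusionModelConfig, n_raw_channels: int, raw_len: int
) -> FusionNet:
    """Construct an untrained network with seeded weight initialization."""
    rng = np.random.default_rng(config.seed)
    return FusionNet(config, n_raw_channels, raw_len, rng)


def _standardize(x, mean, std):
    return (x - mean) / std


def _prepare(dataset: Dataset, config: FusionModelConfig):
    idx = np.array(
        [dataset.channel_names.index(c) for c in MODALITY_CHANNELS[config.modality]]
    )
    return dataset.raw[:, idx, :], idx


def train(
    model: FusionNet | FusionModelConfig,
    dataset: Dataset,
    seed: int | None = None,
) -> TrainedModel:
    """Train the fusion network with Adam on softmax cross-entropy.

    Standardization statistics (per-channel raw mean/SD, feature and
    demographic z-scores) are computed on this training set only and
    stored with the model, so evaluation on held-out folds involves no
    leakage.  All randomness (init, shuffling, dropout) derives from the
    seed, making repeated runs bit-identical.
    """
    if isinstance(model, FusionModelConfig):
        config = model if seed is None else replace(model, seed=seed)
        raw_sel_probe = _prepare(dataset, config)[0]
        net = build_model(config, raw_sel_probe.shape[1], raw_sel_probe.shape[2])
    else:
        net = model
        config = net.config if seed is None else replace(net.config, seed=seed)
        if seed is not None:
            net = build_model(config, net.n_raw_channels, net.raw_len)

    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")

    raw_sel, channel_idx = _prepare(dataset, config)
    raw_mean = raw_sel.mean(axis=(0, 2), keepdims=True)
    raw_std = raw_sel.std(axis=(0, 2), keepdims=True) + 1e-12
    feat_mean = dataset.features.mean(axis=0)
    feat_std = dataset.features.std(axis=0) + 1e-12
    demo_mean = dataset.demographics.mean(axis=0)
    demo_std = dataset.demographics.std(axis=0) + 1e-12

    raw = _standardize(raw_sel, raw_mean, raw_std)
    feat = _standardize(dataset.features, feat_mean, feat_std)
    demo = _standardize(dataset.demographics, demo_mean, demo_std)

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    n = len(labels)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = net.forward(raw[batch], feat[batch], demo[batch], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[batch])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == labels[batch]).sum())
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )

    return TrainedModel(
        net=net,
        config=config,
        training_history=history,
        raw_mean=raw_mean,
        raw_std=raw_std,
        feat_mean=feat_mean,
        feat_std=feat_std,
        demo_mean=demo_mean,
        demo_std=demo_std,
        channel_idx=channel_idx,
        input_spec={
            "channels": [dataset.channel_names[i] for i in channel_idx],
            "window_len": int(raw.shape[2]),
        },
    )


def predict_proba(
    trained: TrainedModel, dataset: Dataset, batch_size: int = 64
) -> np.ndarray:
    """Class probabilities (n, 2); columns follow ``CLASS_NAMES`` order."""
    raw_sel = dataset.raw[:, trained.channel_idx, :]
    if raw_sel.shape[2] != trained.input_spec["window_len"]:
        raise ValueError(
            f"window length {raw_sel.shape[2]} does not match the trained "
            f"input spec {trained.input_spec['window_len']}"
        )
    raw = _standardize(raw_sel, trained.raw_mean, trained.raw_std)
    feat = _standardize(dataset.features, trained.feat_mean, trained.feat_std)
    demo = _standardize(dataset.demographics, trained.demo_mean, trained.demo_std)
    out = []
    for start in range(0, raw.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        logits = trained.net.forward(raw[sl], feat[sl], demo[sl], train=False)
        out.append(nn.softmax(logits))
    return np.concatenate(out, axis=0)


def embed(trained: TrainedModel, dataset: Dataset) -> np.ndarray:
    """Post-concatenation activations for every sample (t-SNE input)."""
    predict_proba(trained, dataset, batch_size=len(dataset) or 1)
    return trained.net.embedding_.copy()


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

class _SklearnBaseline:
    """SVM / random-forest baseline over the feature + demographics table."""

    def __init__(self, kind: str, seed: int):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        if kind == "svm":
            self.clf = make_pipeline(
                StandardScaler(), SVC(kernel="rbf", probability=True, random_state=seed)
            )
        else:
            self.clf = RandomForestClassifier(n_estimators=200, random_state=seed)

    @staticmethod
    def _table(dataset: Dataset) -> np.ndarray:
        return np.hstack([dataset.features, dataset.demographics])

    def fit(self, dataset: Dataset):
        self.clf.fit(self._table(dataset), dataset.labels)
        return self

    def predict_proba(self, dataset: Dataset) -> np.ndarray:
        return self.clf.predict_proba(self._table(dataset))


class _RawNetBaseline:
    """CNN-only / LSTM-only baseline consuming raw windows only."""

    def __init__(self, arch: str, config: FusionModelConfig, seed: int):
        self.config = replace(
            config, arch=arch, use_features=False, use_demo=False, seed=seed
        )

    def fit(self, dataset: Dataset):
        self.trained = train(self.config, dataset)
        return self

    def predict_proba(self, dataset: Dataset) -> np.ndarray:
        return predict_proba(self.trained, dataset)


def train_baseline(
    kind: str,
    dataset: Dataset,
    seed: int = 0,
    config: FusionModelConfig | None = None,
):
    """Train one of the comparison models: ``svm``, ``rf``, ``cnn``, ``lstm``.

    SVM and RF consume the 9-feature + demographics table; CNN and LSTM
    consume raw windows only.  All expose ``predict_proba(dataset)``.
    """
    kind = kind.lower()
    if kind in ("svm", "rf"):
        return _SklearnBaseline(kind, seed).fit(dataset)
    if kind in ("cnn", "lstm"):
        return _RawNetBaseline(kind, config or FusionModelConfig(), seed).fit(dataset)
    raise ValueError(f"unknown baseline kind {kind!r}")
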