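"""The five-branch attention-fusion classifier and the MLP baseline.

``AttentionFusionClassifier`` is the study's model: one shared (Siamese)
encoder maps each branch's feature vector to an embedding, an additive
(tanh) self-attention scorer assigns every subject a nonnegative per-branch
weight vector summing to 1, the weighted embedding sum passes through a
linear head and sigmoid to give P(methylated). Branch weights are shared by
construction — a single parameter set, not five tied copies — which is what
lets the model weigh modalities without multiplying parameters, and what
makes inference with absent modalities well-defined: an absent branch's
attention score is masked to -inf before the softmax, which is exactly a
renormalization of the remaining weights.

``MLPBaselineClassifier`` is the comparison model: a 3-layer perceptron
(hidden sizes 100 and 32, dropout 0.4) on a single branch's 400 features.

Both train with Adam on binary cross-entropy for at most 200 epochs with
early stopping on the AUC of an inner stratified validation split, and are
bit-reproducible given ``random_state`` (single-threaded).
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from ._nn import NEG_INF, Adam, bce_loss, copy_tree, fast_auc, flatten_params, \
    init_dense, sigmoid, softmax, stack_backward, stack_forward, tree_astype
from .features import BRANCHES, N_BRANCHES


def masked_softmax(scores: np.ndarray, present: np.ndarray | None) -> np.ndarray:
    """Softmax over the branch axis with absent branches masked to -inf.

    Holding scores fixed, masking branch j renormalizes the remaining
    weights: alpha_k -> alpha_k / (1 - alpha_j). The input dtype is
    preserved (training runs in float32; inference in float64).
    """
    scores = np.asarray(scores)
    if scores.dtype not in (np.float32, np.float64):
        scores = scores.astype(np.float64)
    if present is not None:
        present = np.broadcast_to(np.asarray(present, dtype=bool), scores.shape)
        if not present.any(axis=-1).all():
            raise ValueError("at least one branch must be present")
        scores = np.where(present, scores, NEG_INF)
    return softmax(scores, axis=-1)


class _FusionNet:
    """Forward/backward of the shared-encoder attention-fusion network.

    The attention score of branch b is ``s_b = u . tanh(W e_b + c) +
    gamma * beta_b``: an additive content scorer plus a learned per-branch
    bias ``beta`` (a branch embedding, the attention analogue of a
    positional embedding). The bias is what lets the model express a stable
    preference for informative modalities — with a strict Siamese encoder
    and a branch-symmetric scorer the architecture would be exchangeable
    across branches, and mean attention could never concentrate. ``u``
    starts at zero so attention begins uniform and sharpens only as the
    gradient supports it; ``gamma`` (``branch_bias_scale``) amplifies the
    bias path so modality preference is learned on the same timescale as
    the encoder.
    """

    def __init__(self, dropout: float, branch_bias_scale: float = 30.0):
        self.dropout = dropout
        self.branch_bias_scale = branch_bias_scale

    def init_params(self, rng: np.random.Generator, n_features: int,
                    encoder_hidden: list[int], embed_dim: int,
                    n_branches: int, beta_init=None) -> dict:
        e = embed_dim
        beta = (np.zeros(n_branches) if beta_init is None
                else np.asarray(beta_init, dtype=np.float64).copy())
        return {
            "encoder": init_dense(rng, [n_features, *encoder_hidden, e]),
            "att": {
                "W": rng.standard_normal((e, e)) / np.sqrt(e),
                "b": np.zeros(e),
                "beta": beta,
                "u": np.zeros(e),
            },
            "head": {"w": rng.standard_normal(e) / np.sqrt(e),
                     "b": np.zeros(1)},
        }

    def forward(self, params: dict, X: np.ndarray, present=None,
                train: bool = False, rng=None):
        # X: (B, M, F) standardized
        e, enc_cache = stack_forward(params["encoder"], X,
                                     self.dropout if train else 0.0, rng, train)
        t = np.tanh(e @ params["att"]["W"] + params["att"]["b"])
        s = t @ params["att"]["u"] \
            + self.branch_bias_scale * params["att"]["beta"]   # (B, M)
        alpha = masked_softmax(s, present)
        fused = np.einsum("bm,bme->be", alpha, e)
        z = fused @ params["head"]["w"] + params["head"]["b"][0]
        p = sigmoid(z)
        cache = {"enc": enc_cache, "e": e, "t": t, "alpha": alpha, "fused": fused}
        return p, cache

    def backward(self, params: dict, cache: dict, dz: np.ndarray) -> dict:
        e, t, alpha, fused = cache["e"], cache["t"], cache["alpha"], cache["fused"]
        u, W = params["att"]["u"], params["att"]["W"]
        w = params["head"]["w"]
        d_head = {"w": fused.T @ dz, "b": np.array([dz.sum()])}
        dfused = dz[:, None] * w[None, :]
        dalpha = np.einsum("be,bme->bm", dfused, e)
        de = alpha[..., None] * dfused[:, None, :]
        ds = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        du = np.einsum("bm,bme->e", ds, t)
        dta = (ds[..., None] * u) * (1.0 - t * t)
        d_att = {"W": np.einsum("bmi,bmj->ij", e, dta),
                 "b": dta.sum(axis=(0, 1)),
                 "beta": self.branch_bias_scale * ds.sum(axis=0), "u": du}
        de = de + dta @ W.T
        enc_grads, _ = stack_backward(params["encoder"], cache["enc"], de)
        return {"encoder": enc_grads, "att": d_att, "head": d_head}


class _MLPNet:
    """Forward/backward of the single-branch MLP baseline."""

    def __init__(self, dropout: float):
        self.dropout = dropout

    def init_params(self, rng, n_features: int, hidden: list[int]) -> dict:
        return {"stack": init_dense(rng, [n_features, *hidden, 1])}

    def forward(self, params, X, present=None, train=False, rng=None):
        z, cache = stack_forward(params["stack"], X,
                                 self.dropout if train else 0.0, rng, train)
        return sigmoid(z[..., 0]), {"stack": cache}

    def backward(self, params, cache, dz):
        grads, _ = stack_backward(params["stack"], cache["stack"], dz[..., None])
        return {"stack": grads}


def _run_training(net, params, X_tr, y_tr, X_val, y_val, *, learning_rate,
                  batch_size, max_epochs, patience, rng, weight_decay=0.0,
                  min_epochs=0):
    """AdamW/BCE loop with early stopping on inner-validation AUC.

    ``min_epochs`` is a burn-in during which patience cannot fire: with a
    small inner split the epoch-level AUC is noisy, and a lucky early peak
    would otherwise end training long before the attention weights and
    encoder have converged.
    """
    opt = Adam(flatten_params(params), lr=learning_rate,
               weight_decay=weight_decay)
    best_params = copy_tree(params)
    best_auc, best_epoch, wait = -np.inf, -1, 0
    history = {"train_loss": [], "val_auc": []}
    n = len(y_tr)
    for epoch in range(max_epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            p, cache = net.forward(params, X_tr[idx], train=True, rng=rng)
            losses.append(bce_loss(p, y_tr[idx]))
            dz = (p - y_tr[idx]) / len(idx)
            grads = net.backward(params, cache, dz)
            opt.step(flatten_params(grads))
        val_p, _ = net.forward(params, X_val)
        val_auc = fast_auc(y_val, val_p)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auc"].append(val_auc)
        if epoch + 1 < min_epochs:
            continue  # burn-in: neither snapshot nor stop on noisy epochs
        if val_auc > best_auc + 1e-12:
            best_auc, best_epoch, wait = val_auc, epoch, 0
            best_params = copy_tree(params)
        else:
            wait += 1
            if wait >= patience:
                break
    if best_epoch < 0:  # burn-in covered the whole budget: keep final weights
        best_params = copy_tree(params)
        best_auc, best_epoch = history["val_auc"][-1], epoch
    history.update(best_epoch=best_epoch, best_val_auc=best_auc,
                   stopped_epoch=epoch)
    return best_params, history


class _BaseNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit plumbing: label checks, z-scoring, inner split, training."""

    def _reshape(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _build_net(self):
        raise NotImplementedError

    def _prepare_labels(self, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        y01 = (y == self.classes_[1]).astype(np.float64)
        counts = np.bincount(y01.astype(int))
        if counts.min() < 2:
            raise ValueError("need at least 2 subjects per class")
        return y01

    def fit(self, X, y):
        X = self._reshape(np.asarray(X, dtype=np.float64))
        y01 = self._prepare_labels(y)
        if X.shape[0] != len(y01):
            raise ValueError("X and y length mismatch")
        rng = np.random.Generator(np.random.PCG64(self.random_state))

        # per-feature standardization fit on the training data only
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0), 1e-8)
        Xs = (X - self.mean_) / self.scale_
        # univariate screening gate (training data only): zero out features
        # whose class-mean difference is indistinguishable from noise
        self.gate_ = self._feature_gate(Xs, y01)
        Xs = Xs * self.gate_

        self._prepare_fit(Xs, y01, rng)
        X32 = Xs.astype(np.float32)
        y32 = y01.astype(np.float32)

        # the loss surface is non-convex and a single run can settle in a
        # poor basin; fit n_restarts members (each with its own stratified
        # inner split, init and batch stream) and average their predicted
        # probabilities — a restart ensemble. With n_restarts=1 this reduces
        # to a single early-stopped fit.
        net = self._build_net()
        self.members_ = []
        for _ in range(max(1, int(getattr(self, "n_restarts", 1)))):
            split_seed = int(rng.integers(2 ** 31))
            splitter = StratifiedShuffleSplit(n_splits=1,
                                              test_size=self.val_fraction,
                                              random_state=split_seed)
            tr_idx, val_idx = next(splitter.split(Xs, y01))
            # members train in float32 (fast BLAS) and are stored in float64
            # so inference contracts hold to full precision
            params = tree_astype(self._init_params(net, rng, Xs.shape[-1]),
                                 np.float32)
            params, history = _run_training(
                net, params, X32[tr_idx], y32[tr_idx], X32[val_idx],
                y32[val_idx],
                learning_rate=self.learning_rate, batch_size=self.batch_size,
                max_epochs=self.max_epochs, patience=self.patience, rng=rng,
                weight_decay=self.weight_decay, min_epochs=self.min_epochs)
            self.members_.append((tree_astype(params, np.float64), history))
        # expose the member with the best inner AUC for introspection
        best = max(self.members_, key=lambda m: m[1]["best_val_auc"])
        self.params_, self.history_ = best
        self._net = net
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def _prepare_fit(self, Xs, y01, rng):
        """Hook run once before member training (default: nothing)."""

    def _feature_gate(self, Xs, y01):
        """0/1 mask over input features from a univariate two-sample screen.

        On z-scored features the class-mean difference divided by its
        standard error is approximately standard normal under the null; a
        feature is kept when |z| >= screen_z. Computed on the training fold
        only, so cross-validation stays leak-free. ``screen_z=0`` disables
        screening (all-ones gate).
        """
        screen_z = float(getattr(self, "screen_z", 0.0) or 0.0)
        if screen_z <= 0:
            return np.ones(Xs.shape[1:])
        pos = y01 == 1
        d = Xs[pos].mean(axis=0) - Xs[~pos].mean(axis=0)
        se = np.sqrt(1.0 / pos.sum() + 1.0 / (~pos).sum())
        return (np.abs(d / se) >= screen_z).astype(np.float64)

    def _scored(self, X, present=None):
        """Ensemble-averaged probabilities; cache of the best member."""
        check_is_fitted(self, "params_")
        X = self._reshape(np.asarray(X, dtype=np.float64))
        Xs = (X - self.mean_) / self.scale_ * self.gate_
        probs, best_cache = [], None
        for params, _ in self.members_:
            p, cache = self._net.forward(params, Xs, present=present)
            probs.append(p)
            if params is self.params_:
                best_cache = cache
        return np.mean(probs, axis=0), best_cache

    def _member_caches(self, X, present=None):
        X = self._reshape(np.asarray(X, dtype=np.float64))
        Xs = (X - self.mean_) / self.scale_ * self.gate_
        return [self._net.forward(params, Xs, present=present)[1]
                for params, _ in self.members_]

    def predict_proba(self, X):
        p, _ = self._scored(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, threshold: float = 0.5):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= threshold).astype(int)]

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]


class AttentionFusionClassifier(_BaseNetClassifier):
    """Five-branch Siamese attention-fusion classifier.

    Parameters
    ----------
    embed_dim : int
        Branch embedding width produced by the shared encoder.
    encoder_hidden : tuple of int
        Hidden-layer widths of the shared encoder (ReLU, dropout).
    dropout : float
        Dropout rate on encoder hidden units during training.
    weight_decay : float
        Decoupled (AdamW) decay on weight matrices; biases and attention
        parameters are not decayed. Strong by design: it keeps the network
        near linear-model capacity so early stopping has time to work.
    branch_bias_scale : float
        Gain on the learned per-branch attention-score bias.
    learning_rate, batch_size : Adam step size and minibatch size.
    max_epochs : int
        Epoch budget (200); early stopping usually halts sooner.
    patience : int
        Epochs without inner-validation AUC improvement before stopping.
    min_epochs : int
        Burn-in during which neither stopping nor best-epoch snapshots
        happen (the small inner split makes epoch-level AUC noisy).
    n_restarts : int
        Members in the restart ensemble; predictions and attention weights
        are member averages. 1 disables ensembling.
    probe_gain : float
        Scale of the attention-bias warm start from per-branch linear-probe
        AUCs; 0 disables the probe.
    screen_z : float
        Univariate screening threshold (|z| of the class-mean difference on
        the training fold) below which a feature is zeroed; 0 disables.
    val_fraction : float
        Fraction of the training data held out (stratified) for early
        stopping.
    n_branches : int
        Number of input branches (5: FLAIR, T1, T2, T1wCE, delta-T1).
    random_state : int
        Seeds initialization, batch order, dropout, probes and splits.

    ``X`` may be ``(n, n_branches, f)`` or flat ``(n, n_branches * f)``.
    """

    def __init__(self, embed_dim: int = 64, encoder_hidden: tuple = (128,),
                 dropout: float = 0.3, weight_decay: float = 10.0,
                 branch_bias_scale: float = 30.0, learning_rate: float = 1e-3,
                 max_epochs: int = 200, patience: int = 20, min_epochs: int = 100,
                 n_restarts: int = 3,
                 probe_gain: float = 10.0, screen_z: float = 3.0,
                 val_fraction: float = 0.1, batch_size: int = 32,
                 n_branches: int = N_BRANCHES, random_state: int = 0):
        self.embed_dim = embed_dim
        self.encoder_hidden = encoder_hidden
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.branch_bias_scale = branch_bias_scale
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.n_restarts = n_restarts
        self.probe_gain = probe_gain
        self.screen_z = screen_z
        self.val_fraction = val_fraction
        self.batch_size = batch_size
        self.n_branches = n_branches
        self.random_state = random_state

    def _reshape(self, X):
        if X.ndim == 2:
            if X.shape[1] % self.n_branches:
                raise ValueError(f"flat input width {X.shape[1]} not divisible "
                                 f"by n_branches={self.n_branches}")
            X = X.reshape(X.shape[0], self.n_branches, -1)
        if X.ndim != 3 or X.shape[1] != self.n_branches:
            raise ValueError(f"expected (n, {self.n_branches}, f) input, "
                             f"got {X.shape}")
        return X

    def _build_net(self):
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")
        return _FusionNet(self.dropout, self.branch_bias_scale)

    def _prepare_fit(self, Xs, y01, rng):
        if self.probe_gain > 0:
            probe_aucs = self._probe_branches(Xs, y01, rng)
            self.probe_aucs_ = probe_aucs
            self._beta_init = (self.probe_gain * (probe_aucs - 0.5)
                               / self.branch_bias_scale)
        else:
            self.probe_aucs_ = None
            self._beta_init = None

    def _init_params(self, net, rng, n_features):
        return net.init_params(rng, n_features, list(self.encoder_hidden),
                               self.embed_dim, self.n_branches,
                               beta_init=getattr(self, "_beta_init", None))

    def _probe_branches(self, Xs, y01, rng):
        """Per-branch linear-probe AUCs to warm-start the attention bias.

        A branch whose features alone separate the classes should start
        with higher attention; learning this preference from scratch inside
        the softmax is fragile (a wrong early commitment starves the true
        branch of gradient), whereas a split-half ridge-logistic screen is
        cheap, deterministic and directly measures marginal utility. The
        bias stays fully learnable afterwards.
        """
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import StratifiedKFold

        probe_seed = int(rng.integers(2 ** 31))
        skf = StratifiedKFold(n_splits=2, shuffle=True,
                              random_state=probe_seed)
        aucs = np.zeros(self.n_branches)
        for b in range(self.n_branches):
            Xb = Xs[:, b, :]
            fold_aucs = []
            for tr, te in skf.split(Xb, y01):
                lr = LogisticRegression(C=0.01, max_iter=1000)
                lr.fit(Xb[tr], y01[tr])
                fold_aucs.append(roc_auc_score(y01[te],
                                               lr.decision_function(Xb[te])))
            aucs[b] = np.mean(fold_aucs)
        return aucs

    # -- attention / missing-modality API ------------------------------------

    def attention_weights(self, X, present=None) -> np.ndarray:
        """Per-subject branch attention vectors (each sums to 1).

        For a restart ensemble these are the member-averaged weights, which
        remain a nonnegative vector summing to 1.
        """
        caches = self._member_caches(X, present=self._check_present(present))
        return np.mean([c["alpha"] for c in caches], axis=0)

    def predict_proba_missing(self, X, present) -> np.ndarray:
        """Predict with absent branches masked out of the attention softmax.

        ``present`` is a boolean vector of length ``n_branches`` (or an
        (n, n_branches) matrix); at least one branch must be present.
        """
        p, _ = self._scored(X, present=self._check_present(present))
        return np.column_stack([1.0 - p, p])

    def _check_present(self, present):
        if present is None:
            return None
        present = np.asarray(present, dtype=bool)
        if present.shape[-1] != self.n_branches:
            raise ValueError(f"present must have {self.n_branches} entries")
        return present

    @property
    def encoder_params_(self):
        """The single shared encoder parameter set (Siamese by construction)."""
        check_is_fitted(self, "params_")
        return self.params_["encoder"]


class MLPBaselineClassifier(_BaseNetClassifier):
    """3-layer MLP baseline on a single branch's feature vector.

    Hidden layers of 100 and 32 units with dropout 0.4, matching the
    comparison model this package evaluates against. ``X`` may be a flat
    ``(n, f)`` matrix, or the full ``(n, 5, f)`` branch tensor, in which
    case the configured ``branch`` row (default T1wCE) is selected.
    """

    def __init__(self, hidden: tuple = (100, 32), dropout: float = 0.4,
                 branch: str = "t1wce", weight_decay: float = 30.0,
                 learning_rate: float = 1e-3,
                 max_epochs: int = 200, patience: int = 20, min_epochs: int = 60,
                 n_restarts: int = 3, screen_z: float = 3.0,
                 val_fraction: float = 0.1, batch_size: int = 32,
                 random_state: int = 0):
        self.hidden = hidden
        self.dropout = dropout
        self.branch = branch
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.n_restarts = n_restarts
        self.screen_z = screen_z
        self.val_fraction = val_fraction
        self.batch_size = batch_size
        self.random_state = random_state

    def _reshape(self, X):
        if X.ndim == 3:
            X = X[:, BRANCHES.index(self.branch), :]
        if X.ndim != 2:
            raise ValueError(f"expected (n, f) input, got {X.shape}")
        return X

    def _build_net(self):
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")
        return _MLPNet(self.dropout)

    def _init_params(self, net, rng, n_features):
        return net.init_params(rng, n_features, list(self.hidden))

    @property
    def architecture_(self) -> tuple:
        """Layer widths input->hidden->output after fitting."""
        check_is_fitted(self, "params_")
        dims = [layer["W"].shape[0] for layer in self.params_["stack"]]
        dims.append(self.params_["stack"][-1]["W"].shape[1])
        return tuple(dims)


# -- checkpoint I/O ----------------------------------------------------------

def save_model(model: _BaseNetClassifier, path) -> None:
    """Serialize a fitted model (config + member weights + feature scaler)."""
    check_is_fitted(model, "params_")
    arrays = {}
    for m, (params, _) in enumerate(model.members_):
        for i, arr in enumerate(flatten_params(params)):
            arrays[f"m{m:02d}p{i:03d}"] = arr
    arrays["mean"] = model.mean_
    arrays["scale"] = model.scale_
    arrays["gate"] = model.gate_
    arrays["classes"] = model.classes_
    meta = {"class": type(model).__name__, "params": model.get_params(),
            "n_members": len(model.members_),
            "best_member": max(range(len(model.members_)),
                               key=lambda i: model.members_[i][1]
                               ["best_val_auc"]),
            "histories": [h for _, h in model.members_]}
    np.savez(path, _meta=json.dumps(meta, default=list), **arrays)


def load_model(path) -> _BaseNetClassifier:
    """Load a model saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        member_flats = []
        for m in range(meta["n_members"]):
            prefix = f"m{m:02d}p"
            keys = sorted(k for k in data.files if k.startswith(prefix))
            member_flats.append([data[k] for k in keys])
        mean, scale, classes = data["mean"], data["scale"], data["classes"]
        gate = data["gate"]
    cls = {"AttentionFusionClassifier": AttentionFusionClassifier,
           "MLPBaselineClassifier": MLPBaselineClassifier}[meta["class"]]
    params = meta["params"]
    for key in ("encoder_hidden", "hidden"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    model = cls(**params)
    rng = np.random.Generator(np.random.PCG64(0))
    net = model._build_net()
    model.members_ = []
    for flat, history in zip(member_flats, meta["histories"]):
        tree = model._init_params(net, rng, int(mean.shape[-1]))
        for tgt, src in zip(flatten_params(tree), flat):
            tgt[...] = src
        model.members_.append((tree, history))
    model.params_, model.history_ = model.members_[meta["best_member"]]
    model._net = net
    model.mean_ = mean
    model.scale_ = scale
    model.gate_ = gate
    model.classes_ = classes
    model.n_features_in_ = int(np.prod(mean.shape))
    return model


# thin functional wrappers matching the operation-level API ------------------

def train_fusion(cohort, **config) -> AttentionFusionClassifier:
    """Fit an :class:`AttentionFusionClassifier` on a labeled cohort."""
    if cohort.y is None:
        raise ValueError("cohort has no labels")
    return AttentionFusionClassifier(**config).fit(cohort.X, cohort.y)


def predict_fusion(model: AttentionFusionClassifier, subject_matrix: np.ndarray):
    """P(methylated) and attention weights for one 5 x f subject matrix."""
    X = np.asarray(subject_matrix, dtype=np.float64)[None, ...]
    prob = model.predict_proba(X)[0, 1]
    attn = model.attention_weights(X)[0]
    return float(prob), attn


def predict_with_missing(model: AttentionFusionClassifier,
                         subject_matrix: np.ndarray, present):
    """Like :func:`predict_fusion` with absent branches masked."""
    X = np.asarray(subject_matrix, dtype=np.float64)[None, ...]
    present = np.asarray(present, dtype=bool)
    prob = model.predict_proba_missing(X, present)[0, 1]
    attn = model.attention_weights(X, present=present)[0]
    return float(prob), attn


def train_mlp_baseline(cohort, **config) -> MLPBaselineClassifier:
    """Fit the single-branch MLP baseline on a labeled cohort."""
    if cohort.y is None:
        raise ValueError("cohort has no labels")
    return MLPBaselineClassifier(**config).fit(cohort.X, cohort.y)
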