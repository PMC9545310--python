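"""Group-aware five-fold cross-validation training.

Cases are split into folds by *group* (patient identity), so initial and
follow-up scans of the same patient can never leak across the
train/validation boundary — nor across the pool/test boundary.  Each fold
trains the network with Adam on a full-volume mean-squared-error loss,
monitors validation loss every epoch, stops early when it has not
improved for ``early_stop_patience`` epochs, and restores the weights of
the best-validation epoch.

Default hyperparameters are the full-scale values (Adam lr 5.0e−5,
β₁ 0.90, β₂ 0.999, ε 1.0e−7, batch 2, up to 1000 epochs, patience 50);
desk-scale experiments pass smaller budgets and a larger learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .model import NetConfig, UNet3D, build_unet
from .volumes import PairedCase

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "TrainedModel",
    "split_folds",
    "split_pool_test",
    "train_fold",
    "train_cv",
    "mse_loss",
]


@dataclass
class TrainConfig:
    learning_rate: float = 5.0e-5
    beta1: float = 0.90
    beta2: float = 0.999
    epsilon: float = 1.0e-7
    max_epochs: int = 1000
    batch_size: int = 2
    early_stop_patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.epsilon) <= 0:
            raise ValueError("optimizer hyperparameters must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if not 0 < self.early_stop_patience < self.max_epochs:
            raise ValueError("early_stop_patience must lie in (0, max_epochs)")


@dataclass
class FoldAssignment:
    """Mapping of case ids to cross-validation folds plus the held-out test set."""

    k: int
    fold_of_case: dict[str, int]
    test_ids: list[str] = field(default_factory=list)

    def fold_cases(self, fold_index: int) -> list[str]:
        return [c for c, f in self.fold_of_case.items() if f == fold_index]

    def train_val_ids(self, fold_index: int) -> tuple[list[str], list[str]]:
        train = [c for c, f in self.fold_of_case.items() if f != fold_index]
        val = self.fold_cases(fold_index)
        return train, val


@dataclass
class TrainedModel:
    """Best-validation-loss checkpoint of one fold plus its loss history."""

    network: UNet3D
    history: dict[str, list[float]]
    fold_index: int
    best_epoch: int

    def __post_init__(self) -> None:
        val = self.history.get("val_loss", [])
        if val and not np.isclose(val[self.best_epoch], min(val)):
            raise ValueError("checkpoint epoch must carry the minimum validation loss")


def _group_partition(groups: list[str], k: int, rng) -> dict[str, int]:
    """Assign whole groups to k folds, balancing case counts greedily."""
    uniq: dict[str, int] = {}
    for g in groups:
        uniq[g] = uniq.get(g, 0) + 1
    names = list(uniq)
    rng.shuffle(names)
    # larger groups first so the greedy balance closes exactly when possible
    names.sort(key=lambda g: -uniq[g])
    loads = [0] * k
    fold_of_group = {}
    for g in names:
        fold = int(np.argmin(loads))
        fold_of_group[g] = fold
        loads[fold] += uniq[g]
    return fold_of_group


def split_folds(cases: list[tuple[str, str]], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Group-aware k-fold split of ``(case_id, group_id)`` pairs.

    All cases sharing a ``group_id`` land in the same fold.  With 60
    singleton-group cases and k = 5, every fold holds 12 validation cases
    (48 training).  Deterministic given ``seed``.
    """
    groups = [g for _, g in cases]
    if len(set(groups)) < k:
        raise ValueError(f"need at least {k} distinct groups, got {len(set(groups))}")
    rng = np.random.default_rng(seed)
    fold_of_group = _group_partition(groups, k, rng)
    return FoldAssignment(k=k, fold_of_case={c: fold_of_group[g] for c, g in cases})


def split_pool_test(
    cases: list[tuple[str, str]], n_test: int, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Hold out ``n_test`` cases group-aware, then k-fold the remaining pool.

    Groups are drawn into the test set until it holds at least ``n_test``
    cases; paired scans therefore never straddle the pool/test boundary.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for c, g in cases:
        by_group.setdefault(g, []).append(c)
    names = list(by_group)
    rng.shuffle(names)
    test_ids: list[str] = []
    pool_groups = []
    for g in names:
        if len(test_ids) < n_test:
            test_ids.extend(by_group[g])
        else:
            pool_groups.append(g)
    pool = [(c, g) for c, g in cases if g in set(pool_groups)]
    fa = split_folds(pool, k=k, seed=int(rng.integers(0, 2**31 - 1)))
    fa.test_ids = sorted(test_ids)
    return fa


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over the full volume (masked background included)."""
    d = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    return float(np.mean(d * d))


def _case_tensors(case: PairedCase) -> tuple[np.ndarray, np.ndarray]:
    if case.ventilation is None:
        raise ValueError(f"case {case.case_id} has no ventilation target")
    return (
        np.asarray(case.ct.data, dtype=np.float32),
        np.asarray(case.ventilation.data, dtype=np.float32),
    )


def train_fold(
    pool: list[PairedCase],
    fold: FoldAssignment,
    fold_index: int,
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Train one cross-validation fold and return its best checkpoint.

    The training set is every pool case outside ``fold_index``; the
    validation set is the fold itself.  Weight initialization, batch
    order and dropout all derive from ``train_cfg.seed`` and
    ``fold_index``, so a rerun reproduces the history bit for bit.
    """
    train_ids, val_ids = fold.train_val_ids(fold_index)
    by_id = {c.case_id: c for c in pool}
    train_cases = [by_id[i] for i in train_ids if i in by_id]
    val_cases = [by_id[i] for i in val_ids if i in by_id]
    if not train_cases:
        raise ValueError(f"fold {fold_index}: empty training set")

    ss = np.random.SeedSequence([train_cfg.seed, fold_index])
    init_seed, order_seed, drop_seed = [int(s) for s in ss.generate_state(3) >> 1]
    net = build_unet(net_cfg, seed=init_seed)
    order_rng = np.random.default_rng(order_seed)
    drop_rng = np.random.default_rng(drop_seed)
    opt = Adam(
        net.parameters(),
        lr=train_cfg.learning_rate,
        beta1=train_cfg.beta1,
        beta2=train_cfg.beta2,
        eps=train_cfg.epsilon,
    )
    reg = net.regularization_flags()
    l2 = net_cfg.l2_weight

    data = [_case_tensors(c) for c in train_cases]
    vdata = [_case_tensors(c) for c in val_cases]
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    since_best = 0

    for epoch in range(train_cfg.max_epochs):
        idx = order_rng.permutation(len(data))
        epoch_loss = 0.0
        for start in range(0, len(idx), train_cfg.batch_size):
            batch = idx[start : start + train_cfg.batch_size]
            net.zero_grads()
            for i in batch:
                ct, target = data[i]
                y = net.forward(ct, training=True, rng=drop_rng)
                diff = y - target
                epoch_loss += float(np.mean(diff.astype(np.float64) ** 2))
                net.backward((2.0 / (diff.size * len(batch))) * diff)
            grads = net.gradients()
            params = net.parameters()
            for g, p, r in zip(grads, params, reg):
                if r and l2 > 0:
                    g += 2.0 * l2 * p
            opt.step(grads)
        history["train_loss"].append(epoch_loss / len(data))

        if vdata:
            vloss = float(
                np.mean([mse_loss(net.forward(ct), target) for ct, target in vdata])
            )
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if verbose:
            print(
                f"fold {fold_index} epoch {epoch:3d} "
                f"train {history['train_loss'][-1]:.5f} val {vloss:.5f}"
            )
        if vloss < best_val:
            best_val = vloss
            best_weights = net.get_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_cfg.early_stop_patience:
                break

    net.set_weights(best_weights)
    return TrainedModel(network=net, history=history, fold_index=fold_index, best_epoch=best_epoch)


def train_cv(
    pool: list[PairedCase],
    fold_assignment: FoldAssignment,
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    verbose: bool = False,
) -> list[TrainedModel]:
    """Train every fold with the identical assignment; returns k models."""
    return [
        train_fold(pool, fold_assignment, f, net_cfg, train_cfg, verbose=verbose)
        for f in range(fold_assignment.k)
    ]
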