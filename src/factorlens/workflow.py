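"""High-level recipes combining the network, formula, and triplet layers.

``distill_surface`` is the standard protocol for turning a factor matrix into
a closed-form formula: an 80/20 seeded split, multi-restart penalized
training, capacity escalation when a validation slice of the training split
shows an inadequate fit, formula extraction, and held-out verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formula import AccuracyReport, SymbolicFormula, extract_formula, verification_accuracy
from .network import EqlNetwork, TrainConfig, fit_with_restarts
from .operators import OperatorSet
from .triplets import TripletDataset


@dataclass
class DistillResult:
    """Everything produced by one surface-distillation run."""

    network: EqlNetwork
    formula: SymbolicFormula
    report: AccuracyReport
    train_set: TripletDataset
    test_set: TripletDataset
    history: list
    depth_used: int


# two-round capacity schedule: a compact two-layer network suffices for most
# surfaces; deeply nested compositions escalate to three layers
_ROUNDS = (
    dict(depth=2, epochs=1800, restarts=2),
    dict(depth=3, epochs=2500, restarts=3),
)
_ESCALATE_BELOW = 97.0   # validation accuracy (%) that triggers the next round
_DISTILL_LAM = 3e-4


def distill_surface(dataset: TripletDataset,
                    seed: int = 0,
                    tau: float = 0.05,
                    train_frac: float = 0.8,
                    operator_set: OperatorSet = OperatorSet(),
                    lam: float = _DISTILL_LAM,
                    theta: float = 0.01) -> DistillResult:
    """Fit, prune and verify a symbolic formula for a triplet dataset.

    The dataset is split ``train_frac``/rest by a seeded shuffle; the test
    split is touched only by the final verification.  Model selection
    (between restarts and capacity rounds) uses a 10% validation slice of the
    training split.  Returns the trained network, the extracted formula, and
    the held-out tolerance-band accuracy at ``tau``.
    """
    train_set, test_set = dataset.split(train_frac, seed=seed)
    fit_set, val_set = train_set.split(0.9, seed=seed + 1)

    best = None  # (val_accuracy, network, history, depth)
    for round_no, round_cfg in enumerate(_ROUNDS):
        cfg = TrainConfig(epochs=round_cfg["epochs"], lam=lam,
                          seed=seed + 100 * round_no)
        net, history = fit_with_restarts(
            fit_set, operator_set=operator_set, depth=round_cfg["depth"],
            config=cfg, restarts=round_cfg["restarts"])
        try:
            val_acc = verification_accuracy(net, val_set, tau).accuracy
        except ValueError:
            val_acc = 0.0
        if best is None or val_acc > best[0]:
            best = (val_acc, net, history, round_cfg["depth"])
        if best[0] >= _ESCALATE_BELOW:
            break

    _, net, history, depth = best
    net.theta = theta
    formula = extract_formula(net, theta)
    report = verification_accuracy(net, test_set, tau)
    return DistillResult(network=net, formula=formula, report=report,
                         train_set=train_set, test_set=test_set,
                         history=history, depth_used=depth)
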