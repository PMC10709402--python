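"""SGD with momentum, per-group learning rates and weight decay."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .tensor import Tensor


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``param_groups`` is a list of dicts with keys ``params`` (list of
    Tensors), ``lr``, ``weight_decay`` and optionally ``momentum`` and a
    free-form ``name``.  Learning rates may be rescheduled per group by
    assigning ``group["lr"]`` between steps; a scheduler can skip groups
    flagged ``fixed_lr=True``.
    """

    def __init__(self, param_groups: List[Dict], lr: float = 0.05,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        if param_groups and isinstance(param_groups[0], Tensor):
            param_groups = [{"params": list(param_groups)}]
        self.param_groups: List[Dict] = []
        for group in param_groups:
            g = dict(group)
            g.setdefault("lr", lr)
            g.setdefault("momentum", momentum)
            g.setdefault("weight_decay", weight_decay)
            g.setdefault("fixed_lr", False)
            self.param_groups.append(g)
        self._velocity: Dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for group in self.param_groups:
            for p in group["params"]:
                p.zero_grad()

    def step(self) -> None:
        for group in self.param_groups:
            lr = group["lr"]
            mu = group["momentum"]
            wd = group["weight_decay"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                if wd:
                    g = g + wd * p.data
                if mu:
                    v = self._velocity.get(id(p))
                    if v is None:
                        v = np.zeros_like(p.data)
                        self._velocity[id(p)] = v
                    v *= mu
                    v += g
                    g = v
                p.data -= lr * g

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> Dict:
        velocities = []
        for group in self.param_groups:
            for p in group["params"]:
                v = self._velocity.get(id(p))
                velocities.append(v.copy() if v is not None else None)
        return {
            "velocities": velocities,
            "groups": [{k: v for k, v in g.items() if k != "params"}
                       for g in self.param_groups],
        }

    def load_state_dict(self, state: Dict) -> None:
        flat_params = [p for g in self.param_groups for p in g["params"]]
        if len(flat_params) != len(state["velocities"]):
            raise ValueError("optimizer state does not match parameter count")
        for p, v in zip(flat_params, state["velocities"]):
            if v is not None:
                self._velocity[id(p)] = np.asarray(v, dtype=np.float32).copy()
        for g, meta in zip(self.param_groups, state["groups"]):
            g.update(meta)
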