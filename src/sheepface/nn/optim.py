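"""Stochastic gradient descent with momentum, weight decay and ascent groups."""

from __future__ import annotations

import numpy as np


class SGD:
    """SGD over parameter groups.

    Each group is a dict with keys ``params`` (list of Parameters), and
    optionally ``lr``, ``momentum``, ``weight_decay`` and ``maximize``.  A
    group with ``maximize=True`` performs gradient ascent, which is how the
    correlation module is driven toward the most correlated projections.
    """

    def __init__(self, groups, lr=1e-3, momentum=0.9, weight_decay=1e-4):
        if groups and not isinstance(groups[0], dict):
            groups = [{"params": list(groups)}]
        self.defaults = dict(lr=lr, momentum=momentum, weight_decay=weight_decay,
                             maximize=False)
        self.groups = []
        for g in groups:
            merged = dict(self.defaults)
            merged.update(g)
            merged["buffers"] = [np.zeros_like(p.data) for p in merged["params"]]
            self.groups.append(merged)

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        for g in self.groups:
            lr, mom, wd = g["lr"], g["momentum"], g["weight_decay"]
            sign = -1.0 if g["maximize"] else 1.0
            for p, buf in zip(g["params"], g["buffers"]):
                if p.grad is None:
                    continue
                d = sign * p.grad
                if wd:
                    d = d + wd * p.data
                if mom:
                    buf *= mom
                    buf += d
                    d = buf
                p.data = p.data - lr * d
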