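"""Parameter-tree utilities and the Adam optimizer.

Model parameters are nested structures of dicts / lists with numpy arrays at
the leaves.  These helpers apply elementwise updates across such trees so the
training code can treat a whole model (or any sub-tree, e.g. a single cycle
map) as one object.
"""

from __future__ import annotations

import numpy as np


def tree_map(fn, *trees):
    """Apply ``fn`` leafwise across parallel trees of dicts/lists/arrays."""
    first = trees[0]
    if isinstance(first, dict):
        return {k: tree_map(fn, *(t[k] for t in trees)) for k in first}
    if isinstance(first, (list, tuple)):
        return [tree_map(fn, *(t[i] for t in trees)) for i in range(len(first))]
    return fn(*trees)


def tree_leaves(tree):
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k])
    elif isinstance(tree, (list, tuple)):
        for t in tree:
            yield from tree_leaves(t)
    else:
        yield tree


def tree_checksum(tree) -> float:
    """Order-stable scalar digest of every parameter value (for determinism
    contracts in tests, not cryptographic)."""
    total = 0.0
    for i, leaf in enumerate(tree_leaves(tree)):
        total += float(np.sum(np.asarray(leaf, dtype=np.float64) * (i + 1)))
    return total


class Adam:
    """Standard Adam (Kingma & Ba) over a parameter tree."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        self.m = tree_map(lambda m, g: b1 * m + (1 - b1) * g, self.m, grads)
        self.v = tree_map(lambda v, g: b2 * v + (1 - b2) * g * g, self.v, grads)
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        lr = self.lr

        def upd(p, m, v):
            return p - lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

        return tree_map(upd, params, self.m, self.v)
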