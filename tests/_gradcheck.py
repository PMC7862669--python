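"""Central finite-difference gradient checking against the autodiff tape."""

import numpy as np

from pixseq.autodiff import Tensor


def max_rel_grad_error(params, step_fn, proj_seed=1, eps=1e-6):
    """Max relative error between tape gradients and central differences.

    ``step_fn`` rebuilds the forward pass and returns a tuple of output
    Tensors; the scalar objective is a fixed random projection of them, so a
    single backward pass exercises every output component.
    """
    prng = np.random.default_rng(proj_seed)
    outs = step_fn()
    weights = [prng.normal(size=o.shape) for o in outs]

    def scalar():
        return sum(float((o.data * w).sum()) for o, w in zip(step_fn(), weights))

    for p in params:
        p.grad = None
    loss = None
    for o, w in zip(step_fn(), weights):
        term = (o * Tensor(w)).sum()
        loss = term if loss is None else loss + term
    loss.backward()

    worst = 0.0
    for p in params:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        fd = np.zeros_like(flat)
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            jp = scalar()
            flat[k] = orig - eps
            jm = scalar()
            flat[k] = orig
            fd[k] = (jp - jm) / (2 * eps)
        denom = np.maximum(np.abs(fd), 1e-6)
        worst = max(worst, float(np.max(np.abs(g.ravel() - fd) / denom)))
    return worst
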