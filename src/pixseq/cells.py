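"""Recurrent cells: peephole LSTM, IndRNN and a plain tanh RNN.

The LSTM follows the peephole form in which the input, forget *and* output
gates all see the previous cell state ``c_{t-1}``:

    i_t = sigma(W_i x_t + U_i h_{t-1} + p_i * c_{t-1} + b_i)
    f_t = sigma(W_f x_t + U_f h_{t-1} + p_f * c_{t-1} + b_f)
    z_t = tanh (W_z x_t + U_z h_{t-1} + b_z)
    c_t = f_t * c_{t-1} + i_t * z_t
    o_t = sigma(W_o x_t + U_o h_{t-1} + p_o * c_{t-1} + b_o)
    h_t = o_t * tanh(c_t)

Peepholes are diagonal (element-wise on the cell state).  Conventional
peephole LSTMs feed ``c_t`` to the output gate; that variant is available via
``peephole_output_current=True``.  Gate activations are logistic sigmoids.

The IndRNN recurrence is element-wise — one recurrent scalar per neuron —
with ReLU activation, so neuron ``n`` sees only its own ``h_{t-1}[n]``:

    h_t = relu(W x_t + u * h_{t-1} + b)
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, parameter

__all__ = ["LstmParams", "IndRnnParams", "RnnParams", "make_cell",
           "lstm_step", "indrnn_step", "rnn_step", "CELL_KINDS"]

CELL_KINDS = ("LSTM", "IndRNN", "RNN")


def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


class LstmParams:
    """Fused-gate peephole LSTM parameters (gate order: i, f, z, o)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 peephole_output_current: bool = False, dtype=np.float64):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.peephole_output_current = peephole_output_current
        self.W = parameter(_glorot(rng, n_in, 4 * n_hidden), dtype)
        self.U = parameter(_glorot(rng, n_hidden, 4 * n_hidden), dtype)
        self.b = parameter(np.zeros(4 * n_hidden), dtype)
        # diagonal peephole weights on the cell state
        self.p_i = parameter(rng.uniform(-0.1, 0.1, n_hidden), dtype)
        self.p_f = parameter(rng.uniform(-0.1, 0.1, n_hidden), dtype)
        self.p_o = parameter(rng.uniform(-0.1, 0.1, n_hidden), dtype)

    def params(self):
        return [self.W, self.U, self.b, self.p_i, self.p_f, self.p_o]

    def zero_state(self, batch: int):
        z = np.zeros((batch, self.n_hidden), dtype=self.W.data.dtype)
        return Tensor(z), Tensor(z.copy())


def lstm_step(p: LstmParams, x_t: Tensor, h_prev: Tensor, c_prev: Tensor):
    """One LSTM step; returns (h_t, c_t).  Shapes: (batch, n_in) -> (batch, H)."""
    H = p.n_hidden
    g = x_t @ p.W + h_prev @ p.U + p.b
    i = (g[:, 0:H] + c_prev * p.p_i).sigmoid()
    f = (g[:, H:2 * H] + c_prev * p.p_f).sigmoid()
    z = g[:, 2 * H:3 * H].tanh()
    c = f * c_prev + i * z
    o_pre = g[:, 3 * H:4 * H] + (c if p.peephole_output_current else c_prev) * p.p_o
    o = o_pre.sigmoid()
    h = o * c.tanh()
    return h, c


class IndRnnParams:
    """Independently recurrent layer: per-neuron scalar recurrence, ReLU."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.W = parameter(_glorot(rng, n_in, n_hidden), dtype)
        self.u = parameter(rng.uniform(0.0, 1.0, n_hidden), dtype)
        self.b = parameter(np.zeros(n_hidden), dtype)

    def params(self):
        return [self.W, self.u, self.b]

    def zero_state(self, batch: int):
        return (Tensor(np.zeros((batch, self.n_hidden), dtype=self.W.data.dtype)),)


def indrnn_step(p: IndRnnParams, x_t: Tensor, h_prev: Tensor) -> Tensor:
    return (x_t @ p.W + p.u * h_prev + p.b).relu()


class RnnParams:
    """Plain fully-connected tanh RNN."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.W = parameter(_glorot(rng, n_in, n_hidden), dtype)
        self.U = parameter(_glorot(rng, n_hidden, n_hidden), dtype)
        self.b = parameter(np.zeros(n_hidden), dtype)

    def params(self):
        return [self.W, self.U, self.b]

    def zero_state(self, batch: int):
        return (Tensor(np.zeros((batch, self.n_hidden), dtype=self.W.data.dtype)),)


def rnn_step(p: RnnParams, x_t: Tensor, h_prev: Tensor) -> Tensor:
    return (x_t @ p.W + h_prev @ p.U + p.b).tanh()


def make_cell(kind: str, n_in: int, n_hidden: int, rng, dtype=np.float64,
              **kwargs):
    """Factory for the encoder-direction cell variants."""
    if kind == "LSTM":
        return LstmParams(n_in, n_hidden, rng, dtype=dtype, **kwargs)
    if kind == "IndRNN":
        return IndRnnParams(n_in, n_hidden, rng, dtype=dtype)
    if kind == "RNN":
        return RnnParams(n_in, n_hidden, rng, dtype=dtype)
    raise ValueError(f"unknown cell kind {kind!r}; choose from {CELL_KINDS}")


def cell_step(p, x_t: Tensor, *state):
    """Uniform step interface: returns (output, new_state_tuple)."""
    if isinstance(p, LstmParams):
        h, c = lstm_step(p, x_t, state[0], state[1])
        return h, (h, c)
    if isinstance(p, IndRnnParams):
        h = indrnn_step(p, x_t, state[0])
        return h, (h,)
    h = rnn_step(p, x_t, state[0])
    return h, (h,)
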