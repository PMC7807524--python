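"""Independent reference implementations used as test oracles.

Everything here is written as plain scalar loops, directly transcribing the
memory-block equations, so that it shares no code path with the vectorized
implementation it checks.
"""

import math

import numpy as np


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def scalar_cell_step(w_il, w_cl, w_hl, w_iphi, w_cphi, w_hphi,
                     w_iw, w_cw, w_hw, w_ic, w_hc,
                     bias_l, bias_phi, bias_c, bias_w,
                     c_prev, h_prev, x, *, output_gate_uses_current=True):
    """One scalar-loop step of the peephole memory block.

    Gate blocks are passed separately: ``w_i*`` are (I, H) input weights,
    ``w_c*`` are (H,) diagonal peepholes, ``w_h*`` are (H, H) recurrent
    weights, and ``w_ic``/``w_hc`` feed the cell input (no peephole).
    Returns (c_new, output).  ``output_gate_uses_current=False`` switches
    the output-gate peephole to the stale cell value — used by a directed
    test to show the two conventions genuinely differ.
    """
    I = len(x)
    H = len(c_prev)
    c_new = [0.0] * H
    out = [0.0] * H
    for j in range(H):
        a_l = bias_l[j]
        a_phi = bias_phi[j]
        a_c = bias_c[j]
        a_w = bias_w[j]
        for i in range(I):
            a_l += w_il[i][j] * x[i]
            a_phi += w_iphi[i][j] * x[i]
            a_c += w_ic[i][j] * x[i]
            a_w += w_iw[i][j] * x[i]
        for h in range(H):
            a_l += w_hl[h][j] * h_prev[h]
            a_phi += w_hphi[h][j] * h_prev[h]
            a_c += w_hc[h][j] * h_prev[h]
            a_w += w_hw[h][j] * h_prev[h]
        a_l += w_cl[j] * c_prev[j]
        a_phi += w_cphi[j] * c_prev[j]
        b_l = sigmoid(a_l)
        b_phi = sigmoid(a_phi)
        c_new[j] = b_phi * c_prev[j] + b_l * math.tanh(a_c)
        peep_c = c_new[j] if output_gate_uses_current else c_prev[j]
        b_w = sigmoid(a_w + w_cw[j] * peep_c)
        out[j] = b_w * math.tanh(c_new[j])
    return np.array(c_new), np.array(out)


def blocks_from_packed(weights):
    """Split a packed LSTMCellWeights into the scalar oracle's gate blocks.

    Packed column order is (input gate, forget gate, cell input, output
    gate); the mapping is fixed by the package's weight layout.
    """
    H = weights.hidden_size
    wx, wh, b = weights.w_x, weights.w_h, weights.bias
    return dict(
        w_il=wx[:, :H], w_iphi=wx[:, H:2 * H], w_ic=wx[:, 2 * H:3 * H],
        w_iw=wx[:, 3 * H:],
        w_hl=wh[:, :H], w_hphi=wh[:, H:2 * H], w_hc=wh[:, 2 * H:3 * H],
        w_hw=wh[:, 3 * H:],
        w_cl=weights.p_in, w_cphi=weights.p_forget, w_cw=weights.p_out,
        bias_l=b[:H], bias_phi=b[H:2 * H], bias_c=b[2 * H:3 * H],
        bias_w=b[3 * H:],
    )


def random_cell(rng, input_size, hidden_size, scale=0.8, with_bias=True):
    """A random packed cell for equivalence testing."""
    from livertrack.lstm import LSTMCellWeights
    H = hidden_size
    return LSTMCellWeights(
        w_x=rng.normal(scale=scale, size=(input_size, 4 * H)),
        w_h=rng.normal(scale=scale, size=(H, 4 * H)),
        p_in=rng.normal(scale=scale, size=H),
        p_forget=rng.normal(scale=scale, size=H),
        p_out=rng.normal(scale=scale, size=H),
        bias=rng.normal(scale=scale, size=4 * H) if with_bias else None,
    )
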