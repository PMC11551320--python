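"""Independent oracles used by the test suite.

These deliberately avoid the package's propagation code paths: the CEST
oracle is a plain forward-Euler integrator of the Bloch-McConnell equations
built directly from the rate-matrix definition, and the rank-correlation
oracle evaluates the classical Spearman formula on explicitly computed
ranks.
"""

import numpy as np

from foldswitch.exchange_core import build_rate_matrix


def euler_cest_profile(model, scheme, observed_state, dt=2e-6, offsets=None):
    """Forward-Euler Bloch-McConnell CEST profile (slow; oracle only)."""
    n = model.n_states
    obs = model.labels.index(observed_state)
    K = build_rate_matrix(model)
    w1 = 2.0 * np.pi * scheme.b1_hz
    rad = scheme.rad_per_ppm
    if offsets is None:
        offsets = np.asarray(scheme.offsets_ppm)
    offsets = np.asarray(offsets, float)

    mats = []
    for off in offsets:
        A = np.kron(K, np.eye(3))
        for i in range(n):
            omega = (model.delta_omega[i] - (off - scheme.carrier_ppm)) * rad
            A[3 * i, 3 * i] -= model.r2[i]
            A[3 * i, 3 * i + 1] += -omega
            A[3 * i + 1, 3 * i] += omega
            A[3 * i + 1, 3 * i + 1] -= model.r2[i]
            A[3 * i + 1, 3 * i + 2] += w1
            A[3 * i + 2, 3 * i + 1] -= w1
            A[3 * i + 2, 3 * i + 2] -= model.r1[i]
        mats.append(A)
    mats = np.stack(mats)

    M = np.zeros((len(offsets), 3 * n))
    M[:, 2::3] = model.populations
    steps = int(round(scheme.t_relax / dt))
    for _ in range(steps):
        M = M + dt * np.einsum("oij,oj->oi", mats, M)
    sat = M[:, 3 * obs + 2]

    # reference: z-block only, same integrator
    Az = K - np.diag(model.r1)
    z = model.populations.copy()
    for _ in range(steps):
        z = z + dt * (Az @ z)
    return sat / z[obs]


def spearman_bruteforce(x, y):
    """Spearman rho via explicit mid-ranks and the Pearson formula."""
    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
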