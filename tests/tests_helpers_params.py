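"""Shared helper: a fixed JointModelParams on the natural scale."""

import numpy as np

from herdsurv import JointModelParams
from herdsurv.io import OUTCOME_KINDS


def make_params(specs, alpha=(0.0, 0.0, 0.0), gamma=(0.0, 0.0), log_h0=None):
    beta = {}
    for k, (b0, scale) in zip(OUTCOME_KINDS, ((28.0, 5.0), (470.0, 30.0), (460.0, 20.0))):
        d = specs[k].dim
        beta[k] = np.r_[b0, np.linspace(scale, -scale / 2, d), 0.5, 1.0, -0.2]
    return JointModelParams(
        beta=beta,
        sigma={"MY": 3.0, "BW": 15.0, "RUM": 60.0},
        D=np.eye(13),
        gamma=np.asarray(gamma, dtype=float),
        alpha=dict(zip(OUTCOME_KINDS, alpha)),
        log_h0=np.full(6, -7.0) if log_h0 is None else np.asarray(log_h0, dtype=float),
        cuts=np.linspace(0.0, 900.0, 7),
    )
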