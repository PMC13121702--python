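"""Delay-embedded inputs on a synthetic sensory-style response.

Stimulus-response recordings from sensory neurons are often modelled with
a short input history.  This example builds a synthetic surrogate — a
Wiener cascade (low-pass filter followed by a static saturation) driven by
a temporally correlated stimulus — and trains a small tanh reservoir whose
input is the stimulus delay-embedded up to lag 5, mirroring how intrinsic
delays are handled without growing the reservoir.
"""

import numpy as np
from scipy.signal import lfilter

from africo.ekf import EKFConfig
from africo.readout import AfricoConfig, africo_train
from africo.reservoir import ESNModel, ReservoirInitSpec, delay_embed, \
    esn_simulate, make_reservoir
from africo.targets import nmse

rng = np.random.default_rng(3)
T_tr, T_val = 1500, 400
stimulus = lfilter([0.3], [1, -0.7], rng.uniform(0, 1, T_tr + T_val))
response = np.tanh(lfilter([0.2, 0.3], [1, -0.6], stimulus)) ** 2

lags = 5
U = delay_embed(stimulus, lags)  # rows [u(k), u(k-1), ..., u(k-5)]
N = 8
model = ESNModel(
    W=make_reservoir(ReservoirInitSpec(N=N, seed=5)),
    W_in=rng.uniform(-1, 1, (N, lags + 1)),
    W_fb=np.zeros((lags + 1, N)),
    activation="tanh",
    feedback_mode="state",
)
trained = africo_train(
    model, U[:T_tr], response[:T_tr], U[T_tr:], response[T_tr:],
    AfricoConfig(ekf=EKFConfig(snr=50), max_degree=3),
)
traj = esn_simulate(trained, U)
print(f"embedded input dimension: {lags + 1} (lag 0..{lags})")
print(f"validation NMSE: {nmse(traj.Y[T_tr:], response[T_tr:]):.4f}")
print(f"readout terms selected: {trained.readout.n_terms}")
print(
    "\nThe delay embedding hands the reservoir a finite stimulus history\n"
    "directly, so an 8-neuron network can capture a saturating filtered\n"
    "response that would otherwise demand a much larger reservoir."
)
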