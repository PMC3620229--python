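"""Firing-rate model of coupled cortical modules.

Each module is a recurrent network of ``N`` rate neurons whose activation
variables :math:`x_i` obey

.. math::

    \\tau \\frac{dx_i}{dt} = -x_i + g \\sum_j J_{ij} r_j
                             + g_{ext} \\sum_k J^{ext}_{ik} r_k,

where the connection terms :math:`J_{ij}` are i.i.d. Gaussian with mean 0 and
variance :math:`1/N` (so about half the connections are excitatory and half
inhibitory), ``g`` scales intra-module coupling and ``g_ext`` scales coupling
between modules.  The firing rate of a neuron is a saturating function of its
activation, bounded below by 0 and above by the maximum rate, equal to the
background rate at zero activation.  The readout used throughout is the
population- and time-averaged rate per module ("activity"), which declines as
inter-module coupling is weakened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RateModelParams",
    "RateWeights",
    "RateState",
    "RateResult",
    "ParameterError",
    "IntegrationError",
    "build_rate_weights",
    "rate_transfer",
    "simulate_rate",
]

#: guard on |x| beyond which the integration is declared divergent
_OVERFLOW_GUARD = 1e6


class ParameterError(ValueError):
    """Raised when a model parameter violates its stated range."""


class IntegrationError(RuntimeError):
    """Raised when the ODE integration diverges."""


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of the firing-rate model (per module).

    Attributes
    ----------
    n_neurons : int
        Neurons per module, ``N``.
    tau_membrane : float
        Membrane time constant in ms.
    g_intra : float
        Intra-module synaptic strength ``g``.
    g_ext : float
        Inter-module synaptic strength ``g_ext``.
    r_background : float
        Background firing rate (normalized units), the rate at zero
        activation.
    r_max : float
        Maximum firing rate (normalized units); rates saturate strictly
        below this value.
    dt : float
        Integration step in ms.
    t_total : float
        Total integration time in ms; the activity readout averages over the
        final third.
    seed : int
        Seed for the initial-condition RNG.
    """

    n_neurons: int = 1000
    tau_membrane: float = 10.0
    g_intra: float = 1.5
    g_ext: float = 0.0
    r_background: float = 0.1
    r_max: float = 1.0
    dt: float = 0.5
    t_total: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ParameterError("n_neurons must be >= 2")
        if self.tau_membrane <= 0:
            raise ParameterError("tau_membrane must be > 0")
        if self.dt <= 0 or self.dt >= self.tau_membrane:
            raise ParameterError("dt must satisfy 0 < dt < tau_membrane")
        if not (0 < self.r_background < self.r_max):
            raise ParameterError("need 0 < r_background < r_max")
        if self.g_intra < 0 or self.g_ext < 0:
            raise ParameterError("g_intra and g_ext must be >= 0")
        if self.t_total <= 0:
            raise ParameterError("t_total must be > 0")

    def replace(self, **kwargs) -> "RateModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RateWeights:
    """Random Gaussian connection weights for a multi-module rate network.

    ``intra[m]`` is the N x N weight block within module ``m``; ``inter[(a, b)]``
    is the block of weights from neurons of module ``b`` onto neurons of
    module ``a``.  All entries are N(0, 1/N); they are scaled at simulation
    time by ``g_intra`` (intra blocks) and ``g_ext`` (inter blocks).
    """

    intra: tuple[np.ndarray, ...]
    inter: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(self.intra)

    @property
    def n_neurons(self) -> int:
        return self.intra[0].shape[0]


@dataclass(frozen=True)
class RateState:
    """Instantaneous state: activations and the rates they imply."""

    activation: np.ndarray  # shape (n_modules, n_neurons)
    rates: np.ndarray  # shape (n_modules, n_neurons)
    time: float


@dataclass(frozen=True)
class RateResult:
    """Outcome of a rate-model run.

    ``mean_rate_trace`` holds the population-mean rate per module at every
    step; ``mean_rate`` is its time average over the final third of the run
    (the measurement window), and ``normalized_rate`` the same divided by
    ``r_max``.
    """

    times: np.ndarray
    mean_rate_trace: np.ndarray  # shape (n_modules, n_steps + 1)
    mean_rate: np.ndarray  # shape (n_modules,)
    normalized_rate: np.ndarray
    final_state: RateState
    params: RateModelParams

    @property
    def overall_mean_rate(self) -> float:
        return float(self.mean_rate.mean())


def build_rate_weights(
    n_neurons: int,
    n_modules: int = 1,
    seed: int = 0,
    inter_fraction: float = 1.0,
    inter_kind: str = "excitatory",
) -> RateWeights:
    """Draw connection weights for ``n_modules`` coupled modules.

    Intra-module blocks are i.i.d. N(0, 1/N) (every ordered pair, including
    self-connections whose effect is O(1/N)), so about half the recurrent
    connections are excitatory and half inhibitory.

    Inter-module blocks model long-range cortico-cortical projections, which
    are excitatory: with ``inter_kind="excitatory"`` (default) every
    cross-module weight is the constant ``1/N``, so at simulation time a
    module receives ``g_ext`` times the mean rate of each other module as a
    common depolarizing drive.  ``inter_kind="gaussian"`` instead draws
    cross-module weights from the same N(0, 1/N) ensemble as the recurrent
    ones.  Either way, cross-module weights may be zeroed with probability
    ``1 - inter_fraction`` so the *number* of inter-module connections can be
    reduced independently of their strength.

    Deterministic for a fixed seed.
    """
    if n_neurons < 2:
        raise ParameterError("n_neurons must be >= 2")
    if n_modules not in (1, 2, 3):
        raise ParameterError("n_modules must be 1, 2 or 3")
    if not (0.0 <= inter_fraction <= 1.0):
        raise ParameterError("inter_fraction must lie in [0, 1]")
    if inter_kind not in ("excitatory", "gaussian"):
        raise ParameterError("inter_kind must be 'excitatory' or 'gaussian'")
    rng = np.random.default_rng(seed)
    sigma = 1.0 / np.sqrt(n_neurons)
    intra = tuple(
        rng.normal(0.0, sigma, size=(n_neurons, n_neurons))
        for _ in range(n_modules)
    )
    inter: dict[tuple[int, int], np.ndarray] = {}
    for a in range(n_modules):
        for b in range(n_modules):
            if a == b:
                continue
            if inter_kind == "gaussian":
                block = rng.normal(0.0, sigma, size=(n_neurons, n_neurons))
            else:
                block = np.full((n_neurons, n_neurons), 1.0 / n_neurons)
            if inter_fraction < 1.0:
                mask = rng.random((n_neurons, n_neurons)) < inter_fraction
                block = block * mask
            inter[(a, b)] = block
    return RateWeights(intra=intra, inter=inter)


def rate_transfer(x, r0: float = 0.1, rmax: float = 1.0):
    """Saturating rate function R(x).

    ``R(x) = r0 + (rmax - r0) tanh(x / (rmax - r0))`` for x >= 0 and
    ``R(x) = r0 + r0 tanh(x / r0)`` for x < 0: equal to the background rate
    at x = 0, saturating at ``rmax`` for large positive and at 0 for large
    negative activation, continuous with unit slope at the origin, strictly
    increasing, with range (0, rmax).
    """
    if not (0 < r0 < rmax):
        raise ParameterError("need 0 < r0 < rmax")
    x = np.asarray(x)
    up = rmax - r0
    return np.where(
        x >= 0,
        r0 + up * np.tanh(x / up),
        r0 + r0 * np.tanh(x / r0),
    )


def _drive(weights: RateWeights, rates: np.ndarray, g: float, g_ext: float) -> np.ndarray:
    """Synaptic input per neuron; ``rates`` has shape (M, N[, K])."""
    out = np.empty_like(rates)
    for m in range(weights.n_modules):
        acc = g * (weights.intra[m] @ rates[m])
        for b in range(weights.n_modules):
            if b != m and (m, b) in weights.inter:
                acc += g_ext * (weights.inter[(m, b)] @ rates[b])
        out[m] = acc
    return out


def simulate_rate(
    params: RateModelParams,
    weights: RateWeights,
    method: str = "rk4",
    record_trace: bool = True,
) -> RateResult:
    """Integrate the rate equations to a statistically steady state.

    Activations start from i.i.d. N(0, 1) values (seeded); the equations are
    advanced with a fixed-step integrator (classical RK4 by default, forward
    Euler as a cross-check) and the population-mean rate of each module is
    averaged over the final third of the run.

    Raises
    ------
    IntegrationError
        If any activation exceeds the overflow guard.
    """
    if weights.n_neurons != params.n_neurons:
        raise ParameterError(
            f"weights built for N={weights.n_neurons} but params have "
            f"N={params.n_neurons}"
        )
    if method not in ("rk4", "euler"):
        raise ParameterError("method must be 'rk4' or 'euler'")

    M, N = weights.n_modules, params.n_neurons
    tau, dt = params.tau_membrane, params.dt
    g, g_ext = params.g_intra, params.g_ext
    r0, rmax = params.r_background, params.r_max
    n_steps = int(round(params.t_total / dt))

    rng = np.random.default_rng(params.seed)
    x = rng.standard_normal((M, N))

    def deriv(xv: np.ndarray) -> np.ndarray:
        r = rate_transfer(xv, r0, rmax)
        return (-xv + _drive(weights, r, g, g_ext)) / tau

    times = np.arange(n_steps + 1) * dt
    trace = np.empty((M, n_steps + 1)) if record_trace else None
    mean_r = rate_transfer(x, r0, rmax).mean(axis=1)
    if record_trace:
        trace[:, 0] = mean_r

    # running sum for the measurement window (final third of the run)
    t_measure_start = 2.0 * params.t_total / 3.0
    acc = np.zeros(M)
    n_acc = 0

    for k in range(1, n_steps + 1):
        if method == "rk4":
            k1 = deriv(x)
            k2 = deriv(x + 0.5 * dt * k1)
            k3 = deriv(x + 0.5 * dt * k2)
            k4 = deriv(x + dt * k3)
            x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            x = x + dt * deriv(x)
        if not np.isfinite(x).all() or np.abs(x).max() > _OVERFLOW_GUARD:
            raise IntegrationError(
                f"activation diverged at t={k * dt:.1f} ms "
                f"(g={g}, g_ext={g_ext}, dt={dt})"
            )
        mean_r = rate_transfer(x, r0, rmax).mean(axis=1)
        if record_trace:
            trace[:, k] = mean_r
        if k * dt >= t_measure_start:
            acc += mean_r
            n_acc += 1

    mean_rate = acc / n_acc
    _check_stationarity(trace, times, t_measure_start, mean_rate)

    rates = rate_transfer(x, r0, rmax)
    final_state = RateState(activation=x, rates=rates, time=n_steps * dt)
    return RateResult(
        times=times,
        mean_rate_trace=trace if record_trace else np.empty((M, 0)),
        mean_rate=mean_rate,
        normalized_rate=mean_rate / rmax,
        final_state=final_state,
        params=params,
    )


def _check_stationarity(trace, times, t_start, mean_rate) -> None:
    """Warn if the two halves of the measurement window disagree by > 5%."""
    if trace is None:
        return
    sel = times >= t_start
    window = trace[:, sel]
    half = window.shape[1] // 2
    if half < 2:
        return
    a = window[:, :half].mean(axis=1)
    b = window[:, half:].mean(axis=1)
    drift = np.abs(a - b) / np.maximum(np.abs(mean_rate), 1e-12)
    if drift.max() > 0.05:
        warnings.warn(
            f"measurement window may be non-stationary "
            f"(half-window drift {drift.max():.1%})",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_rate_batch(
    params: RateModelParams,
    weights: RateWeights,
    g_values: np.ndarray,
    g_ext_values: np.ndarray,
    dtype=np.float64,
) -> np.ndarray:
    """Integrate many (g, g_ext) conditions sharing one weight draw.

    The conditions share the random connectivity and the initial state, so a
    coupling sweep isolates the effect of the swept coupling from weight
    sampling noise.  Returns the per-module mean rate over the measurement
    window, shape ``(n_conditions, n_modules)``.

    This is the throughput path used by sweeps: all conditions advance in one
    set of matrix products per integrator stage.
    """
    g_values = np.asarray(g_values, dtype=float)
    g_ext_values = np.asarray(g_ext_values, dtype=float)
    if g_values.shape != g_ext_values.shape:
        raise ParameterError("g_values and g_ext_values must have equal length")
    M, N, K = weights.n_modules, params.n_neurons, g_values.size
    tau, dt = params.tau_membrane, params.dt
    r0, rmax = params.r_background, params.r_max
    n_steps = int(round(params.t_total / dt))

    intra = [np.ascontiguousarray(w, dtype=dtype) for w in weights.intra]
    inter = {k: np.ascontiguousarray(v, dtype=dtype) for k, v in weights.inter.items()}
    gv = g_values.astype(dtype)[np.newaxis, :]
    gx = g_ext_values.astype(dtype)[np.newaxis, :]

    rng = np.random.default_rng(params.seed)
    x = np.repeat(
        rng.standard_normal((M, N, 1)), K, axis=2
    ).astype(dtype)

    up = dtype(rmax - r0)

    def transfer(xv):
        return np.where(
            xv >= 0,
            r0 + up * np.tanh(xv / up),
            r0 + r0 * np.tanh(xv / dtype(r0)),
        )

    def deriv(xv):
        r = transfer(xv)
        out = np.empty_like(xv)
        for m in range(M):
            acc = gv * (intra[m] @ r[m])
            for b in range(M):
                if b != m and (m, b) in inter:
                    acc += gx * (inter[(m, b)] @ r[b])
            out[m] = (-xv[m] + acc) / tau
        return out

    t_measure_start = 2.0 * params.t_total / 3.0
    acc = np.zeros((M, K))
    n_acc = 0
    for k in range(1, n_steps + 1):
        k1 = deriv(x)
        k2 = deriv(x + (0.5 * dt) * k1)
        k3 = deriv(x + (0.5 * dt) * k2)
        k4 = deriv(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(x).all() or np.abs(x).max() > _OVERFLOW_GUARD:
            raise IntegrationError(f"activation diverged at t={k * dt:.1f} ms")
        if k * dt >= t_measure_start:
            acc += transfer(x).mean(axis=1)
            n_acc += 1
    return (acc / n_acc).T.astype(float)
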