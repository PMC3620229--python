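"""Coupling-sweep experiments: activity decline under inter-modular disconnection.

Orchestrates the study sweeps for both network models:

* rate model, two coupled modules: activity vs inter-module coupling
  strength ``g_ext`` swept from the fully-coupled baseline down to zero;
* spiking model, two or three modules: activity vs inter-module connection
  fraction ``F_ext`` (random deletion of cross-module synapses) or coupling
  strength ``S_ext`` (uniform efficacy loss), plus the joint sweep in which
  intra- and inter-module connections are reduced by the same fraction;
* size-convergence runs repeating the fraction sweep at several module
  sizes with the per-module total coupling K = N*F*S held fixed.

Each sweep reports per-module mean activity, normalized by its value at the
fully-coupled baseline, averaged across seeds, together with the percentage
decreases at a 24% reduction of the swept variable and at full removal —
the quantities that map onto white-matter pathology (a 24% loss of
long-range connectivity) and surgical/functional isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import rate_network as rn
from . import spiking_network as sn
from .io_config import derive_seed

__all__ = [
    "SweepSpec",
    "ActivityCurve",
    "PairedCurves",
    "DecreaseSummary",
    "run_sweep",
    "compare_fraction_vs_strength",
    "joint_reduction_sweep",
    "summarize_decreases",
    "two_module_strength_sweep_spec",
    "multi_module_fraction_sweep_spec",
    "scaled_coupling_strength",
    "size_convergence_curves",
    "REFERENCE_K_INTRA",
]

#: per-module total recurrent coupling K = N * F * S of the reference
#: multi-module configuration (3267 neurons, F = 0.3, S = 0.00075); held
#: fixed when module size is scaled, mirroring the strength re-calibration
#: applied when network size changes
REFERENCE_K_INTRA = 3267 * 0.3 * 0.00075


@dataclass(frozen=True)
class SweepSpec:
    """Specification of one coupling sweep.

    ``grid`` runs in descending order from the fully-coupled baseline to 0.
    For ``swept_variable='joint_f_and_f_ext'`` the grid is the *remaining*
    fraction of connections (1 -> baseline, 0 -> none).
    """

    model: str  # "rate" | "spiking"
    swept_variable: str  # "g_ext" | "f_ext" | "s_ext" | "joint_f_and_f_ext"
    grid: tuple[float, ...]
    n_modules: int
    base_params: object
    n_seeds: int = 5
    root_seed: int = 0
    protocol: sn.SimulationProtocol | None = None
    inter_excitatory_only: bool = False
    exact_deletion: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("rate", "spiking"):
            raise rn.ParameterError("model must be 'rate' or 'spiking'")
        valid = {"g_ext", "f_ext", "s_ext", "joint_f_and_f_ext"}
        if self.swept_variable not in valid:
            raise rn.ParameterError(f"swept_variable must be one of {valid}")
        grid = np.asarray(self.grid, dtype=float)
        if grid.size < 1 or np.any(np.diff(grid) > 0):
            raise rn.ParameterError("grid must be non-increasing")
        if grid.min() < 0:
            raise rn.ParameterError("grid values must be >= 0")
        if self.swept_variable in ("f_ext", "joint_f_and_f_ext"):
            hi = 1.0 if self.swept_variable == "joint_f_and_f_ext" else 1.0
            if grid.max() > hi:
                raise rn.ParameterError("fraction grid values must be <= 1")
        if self.n_seeds < 1:
            raise rn.ParameterError("n_seeds must be >= 1")

    @property
    def baseline(self) -> float:
        return float(self.grid[0])


@dataclass(frozen=True)
class ActivityCurve:
    """Normalized module activity along a coupling sweep.

    ``activity`` is the raw across-seed mean per (grid point, module);
    ``normalized`` divides each module's trace by its baseline (first grid
    point) value, so the baseline row is 1 by construction.  ``se`` is the
    across-seed standard error of the normalized overall activity.
    """

    swept_values: np.ndarray  # (n_points,)
    activity: np.ndarray  # (n_points, n_modules)
    normalized: np.ndarray  # (n_points, n_modules)
    se: np.ndarray  # (n_points,)
    swept_variable: str = ""
    model: str = ""
    per_seed_overall: np.ndarray | None = None  # (n_points, n_seeds)

    @property
    def n_modules(self) -> int:
        return self.activity.shape[1]

    @property
    def overall_normalized(self) -> np.ndarray:
        """Across-module mean activity normalized by its baseline value."""
        overall = self.activity.mean(axis=1)
        return overall / overall[0]

    @property
    def normalization(self) -> np.ndarray:
        """Baseline (maximum) activity per module."""
        return self.activity[0]


@dataclass(frozen=True)
class PairedCurves:
    """Two sweeps sharing a fractional grid, plus their pointwise gap."""

    curve_a: ActivityCurve
    curve_b: ActivityCurve
    label_a: str
    label_b: str

    @property
    def max_pointwise_gap(self) -> float:
        return float(
            np.abs(
                self.curve_a.overall_normalized - self.curve_b.overall_normalized
            ).max()
        )

    def half_loss_fraction(self, which: str = "a") -> float:
        """Reduction fraction at which activity first drops to 50% of
        baseline (linear interpolation; inf if never reached)."""
        curve = self.curve_a if which == "a" else self.curve_b
        frac = 1.0 - curve.swept_values / curve.swept_values[0]
        act = curve.overall_normalized
        for k in range(1, act.size):
            if act[k] <= 0.5:
                if act[k] == act[k - 1]:
                    return float(frac[k])
                w = (act[k - 1] - 0.5) / (act[k - 1] - act[k])
                return float(frac[k - 1] + w * (frac[k] - frac[k - 1]))
        return float("inf")


@dataclass(frozen=True)
class DecreaseSummary:
    """Percentage decreases of activity along a sweep."""

    pct_at_24: float
    pct_at_full: float
    reduction: float = 0.24

    def __post_init__(self) -> None:
        if not (self.pct_at_24 <= self.pct_at_full + 1e-9):
            warnings.warn(
                "decrease at the partial reduction exceeds the full-removal "
                "decrease: curve is non-monotone",
                RuntimeWarning,
                stacklevel=2,
            )


def _rate_sweep_one_seed(spec: SweepSpec, seed_index: int) -> np.ndarray:
    params: rn.RateModelParams = spec.base_params
    wseed = derive_seed(spec.root_seed, "rate-weights", seed_index)
    iseed = derive_seed(spec.root_seed, "rate-init", seed_index)
    weights = rn.build_rate_weights(
        params.n_neurons, spec.n_modules, seed=wseed
    )
    g_vals = np.full(len(spec.grid), params.g_intra)
    gx_vals = np.asarray(spec.grid, dtype=float)
    return rn.simulate_rate_batch(
        params.replace(seed=iseed), weights, g_vals, gx_vals
    )  # (n_points, n_modules)


def _spiking_sweep_one_seed(spec: SweepSpec, seed_index: int) -> np.ndarray:
    params: sn.SpikingModelParams = spec.base_params
    protocol = spec.protocol or sn.SimulationProtocol()
    gseed = derive_seed(spec.root_seed, "graph", seed_index)
    base = build_baseline_graph(spec, gseed)
    out = np.empty((len(spec.grid), spec.n_modules))
    for k, value in enumerate(spec.grid):
        graph = _apply_sweep_value(spec, base, value, seed_index, k)
        rseed = derive_seed(spec.root_seed, "run", seed_index, k)
        try:
            res = sn.run_protocol(params, graph, protocol=protocol, seed=rseed)
        except sn.RegimeError as err:
            raise sn.RegimeError(
                f"sweep aborted at {spec.swept_variable}={value} "
                f"(seed index {seed_index}): {err}"
            ) from err
        out[k] = res.module_rates
    return out


def build_baseline_graph(spec: SweepSpec, gseed: int) -> sn.SynapticGraph:
    """Fully-coupled graph from which swept variants are derived."""
    params: sn.SpikingModelParams = spec.base_params
    if spec.swept_variable in ("f_ext", "s_ext", "joint_f_and_f_ext"):
        baseline_f_ext = (
            params.f_ext if params.f_ext > 0 else params.f_intra
        )
        baseline_s_ext = (
            params.s_ext if params.s_ext > 0 else params.s_intra
        )
        params = params.replace(f_ext=baseline_f_ext, s_ext=baseline_s_ext)
    return sn.build_synaptic_graph(
        params,
        spec.n_modules,
        seed=gseed,
        inter_excitatory_only=spec.inter_excitatory_only,
    )


def _apply_sweep_value(
    spec: SweepSpec,
    base: sn.SynapticGraph,
    value: float,
    seed_index: int,
    point_index: int,
) -> sn.SynapticGraph:
    dseed = derive_seed(spec.root_seed, "delete", seed_index, point_index)
    if spec.swept_variable == "f_ext":
        frac = 1.0 - value / spec.baseline
        return sn.delete_edges(
            base, frac, seed=dseed, which="inter", exact=spec.exact_deletion
        )
    if spec.swept_variable == "s_ext":
        return sn.scale_inter_strength(base, value / spec.baseline)
    if spec.swept_variable == "joint_f_and_f_ext":
        frac = 1.0 - value / spec.baseline
        return sn.delete_edges(
            base, frac, seed=dseed, which="all", exact=spec.exact_deletion
        )
    raise rn.ParameterError(
        f"swept_variable {spec.swept_variable} is not a spiking sweep"
    )


def run_sweep(spec: SweepSpec) -> ActivityCurve:
    """Run one simulation per (grid point, seed) and aggregate.

    Per-point seeds are derived deterministically from ``spec.root_seed``.
    Modules are reported separately; in symmetric topologies their curves
    coincide up to seed noise.
    """
    runner = (
        _rate_sweep_one_seed if spec.model == "rate" else _spiking_sweep_one_seed
    )
    per_seed = np.stack(
        [runner(spec, s) for s in range(spec.n_seeds)]
    )  # (n_seeds, n_points, n_modules)
    activity = per_seed.mean(axis=0)
    normalized = activity / activity[0]
    overall = per_seed.mean(axis=2)  # (n_seeds, n_points)
    overall_norm = overall / overall[:, :1]
    se = (
        overall_norm.std(axis=0, ddof=1) / np.sqrt(spec.n_seeds)
        if spec.n_seeds > 1
        else np.zeros(len(spec.grid))
    )
    return ActivityCurve(
        swept_values=np.asarray(spec.grid, dtype=float),
        activity=activity,
        normalized=normalized,
        se=se,
        swept_variable=spec.swept_variable,
        model=spec.model,
        per_seed_overall=overall.T,
    )


def compare_fraction_vs_strength(spec: SweepSpec) -> PairedCurves:
    """Reduce the *number* vs the *strength* of inter-module connections.

    The two sweeps share the fractional grid derived from ``spec.grid``
    (interpreted as remaining fraction of the baseline).  The model predicts
    no difference: deleting a fraction of cross-module synapses and scaling
    all their strengths by the same fraction remove the same total coupling.
    """
    if spec.n_modules < 2:
        raise rn.ParameterError("need at least two modules to compare")
    params: sn.SpikingModelParams = spec.base_params
    f_base = params.f_ext if params.f_ext > 0 else params.f_intra
    s_base = params.s_ext if params.s_ext > 0 else params.s_intra
    fracs = np.asarray(spec.grid, dtype=float)
    spec_f = SweepSpec(
        model="spiking",
        swept_variable="f_ext",
        grid=tuple(fracs * f_base),
        n_modules=spec.n_modules,
        base_params=params,
        n_seeds=spec.n_seeds,
        root_seed=spec.root_seed,
        protocol=spec.protocol,
    )
    spec_s = SweepSpec(
        model="spiking",
        swept_variable="s_ext",
        grid=tuple(fracs * s_base),
        n_modules=spec.n_modules,
        base_params=params,
        n_seeds=spec.n_seeds,
        root_seed=spec.root_seed,
        protocol=spec.protocol,
    )
    return PairedCurves(
        curve_a=run_sweep(spec_f),
        curve_b=run_sweep(spec_s),
        label_a="fraction reduced",
        label_b="strength reduced",
    )


def joint_reduction_sweep(spec: SweepSpec) -> PairedCurves:
    """Inter-module-only vs joint intra+inter connection loss.

    Curve A deletes only cross-module synapses; curve B deletes every
    synapse (within and across modules) with the same probability.  The
    joint loss required to halve activity is far smaller than the
    inter-module-only loss, which must be complete.
    """
    params: sn.SpikingModelParams = spec.base_params
    f_base = params.f_ext if params.f_ext > 0 else params.f_intra
    fracs = np.asarray(spec.grid, dtype=float)
    spec_a = SweepSpec(
        model="spiking",
        swept_variable="f_ext",
        grid=tuple(fracs * f_base),
        n_modules=spec.n_modules,
        base_params=params,
        n_seeds=spec.n_seeds,
        root_seed=spec.root_seed,
        protocol=spec.protocol,
    )
    spec_b = SweepSpec(
        model="spiking",
        swept_variable="joint_f_and_f_ext",
        grid=tuple(fracs),
        n_modules=spec.n_modules,
        base_params=params,
        n_seeds=spec.n_seeds,
        root_seed=spec.root_seed,
        protocol=spec.protocol,
    )
    return PairedCurves(
        curve_a=run_sweep(spec_a),
        curve_b=run_sweep(spec_b),
        label_a="inter-module only",
        label_b="joint intra+inter",
    )


def summarize_decreases(
    curve: ActivityCurve, reduction: float = 0.24
) -> DecreaseSummary:
    """Percentage decreases at a partial reduction and at full removal.

    The partial point (default 24% below baseline) is read off the grid
    exactly when present, otherwise linearly interpolated.  A non-monotone
    curve beyond ~1.5 standard errors triggers a warning, not an error.
    """
    x = curve.swept_values
    a = curve.overall_normalized
    target = (1.0 - reduction) * x[0]
    at_partial = float(np.interp(target, x[::-1], a[::-1]))
    at_full = float(a[-1])
    if x[-1] > 1e-12 * max(x[0], 1.0):
        warnings.warn(
            "curve does not reach swept value 0; full-removal decrease is "
            "taken at the smallest grid point",
            RuntimeWarning,
            stacklevel=2,
        )
    rises = np.diff(a)
    tol = 1.5 * np.max(curve.se) if curve.se.size else 0.0
    if np.any(rises > max(tol, 1e-9)):
        warnings.warn(
            "activity curve is non-monotone beyond seed noise",
            RuntimeWarning,
            stacklevel=2,
        )
    return DecreaseSummary(
        pct_at_24=100.0 * (1.0 - at_partial),
        pct_at_full=100.0 * (1.0 - at_full),
        reduction=reduction,
    )


# ---------------------------------------------------------------------------
# canonical study configurations
# ---------------------------------------------------------------------------

def two_module_strength_sweep_spec(
    g: float = 1.5,
    n_neurons: int = 1000,
    n_seeds: int = 5,
    root_seed: int = 0,
    grid: tuple[float, ...] | None = None,
    t_total: float = 2000.0,
) -> SweepSpec:
    """Rate model, two coupled modules, ``g_ext`` swept from the unit
    fully-coupled baseline down to zero (the 24%-reduced point is on the
    grid)."""
    if grid is None:
        grid = (1.0, 0.9, 0.76, 0.6, 0.45, 0.3, 0.15, 0.0)
    params = rn.RateModelParams(
        n_neurons=n_neurons, g_intra=g, t_total=t_total
    )
    return SweepSpec(
        model="rate",
        swept_variable="g_ext",
        grid=grid,
        n_modules=2,
        base_params=params,
        n_seeds=n_seeds,
        root_seed=root_seed,
    )


def two_module_strength_decreases(
    g_values: tuple[float, ...] = (1.5, 2.0, 2.5),
    n_neurons: int = 1000,
    n_seeds: int = 5,
    root_seed: int = 0,
    t_total: float = 1500.0,
    grid: tuple[float, ...] = (1.0, 0.76, 0.0),
    dtype=np.float32,
) -> dict[float, DecreaseSummary]:
    """Activity decreases of two coupled rate modules for several ``g``.

    All (g, g_ext) conditions of one seed share a weight draw and initial
    state and are integrated together (one batched run per seed), so the
    comparison across coupling levels is paired.  Returns, per ``g``, the
    percentage decreases at a 24% coupling-strength reduction and at full
    decoupling, averaged over seeds.
    """
    g_flat, gx_flat = [], []
    for g in g_values:
        for x in grid:
            g_flat.append(g)
            gx_flat.append(x)
    per_seed = []
    for s in range(n_seeds):
        wseed = derive_seed(root_seed, "rate-weights", s)
        iseed = derive_seed(root_seed, "rate-init", s)
        params = rn.RateModelParams(
            n_neurons=n_neurons, t_total=t_total, seed=iseed
        )
        weights = rn.build_rate_weights(n_neurons, 2, seed=wseed)
        res = rn.simulate_rate_batch(
            params, weights, np.array(g_flat), np.array(gx_flat), dtype=dtype
        )
        per_seed.append(res.mean(axis=1))  # overall mean across modules
    overall = np.mean(per_seed, axis=0)
    out: dict[float, DecreaseSummary] = {}
    n_grid = len(grid)
    for k, g in enumerate(g_values):
        block = overall[k * n_grid : (k + 1) * n_grid]
        curve = ActivityCurve(
            swept_values=np.asarray(grid, dtype=float),
            activity=block[:, None],
            normalized=(block / block[0])[:, None],
            se=np.zeros(n_grid),
            swept_variable="g_ext",
            model="rate",
        )
        out[g] = summarize_decreases(curve)
    return out


def scaled_coupling_strength(
    n_per_module: int, f: float, k_intra: float = REFERENCE_K_INTRA
) -> float:
    """Coupling strength S keeping the per-module total coupling
    K = N*F*S fixed when the module size or connection fraction changes
    (the strength re-calibration applied across network sizes)."""
    return k_intra / (n_per_module * f)


def multi_module_fraction_sweep_spec(
    n_modules: int = 3,
    n_per_module: int = 3267,
    f: float = 0.3,
    s: float | None = None,
    n_seeds: int = 5,
    root_seed: int = 0,
    grid_fractions: tuple[float, ...] = (1.0, 0.9, 0.76, 0.6, 0.4, 0.2, 0.0),
    protocol: sn.SimulationProtocol | None = None,
) -> SweepSpec:
    """Spiking model: ``F_ext`` swept down from the ``F_ext = F`` baseline.

    With the default size the per-module coupling matches the reference
    configuration (3267 neurons per module, F = 0.3, S = 0.00075); for other
    sizes S is re-derived so K = N*F*S is unchanged.
    """
    if s is None:
        s = scaled_coupling_strength(n_per_module, f)
    n_exc = int(round(0.8 * n_per_module))
    params = sn.SpikingModelParams(
        n_excitatory=n_exc,
        n_inhibitory=n_per_module - n_exc,
        s_intra=s,
        f_intra=f,
        s_ext=s,
        f_ext=f,
    )
    return SweepSpec(
        model="spiking",
        swept_variable="f_ext",
        grid=tuple(np.asarray(grid_fractions) * f),
        n_modules=n_modules,
        base_params=params,
        n_seeds=n_seeds,
        root_seed=root_seed,
        protocol=protocol,
    )


def size_convergence_curves(
    sizes: tuple[int, ...] = (900, 2450, 3267),
    f: float = 0.2,
    n_modules: int = 2,
    n_seeds: int = 3,
    root_seed: int = 0,
    grid_fractions: tuple[float, ...] = (1.0, 0.76, 0.5, 0.25, 0.0),
) -> dict[int, ActivityCurve]:
    """Repeat the fraction sweep at several module sizes (K held fixed).

    The normalized curves converge as the module size grows; the maximum
    pointwise gap between successive sizes shrinks.
    """
    out: dict[int, ActivityCurve] = {}
    for n in sizes:
        spec = multi_module_fraction_sweep_spec(
            n_modules=n_modules,
            n_per_module=n,
            f=f,
            n_seeds=n_seeds,
            root_seed=root_seed,
            grid_fractions=grid_fractions,
        )
        out[n] = run_sweep(spec)
    return out
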