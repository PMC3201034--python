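"""Scaled local sensitivity of the 49 reaction fluxes to the 76 rate constants.

For a flux output Y and a rate constant X the scaled (dimensionless)
local sensitivity is

    S = (X / Y) * dY/dX,

estimated by a central finite difference with a relative perturbation
``delta`` (default 1%): the model is re-integrated at X(1 ± delta) and
Y is, under the default protocol, the flux averaged over the last
complete post-transient cycle of the basal limit cycle (cycle
averaging makes Y insensitive to the phase of the comparison window;
a ``"peak"`` protocol using the cycle maximum is available as an
alternative).  If a perturbation kills the oscillation, Y is taken
from the steady state instead and the column is flagged.

Structural zeros: a constant that appears neither in a flux's rate
law nor anywhere upstream in the dynamical dependency graph cannot
move that flux; those entries are fixed at 0 exactly (and the
reachability relation itself is exposed for independent checking).
The full matrix is 49 x 76 = 3724 entries; the two pure scale factors
are never perturbed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FLUXES, FLUX_IDS, SPECIES, STOICHIOMETRY, make_flux_evaluator
from .oscillation import _refined_peak_times
from .parameters import SENSITIVITY_PARAMS, ParameterSet
from .simulate import SimulationSettings, integrate

__all__ = [
    "SensitivityMatrix",
    "parameter_flux_reachability",
    "cycle_averaged_fluxes",
    "static_flux_sensitivity",
    "flux_sensitivity",
    "sensitivity_matrix",
    "significance_counts",
]

#: integration window for flux evaluation: 200 h of transient decay
#: plus several cycles from which the last complete one is averaged
_SENS_SETTINGS = SimulationSettings(t_end=300.0, transient=200.0, output_step=0.05)
_REFERENCE_SPECIES = "M_B"


def _species_dependency_edges() -> dict[str, set[str]]:
    """j -> set of species whose rate equation contains j."""
    flux_species = {f.id: set(f.species) for f in FLUXES}
    influences: dict[str, set[str]] = {s: set() for s in SPECIES}
    for target, incident in STOICHIOMETRY.items():
        for fid in incident:
            for src in flux_species[fid]:
                influences[src].add(target)
    return influences


def _reach(influences: dict[str, set[str]], seeds: set[str]) -> set[str]:
    seen = set(seeds)
    frontier = list(seeds)
    while frontier:
        s = frontier.pop()
        for t in influences[s]:
            if t not in seen:
                seen.add(t)
                frontier.append(t)
    return seen


def parameter_flux_reachability() -> pd.DataFrame:
    """Boolean 49 x 76 table: can this constant move this flux at all?

    A constant reaches a flux if it appears in the flux's own rate law,
    or if it appears in the rate equation of a species from which some
    species of the flux's rate law is reachable in the dependency graph
    of the dynamical system.  Derived purely from the symbolic term
    registry, independently of any integration.
    """
    influences = _species_dependency_edges()
    # species whose rate equation contains parameter p
    param_direct: dict[str, set[str]] = {p: set() for p in SENSITIVITY_PARAMS}
    flux_params = {f.id: set(f.params) for f in FLUXES}
    for sp, incident in STOICHIOMETRY.items():
        for fid in incident:
            for p in flux_params[fid]:
                param_direct[p].add(sp)
    # species affected by p (directly or via the closure)
    param_species = {p: _reach(influences, seeds) for p, seeds in param_direct.items()}

    table = np.zeros((len(FLUXES), len(SENSITIVITY_PARAMS)), dtype=bool)
    for i, f in enumerate(FLUXES):
        for j, p in enumerate(SENSITIVITY_PARAMS):
            table[i, j] = (p in f.params) or any(
                s in param_species[p] for s in f.species
            )
    return pd.DataFrame(table, index=list(FLUX_IDS), columns=list(SENSITIVITY_PARAMS))


def cycle_averaged_fluxes(
    params: ParameterSet,
    settings: SimulationSettings = _SENS_SETTINGS,
    protocol: str = "cycle_average",
) -> tuple[np.ndarray, bool]:
    """The 49 fluxes averaged over one post-transient cycle.

    Returns ``(Y, oscillatory)``.  The averaging window spans the
    complete post-transient cycles of the reference species (Bmal1
    mRNA), first to last detected peak; if fewer than two peaks remain
    — oscillation death — the fluxes of the final (steady) state are
    returned with ``oscillatory=False``.
    Under ``protocol="peak"`` the cycle maximum replaces the average.
    """
    if protocol not in ("cycle_average", "peak"):
        raise ValueError("protocol must be 'cycle_average' or 'peak'")
    traj = integrate(params, settings)
    tail = traj.after(settings.transient)
    evaluate = make_flux_evaluator(params)
    peak_times = _refined_peak_times(tail.t, tail[_REFERENCE_SPECIES])
    span = tail[_REFERENCE_SPECIES].max() - tail[_REFERENCE_SPECIES].min()
    scale = max(abs(float(tail[_REFERENCE_SPECIES].mean())), 1e-6)
    if peak_times.size < 2 or span < 1e-4 * scale:
        return evaluate(tail.y[-1]), False
    # integer number of cycles: first to last post-transient peak; using
    # several cycles shrinks the window-endpoint error of the average
    t0, t1 = peak_times[0], peak_times[-1]
    window = (tail.t >= t0) & (tail.t <= t1)
    t_win = tail.t[window]
    v = evaluate(tail.y[window].T)  # (49, n)
    if protocol == "peak":
        return v.max(axis=1), True
    return np.trapezoid(v, t_win, axis=1) / (t_win[-1] - t_win[0]), True


@dataclass(frozen=True)
class SensitivityMatrix:
    """49 x 76 scaled local sensitivities plus evaluation metadata."""

    values: pd.DataFrame            # rows: flux ids, columns: constants
    delta: float
    protocol: str
    params: ParameterSet
    oscillation_death: tuple[str, ...] = ()   # constants whose perturbation
                                              # killed the oscillation
    structural_mask: bool = True

    def __post_init__(self):
        assert self.values.shape == (49, 76), "sensitivity matrix must be 49 x 76"

    def __getitem__(self, key: tuple[str, str]) -> float:
        flux, param = key
        return float(self.values.at[flux, param])

    def to_csv(self, path) -> None:
        labelled = self.values.copy()
        labelled.index = [f"{f.id}: {f.name}" for f in FLUXES]
        labelled.to_csv(path, float_format="%.6g")


def _column(
    params: ParameterSet,
    name: str,
    delta: float,
    y_base: np.ndarray,
    protocol: str,
) -> tuple[np.ndarray, bool]:
    """Scaled sensitivities of all 49 fluxes to one constant."""
    x = params[name]
    if x == 0.0 or np.all(y_base == 0):
        return np.zeros(len(FLUXES)), False
    y_hi, osc_hi = cycle_averaged_fluxes(params.replace(**{name: x * (1 + delta)}),
                                         protocol=protocol)
    y_lo, osc_lo = cycle_averaged_fluxes(params.replace(**{name: x * (1 - delta)}),
                                         protocol=protocol)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (y_hi - y_lo) / (2.0 * delta * y_base)
    s[~np.isfinite(s)] = 0.0
    s[y_base == 0.0] = 0.0
    return s, not (osc_hi and osc_lo)


def static_flux_sensitivity(
    state,
    params: ParameterSet,
    flux: str,
    parameter: str,
    delta: float = 0.01,
) -> float:
    """Scaled sensitivity of a flux's rate law at one frozen state.

    No dynamics: the state is held fixed and only the rate law is
    re-evaluated at X(1 ± delta).  For a mass-action flux k·[X] the
    result is +1 exactly; for a Michaelis–Menten flux V·[X]/(K+[X])
    it is +1 w.r.t. V and −K/(K+[X]) + O(delta²) w.r.t. K.  Used as
    the analytic cross-check of the finite-difference machinery.
    """
    if flux not in FLUX_IDS:
        raise KeyError(f"unknown flux {flux!r}")
    i = FLUX_IDS.index(flux)
    x = params[parameter]
    y0 = float(make_flux_evaluator(params)(np.asarray(state, float))[i])
    if x == 0.0 or y0 == 0.0:
        return 0.0
    f = np.asarray(state, float)
    y_hi = float(make_flux_evaluator(
        params.replace(**{parameter: x * (1 + delta)}))(f)[i])
    y_lo = float(make_flux_evaluator(
        params.replace(**{parameter: x * (1 - delta)}))(f)[i])
    return (y_hi - y_lo) / (2.0 * delta * y0)


def flux_sensitivity(
    params: ParameterSet,
    flux: str,
    parameter: str,
    delta: float = 0.01,
    protocol: str = "cycle_average",
) -> float:
    """Scaled sensitivity S of one flux to one constant (see module docs)."""
    if flux not in FLUX_IDS:
        raise KeyError(f"unknown flux {flux!r}")
    if parameter not in SENSITIVITY_PARAMS:
        raise KeyError(
            f"{parameter!r} is not one of the 76 perturbable constants"
        )
    reach = parameter_flux_reachability()
    if not reach.at[flux, parameter]:
        return 0.0
    y_base, _ = cycle_averaged_fluxes(params, protocol=protocol)
    s, _ = _column(params, parameter, delta, y_base, protocol)
    return float(s[FLUX_IDS.index(flux)])


def sensitivity_matrix(
    params: ParameterSet,
    delta: float = 0.01,
    protocol: str = "cycle_average",
    structural_mask: bool = True,
    progress: bool = False,
) -> SensitivityMatrix:
    """All 3724 scaled sensitivities at one basal parameter set.

    Two integrations per constant (central difference), 152 in total;
    deterministic.  With ``structural_mask`` (default) entries the
    dependency graph proves unreachable are fixed at exactly 0 and
    their columns are not re-integrated when every entry is masked.
    """
    y_base, oscillatory = cycle_averaged_fluxes(params, protocol=protocol)
    if not oscillatory:
        raise ValueError(
            "sensitivity analysis requires a sustained basal limit cycle"
        )
    reach = parameter_flux_reachability().to_numpy()
    mat = np.zeros((len(FLUXES), len(SENSITIVITY_PARAMS)))
    death: list[str] = []
    for j, name in enumerate(SENSITIVITY_PARAMS):
        if progress and j % 10 == 0:  # pragma: no cover - cosmetic
            print(f"sensitivity: constant {j + 1}/{len(SENSITIVITY_PARAMS)}",
                  file=sys.stderr)
        if structural_mask and not reach[:, j].any():
            continue
        s, died = _column(params, name, delta, y_base, protocol)
        if structural_mask:
            s = np.where(reach[:, j], s, 0.0)
        mat[:, j] = s
        if died:
            death.append(name)
    values = pd.DataFrame(mat, index=list(FLUX_IDS), columns=list(SENSITIVITY_PARAMS))
    return SensitivityMatrix(values, delta, protocol, params,
                             tuple(death), structural_mask)


def significance_counts(
    S: SensitivityMatrix, threshold: float = 1.0
) -> dict:
    """Summaries of the matrix at a significance cutoff.

    Returns a dict with

    ``per_parameter``
        DataFrame (one row per constant, descending): number of fluxes
        with ``|S| >= threshold`` and the maximum ``|S|`` over fluxes.
    ``n_parameters_max_above_0p9``
        how many of the 76 constants have ``max |S| > 0.9``.
    ``ranking``
        constants ordered by significant-flux count (ties by max |S|).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    absval = S.values.abs()
    counts = (absval >= threshold).sum(axis=0)
    max_abs = absval.max(axis=0)
    per_param = pd.DataFrame({
        "n_fluxes_significant": counts,
        "max_abs_S": max_abs,
    }).sort_values(["n_fluxes_significant", "max_abs_S"], ascending=False)
    return {
        "per_parameter": per_param,
        "n_parameters_max_above_0p9": int((max_abs > 0.9).sum()),
        "ranking": list(per_param.index),
    }
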