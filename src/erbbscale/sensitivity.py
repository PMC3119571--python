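"""Local and global parameter sensitivity analysis, and least-squares
rate-constant fitting, for the ErbB signaling model.

Local mode: normalized logarithmic sensitivities
S = d ln(metric) / d ln(parameter), estimated by central finite
differences of the log-metric against the log-parameter.  Global mode:
Latin-hypercube sampling in log-space over stated parameter ranges and
partial rank correlation coefficients (PRCC) of the metric against
each parameter.  "Parameters" include both rate constants and species
totals (receptor/ligand/enzyme levels), because the perturbations of
interest at the cellular scale are mostly expression-level changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from erbbscale.errors import LookupError_, StatisticsError, UsageError
from erbbscale.signaling import (
    ModelSpec,
    SensitivityResult,
    output_metric,
    simulate,
)

#: Friendly names for species totals used as sensitivity parameters.
SPECIES_ALIASES = {
    "EGFR": "R1",
    "ErbB2": "R2",
    "ErbB3": "R3",
    "NRG": "NRG",
    "EGF": "EGF",
    "PTEN": "PTEN",
    "ErbB_phosphatase": "PTP",
    "PI3K": "PI3K",
    "GAB-1": "GAB1",
    "GAB1": "GAB1",
    "Grb2": "Grb2",
    "Shc": "Shc",
    "Ras": "RasGDP",
    "Raf": "Raf",
    "MEK": "MEK",
    "ERK": "ERK",
    "AKT": "AKT",
    "PIP2": "PIP2",
    "Lapatinib": "Lap",
}

#: Default parameter panel for the NRG-stimulated pAKT analysis.
DEFAULT_LOCAL_PANEL = (
    "ErbB3",
    "NRG",
    "EGFR",
    "ErbB2",
    "PTEN",
    "ErbB_phosphatase",
    "PI3K",
    "AKT",
)


def _perturbed(model: ModelSpec, name: str, factor: float) -> ModelSpec:
    """Model with one parameter or species total scaled by ``factor``."""
    if name in model.parameters:
        return model.with_parameters(**{name: model.parameters[name] * factor})
    species_name = SPECIES_ALIASES.get(name, name)
    try:
        idx = model.species_index(species_name)
    except LookupError_:
        raise LookupError_(
            f"{name!r} is neither a rate constant nor a species of this model"
        ) from None
    return model.with_initial(species_name, model.species[idx].initial * factor)


def _base_value(model: ModelSpec, name: str) -> float:
    if name in model.parameters:
        return model.parameters[name]
    species_name = SPECIES_ALIASES.get(name, name)
    return model.species[model.species_index(species_name)].initial


def local_sensitivity(
    model: ModelSpec,
    parameters=DEFAULT_LOCAL_PANEL,
    metric: tuple = ("pAKT", "peak"),
    rel_step: float = 0.05,
    t_end: float = 60.0,
) -> SensitivityResult:
    """Normalized local sensitivity coefficients S = (p/y)(dy/dp).

    Central finite difference of log-metric vs log-parameter at the
    packaged operating point.  Parameters whose base value is zero in
    this scenario (e.g. an absent ligand) get coefficient 0.
    """
    if not (0 < rel_step <= 0.1):
        raise UsageError("rel_step must be in (0, 0.1]")
    species, which = metric
    y0 = output_metric(simulate(model, t_end=t_end), species, which)
    if y0 == 0:
        raise StatisticsError(
            f"metric {metric} is 0 at the base point; sensitivity undefined"
        )
    coeffs = {}
    for name in parameters:
        base = _base_value(model, name)
        if base == 0:
            coeffs[name] = 0.0
            continue
        up = output_metric(
            simulate(_perturbed(model, name, 1.0 + rel_step), t_end=t_end),
            species,
            which,
        )
        dn = output_metric(
            simulate(_perturbed(model, name, 1.0 - rel_step), t_end=t_end),
            species,
            which,
        )
        if up <= 0 or dn <= 0:
            # Fall back to a linear difference when the metric hits zero.
            coeffs[name] = (up - dn) / (2 * rel_step * y0)
            continue
        coeffs[name] = (np.log(up) - np.log(dn)) / (
            np.log(1 + rel_step) - np.log(1 - rel_step)
        )
    ranking = tuple(sorted(coeffs, key=lambda n: abs(coeffs[n]), reverse=True))
    return SensitivityResult(
        metric=f"{species}-{which}",
        mode="local",
        coefficients=coeffs,
        ranking=ranking,
    )


def _prcc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation of each column of x with y."""
    n, d = x.shape
    rx = np.column_stack([stats.rankdata(x[:, j]) for j in range(d)])
    ry = stats.rankdata(y)
    out = np.empty(d)
    for j in range(d):
        others = np.delete(rx, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(design, rx[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        res_x = rx[:, j] - design @ beta_x
        res_y = ry - design @ beta_y
        sx, sy = res_x.std(), res_y.std()
        out[j] = 0.0 if sx == 0 or sy == 0 else float(
            np.corrcoef(res_x, res_y)[0, 1]
        )
    return out


def global_sensitivity(
    model: ModelSpec,
    parameter_ranges: dict,
    n_samples: int,
    metric: tuple = ("pAKT", "peak"),
    seed: int = 0,
    t_end: float = 60.0,
    metric_fn=None,
) -> SensitivityResult:
    """PRCC global sensitivity over Latin-hypercube samples.

    ``parameter_ranges`` maps parameter/species names to (lo, hi)
    bounds; sampling is log-uniform.  ``metric_fn(result) -> float``
    overrides the (species, metric) readout when a composite metric
    (e.g. combined pAKT/pERK drive) is wanted.  Seeded and
    reproducible.
    """
    names = list(parameter_ranges)
    if n_samples < 10 * len(names):
        raise UsageError(
            f"n_samples must be >= 10 x n_parameters ({10 * len(names)})"
        )
    active, degenerate = [], []
    for name in names:
        lo, hi = parameter_ranges[name]
        if not (lo > 0 and hi > 0):
            raise UsageError(f"range for {name} must be positive")
        if lo == hi:
            degenerate.append(name)
            warnings.warn(f"degenerate range for {name}; coefficient set to 0")
        else:
            active.append(name)

    sampler = qmc.LatinHypercube(d=len(active), seed=seed)
    unit = sampler.random(n_samples)
    los = np.log(np.array([parameter_ranges[n][0] for n in active]))
    his = np.log(np.array([parameter_ranges[n][1] for n in active]))
    samples = np.exp(los + unit * (his - los))

    species, which = metric
    ys = np.empty(n_samples)
    for i in range(n_samples):
        m = model
        for j, name in enumerate(active):
            base = _base_value(m, name)
            factor = samples[i, j] / base if base > 0 else 0.0
            if base > 0:
                m = _perturbed(m, name, factor)
            else:
                # Absent-by-default species: set the absolute value.
                sp_name = SPECIES_ALIASES.get(name, name)
                if name in m.parameters:
                    m = m.with_parameters(**{name: samples[i, j]})
                else:
                    m = m.with_initial(sp_name, samples[i, j])
        result = simulate(m, t_end=t_end)
        ys[i] = (
            metric_fn(result) if metric_fn is not None
            else output_metric(result, species, which)
        )

    coeffs = dict.fromkeys(degenerate, 0.0)
    if active:
        prcc = _prcc(samples, ys)
        coeffs.update(dict(zip(active, prcc)))
    ranking = tuple(sorted(coeffs, key=lambda n: abs(coeffs[n]), reverse=True))
    label = f"{species}-{which}" if metric_fn is None else "custom"
    return SensitivityResult(
        metric=label, mode="global", coefficients=coeffs, ranking=ranking
    )


# ---------------------------------------------------------------------------
# Rate-constant fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    estimates: dict
    cost: float
    n_starts: int
    non_identifiable: tuple
    success: bool


def fit_rate_constants(
    model: ModelSpec,
    observed: dict,
    free_parameters,
    bounds: dict,
    seed: int = 0,
    n_starts: int = 4,
    t_end: float = 60.0,
) -> FitResult:
    """Least-squares trajectory fit of up to 5 free rate constants.

    ``observed`` maps species names to (t, y) arrays where y may be
    (n_times,) or (n_replicates, n_times); residuals are pooled over
    replicates.  Optimisation runs in log-parameter space with
    multi-start (seeded Latin-hypercube starts within the bounds plus
    the current values) to mitigate local minima.  Parameters whose
    fitted gradient is numerically flat are flagged non-identifiable.
    """
    free_parameters = list(free_parameters)
    if len(free_parameters) > 5:
        raise UsageError("at most 5 free parameters are supported")
    for name in free_parameters:
        if name not in model.parameters:
            raise LookupError_(f"unknown rate constant {name!r}")
        if name not in bounds:
            raise UsageError(f"missing bounds for {name!r}")
    for species in observed:
        model.species_index(species)  # raises on unknown species

    lo = np.log(np.array([bounds[n][0] for n in free_parameters]))
    hi = np.log(np.array([bounds[n][1] for n in free_parameters]))

    obs_items = []
    scale = {}
    for species, (t, y) in observed.items():
        y = np.atleast_2d(np.asarray(y, dtype=float))
        t = np.asarray(t, dtype=float)
        obs_items.append((species, t, y))
        scale[species] = max(float(np.abs(y).max()), 1e-12)

    def residuals(log_p):
        m = model.with_parameters(
            **{n: float(np.exp(v)) for n, v in zip(free_parameters, log_p)}
        )
        try:
            result = simulate(m, t_end=t_end)
        except Exception:
            return np.full(sum(y.size for _, _, y in obs_items), 1e3)
        res = []
        for species, t, y in obs_items:
            pred = np.interp(t, result.time, result.trajectory(species))
            res.append(((y - pred[None, :]) / scale[species]).ravel())
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    starts = [
        np.clip(
            np.log(np.array([model.parameters[n] for n in free_parameters])),
            lo,
            hi,
        )
    ]
    if n_starts > 1:
        unit = qmc.LatinHypercube(d=len(free_parameters), seed=seed).random(
            n_starts - 1
        )
        starts.extend(lo + u * (hi - lo) for u in unit)

    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol

    # Flat-gradient detection: a free parameter whose jacobian column is
    # numerically zero does not influence the observed species.
    col_norms = np.linalg.norm(best.jac, axis=0)
    flat = tuple(
        n for n, c in zip(free_parameters, col_norms) if c < 1e-8
    )
    if flat:
        warnings.warn(
            f"parameters {flat} show a flat objective (non-identifiable)"
        )
    estimates = {
        n: float(np.exp(v)) for n, v in zip(free_parameters, best.x)
    }
    return FitResult(
        estimates=estimates,
        cost=float(best.cost),
        n_starts=len(starts),
        non_identifiable=flat,
        success=bool(best.success),
    )
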