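"""Estimation of hyperelastic constants from uniaxial tensile tests.

The graft constants are identified by bounded nonlinear least squares in
nominal-stress space: minimize sum_i (P_model(lam_i) - P_obs_i)^2 over the
model parameters, with a Latin-hypercube multi-start to escape poor basins.
Acceptance of a fit is judged in *curve space* (how well the fitted stress
curve reproduces the data), not parameter space: a single uniaxial path does
not identify all parameters of rich families such as the five-parameter
Mooney-Rivlin, and the Jacobian condition number / per-parameter
identifiability flags in :class:`FitResult` report exactly that degeneracy.

Also provided: the small-strain elastic modulus and the ultimate tensile
strength of a record, and a side-by-side multi-model fit report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .constitutive import (
    ConfigurationError,
    HGOParams,
    MaterialModel,
    MooneyRivlin5Params,
    OgdenParams,
    Yeoh3Params,
    uniaxial_nominal_stress,
)

__all__ = [
    "TensileDataset",
    "FitResult",
    "FitError",
    "FitOptions",
    "fit_model",
    "initial_modulus",
    "ultimate_strength",
    "UltimateStrength",
    "fit_report",
]

DEFAULT_SEED = 20220407


class FitError(RuntimeError):
    """All optimizer starts failed to converge."""


@dataclass(frozen=True)
class TensileDataset:
    """One uniaxial tensile record of a tubular graft specimen.

    ``stretch`` is the axial stretch ratio lambda >= 1 (non-decreasing) and
    ``stress`` the nominal (engineering) stress in MPa computed on the
    undeformed wall cross-section.  Geometry in mm, load rate in mm/min,
    preload in MPa (the stress offset at which the record starts).
    """

    specimen_id: str
    diameter_mm: float
    thickness_mm: float
    length_mm: float
    stretch: np.ndarray
    stress: np.ndarray
    rate_mm_per_min: float = 30.0
    preload_mpa: float = 0.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)
        if lam.shape != sig.shape or lam.ndim != 1:
            raise ValueError("stretch and stress must be 1-D arrays of equal length")
        if lam.size and lam[0] < 1.0 - 1e-12:
            raise ValueError("first sample must be at stretch >= 1")
        if np.any(np.diff(lam) < -1e-12):
            raise ValueError("stretches must be non-decreasing")
        if not np.all(np.isfinite(sig)):
            raise ValueError("stresses must be finite")

    def __len__(self) -> int:
        return self.stretch.size

    def preload_corrected(self) -> "TensileDataset":
        """Shift stresses so the record starts at the stated preload and
        re-reference stretch to the preloaded state."""
        if len(self) == 0:
            return self
        lam = self.stretch / self.stretch[0]
        sig = self.stress - self.stress[0] + self.preload_mpa
        return replace(self, stretch=lam, stress=sig)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit to one dataset."""

    model_tag: str
    model: MaterialModel
    params: dict
    rmse_mpa: float
    r_squared: float
    condition_number: float
    identifiability_flags: dict
    converged: bool
    n_starts: int
    cost_trace: tuple[tuple[float, float], ...]  # (initial, final) cost per start
    dataset_id: str = ""

    @property
    def flagged(self) -> bool:
        return any(self.identifiability_flags.values())


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration for :func:`fit_model`."""

    n_starts: int = 16
    seed: int = DEFAULT_SEED
    ogden_n_terms: int = 2
    hgo_beta_deg: float = 45.0
    condition_threshold: float = 1e3
    max_nfev: int = 2000
    coeff_bound_mpa: float = 10.0  # |c| bound for Mooney-Rivlin / Yeoh coefficients
    alpha_bound: float = 30.0  # |alpha| bound for Ogden exponents
    k2_bound: float = 100.0


# --- model parameterizations -------------------------------------------------


def _model_space(tag: str, opts: FitOptions):
    """(names, lower, upper, builder) for each fit family."""
    c = opts.coeff_bound_mpa
    if tag == "mooney_rivlin5":
        names = ["c10", "c01", "c20", "c11", "c02"]
        lo = [-c] * 5
        hi = [c] * 5

        def build(x):
            return MooneyRivlin5Params(*x)

    elif tag == "yeoh3":
        names = ["c10", "c20", "c30"]
        lo = [1e-8, -c, -c]
        hi = [c, c, c]

        def build(x):
            return Yeoh3Params(*x)

    elif tag == "ogden":
        n = opts.ogden_n_terms
        names = [f"mu{p+1}" for p in range(n)] + [f"alpha{p+1}" for p in range(n)]
        lo = [-c] * n + [-opts.alpha_bound] * n
        hi = [c] * n + [opts.alpha_bound] * n

        def build(x):
            mus, alphas = x[:n], x[n:]
            return OgdenParams(terms=tuple(zip(mus, alphas)))

    elif tag == "hgo":
        names = ["c10", "k1", "k2", "kappa"]
        lo = [1e-8, 0.0, 1e-6, 0.0]
        hi = [c, c, opts.k2_bound, 1.0 / 3.0]
        beta = np.radians(opts.hgo_beta_deg)

        def build(x):
            return HGOParams(
                c10=x[0], k1=x[1], k2=x[2], kappa=x[3], fiber_angles=(beta, -beta)
            )

    else:
        raise ConfigurationError(f"unknown fit model tag {tag!r}")
    return names, np.asarray(lo, float), np.asarray(hi, float), build


def _safe_build(build, x):
    try:
        return build(x)
    except (ConfigurationError, ValueError):
        return None


def fit_model(data: TensileDataset, model_tag: str, options: FitOptions | None = None) -> FitResult:
    """Fit one constitutive family to a tensile dataset.

    Multi-start bounded least squares (scipy trust-region reflective) from a
    seeded Latin-hypercube over the parameter bounds; the best start by final
    cost wins.  Raises :class:`FitError` if no start converges and
    ``ValueError`` if the dataset is smaller than the parameter count.
    """
    opts = options or FitOptions()
    names, lo, hi, build = _model_space(model_tag, opts)
    npar = len(names)
    if len(data) < max(npar + 1, 8):
        raise ValueError(
            f"{len(data)} samples cannot constrain {npar} parameters "
            f"(need at least {max(npar + 1, 8)})"
        )
    lam = data.stretch
    obs = data.stress

    def residual(x):
        model = _safe_build(build, x)
        if model is None:
            return np.full(lam.size, 1e3)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = np.asarray(uniaxial_nominal_stress(model, lam))
        pred = np.where(np.isfinite(pred), pred, 1e6)
        return pred - obs

    sampler = qmc.LatinHypercube(d=npar, seed=opts.seed)
    starts = qmc.scale(sampler.random(opts.n_starts), lo, hi)
    # keep exponents away from the degenerate alpha = 0 axis
    if model_tag == "ogden":
        n = npar // 2
        a = starts[:, n:]
        a[np.abs(a) < 0.5] = 2.0
        starts[:, n:] = a

    best = None
    trace: list[tuple[float, float]] = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        cost0 = 0.5 * float(np.sum(residual(x0) ** 2))
        try:
            res = optimize.least_squares(
                residual, x0, bounds=(lo, hi), max_nfev=opts.max_nfev, method="trf"
            )
        except Exception:
            continue
        trace.append((cost0, float(res.cost)))
        if not res.success or _safe_build(build, res.x) is None:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(
            f"no optimizer start converged for {model_tag} on {data.specimen_id}; "
            f"{len(trace)} starts attempted"
        )

    model = build(best.x)
    pred = np.asarray(uniaxial_nominal_stress(model, lam))
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    # identifiability from the Jacobian at the solution
    jac = np.asarray(best.jac)
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    flags = {name: False for name in names}
    if cond > opts.condition_threshold:
        # flag parameters with large participation in near-null directions
        weak = s < s[0] / opts.condition_threshold
        part = np.sqrt(np.sum(vt[weak] ** 2, axis=0)) if np.any(weak) else np.zeros(npar)
        for j, name in enumerate(names):
            flags[name] = bool(part[j] > 1.0 / np.sqrt(2 * npar))
        if not any(flags.values()):
            flags[names[int(np.argmax(np.abs(vt[-1])))]] = True

    return FitResult(
        model_tag=model_tag,
        model=model,
        params=dict(zip(names, map(float, best.x))),
        rmse_mpa=rmse,
        r_squared=r2,
        condition_number=cond,
        identifiability_flags=flags,
        converged=True,
        n_starts=opts.n_starts,
        cost_trace=tuple(trace),
        dataset_id=data.specimen_id,
    )


def initial_modulus(data: TensileDataset, max_stretch: float = 1.05) -> float:
    """Small-strain elastic modulus E (MPa).

    Ordinary least squares of nominal stress against engineering strain
    through the preload-corrected origin, over samples with lambda <=
    ``max_stretch``.  Requires at least three samples in the window.
    """
    corrected = data.preload_corrected()
    mask = corrected.stretch <= max_stretch
    if int(mask.sum()) < 3:
        raise ValueError(
            f"need >= 3 samples with stretch <= {max_stretch}, found {int(mask.sum())}"
        )
    strain = corrected.stretch[mask] - 1.0
    stress = corrected.stress[mask] - corrected.preload_mpa
    denom = float(np.sum(strain**2))
    if denom == 0.0:
        raise ValueError("small-strain window has zero strain range")
    return float(np.sum(strain * stress) / denom)


@dataclass(frozen=True)
class UltimateStrength:
    sigma_y_mpa: float
    stretch_at_failure: float
    ruptured: bool  # False => monotone record, terminal stress returned


def ultimate_strength(data: TensileDataset) -> UltimateStrength:
    """Maximum nominal stress over the record and the stretch at which it occurs.

    If the maximum sits at the terminal sample (no post-peak drop) the record
    is flagged as "no rupture detected".
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    i = int(np.argmax(data.stress))
    ruptured = i < len(data) - 1
    return UltimateStrength(
        sigma_y_mpa=float(data.stress[i]),
        stretch_at_failure=float(data.stretch[i]),
        ruptured=ruptured,
    )


def fit_report(
    results: Sequence[FitResult],
    data: TensileDataset,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Side-by-side comparison table of several fits to the same dataset.

    With ``plot_path`` an overlay figure of the data and each fitted stress
    curve is also written.
    """
    if not results:
        raise ValueError("no fit results to report")
    ids = {r.dataset_id for r in results}
    if ids - {data.specimen_id}:
        raise ValueError(f"results fitted on {ids}, not on {data.specimen_id!r}")
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.model_tag,
                "rmse_mpa": r.rmse_mpa,
                "r_squared": r.r_squared,
                "condition_number": r.condition_number,
                "flagged_params": ",".join(k for k, v in r.identifiability_flags.items() if v),
                **{f"p_{k}": v for k, v in r.params.items()},
            }
        )
    if plot_path is not None:
        plot_fit_overlay(results, data, plot_path)
    return pd.DataFrame(rows)


def plot_fit_overlay(
    results: Sequence[FitResult], data: TensileDataset, path: str
) -> None:
    """Overlay the tensile record and each fitted nominal-stress curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(data.stretch, data.stress, "k.", ms=3, label=f"data ({data.specimen_id})")
    lam = np.linspace(float(data.stretch[0]), float(data.stretch[-1]), 200)
    for r in results:
        ax.plot(lam, uniaxial_nominal_stress(r.model, lam),
                label=f"{r.model_tag} (RMSE {r.rmse_mpa:.3g} MPa)")
    ax.set_xlabel("stretch $\\lambda$")
    ax.set_ylabel("nominal stress [MPa]")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
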