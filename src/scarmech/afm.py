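"""AFM force-indentation analysis: Hertz and Kelvin-Voigt-Maxwell fits.

Nanoindentation with a spherical probe of radius ``R`` on soft tissue produces
an approach force curve F(delta).  Two models are fitted:

* **Hertz (elastic)** — rigid sphere on an elastic half-space:

      F = (4/3) * E / (1 - nu**2) * sqrt(R) * delta**1.5

  with apparent Young's modulus ``E`` and Poisson ratio ``nu`` (0.5 for
  incompressible tissue).

* **Kelvin-Voigt-Maxwell (viscoelastic)** — the elastic spring in the Hertz
  term acts in parallel with a dashpot of apparent viscosity ``eta``.  By the
  elastic-viscoelastic correspondence the modulus is replaced by the operator
  ``E + eta * d/dt`` acting on delta**1.5, giving for a constant approach
  speed ``v``:

      F = (4 sqrt(R)) / (3 (1 - nu**2)) * (E * delta**1.5
                                           + 1.5 * eta * v * sqrt(delta))

  which reduces to the Hertz solution as ``eta -> 0``.

Both fits treat the contact point and a constant force baseline as free
parameters and use bounded least squares with a multi-start grid over the
contact point, since the contact-point/modulus coupling creates local minima.
The Hertz fit restricts the data to indentations of at most 3 um beyond the
fitted contact point (deep indentation violates the small-strain assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "ViscoFit",
    "hertz_force",
    "kvm_force",
    "hertz_sphere_fit",
    "kvm_fit",
    "contact_point_estimate",
]


def hertz_force(delta, young_modulus, bead_radius=18.5e-6, poisson=0.5):
    """Hertz sphere contact force (N) at indentation depth ``delta`` (m).

    Negative depths (pre-contact) give zero force.
    """
    delta = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    return (4.0 / 3.0) * young_modulus / (1.0 - poisson ** 2) \
        * np.sqrt(bead_radius) * delta ** 1.5


def kvm_force(delta, young_modulus, viscosity, speed,
              bead_radius=18.5e-6, poisson=0.5):
    """Kelvin-Voigt-Maxwell approach force (N) at constant indentation speed.

    ``viscosity`` is the apparent viscosity in Pa*s and ``speed`` the approach
    speed in m/s.  Reduces to :func:`hertz_force` when ``viscosity`` is 0.
    """
    delta = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    pref = (4.0 * np.sqrt(bead_radius)) / (3.0 * (1.0 - poisson ** 2))
    return pref * (young_modulus * delta ** 1.5
                   + 1.5 * viscosity * speed * np.sqrt(delta))


@dataclass
class ForceCurve:
    """Sampled approach force curve with probe metadata.

    ``indentation_m`` is the tip-sample distance coordinate increasing during
    approach; the sample surface (contact point) is generally at an unknown
    positive offset estimated by the fit.
    """

    time_s: np.ndarray
    indentation_m: np.ndarray
    force_n: np.ndarray
    spring_constant_n_per_m: float = 0.033
    bead_radius_m: float = 18.5e-6
    poisson: float = 0.5
    approach_speed_m_per_s: float = 7e-6
    setpoint_n: float = 12e-9
    truth: dict = field(default_factory=dict)   # generator ground truth, if any

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.indentation_m = np.asarray(self.indentation_m, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if not (self.time_s.shape == self.indentation_m.shape == self.force_n.shape):
            raise ValueError("time, indentation and force must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.bead_radius_m <= 0:
            raise ValueError("bead radius must be positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5]")

    @classmethod
    def from_tsv(cls, path, **metadata) -> "ForceCurve":
        """Read a TSV with columns time_s, force_N and indentation_m or height_m.

        When only ``height_m`` (piezo extension) is present, the indentation is
        corrected for cantilever deflection: delta = height - F / k.
        """
        df = pd.read_csv(path, sep="\t")
        if "indentation_m" in df.columns:
            indent = df["indentation_m"].to_numpy()
        elif "height_m" in df.columns:
            k = metadata.get("spring_constant_n_per_m", cls.spring_constant_n_per_m)
            indent = df["height_m"].to_numpy() - df["force_N"].to_numpy() / k
        else:
            raise ValueError("need an indentation_m or height_m column")
        return cls(time_s=df["time_s"].to_numpy(), indentation_m=indent,
                   force_n=df["force_N"].to_numpy(), **metadata)

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "time_s": self.time_s,
            "indentation_m": self.indentation_m,
            "force_N": self.force_n,
        }).to_csv(path, sep="\t", index=False)

    def estimated_speed(self) -> float:
        """Median indentation rate (m/s) over the sampled approach."""
        return float(np.median(np.diff(self.indentation_m) / np.diff(self.time_s)))


@dataclass
class ViscoFit:
    model: str                       # "hertz" | "kvm"
    young_modulus_pa: float
    young_modulus_stderr_pa: float | None
    viscosity_pa_s: float | None
    viscosity_stderr_pa_s: float | None
    contact_point_m: float
    contact_point_stderr_m: float | None
    baseline_n: float
    residual_norm_n: float
    n_points_fit: int
    converged: bool


def _check_contact(curve: ForceCurve) -> None:
    f = curve.force_n
    if np.allclose(f, f[0]):
        raise ValueError("flat force signal: no contact detected")
    n_base = max(5, len(f) // 10)
    baseline = np.median(f[:n_base])
    noise = 1.4826 * np.median(np.abs(f[:n_base] - baseline)) + 1e-15
    if f.max() - baseline < max(10.0 * noise, 1e-12):
        raise ValueError("force never rises above baseline noise: no contact detected")


def _basis(dc: np.ndarray, model: str, curve: ForceCurve, speed: float) -> np.ndarray:
    """Design matrix: the model is linear in (E, [eta], baseline) given contact."""
    pref = (4.0 * np.sqrt(curve.bead_radius_m)) / (3.0 * (1.0 - curve.poisson ** 2))
    cols = [pref * dc ** 1.5]
    if model == "kvm":
        cols.append(pref * 1.5 * speed * np.sqrt(dc))
    cols.append(np.ones_like(dc))
    return np.column_stack(cols)


def _profile_solve(x: np.ndarray, f: np.ndarray, contact: float, model: str,
                   curve: ForceCurve, speed: float):
    """Best linear parameters and SSE for a fixed contact point.

    Negative amplitude solutions are rejected by re-solving on the reduced
    basis (eta pinned to 0), so fitted E > 0 and eta >= 0 always hold.
    """
    dc = np.clip(x - contact, 0.0, None)
    a = _basis(dc, model, curve, speed)
    coef, *_ = np.linalg.lstsq(a, f, rcond=None)
    if model == "kvm" and coef[1] < 0:
        a2 = a[:, [0, 2]]
        c2, *_ = np.linalg.lstsq(a2, f, rcond=None)
        coef = np.array([c2[0], 0.0, c2[1]])
    resid = a @ coef - f
    return coef, float(resid @ resid)


def _fit(curve: ForceCurve, model: str, max_indentation_m: float | None,
         n_grid: int = 120):
    """Variable-projection fit: profile the SSE over the contact point.

    The force model is linear in its amplitude parameters once the contact
    point is fixed, so each candidate contact costs one linear least-squares
    solve.  A dense grid plus golden-section refinement finds the global
    profile minimum; a Levenberg-Marquardt polish at the optimum supplies the
    parameter standard errors.
    """
    _check_contact(curve)
    x, f = curve.indentation_m, curve.force_n
    speed = curve.approach_speed_m_per_s or curve.estimated_speed()

    def profile(xx, ff):
        span = xx.max() - xx.min()
        grid = np.linspace(xx.min(), xx.max() - 1e-4 * span, n_grid)
        sses = [_profile_solve(xx, ff, c, model, curve, speed)[1] for c in grid]
        i = int(np.argmin(sses))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        res = minimize_scalar(
            lambda c: _profile_solve(xx, ff, c, model, curve, speed)[1],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12})
        contact = float(res.x)
        coef, sse = _profile_solve(xx, ff, contact, model, curve, speed)
        return contact, coef, sse

    contact, coef, sse = profile(x, f)
    sub_x, sub_f = x, f
    if max_indentation_m is not None:
        for _ in range(2):
            keep = (x - contact) <= max_indentation_m
            if keep.sum() == len(sub_x):
                break
            sub_x, sub_f = x[keep], f[keep]
            contact, coef, sse = profile(sub_x, sub_f)

    n_post = int((sub_x > contact).sum())
    if n_post < 10:
        raise ValueError(f"only {n_post} post-contact samples: need >= 10")

    # Levenberg-Marquardt polish at the profiled optimum for standard errors
    def residual(params):
        dc = sub_x - params["contact"].value
        if model == "hertz":
            pred = hertz_force(dc, params["young"].value,
                               curve.bead_radius_m, curve.poisson)
        else:
            pred = kvm_force(dc, params["young"].value, params["eta"].value,
                             speed, curve.bead_radius_m, curve.poisson)
        return pred + params["baseline"].value - sub_f

    params = Parameters()
    params.add("contact", value=contact, vary=True)
    params.add("young", value=max(coef[0], 1e-6), min=0.0)
    if model == "kvm":
        params.add("eta", value=max(coef[1], 0.0), min=0.0)
    params.add("baseline", value=coef[-1])
    out = minimize(residual, params, method="leastsq")
    p = out.params if out.chisqr <= sse * (1 + 1e-9) else params
    chisqr = min(float(out.chisqr), sse)

    if p["young"].value <= 0:
        raise RuntimeError("non-physical (non-positive) modulus solution")

    def _stderr(name):
        try:
            s = p[name].stderr
        except KeyError:
            return None
        return float(s) if s is not None else None

    return ViscoFit(
        model=model,
        young_modulus_pa=float(p["young"].value),
        young_modulus_stderr_pa=_stderr("young"),
        viscosity_pa_s=(float(p["eta"].value) if model == "kvm" else None),
        viscosity_stderr_pa_s=(_stderr("eta") if model == "kvm" else None),
        contact_point_m=float(p["contact"].value),
        contact_point_stderr_m=_stderr("contact"),
        baseline_n=float(p["baseline"].value),
        residual_norm_n=float(np.sqrt(chisqr)),
        n_points_fit=len(sub_x),
        converged=True,
    )


def hertz_sphere_fit(curve: ForceCurve, max_indentation_m: float = 3e-6) -> ViscoFit:
    """Fit the spherical Hertz model with free contact point and baseline.

    Only samples within ``max_indentation_m`` beyond the fitted contact point
    enter the final fit (default 3 um).
    """
    return _fit(curve, "hertz", max_indentation_m)


def kvm_fit(curve: ForceCurve) -> ViscoFit:
    """Fit the constant-speed Kelvin-Voigt-Maxwell model (apparent E and eta)."""
    return _fit(curve, "kvm", None)


def contact_point_estimate(curve: ForceCurve):
    """Contact point position +/- standard error from a joint Hertz fit.

    Raises
    ------
    ValueError
        If the pre-contact baseline covers less than 5% of the samples or no
        contact is detectable.
    """
    fit = _fit(curve, "hertz", None)
    n_pre = int((curve.indentation_m <= fit.contact_point_m).sum())
    if n_pre < 0.05 * len(curve.indentation_m):
        raise ValueError("pre-contact baseline shorter than 5% of samples")
    return fit.contact_point_m, fit.contact_point_stderr_m
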