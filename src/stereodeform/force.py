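"""Force estimation from tool-induced surface displacement.

The tool tip occludes the contact point, so the peak surface displacement is
inferred by fitting an isotropic 2D Gaussian bump to the displacement
magnitudes of the visible features around the tip; an empirically calibrated
degree-2 polynomial (``F = a2 d^2 + a1 d + a0``, d in mm, F in N) then maps
the inferred peak displacement to the exerted force. Forces of interest are
small — sharp dissection uses forces below about 0.3 N — so calibration data
at millimeter-scale displacements is expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FittingError, StereoDeformError, UnderdeterminedFitError

__all__ = [
    "ForceDisplacementModel",
    "GaussianIndentation",
    "DiskRegion",
    "ForceEstimate",
    "calibrate_material",
    "fit_indentation",
    "estimate_force",
    "DEMO_MODEL",
]


@dataclass
class ForceDisplacementModel:
    """Quadratic force-displacement law ``F = a2 d^2 + a1 d + a0``.

    ``d_max`` is the largest displacement seen during calibration (mm);
    evaluation beyond ``1.2 * d_max`` is refused as extrapolation.
    ``residual_rms`` is the RMS fit residual in newtons.
    """

    a2: float
    a1: float
    a0: float
    d_max: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.a2, self.a1, self.a0, self.d_max]).all():
            raise ValueError("model coefficients must be finite")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a2, self.a1, self.a0)

    def evaluate(self, d):
        """Force (N) at displacement d (mm); vectorized."""
        d = np.asarray(d, dtype=float)
        out = self.a2 * d * d + self.a1 * d + self.a0
        return float(out) if out.ndim == 0 else out

    def is_monotone(self) -> bool:
        """True if F(d) is non-decreasing on [0, d_max]."""
        d = np.linspace(0.0, self.d_max, 256)
        dF = 2 * self.a2 * d + self.a1
        return bool(np.all(dF >= -1e-12))

    def save(self, path) -> None:
        lines = [
            "stereodeform-material 1",
            "coefficients: %.17g %.17g %.17g" % (self.a2, self.a1, self.a0),
            "d_max: %.17g" % self.d_max,
            "residual_rms: %.17g" % self.residual_rms,
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "ForceDisplacementModel":
        lines = Path(path).read_text().strip().splitlines()
        if not lines or lines[0].strip() != "stereodeform-material 1":
            raise StereoDeformError(f"{path}: not a stereodeform material model file")
        kv = {}
        for line in lines[1:]:
            key, _, rest = line.partition(":")
            kv[key.strip()] = [float(v) for v in rest.split()]
        a2, a1, a0 = kv["coefficients"]
        return cls(
            a2=a2,
            a1=a1,
            a0=a0,
            d_max=kv["d_max"][0],
            residual_rms=kv.get("residual_rms", [0.0])[0],
        )


#: Toy material model for demos and closed-loop synthetic tests. The scale is
#: consistent with sub-0.3 N forces at few-mm displacements but the numbers
#: are NOT a measured tissue property.
DEMO_MODEL = ForceDisplacementModel(a2=0.01, a1=0.02, a0=0.0, d_max=12.0)


def calibrate_material(
    displacements,
    forces,
    force_through_origin: bool = False,
) -> ForceDisplacementModel:
    """Least-squares degree-2 fit of force (N) against displacement (mm).

    Requires at least 3 distinct displacement values (2 when the intercept is
    forced through the origin). Reports the RMS residual and records
    ``d_max`` as the largest calibrated displacement.
    """
    d = np.asarray(displacements, dtype=float).ravel()
    F = np.asarray(forces, dtype=float).ravel()
    if d.size != F.size:
        raise ValueError("displacements and forces must have equal length")
    n_distinct = np.unique(d).size
    needed = 2 if force_through_origin else 3
    if n_distinct < needed:
        raise UnderdeterminedFitError(
            f"need >= {needed} distinct displacement values, got {n_distinct}"
        )
    if force_through_origin:
        X = np.stack([d * d, d], axis=1)
        coef, *_ = np.linalg.lstsq(X, F, rcond=None)
        a2, a1, a0 = float(coef[0]), float(coef[1]), 0.0
    else:
        X = np.stack([d * d, d, np.ones_like(d)], axis=1)
        coef, *_ = np.linalg.lstsq(X, F, rcond=None)
        a2, a1, a0 = (float(c) for c in coef)
    resid = a2 * d * d + a1 * d + a0 - F
    rms = float(np.sqrt(np.mean(resid**2)))
    d_max = float(d.max()) if d.max() > 0 else 1.0
    return ForceDisplacementModel(a2=a2, a1=a1, a0=a0, d_max=d_max, residual_rms=rms)


@dataclass
class DiskRegion:
    """Circular occluded region (e.g. the tool tip) in surface coordinates, mm."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).ravel()
        if self.radius < 0:
            raise ValueError("radius must be non-negative")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.sum((pts - self.center) ** 2, axis=1) <= self.radius**2


@dataclass
class GaussianIndentation:
    """Isotropic Gaussian model of the indentation displacement field:
    ``D(u) = A exp(-||u - center||^2 / (2 sigma^2)) + baseline`` (mm)."""

    amplitude: float
    center: np.ndarray
    sigma: float
    baseline: float = 0.0
    fit_rms: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).ravel()
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def peak(self) -> float:
        """Displacement at the (occluded) indentation center, mm."""
        return float(self.amplitude + self.baseline)

    def evaluate(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r2 = np.sum((pts - self.center) ** 2, axis=1)
        return self.amplitude * np.exp(-r2 / (2.0 * self.sigma**2)) + self.baseline


def fit_indentation(
    positions,
    displacements,
    tool_region: DiskRegion | np.ndarray | None = None,
    fit_baseline: bool = True,
    sigma_bounds: tuple[float, float] = (0.5, 50.0),
) -> GaussianIndentation:
    """Fit the Gaussian indentation model to (surface position, D) samples.

    ``positions`` are (N, 2) surface coordinates in mm (tangent-plane
    projection), ``displacements`` the matching 3D displacement magnitudes in
    mm. Samples inside ``tool_region`` (the occluded tool-tip area; a
    :class:`DiskRegion` or a boolean exclusion mask) are discarded before the
    fit — the model's purpose is to extrapolate the peak under the tool.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    D = np.asarray(displacements, dtype=float).ravel()
    if pos.shape[0] != D.size:
        raise ValueError("positions and displacements must have equal length")
    if tool_region is not None:
        occluded = (
            tool_region.contains(pos)
            if isinstance(tool_region, DiskRegion)
            else np.asarray(tool_region, dtype=bool).ravel()
        )
        pos, D = pos[~occluded], D[~occluded]
    if pos.shape[0] < 5:
        raise UnderdeterminedFitError(
            f"need >= 5 samples outside the occluded region, got {pos.shape[0]}"
        )
    if np.all(np.abs(D) < 1e-12):
        return GaussianIndentation(
            amplitude=0.0, center=pos.mean(axis=0), sigma=1.0, baseline=0.0
        )

    # moment-based initial guess: displacement-weighted centroid and spread
    w = np.maximum(D - D.min(), 0.0)
    wsum = w.sum()
    c0 = (pos * w[:, None]).sum(axis=0) / wsum if wsum > 0 else pos.mean(axis=0)
    r2 = np.sum((pos - c0) ** 2, axis=1)
    s0 = float(np.sqrt((r2 * w).sum() / wsum)) if wsum > 0 else 5.0
    s0 = float(np.clip(s0, *sigma_bounds))
    A0 = float(max(D.max(), 1e-6))

    if fit_baseline:

        def model(xy, A, cx, cy, s, b):
            rr = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            return A * np.exp(-rr / (2.0 * s * s)) + b

        p0 = [A0, c0[0], c0[1], s0, 0.0]
        lo = [0.0, pos[:, 0].min() - 50, pos[:, 1].min() - 50, sigma_bounds[0], -5.0]
        hi = [10 * A0 + 1, pos[:, 0].max() + 50, pos[:, 1].max() + 50, sigma_bounds[1], 5.0]
    else:

        def model(xy, A, cx, cy, s):
            rr = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            return A * np.exp(-rr / (2.0 * s * s))

        p0 = [A0, c0[0], c0[1], s0]
        lo = [0.0, pos[:, 0].min() - 50, pos[:, 1].min() - 50, sigma_bounds[0]]
        hi = [10 * A0 + 1, pos[:, 0].max() + 50, pos[:, 1].max() + 50, sigma_bounds[1]]

    try:
        popt, _ = curve_fit(
            model, pos, D, p0=p0, bounds=(lo, hi), maxfev=20000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError as exc:
        raise FittingError(
            f"Gaussian indentation fit did not converge: {exc}; "
            f"n={D.size}, D range [{D.min():.3g}, {D.max():.3g}] mm, p0={p0}"
        ) from exc
    resid = model(pos, *popt) - D
    rms = float(np.sqrt(np.mean(resid**2)))
    baseline = float(popt[4]) if fit_baseline else 0.0
    return GaussianIndentation(
        amplitude=float(popt[0]),
        center=np.array([popt[1], popt[2]]),
        sigma=float(popt[3]),
        baseline=baseline,
        fit_rms=rms,
    )


@dataclass
class ForceEstimate:
    """Force readout at the tool tip."""

    force: float  # N
    peak_mm: float
    extrapolated: bool

    def __float__(self) -> float:
        return self.force


def estimate_force(
    model: ForceDisplacementModel, indentation: GaussianIndentation
) -> ForceEstimate:
    """Evaluate the material model at the inferred peak displacement.

    The peak must be non-negative and within 1.2x the calibrated range (mild
    extrapolation is allowed but flagged). A warning is emitted when the
    fitted polynomial is not monotone on its calibrated range, since the
    displacement-to-force readout is then ambiguous.
    """
    peak = indentation.peak
    if peak < 0:
        raise ValueError(f"negative peak displacement: {peak:.4g} mm")
    if peak > 1.2 * model.d_max:
        raise ValueError(
            f"peak displacement {peak:.4g} mm exceeds 1.2 * d_max = {1.2 * model.d_max:.4g} mm"
        )
    if not model.is_monotone():
        warnings.warn(
            "force-displacement model is not monotone on [0, d_max]; "
            "force readout may be ambiguous"
        )
    return ForceEstimate(
        force=float(model.evaluate(peak)),
        peak_mm=float(peak),
        extrapolated=bool(peak > model.d_max),
    )
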