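"""Synthetic CT phantoms and survival cohorts with known ground truth.

Every pipeline stage gets an oracle:

* :func:`generate_phantom` voxelizes an ellipsoidal pericardial sac with an
  EAT shell of controllable thickness field and controllable HU distribution
  (Gaussian or skew-normal, so elevated-HU features like ``Negative_skewness``
  and ``Pro_50_30`` have analytic targets), a soft-tissue core (+40 HU) and
  air background (-900 HU);
* :func:`simulate_survival` draws event times from a Weibull
  proportional-hazards model with known coefficients and administrative
  uniform censoring calibrated to a target event fraction (default 56%,
  an enriched-event cohort);
* :func:`simulate_feature_table` draws a correlated 148-column feature table
  on the catalog's names for modeling-scale cohorts where extracting
  hundreds of phantoms would be wasteful.

Default phantom grids are scaled down (128x128 in-plane at 2 mm pixels,
2.5 mm slices) from the clinical 512x512 x 0.5 mm geometry; the clinical
geometry is available via ``PhantomSpec.clinical()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureCatalog, default_catalog
from .imaging import BinaryMask, ImageVolume

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "simulate_survival", "simulate_feature_table"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, HU model and seed for one synthetic phantom."""

    shape: tuple = (40, 128, 128)
    spacing: tuple = (2.5, 2.0, 2.0)  # (dz, dy, dx) mm
    semi_axes: tuple = (40.0, 65.0, 55.0)  # sac ellipsoid (az, ay, ax) mm
    center: tuple | None = None  # defaults to the grid center (mm)
    thickness_kind: str = "lobed"  # constant | gradient | lobed
    t0: float = 8.0  # baseline EAT shell thickness, mm
    t_amp: float = 4.0  # modulation amplitude, mm
    hu_dist: str = "gaussian"  # gaussian | skewnorm
    hu_loc: float = -80.0
    hu_scale: float = 20.0
    hu_shape: float = 0.0  # skew-normal shape parameter a
    core_hu: float = 40.0
    background_hu: float = -900.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing) or any(a <= 0 for a in self.semi_axes):
            raise ValueError("spacing and semi-axes must be strictly positive")
        if self.t0 < 0 or self.t0 - abs(self.t_amp) < 0:
            raise ValueError("thickness field must be >= 0 everywhere")
        if self.thickness_kind not in ("constant", "gradient", "lobed"):
            raise ValueError(f"unknown thickness_kind {self.thickness_kind!r}")

    @staticmethod
    def clinical(**overrides) -> "PhantomSpec":
        """Clinical calcium-score geometry: ~50 slices of 512x512 at 0.5 mm."""
        base = PhantomSpec(shape=(50, 512, 512), spacing=(2.5, 0.5, 0.5))
        return replace(base, **overrides)

    def thickness_at(self, phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Thickness field t(phi, theta) in mm on the given angles (radians)."""
        if self.thickness_kind == "constant":
            return np.full(np.broadcast(phi, theta).shape, self.t0)
        if self.thickness_kind == "gradient":
            return self.t0 + self.t_amp * np.cos(phi)
        return self.t0 + self.t_amp * np.cos(theta) * np.sin(phi)


def generate_phantom(spec: PhantomSpec):
    """Voxelize the phantom; returns ``(volume, sac_mask, truth)``.

    The EAT shell is the set of sac voxels whose radial distance to the sac
    boundary (along the ray from the sac center — analytic for an ellipsoid)
    is at most the local thickness field at the voxel's direction.
    ``truth`` carries the constructed EAT mask, analytic volumes where a
    closed form exists (spherical sac, constant thickness), the HU model
    parameters, and any discretization warnings.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing)
    nz, ny, nx = spec.shape
    z, y, x = np.meshgrid(
        np.arange(nz) * spacing[0],
        np.arange(ny) * spacing[1],
        np.arange(nx) * spacing[2],
        indexing="ij",
    )
    if spec.center is None:
        center = ((nz - 1) * spacing[0] / 2, (ny - 1) * spacing[1] / 2, (nx - 1) * spacing[2] / 2)
    else:
        center = spec.center
    az, ay, ax = spec.semi_axes
    dz, dy, dx = z - center[0], y - center[1], x - center[2]
    sac_data = (dz / az) ** 2 + (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0
    if not sac_data.any():
        raise ValueError("sac ellipsoid does not intersect the grid")
    if sac_data[0].any() or sac_data[-1].any() or sac_data[:, 0].any() or sac_data[:, -1].any() \
            or sac_data[:, :, 0].any() or sac_data[:, :, -1].any():
        raise ValueError("sac ellipsoid touches the grid boundary; enlarge the grid")

    # radial depth: distance to the sac boundary along the ray from the
    # center, R(u) - |p| with R(u) = 1/sqrt(sum (u_i/a_i)^2). Analytic, so
    # the shell is exactly t(phi, theta) thick as seen from the centroid.
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    rs = np.maximum(r, 1e-12)
    uz, uy, ux = dz / rs, dy / rs, dx / rs
    R = 1.0 / np.sqrt(np.maximum((uz / az) ** 2 + (uy / ay) ** 2 + (ux / ax) ** 2, 1e-18))
    depth = np.where(r > 0, R - r, np.min(spec.semi_axes))
    phi = np.arccos(np.clip(np.where(r > 0, uz, 1.0), -1, 1))
    theta = np.arctan2(dy, dx)
    t_field = spec.thickness_at(phi, theta)
    eat_data = sac_data & (depth <= t_field)

    hu = np.full(spec.shape, spec.background_hu, dtype=float)
    hu[sac_data] = spec.core_hu
    n_eat = int(eat_data.sum())
    if spec.hu_dist == "gaussian":
        draws = rng.normal(spec.hu_loc, spec.hu_scale, size=n_eat)
    elif spec.hu_dist == "skewnorm":
        draws = sps.skewnorm.rvs(
            spec.hu_shape, loc=spec.hu_loc, scale=spec.hu_scale, size=n_eat, random_state=rng
        )
    else:
        raise ValueError(f"unknown hu_dist {spec.hu_dist!r}")
    hu[eat_data] = draws
    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    warnings_list = []
    min_thickness = float(np.min(spec.thickness_at(np.linspace(0, np.pi, 181), 0.0)))
    if spec.thickness_kind == "lobed":
        min_thickness = spec.t0 - abs(spec.t_amp)
    if min_thickness < max(spec.spacing):
        warnings_list.append(
            f"EAT shell ({min_thickness:.1f} mm minimum) thinner than one voxel "
            f"({max(spec.spacing):.1f} mm) somewhere"
        )

    is_sphere = np.allclose(spec.semi_axes, spec.semi_axes[0])
    analytic_eat = None
    if is_sphere and spec.thickness_kind == "constant":
        rr = spec.semi_axes[0]
        analytic_eat = 4.0 / 3.0 * np.pi * (rr**3 - max(rr - spec.t0, 0.0) ** 3)
    truth = {
        "spec": spec,
        "eat_mask": BinaryMask(eat_data, spec.spacing),
        "eat_voxels": n_eat,
        "sac_voxels": int(sac_data.sum()),
        "analytic_sac_volume_mm3": 4.0 / 3.0 * np.pi * az * ay * ax,
        "analytic_eat_volume_mm3": analytic_eat,
        "hu_params": {
            "dist": spec.hu_dist,
            "loc": spec.hu_loc,
            "scale": spec.hu_scale,
            "shape": spec.hu_shape,
        },
        "warnings": warnings_list,
    }
    vol = ImageVolume(hu, spec.spacing)
    sac = BinaryMask(sac_data, spec.spacing)
    return vol, sac, truth


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Weibull proportional-hazards cohort generator settings.

    ``beta`` maps feature names to log-hazard coefficients (applied to
    z-scored features). Censoring is administrative-uniform: C ~ U(0, w)
    with the window width w calibrated by bisection so the realized event
    fraction hits ``event_fraction`` (default 0.56, the enriched-event
    design). ``baseline_scale`` is in days; 6 years is the default maximum
    administrative follow-up.
    """

    beta: dict = field(default_factory=dict)
    baseline_shape: float = 1.2
    baseline_scale: float = 1000.0
    admin_window_days: float = 6 * 365.0
    event_fraction: float | None = 0.56
    seed: int = 0

    def __post_init__(self):
        if self.event_fraction is not None and not 0 < self.event_fraction < 1:
            raise ValueError("event_fraction must be in (0, 1)")


def weibull_ph_survival(t: np.ndarray, lp: float, shape: float, scale: float) -> np.ndarray:
    """Analytic S(t | linear predictor) of the simulator's Weibull PH model."""
    return np.exp(-((np.asarray(t, float) / scale) ** shape) * np.exp(lp))


def simulate_survival(features: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Draw (time_days, event) per subject under a Weibull PH model.

    Event time inversion: T = scale * (-ln U / exp(beta.x))^(1/shape) with
    z-scored features. Returns a DataFrame indexed like ``features`` with
    columns ``time_days`` and ``event``.
    """
    missing = [k for k in spec.beta if k not in features.columns]
    if missing:
        raise KeyError(f"beta names absent from feature table: {missing}")
    rng = np.random.default_rng(spec.seed)
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    lp = np.zeros(n)
    for name, b in spec.beta.items():
        col = features[name].to_numpy(float)
        sd = col.std()
        if sd > 0:
            lp += b * (col - col.mean()) / sd
    u = rng.uniform(size=n)
    T = spec.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / spec.baseline_shape)

    if spec.event_fraction is None:
        time, event = T, np.ones(n, dtype=int)
    else:
        uc = rng.uniform(size=n)

        def realized(w):
            return float(np.mean(T <= w * uc))

        w_lo, w_hi = 1e-3, 200.0 * spec.admin_window_days
        f_lo, f_hi = realized(w_lo), realized(w_hi)
        if not f_lo <= spec.event_fraction <= f_hi:
            raise ValueError(
                f"target event fraction {spec.event_fraction} unattainable; "
                f"achievable range [{f_lo:.3f}, {f_hi:.3f}]"
            )
        for _ in range(200):
            w_mid = 0.5 * (w_lo + w_hi)
            if realized(w_mid) < spec.event_fraction:
                w_lo = w_mid
            else:
                w_hi = w_mid
        C = w_hi * uc
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    out = pd.DataFrame(
        {"time_days": np.maximum(time, 1e-6), "event": event}, index=features.index
    )
    out.index.name = features.index.name or "study_id"
    return out


def simulate_feature_table(
    n: int,
    seed: int = 0,
    catalog: FeatureCatalog | None = None,
    n_factors: int = 6,
) -> pd.DataFrame:
    """Correlated synthetic feature table on the 148 catalog names.

    A low-rank latent-factor model induces the block correlation seen in
    real fat-omics tables (volumes co-vary, HU bins co-vary); per-category
    transforms put columns on plausible scales (volumes positive via exp,
    probabilities in [0, 1] via a logistic). This is a modeling-stage
    stand-in, not a substitute for phantom-derived features.
    """
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, n_factors))
    rows = []
    for d in catalog.definitions:
        load = rng.normal(scale=0.6, size=n_factors)
        raw = z @ load + rng.normal(scale=0.7, size=n)
        name = d.name
        if name.startswith(("vol", "Vol", "EAT_vol", "SAC_vol")):
            scale = rng.uniform(1.0, 80.0)
            col = scale * np.exp(0.35 * raw)
        elif name.startswith(("Pro", "EAT_sac_fraction", "Thickness_frac")):
            col = 1.0 / (1.0 + np.exp(-0.8 * raw))
        elif name.startswith("Thickness_count"):
            col = 16200.0 * np.exp(0.2 * raw)
        elif "axis" in name.lower() or name.startswith("Thickness_M"):
            col = rng.uniform(10.0, 120.0) + 8.0 * raw
        else:  # HU statistics and their subregion variants
            col = -80.0 + 15.0 * raw
        rows.append(col)
    X = pd.DataFrame(
        np.column_stack(rows), columns=catalog.names,
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="study_id"),
    )
    return X
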