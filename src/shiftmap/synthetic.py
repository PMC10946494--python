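"""Latent-factor generator for correlated chemical-shift tables.

The generative assumption behind the whole package is that chemically
homologous protons experience the same matrix effects (pH, ionic strength,
protein binding), so their shifts co-vary almost linearly. This module makes
that assumption executable: each sample draws standard-normal latent factor
values, and each spin system's shift is

    delta_ij = mu_i + sum_f L_if * f_jf + eps_ij,   eps ~ N(0, sigma_i^2),

followed by per-system random detection (missing completely at random) and
rounding to the recording precision (4 decimals), so quantization error
(~2.9e-5 ppm sd) is part of the simulated measurement.

:func:`serum_panel_spec` builds a 16-system panel shaped like real serum
profiling data: one dominant global matrix factor (drift ranges ~0.05 ppm),
weak class-specific factors (amino acids / carboxylic acids+sugar /
alcohol+ketone) that make within-class models strictly the most accurate,
a glycine--histidine-specific factor plus an idiosyncratic histidine factor
(so histidine's best model sits near R^2 ~ 0.97, the panel's outlier), and
scarce detection for ethanol (157/940) and 3-hydroxybutyrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import ModelMatrix
from .registry import Registry, default_registry
from .table import ShiftTable, quantize_ppm

__all__ = [
    "SystemSpec",
    "SyntheticSpec",
    "simulate_shift_table",
    "serum_panel_spec",
    "recovery_report",
]

# Generator constants for the serum-like panel (ppm). Chosen so that column
# ranges are ~0.05 ppm, single within-class edge rmse ~1e-4 ppm, cross-class
# R^2 ~0.998 and histidine's best model R^2 ~0.97. The histidine-specific
# factor is bounded (unit-variance uniform): pH-like effects have finite
# range, which keeps histidine's worst-case error near ~3 linewidths instead
# of growing with the Gaussian tail. See docs/methods.md.
GLOBAL_SCALE = 8.0e-3
CLASS_SCALE = 2.5e-4
GLY_HIS_SCALE = 2.0e-4
HIS_OWN_SCALE = 1.408e-3
NOISE_SIGMA = 6.0e-5
ETHANOL_DETECT = 157.0 / 940.0
HYDROXYBUTYRATE_DETECT = 0.25

# Per-system sensitivity multipliers (dimensionless); valine is the 1.0
# reference. Spread within [0.9, 1.1] so fitted slopes differ from 1.
_SENSITIVITY = {
    "valine_CH3": 1.00,
    "alanine_CH3": 1.06,
    "leucine_CH3": 0.94,
    "isoleucine_CH3": 1.02,
    "tyrosine_CH": 0.92,
    "phenylalanine_CH": 1.08,
    "glycine_CH2": 1.00,
    "histidine_CH": 1.00,
    "lactate_CH3": 0.96,
    "acetate_CH3": 1.04,
    "pyruvate_CH3": 0.98,
    "formate_CH": 1.10,
    "hydroxybutyrate_CH3": 0.90,
    "glucose_anomeric": 1.05,
    "ethanol_CH3": 0.95,
    "acetone_CH3": 1.01,
}


@dataclass
class SystemSpec:
    """Generative description of one spin system."""

    id: str
    mu: float  # nominal shift, ppm
    loadings: dict[str, float]  # factor name -> sensitivity (ppm per unit factor)
    sigma: float = NOISE_SIGMA  # residual measurement noise, ppm
    detect_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.loadings:
            raise ValueError(f"{self.id}: every system must load on >= 1 factor")
        if self.sigma < 0:
            raise ValueError(f"{self.id}: sigma must be >= 0")
        if not 0.0 < self.detect_prob <= 1.0:
            raise ValueError(f"{self.id}: detect_prob must be in (0, 1]")


@dataclass
class SyntheticSpec:
    """A correlated-shift dataset description: systems + latent factors.

    ``factor_dists`` maps a factor name to its (unit-variance) law:
    ``"normal"`` (default) or ``"uniform"`` for bounded, pH-like effects.
    """

    systems: list[SystemSpec]
    factors: list[str]
    seed: int | None = None
    precision: int | None = 4  # None disables quantization (exact-line limit)
    factor_dists: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.factors)
        for s in self.systems:
            stray = set(s.loadings) - known
            if stray:
                raise ValueError(f"{s.id}: loadings on undeclared factors {stray}")
        bad = {
            f: d for f, d in self.factor_dists.items()
            if d not in ("normal", "uniform") or f not in known
        }
        if bad:
            raise ValueError(f"invalid factor distribution entries: {bad}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.systems]

    def loading_matrix(self) -> np.ndarray:
        """(n_systems, n_factors) loading matrix in spec order."""
        L = np.zeros((len(self.systems), len(self.factors)))
        fidx = {f: j for j, f in enumerate(self.factors)}
        for i, s in enumerate(self.systems):
            for f, val in s.loadings.items():
                L[i, fidx[f]] = val
        return L

    def quantization_variance(self) -> float:
        """Variance of the rounding error added by the recording precision."""
        if self.precision is None:
            return 0.0
        step = 10.0 ** (-self.precision)
        return step * step / 12.0


def simulate_shift_table(
    spec: SyntheticSpec, n_samples: int, seed: int | None = None
) -> ShiftTable:
    """Draw a shift table from the generative model.

    Fully reproducible: same spec + seed + n gives a bit-identical table.
    ``seed`` overrides ``spec.seed`` when given.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_sys = len(spec.systems)
    F = rng.standard_normal((n_samples, len(spec.factors)))
    for j, f in enumerate(spec.factors):
        if spec.factor_dists.get(f, "normal") == "uniform":
            # unit-variance uniform on (-sqrt(3), sqrt(3)); redrawn so the
            # factor stream stays aligned with the normal draws above
            F[:, j] = rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), n_samples)
    eps = rng.standard_normal((n_samples, n_sys))
    detect_u = rng.random((n_samples, n_sys))

    L = spec.loading_matrix()
    mu = np.array([s.mu for s in spec.systems])
    sigma = np.array([s.sigma for s in spec.systems])
    values = mu + F @ L.T + eps * sigma
    pdet = np.array([s.detect_prob for s in spec.systems])
    values[detect_u >= pdet] = np.nan

    if spec.precision is not None:
        p = spec.precision
        flat = values.ravel()
        values = np.array(
            [quantize_ppm(v, p) if not np.isnan(v) else np.nan for v in flat]
        ).reshape(values.shape)

    df = pd.DataFrame(
        values,
        index=pd.Index([f"S{i + 1:05d}" for i in range(n_samples)], name="sample"),
        columns=spec.ids,
    )
    return ShiftTable(df, precision=spec.precision or 4)


def serum_panel_spec(
    registry: Registry | None = None,
    sigma: float = NOISE_SIGMA,
    full_detection: bool = False,
    precision: int | None = 4,
    seed: int | None = None,
    collinear: bool = False,
) -> SyntheticSpec:
    """The 16-system serum-like panel (see module docstring for the shape).

    With ``collinear=True`` only the global matrix factor is loaded, so all
    systems are exactly proportional: together with ``sigma=0`` and
    ``precision=None`` this is the exact-line limit in which predictions
    reproduce observations identically.
    """
    registry = registry or default_registry()
    factors = ["global", "amino_acid", "acid_sugar", "alcohol_ketone",
               "gly_his", "histidine_own"]
    systems: list[SystemSpec] = []
    for s in registry:
        k = _SENSITIVITY.get(s.id, 1.0)
        if collinear:
            loadings = {"global": GLOBAL_SCALE * k}
        else:
            loadings = {"global": GLOBAL_SCALE * k, s.class_group: CLASS_SCALE * k}
            if s.id == "glycine_CH2":
                loadings["gly_his"] = GLY_HIS_SCALE
            if s.id == "histidine_CH":
                loadings["gly_his"] = GLY_HIS_SCALE
                loadings["histidine_own"] = HIS_OWN_SCALE
        detect = 1.0
        if not full_detection:
            if s.id == "ethanol_CH3":
                detect = ETHANOL_DETECT
            elif s.id == "hydroxybutyrate_CH3":
                detect = HYDROXYBUTYRATE_DETECT
        systems.append(
            SystemSpec(
                id=s.id, mu=s.nominal_delta, loadings=loadings,
                sigma=sigma, detect_prob=detect,
            )
        )
    return SyntheticSpec(
        systems=systems, factors=factors, seed=seed, precision=precision,
        factor_dists={"histidine_own": "uniform"},
    )


def population_slope(spec: SyntheticSpec, response_id: str, predictor_id: str) -> float:
    """The slope OLS consistently estimates for a pair under this spec.

    cov(y, x) / var(x), with var(x) including measurement noise and the
    quantization variance of the recording precision. NaN when the pair
    shares no factor (slope undefined).
    """
    by_id = {s.id: s for s in spec.systems}
    sy, sx = by_id[response_id], by_id[predictor_id]
    cov = sum(ly * sx.loadings.get(f, 0.0) for f, ly in sy.loadings.items())
    if cov == 0.0:
        return float("nan")
    var_x = (
        sum(v * v for v in sx.loadings.values())
        + sx.sigma**2
        + spec.quantization_variance()
    )
    return cov / var_x


def latent_ratio(spec: SyntheticSpec, response_id: str, predictor_id: str) -> float:
    """s_y / s_x for pairs whose loading vectors are proportional, else NaN."""
    by_id = {s.id: s for s in spec.systems}
    sy, sx = by_id[response_id], by_id[predictor_id]
    facs = set(sy.loadings) | set(sx.loadings)
    ly = np.array([sy.loadings.get(f, 0.0) for f in sorted(facs)])
    lx = np.array([sx.loadings.get(f, 0.0) for f in sorted(facs)])
    nx = float(np.linalg.norm(lx))
    if nx == 0.0:
        return float("nan")
    ratio = float(np.dot(ly, lx) / (nx * nx))
    if np.allclose(ly, ratio * lx, rtol=1e-9, atol=1e-15):
        return ratio
    return float("nan")


def recovery_report(spec: SyntheticSpec, m: ModelMatrix) -> pd.DataFrame:
    """Parameter-recovery harness: fitted slopes vs generative truth.

    For every fitted pair sharing at least one latent factor, reports the
    population OLS slope (the attenuated cov/var target that OLS estimates
    under measurement noise + quantization), the latent sensitivity ratio
    s_y/s_x where the loading vectors are proportional (NaN otherwise), and
    the z-score (fitted - population) / SE. Pairs spanning disjoint factors
    are excluded.
    """
    rows = []
    for (resp, pred), pm in m.models.items():
        pop = population_slope(spec, resp, pred)
        if math.isnan(pop):
            continue
        ratio = latent_ratio(spec, resp, pred)
        z = (pm.a - pop) / pm.se_a if pm.se_a and math.isfinite(pm.se_a) else float("nan")
        rows.append(
            (resp, pred, pm.n, pm.a, pm.se_a, pop, ratio, z, pm.stable and pm.usable)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "response", "predictor", "n", "fitted_a", "se_a",
            "pop_slope", "latent_ratio", "z", "stable",
        ],
    )
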