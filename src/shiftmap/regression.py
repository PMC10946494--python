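"""Pairwise linear shift models.

Every ordered pair of spin systems (response y, predictor x) gets an ordinary
least-squares fit of the form ``y = a*x + b`` over the pairwise-complete
samples, together with the quality metrics used to rank predictors:

* ``r2``   — goodness of fit (squared Pearson correlation),
* ``rmse`` — root-mean-square residual in ppm (denominator n by default),
* ``rrmse``— 100 * rmse / mean(observed y), in percent; on ~1 ppm signals an
  rmse of 1e-4 ppm reads as ~0.01 %,
* ``max_abs_resid`` — the training error envelope in ppm.

Pairs with fewer than ``min_n`` co-detections are kept but flagged unstable
(e.g. ethanol vs 3-hydroxybutyrate, both scarce in serum); unstable models are
excluded from predictor selection and map building.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .table import ShiftTable, paired_values

__all__ = [
    "PairModel",
    "ModelMatrix",
    "RegressionError",
    "DegeneratePredictorError",
    "NoStablePredictorError",
    "fit_pair",
    "fit_all_pairs",
    "rrmse_matrix",
    "best_predictor",
]

DEFAULT_MIN_N = 50  # below this many paired samples a model is unstable


class RegressionError(ValueError):
    pass


class DegeneratePredictorError(RegressionError):
    """Predictor column is constant; the slope is undefined."""


class NoStablePredictorError(RegressionError):
    """No stable candidate model exists for the requested response."""


@dataclass
class PairModel:
    """One fitted ``y = a*x + b`` shift model with its quality metrics."""

    response_id: str
    predictor_id: str
    a: float
    b: float
    n: int
    r2: float
    rmse: float
    rrmse: float
    max_abs_resid: float
    se_a: float
    usable: bool = True
    stable: bool = True

    def predict(self, x: float) -> float:
        return self.a * x + self.b

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PairModel":
        return cls(**d)


def fit_pair(
    y: np.ndarray,
    x: np.ndarray,
    response_id: str = "y",
    predictor_id: str = "x",
    min_n: int | None = None,
    rmse_ddof: int = 0,
) -> PairModel:
    """Ordinary least squares with intercept on one (y, x) pair.

    ``rmse_ddof`` selects the RMSE denominator ``n - rmse_ddof`` (0 by
    default). The slope standard error uses the conventional n-2 residual
    variance. A constant predictor raises; a constant response yields a model
    flagged unusable (r2 undefined).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise RegressionError("y and x must be 1-D and equally long")
    n = y.size
    if n < 2:
        raise RegressionError(f"need at least 2 paired samples, got {n}")
    xbar = float(np.mean(x))
    ybar = float(np.mean(y))
    xc = x - xbar
    yc = y - ybar
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise DegeneratePredictorError(
            f"predictor {predictor_id!r} is constant over the {n} paired samples"
        )
    sxy = float(np.dot(xc, yc))
    a = sxy / sxx
    b = ybar - a * xbar
    resid = y - (a * x + b)
    ssres = float(np.dot(resid, resid))
    sstot = float(np.dot(yc, yc))
    usable = sstot > 0.0
    if usable:
        r2 = 1.0 - ssres / sstot
        r2 = min(1.0, max(0.0, r2))
    else:
        r2 = float("nan")
    rmse = math.sqrt(ssres / (n - rmse_ddof))
    rrmse = 100.0 * rmse / abs(ybar) if ybar != 0.0 else float("nan")
    max_abs_resid = float(np.max(np.abs(resid)))
    se_a = math.sqrt((ssres / (n - 2)) / sxx) if n > 2 else float("nan")
    stable = usable and (min_n is None or n >= min_n)
    return PairModel(
        response_id=response_id,
        predictor_id=predictor_id,
        a=a,
        b=b,
        n=n,
        r2=r2,
        rmse=rmse,
        rrmse=rrmse,
        max_abs_resid=max_abs_resid,
        se_a=se_a,
        usable=usable,
        stable=stable,
    )


@dataclass
class ModelMatrix:
    """All fitted ordered-pair models for one shift table.

    ``models`` maps ``(response_id, predictor_id)`` to a :class:`PairModel`.
    For k fully observed systems there are exactly k*(k-1) entries; pairs with
    fewer than 2 co-detections are absent, pairs below ``min_n`` are present
    but unstable.
    """

    models: dict[tuple[str, str], PairModel]
    systems: list[str]
    min_n: int = DEFAULT_MIN_N

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self.models

    def get(self, response_id: str, predictor_id: str) -> PairModel:
        try:
            return self.models[(response_id, predictor_id)]
        except KeyError:
            raise KeyError(
                f"no fitted model for response {response_id!r} "
                f"from predictor {predictor_id!r}"
            ) from None

    def incoming(self, response_id: str) -> dict[str, PairModel]:
        """All models predicting ``response_id``, keyed by predictor."""
        return {
            p: m for (r, p), m in self.models.items() if r == response_id
        }

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "systems": self.systems,
            "min_n": self.min_n,
            "models": [m.to_dict() for m in self.models.values()],
        }
        text = json.dumps(payload, indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelMatrix":
        text = Path(source).read_text(encoding="utf-8") if Path(
            str(source)
        ).exists() else str(source)
        payload = json.loads(text)
        models = {
            (d["response_id"], d["predictor_id"]): PairModel.from_dict(d)
            for d in payload["models"]
        }
        return cls(models=models, systems=payload["systems"], min_n=payload["min_n"])


def fit_all_pairs(
    t: ShiftTable, min_n: int = DEFAULT_MIN_N, rmse_ddof: int = 0
) -> ModelMatrix:
    """Fit every ordered (response, predictor) pair of the table.

    Uses pairwise-complete observations per pair, so per-model n varies with
    co-detection (the study design: scarce metabolites keep their own
    sample support). Degenerate pairs (constant predictor) are recorded as
    unusable placeholder entries so the k*(k-1) bookkeeping stays intact.
    """
    systems = t.systems
    if len(systems) < 2:
        raise RegressionError("need at least 2 spin systems to fit pairs")
    models: dict[tuple[str, str], PairModel] = {}
    for resp in systems:
        for pred in systems:
            if resp == pred:
                continue
            y, x, n = paired_values(t, resp, pred)
            if n < 2:
                continue
            try:
                m = fit_pair(y, x, resp, pred, min_n=min_n, rmse_ddof=rmse_ddof)
            except DegeneratePredictorError:
                m = PairModel(
                    response_id=resp, predictor_id=pred,
                    a=float("nan"), b=float("nan"), n=n,
                    r2=float("nan"), rmse=float("nan"), rrmse=float("nan"),
                    max_abs_resid=float("nan"), se_a=float("nan"),
                    usable=False, stable=False,
                )
            models[(resp, pred)] = m
    return ModelMatrix(models=models, systems=systems, min_n=min_n)


def rrmse_matrix(m: ModelMatrix, mask_unstable: bool = True) -> pd.DataFrame:
    """Response x predictor table of rRMSE values in percent.

    The diagonal is empty (NaN); with ``mask_unstable`` (default) unstable and
    unusable models are masked as well, matching how they are greyed out in a
    quality heatmap.
    """
    if len(m) == 0:
        raise RegressionError("empty model matrix")
    df = pd.DataFrame(np.nan, index=m.systems, columns=m.systems, dtype=float)
    for (resp, pred), pm in m.models.items():
        if mask_unstable and not (pm.stable and pm.usable):
            continue
        df.loc[resp, pred] = pm.rrmse
    df.index.name = "response"
    df.columns.name = "predictor"
    return df


def best_predictor(
    m: ModelMatrix,
    response_id: str,
    candidates: set[str] | None = None,
) -> str:
    """The stable candidate predictor minimizing |rRMSE| for a response.

    Ties break by higher r2, then lexicographic predictor id. ``candidates``
    defaults to every other system (global best); pass a restricted set to
    mimic class-guided selection.
    """
    incoming = m.incoming(response_id)
    if candidates is not None:
        incoming = {p: pm for p, pm in incoming.items() if p in candidates}
    eligible = {
        p: pm
        for p, pm in incoming.items()
        if pm.stable and pm.usable and math.isfinite(pm.rrmse)
    }
    if not eligible:
        unstable = sorted(incoming)
        raise NoStablePredictorError(
            f"no stable predictor for {response_id!r}; "
            f"unstable/unusable candidates: {unstable}"
        )
    return min(
        eligible, key=lambda p: (abs(eligible[p].rrmse), -eligible[p].r2, p)
    )
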