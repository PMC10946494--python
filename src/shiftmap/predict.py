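"""Per-sample shift prediction from a bound map, and validation.

Two modes mirror how the maps are used in practice:

* **semi** (semi-automated / user-guided): each response is predicted from
  its predictor's *observed* shift in that sample. When the primary predictor
  is undetected, a per-sample fallback to the alternate edge is tried (e.g.
  acetone from pyruvate when ethanol is absent); otherwise the value is
  reported unavailable.
* **auto** (fully automated): only the anchor's observed shift is used; the
  map is traversed from the root and every node is predicted from its
  parent's *predicted* value, i.e. a composition of affine models.

Chaining is done on unrounded values; the reported shift is rounded to the
table precision. Validation compares predictions against observed shifts and
expresses errors both in ppm and in linewidth units (Δv1/2 ≈ 0.001 ppm at
600 MHz, so the common ~0.05 ppm drift range is ~50 linewidths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import MapError, PredictionMap
from .table import ShiftTable, quantize_ppm

__all__ = [
    "PredictionResult",
    "ValidationReport",
    "predict_semi",
    "predict_auto",
    "validate_predictions",
    "DEFAULT_LINEWIDTH_PPM",
]

log = logging.getLogger(__name__)

#: Full width at half maximum of a serum/plasma peak at 600 MHz, in ppm.
DEFAULT_LINEWIDTH_PPM = 0.001

SOURCE_OBSERVED = "observed_anchor"
SOURCE_PRIMARY = "primary_edge"
SOURCE_ALTERNATE = "alternate_edge"
SOURCE_UNAVAILABLE = "unavailable"

_COLUMNS = ["sample", "system", "predicted", "predicted_raw", "source", "est_error"]


@dataclass
class PredictionResult:
    """Long-format per-(sample, system) predictions.

    ``frame`` columns: sample, system, predicted (rounded ppm), predicted_raw
    (unrounded ppm), source, est_error (conservative max-envelope estimate in
    ppm; NaN where no estimate applies).
    """

    mode: str
    frame: pd.DataFrame

    def wide(self, raw: bool = False) -> pd.DataFrame:
        """Samples x systems matrix of predicted shifts (NaN = unavailable)."""
        col = "predicted_raw" if raw else "predicted"
        return self.frame.pivot(index="sample", columns="system", values=col)

    def sources(self) -> pd.DataFrame:
        return self.frame.pivot(index="sample", columns="system", values="source")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path, mode: str | None = None) -> "PredictionResult":
        frame = pd.read_csv(path, na_values=["NA"])
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: prediction CSV lacks columns {missing}")
        return cls(mode=mode or "semi", frame=frame[_COLUMNS])


def _require_bound(pmap: PredictionMap) -> None:
    if not pmap.is_bound:
        raise MapError("map is not bound to fitted models; call bind_map first")


def predict_semi(
    pmap: PredictionMap,
    t: ShiftTable,
    use_alternates: bool = True,
    precision: int | None = None,
) -> PredictionResult:
    """Predict every map node per sample from observed predictor shifts."""
    _require_bound(pmap)
    precision = t.precision if precision is None else precision
    rows: list[tuple] = []
    observed = t.data
    for sample in t.sample_ids:
        # anchor: carried through as observed
        if pmap.root in observed.columns and not np.isnan(
            observed.at[sample, pmap.root]
        ):
            v = float(observed.at[sample, pmap.root])
            rows.append((sample, pmap.root, v, v, SOURCE_OBSERVED, 0.0))
        else:
            rows.append(
                (sample, pmap.root, np.nan, np.nan, SOURCE_UNAVAILABLE, np.nan)
            )
        for resp in pmap.parents:
            edge = pmap.parents[resp]
            source = SOURCE_UNAVAILABLE
            raw = np.nan
            est = np.nan
            x = (
                observed.at[sample, edge.predictor]
                if edge.predictor in observed.columns
                else np.nan
            )
            if not np.isnan(x):
                raw = edge.model.predict(float(x))
                source = SOURCE_PRIMARY
                est = edge.model.max_abs_resid
            elif use_alternates and resp in pmap.alternates:
                alt = pmap.alternates[resp]
                xa = (
                    observed.at[sample, alt.predictor]
                    if alt.predictor in observed.columns
                    else np.nan
                )
                if not np.isnan(xa):
                    raw = alt.model.predict(float(xa))
                    source = SOURCE_ALTERNATE
                    est = alt.model.max_abs_resid
                    log.debug(
                        "sample %s: %s predicted via alternate %s",
                        sample, resp, alt.predictor,
                    )
            pred = quantize_ppm(raw, precision) if not np.isnan(raw) else np.nan
            rows.append((sample, resp, pred, raw, source, est))
    return PredictionResult("semi", pd.DataFrame(rows, columns=_COLUMNS))


def predict_auto(
    pmap: PredictionMap,
    anchor_values: pd.Series,
    precision: int = 4,
) -> PredictionResult:
    """Chain-predict the whole map from the anchor shift alone.

    ``anchor_values`` is a Series of observed anchor shifts indexed by sample
    id; samples with a missing anchor are skipped (logged). Per-node
    ``est_error`` is the map's chained max-envelope estimate.
    """
    _require_bound(pmap)
    anchor_values = pd.Series(anchor_values, dtype=float)
    order = pmap.topological_order()
    rows: list[tuple] = []
    for sample, v0 in anchor_values.items():
        if np.isnan(v0):
            log.warning("sample %s skipped: anchor %s missing", sample, pmap.root)
            continue
        values: dict[str, float] = {pmap.root: float(v0)}
        rows.append((sample, pmap.root, float(v0), float(v0), SOURCE_OBSERVED, 0.0))
        for node in order[1:]:
            edge = pmap.parents[node]
            raw = edge.model.predict(values[edge.predictor])
            values[node] = raw
            rows.append(
                (
                    sample,
                    node,
                    quantize_ppm(raw, precision),
                    raw,
                    SOURCE_PRIMARY,
                    pmap.chain_envelope.get(node, np.nan),
                )
            )
    return PredictionResult("auto", pd.DataFrame(rows, columns=_COLUMNS))


@dataclass
class ValidationReport:
    """Per-system prediction errors, in ppm and linewidth units.

    ``frame`` is indexed by system with columns n, max_abs_error_ppm,
    rmse_ppm, max_abs_error_linewidths, rmse_linewidths. ``overall`` holds
    the same metrics pooled over all evaluated (sample, system) pairs.
    """

    frame: pd.DataFrame
    overall: dict
    linewidth_ppm: float = DEFAULT_LINEWIDTH_PPM

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.loc["__overall__"] = [
            self.overall[c] for c in out.columns
        ]
        out.to_csv(path, index_label="system", na_rep="NA")


def validate_predictions(
    p: PredictionResult,
    observed: ShiftTable,
    linewidth_ppm: float = DEFAULT_LINEWIDTH_PPM,
) -> ValidationReport:
    """Compare predictions with observed shifts, system by system.

    Only (sample, system) pairs with both a prediction and an observed value
    contribute; systems with no overlap are reported with n=0 and empty
    metrics. Errors are predicted - observed on the rounded predictions.
    """
    if linewidth_ppm <= 0:
        raise ValueError("linewidth_ppm must be positive")
    pred = p.frame[p.frame["source"] != SOURCE_UNAVAILABLE]
    systems = list(dict.fromkeys(p.frame["system"]))
    unknown = [s for s in systems if s not in observed.systems]
    records = []
    all_errors: list[np.ndarray] = []
    for system in systems:
        if system in unknown:
            records.append((system, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        sub = pred[pred["system"] == system]
        obs = observed.column(system).reindex(sub["sample"]).to_numpy(dtype=float)
        prd = sub["predicted"].to_numpy(dtype=float)
        ok = ~np.isnan(obs) & ~np.isnan(prd)
        err = prd[ok] - obs[ok]
        n = int(ok.sum())
        if n == 0:
            records.append((system, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        max_abs = float(np.max(np.abs(err)))
        rmse = float(np.sqrt(np.mean(err**2)))
        records.append(
            (system, n, max_abs, rmse, max_abs / linewidth_ppm, rmse / linewidth_ppm)
        )
        all_errors.append(err)
    frame = pd.DataFrame(
        records,
        columns=[
            "system", "n", "max_abs_error_ppm", "rmse_ppm",
            "max_abs_error_linewidths", "rmse_linewidths",
        ],
    ).set_index("system")
    if all_errors:
        pooled = np.concatenate(all_errors)
        overall = {
            "n": int(pooled.size),
            "max_abs_error_ppm": float(np.max(np.abs(pooled))),
            "rmse_ppm": float(np.sqrt(np.mean(pooled**2))),
        }
        overall["max_abs_error_linewidths"] = (
            overall["max_abs_error_ppm"] / linewidth_ppm
        )
        overall["rmse_linewidths"] = overall["rmse_ppm"] / linewidth_ppm
    else:
        overall = {
            "n": 0, "max_abs_error_ppm": np.nan, "rmse_ppm": np.nan,
            "max_abs_error_linewidths": np.nan, "rmse_linewidths": np.nan,
        }
    return ValidationReport(frame=frame, overall=overall, linewidth_ppm=linewidth_ppm)
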