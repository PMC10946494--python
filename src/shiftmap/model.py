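"""Model/Results facade over the pairwise-regression map workflow.

``ShiftMapModel`` holds the data (a shift table plus a spin-system registry)
and configuration; ``fit()`` runs the pairwise OLS sweep and map assembly and
returns a ``ShiftMapResults`` carrying the fitted model matrix, the bound
prediction map, per-edge uncertainties and a ``summary()`` table. Prediction
and validation hang off the results object:

>>> from shiftmap import ShiftMapModel, serum_panel_spec, simulate_shift_table
>>> table = simulate_shift_table(serum_panel_spec(), 940, seed=7)
>>> res = ShiftMapModel(table).fit(topology="published")
>>> print(res.summary())                       # doctest: +SKIP
>>> pred = res.predict_auto(table.column("valine_CH3"))
>>> report = res.validate(pred, table)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mapping import (
    DEFAULT_ROOT,
    PredictionMap,
    bind_map,
    build_map,
    published_map,
)
from .predict import (
    DEFAULT_LINEWIDTH_PPM,
    PredictionResult,
    ValidationReport,
    predict_auto,
    predict_semi,
    validate_predictions,
)
from .regression import DEFAULT_MIN_N, ModelMatrix, best_predictor, fit_all_pairs, rrmse_matrix
from .registry import Registry, default_registry
from .table import ShiftTable, read_shift_table

__all__ = ["ShiftMapModel", "ShiftMapResults"]


class ShiftMapModel:
    """Pairwise linear shift-prediction model for a panel of spin systems.

    Parameters
    ----------
    table : ShiftTable
        Training shifts (samples x systems, ppm, missing allowed).
    registry : Registry, optional
        Spin-system metadata; defaults to the packaged 16-system panel when
        the table's columns are covered by it, otherwise stays None (class-
        guided map building then requires an explicit registry).
    min_n : int
        Minimum paired-sample count for a model to count as stable.
    rmse_ddof : int
        Denominator correction for RMSE (0: divide by n).
    """

    def __init__(
        self,
        table: ShiftTable,
        registry: Registry | None = None,
        min_n: int = DEFAULT_MIN_N,
        rmse_ddof: int = 0,
    ):
        self.table = table
        if registry is None:
            candidate = default_registry()
            if all(s in candidate for s in table.systems):
                registry = candidate
        self.registry = registry
        self.min_n = min_n
        self.rmse_ddof = rmse_ddof

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ShiftMapModel":
        sep = kwargs.pop("sep", None)
        precision = kwargs.pop("precision", 4)
        return cls(read_shift_table(path, sep=sep, precision=precision), **kwargs)

    def fit(
        self,
        root: str = DEFAULT_ROOT,
        topology: str | PredictionMap = "auto",
        weight: str = "rrmse",
        class_guided: bool = False,
        bridges: tuple[str, ...] = (),
    ) -> "ShiftMapResults":
        """Fit all pairwise models and assemble the prediction map.

        ``topology`` is ``"auto"`` (minimum-error arborescence), ``"published"``
        (the fixed serum/plasma map) or an explicit unbound
        :class:`PredictionMap` to bind.
        """
        mm = fit_all_pairs(self.table, min_n=self.min_n, rmse_ddof=self.rmse_ddof)
        if isinstance(topology, PredictionMap):
            pmap = bind_map(topology, mm)
        elif topology == "published":
            pmap = bind_map(published_map(), mm)
        elif topology == "auto":
            pmap = build_map(
                mm, root_id=root, weight=weight,
                class_guided=class_guided, bridges=bridges,
                registry=self.registry,
            )
        else:
            raise ValueError(f"unknown topology {topology!r}")
        return ShiftMapResults(self, mm, pmap)


class ShiftMapResults:
    """Fitted pairwise models + bound prediction map for one training table."""

    def __init__(self, model: ShiftMapModel, model_matrix: ModelMatrix,
                 pmap: PredictionMap):
        self.model = model
        self.model_matrix = model_matrix
        self.map = pmap

    @property
    def root(self) -> str:
        return self.map.root

    # ---- inspection ----------------------------------------------------

    def edges_frame(self) -> pd.DataFrame:
        """One row per primary map edge with coefficients and metrics."""
        rows = []
        for node in self.map.topological_order()[1:]:
            e = self.map.parents[node]
            m = e.model
            rows.append(
                (
                    e.predictor, node, self.map.depth(node), m.a, m.b, m.n,
                    m.r2, m.rmse, m.rrmse, m.max_abs_resid,
                    self.map.chain_rmse.get(node),
                    self.map.chain_envelope.get(node),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "predictor", "response", "depth", "a", "b", "n", "r2",
                "rmse_ppm", "rrmse_pct", "max_abs_resid_ppm",
                "chain_rmse_ppm", "chain_envelope_ppm",
            ],
        )

    def rrmse_table(self, mask_unstable: bool = True) -> pd.DataFrame:
        return rrmse_matrix(self.model_matrix, mask_unstable=mask_unstable)

    def best_predictor(self, response_id: str, candidates=None) -> str:
        return best_predictor(self.model_matrix, response_id, candidates)

    def summary(self) -> str:
        ef = self.edges_frame()
        lines = [
            "Chemical-shift prediction map".center(78),
            "=" * 78,
            f"Anchor (root):        {self.root}",
            f"Predicted systems:    {self.map.n_predicted}",
            f"Fitted pair models:   {len(self.model_matrix)} "
            f"(min_n={self.model_matrix.min_n})",
            f"Training samples:     {self.model.table.n_samples}",
            "-" * 78,
            ef.to_string(
                index=False,
                float_format=lambda v: f"{v:.6g}",
            ),
            "-" * 78,
            "rmse/rrmse are training-data metrics; chain_* are the chained",
            "error estimates at each node (quadrature rmse / summed max-"
            "residual envelope).",
        ]
        return "\n".join(lines)

    # ---- prediction ----------------------------------------------------

    def predict_semi(self, table: ShiftTable | None = None,
                     use_alternates: bool = True) -> PredictionResult:
        return predict_semi(self.map, table if table is not None else self.model.table,
                            use_alternates=use_alternates)

    def predict_auto(self, anchor_values=None) -> PredictionResult:
        if anchor_values is None:
            anchor_values = self.model.table.column(self.root)
        return predict_auto(self.map, anchor_values)

    def validate(
        self,
        predictions: PredictionResult,
        observed: ShiftTable,
        linewidth_ppm: float = DEFAULT_LINEWIDTH_PPM,
    ) -> ValidationReport:
        return validate_predictions(predictions, observed, linewidth_ppm)

    # ---- plotting ------------------------------------------------------

    def plot_rrmse(self, ax=None):
        from .plotting import plot_rrmse_heatmap

        return plot_rrmse_heatmap(self.model_matrix, ax=ax)

    def plot_map(self, ax=None):
        from .plotting import plot_prediction_map

        return plot_prediction_map(self.map, ax=ax)
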