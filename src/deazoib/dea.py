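"""Output-oriented BCC (variable returns to scale) data envelopment analysis.

Each decision-making unit (DMU) — here, a hospital — converts m inputs
(beds, personnel, purchases) into s outputs (discharges, outpatient
activity).  The output-oriented BCC model asks, for a unit under
evaluation, by which factor phi >= 1 all of its outputs could be expanded
simultaneously if it operated as well as the best convex combination of
its peers, holding inputs fixed:

    max  phi
    s.t. sum_j lambda_j x_ij <= x_i0     (i = 1..m)
         sum_j lambda_j y_rj >= phi y_r0 (r = 1..s)
         sum_j lambda_j = 1              (variable returns to scale)
         lambda_j >= 0

Pure technical efficiency (PTE) is 1/phi, in (0, 1]; a unit with PTE = 1
lies on the efficiency frontier.  The convexity constraint sum(lambda)=1
distinguishes the BCC model from the constant-returns CCR model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "ProductionDataset",
    "DEAScore",
    "DEAResult",
    "solve_bcc_output",
    "run_dea",
]

#: default tolerance for calling a unit "on the frontier" (pte >= 1 - tol)
DEFAULT_FRONTIER_TOL = 1e-6


@dataclass(frozen=True)
class ProductionDataset:
    """Per-unit positive input and output matrices for the DEA stage.

    Parameters
    ----------
    unit_ids
        Unique identifiers, one per unit.
    inputs
        Array of shape (n, m): quantity of input i consumed by unit j.
    outputs
        Array of shape (n, s): quantity of output r produced by unit j.
    """

    unit_ids: tuple
    inputs: np.ndarray
    outputs: np.ndarray

    def __post_init__(self) -> None:
        inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        outputs = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "outputs", outputs)
        n = len(self.unit_ids)
        if n < 1:
            raise ValueError("dataset must contain at least one unit")
        if len(set(self.unit_ids)) != n:
            raise ValueError("unit_ids must be unique")
        if inputs.shape[0] != n or outputs.shape[0] != n:
            raise ValueError("inputs/outputs row counts must equal len(unit_ids)")
        if inputs.shape[1] < 1 or outputs.shape[1] < 1:
            raise ValueError("need at least one input and one output column")
        for name, mat in (("inputs", inputs), ("outputs", outputs)):
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{name} must be finite")
            if np.any(mat <= 0):
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.outputs.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        input_cols: Sequence[str],
        output_cols: Sequence[str],
        id_col: str | None = None,
    ) -> "ProductionDataset":
        ids = df[id_col].tolist() if id_col is not None else df.index.tolist()
        return cls(
            unit_ids=tuple(ids),
            inputs=df.loc[:, list(input_cols)].to_numpy(dtype=float),
            outputs=df.loc[:, list(output_cols)].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class DEAScore:
    """BCC score for one unit: expansion factor phi, PTE = 1/phi, peer weights."""

    unit_id: object
    phi: float
    pte: float
    lambdas: np.ndarray
    on_frontier: bool


@dataclass(frozen=True)
class DEAResult:
    """Scores for every unit plus frontier summary statistics."""

    scores: tuple
    mean_pte: float
    n_frontier: int
    pct_frontier: float

    @property
    def pte(self) -> np.ndarray:
        return np.array([s.pte for s in self.scores])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": [s.unit_id for s in self.scores],
                "phi": [s.phi for s in self.scores],
                "pte": [s.pte for s in self.scores],
                "on_frontier": [s.on_frontier for s in self.scores],
            }
        )


def solve_bcc_output(
    dataset: ProductionDataset,
    unit_index: int,
    tol: float = 1e-8,
    frontier_tol: float = DEFAULT_FRONTIER_TOL,
) -> DEAScore:
    """Solve the output-oriented BCC linear program for one unit.

    Decision variables are (phi, lambda_1..lambda_n).  The evaluated unit
    itself (lambda_unit = 1, phi = 1) is always feasible, so the optimum
    satisfies phi >= 1 and the LP cannot be infeasible for valid data.

    Parameters
    ----------
    dataset
        Validated production data.
    unit_index
        Index of the unit under evaluation, in ``[0, n)``.
    tol
        Solver feasibility tolerance.
    frontier_tol
        A unit is flagged ``on_frontier`` when ``pte >= 1 - frontier_tol``.
    """
    n = dataset.n_units
    if not 0 <= unit_index < n:
        raise IndexError(f"unit_index {unit_index} out of range [0, {n})")
    X = dataset.inputs  # (n, m)
    Y = dataset.outputs  # (n, s)
    x0 = X[unit_index]
    y0 = Y[unit_index]
    m, s = dataset.n_inputs, dataset.n_outputs

    # variables z = (phi, lambda); minimize -phi
    c = np.zeros(n + 1)
    c[0] = -1.0
    # input constraints:  lambda^T X_col <= x_i0
    A_in = np.hstack([np.zeros((m, 1)), X.T])
    # output constraints: phi*y_r0 - lambda^T Y_col <= 0
    A_out = np.hstack([y0[:, None], -Y.T])
    A_ub = np.vstack([A_in, A_out])
    b_ub = np.concatenate([x0, np.zeros(s)])
    A_eq = np.hstack([[0.0], np.ones(n)])[None, :]
    bounds = [(0, None)] * (n + 1)

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    if not res.success:  # pragma: no cover - cannot occur for valid data
        raise RuntimeError(
            f"BCC LP failed for unit {dataset.unit_ids[unit_index]}: {res.message}"
        )
    phi = float(res.x[0])
    if phi < 1.0 - 1e-9:  # pragma: no cover - solver contract
        raise RuntimeError(f"phi={phi} < 1: self-evaluation is always feasible")
    phi = max(phi, 1.0)  # absorb solver noise so pte stays in (0, 1]
    lambdas = np.clip(res.x[1:], 0.0, None)
    pte = 1.0 / phi
    return DEAScore(
        unit_id=dataset.unit_ids[unit_index],
        phi=phi,
        pte=pte,
        lambdas=lambdas,
        on_frontier=bool(pte >= 1.0 - frontier_tol),
    )


def run_dea(
    dataset: ProductionDataset,
    frontier_tol: float = DEFAULT_FRONTIER_TOL,
    tol: float = 1e-8,
) -> DEAResult:
    """Score every unit against the empirical VRS frontier.

    Returns one :class:`DEAScore` per unit plus the mean PTE and the
    number/percentage of frontier units.
    """
    scores = tuple(
        solve_bcc_output(dataset, j, tol=tol, frontier_tol=frontier_tol)
        for j in range(dataset.n_units)
    )
    pte = np.array([s.pte for s in scores])
    n_frontier = int(sum(s.on_frontier for s in scores))
    return DEAResult(
        scores=scores,
        mean_pte=float(pte.mean()),
        n_frontier=n_frontier,
        pct_frontier=100.0 * n_frontier / dataset.n_units,
    )
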