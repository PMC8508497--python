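"""Two-stage orchestration: DEA scoring, covariate preparation, Bayesian
ZOIB fit and report generation.

The second stage regresses the DEA pure-technical-efficiency scores on
unit-level and group-level covariates.  Quantitative covariates are
standardized to mean 0 / sd 1 — unit-level columns over the n unit rows,
group-level columns over the J distinct group values (they are regional
attributes, so "one standard deviation" is meant at the regional level).
Factors are dummy-coded against a declared reference category.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dea import ProductionDataset, run_dea
from .inference import ChainSet, MCMCConfig, convergence_check, sample_posterior, summarize
from .report import report_table, write_report
from .zoib import HierarchicalDesign, PriorConfig, ResponseVector

__all__ = [
    "StudyConfig",
    "standardize",
    "zscore",
    "build_design",
    "fit_two_stage",
    "TwoStageResult",
]

logger = logging.getLogger("deazoib")


def standardize(values, name: str = "<column>", ddof: int = 1) -> np.ndarray:
    """(x - mean) / sd with the sample standard deviation (denominator
    n - 1).  Raises on constant columns, naming the offender."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"cannot standardize constant column {name!r}")
    sd = x.std(ddof=ddof)
    return (x - x.mean()) / sd


def zscore(x, mean: float, sd: float):
    """Standardized value (x - mean) / sd from published summary
    statistics."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    out = (np.asarray(x, dtype=float) - mean) / sd
    return float(out) if out.ndim == 0 else out


@dataclass
class StudyConfig:
    """Configuration of a full two-stage run.

    ``response_col`` may name a precomputed PTE column, decoupling the
    regression stage from DEA; when it is None the DEA stage must be
    configured and its PTE scores become the response.
    """

    data_path: str | None = None
    # DEA stage
    dea_input_cols: list = field(default_factory=list)
    dea_output_cols: list = field(default_factory=list)
    id_col: str | None = None
    frontier_tol: float = 1e-6
    # regression stage
    response_col: str | None = None
    group_col: str = "group"
    level1_cols: list = field(default_factory=list)
    level2_cols: list = field(default_factory=list)
    factors: dict = field(default_factory=dict)  # column -> reference level
    endpoint_tol: float = 1e-6
    prior: str = "default"
    chains: int = 4
    warmup: int = 1000
    iters: int = 5000
    seed: int = 0
    # outputs
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self, df: pd.DataFrame) -> None:
        used = (
            list(self.dea_input_cols)
            + list(self.dea_output_cols)
            + list(self.level1_cols)
            + list(self.level2_cols)
        )
        if self.response_col:
            used.append(self.response_col)
        missing = [c for c in used + [self.group_col] if c not in df.columns]
        if missing:
            raise ValueError(f"columns not found in data: {missing}")
        overlap = set(self.dea_input_cols) & set(self.dea_output_cols)
        if overlap:
            raise ValueError(f"columns used as both DEA input and output: {sorted(overlap)}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _dummy_code(df: pd.DataFrame, col: str, reference: str) -> pd.DataFrame:
    levels = list(pd.unique(df[col]))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present in column {col!r}")
    others = [l for l in levels if l != reference]
    return pd.DataFrame(
        {f"{col}[{lvl}]": (df[col] == lvl).astype(float).to_numpy() for lvl in others},
        index=df.index,
    )


def build_design(df: pd.DataFrame, config: StudyConfig) -> HierarchicalDesign:
    """Assemble the hierarchical design from a unit-level table.

    Level-1 quantitative columns are standardized over units; level-2
    columns must be constant within each group and are standardized over
    the J group values before being broadcast back.
    """
    groups = pd.unique(df[config.group_col])
    group_index = {g: j for j, g in enumerate(groups)}
    group_of = df[config.group_col].map(group_index).to_numpy()

    x1_parts, x1_names = [], []
    for col in config.level1_cols:
        if col in config.factors:
            dummies = _dummy_code(df, col, config.factors[col])
            x1_parts.append(dummies.to_numpy())
            x1_names.extend(dummies.columns)
        else:
            x1_parts.append(standardize(df[col].to_numpy(), name=col)[:, None])
            x1_names.append(col)
    X1 = np.column_stack(x1_parts) if x1_parts else np.zeros((len(df), 0))

    x2_cols = []
    for col in config.level2_cols:
        per_group = df.groupby(config.group_col, sort=False)[col].nunique()
        if (per_group > 1).any():
            bad = per_group[per_group > 1].index.tolist()
            raise ValueError(f"level-2 column {col!r} varies within groups {bad}")
        vals = df.groupby(config.group_col, sort=False)[col].first().reindex(groups).to_numpy()
        x2_cols.append(standardize(vals, name=col))
    X2 = np.column_stack(x2_cols) if x2_cols else np.zeros((len(groups), 0))

    return HierarchicalDesign(
        group_of=group_of,
        X1=X1,
        X2=X2,
        x1_names=tuple(x1_names),
        x2_names=tuple(config.level2_cols),
        n_groups=len(groups),
    )


@dataclass
class TwoStageResult:
    """Everything a run produces: DEA scores, posterior summary, formatted
    report, chains and convergence verdicts."""

    dea: pd.DataFrame | None
    summary: pd.DataFrame
    report: pd.DataFrame
    chains: ChainSet
    convergence: pd.DataFrame
    converged: bool
    failed_params: list
    config_hash: str


def fit_two_stage(df: pd.DataFrame, config: StudyConfig) -> TwoStageResult:
    """Run DEA (unless a response column is supplied), prepare covariates,
    sample the ZOIB posterior and build the report.

    Output files (scores CSV, summary CSV/JSON, report) are written when
    ``config.out_dir`` is set, regardless of the convergence verdict;
    unconverged parameters are listed in ``failed_params``.
    """
    config.validate(df)
    dea_df = None
    if config.response_col:
        y_raw = df[config.response_col].to_numpy(dtype=float)
    else:
        if not config.dea_input_cols or not config.dea_output_cols:
            raise ValueError("either response_col or DEA input/output columns are required")
        dataset = ProductionDataset.from_dataframe(
            df, config.dea_input_cols, config.dea_output_cols, id_col=config.id_col
        )
        result = run_dea(dataset, frontier_tol=config.frontier_tol)
        dea_df = result.to_dataframe()
        logger.info(
            "DEA: mean PTE %.4f, %d/%d units on the frontier (%.1f%%)",
            result.mean_pte, result.n_frontier, dataset.n_units, result.pct_frontier,
        )
        y_raw = result.pte

    design = build_design(df, config)
    y = ResponseVector(y=y_raw, endpoint_tol=config.endpoint_tol)
    mcmc = MCMCConfig(chains=config.chains, warmup=config.warmup, iters=config.iters, seed=config.seed)
    logger.info(
        "MCMC: %d chains, %d warmup + %d retained iterations, seed %d, prior %s",
        mcmc.chains, mcmc.warmup, mcmc.iters, mcmc.seed, config.prior,
    )
    chains = sample_posterior(design, y, prior_config=PriorConfig(name=config.prior), mcmc_config=mcmc)
    summary = summarize(chains)
    conv = convergence_check(summary)
    failed = conv.index[~conv["converged"]].tolist()
    report = report_table(summary, factor_refs={c: r for c, r in config.factors.items()})

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if dea_df is not None:
            dea_df.to_csv(out / "dea_scores.csv", index=False)
        write_report(summary, report, out)
        verdict = "converged" if not failed else f"NOT converged: {failed}"
        (out / "run_log.txt").write_text(
            f"config_hash={config.config_hash()}\nseed={config.seed}\n"
            f"chains={config.chains} warmup={config.warmup} iters={config.iters}\n"
            f"prior={config.prior}\nconvergence={verdict}\n"
        )

    return TwoStageResult(
        dea=dea_df,
        summary=summary,
        report=report,
        chains=chains,
        convergence=conv,
        converged=not failed,
        failed_params=failed,
        config_hash=config.config_hash(),
    )
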