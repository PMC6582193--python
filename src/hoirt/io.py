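"""File formats and run configuration.

Conventions: response matrices are comma-delimited, persons in rows with a
header of item ids plus one designated group column; missing cells use a
configurable code (default "NA", which must be distinct from 0/1).  Group
labels are strings, mapped internally to 0..G-1 in order of first
appearance; the anchor group is chosen by label.  Draw storage is a tidy
long-format table (chain, iteration, parameter, value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError
from .model import DimensionMap, ItemBank, ResponseMatrix
from .priors import FourBeta, MCMCConfig, PriorConfig

__all__ = [
    "RunConfig", "read_response_matrix", "write_response_matrix",
    "read_maps", "write_maps", "example_maps", "write_draws", "read_draws",
    "write_summary", "write_implied_matrices", "load_run_config",
]


def read_response_matrix(path, missing_code: str = "NA",
                         group_col: str = "group") -> ResponseMatrix:
    """Read and validate a persons x items CSV into a ResponseMatrix.

    Cells other than 0, 1 or the missing code are rejected with their row
    and column named; duplicate item ids and empty files are errors.
    """
    with open(path) as fh:
        header = fh.readline().strip()
    raw_cols = [c.strip() for c in header.split(",")] if header else []
    if len(set(raw_cols)) != len(raw_cols):
        raise ParameterError(f"duplicate item ids in header of {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] == 0:
        raise ConfigurationError(f"empty response file {path}")
    if group_col not in df.columns:
        raise ConfigurationError(f"missing group column {group_col!r} in {path}")
    labels_col = df[group_col].astype(str)
    item_cols = [c for c in df.columns if c != group_col]
    group_labels: list[str] = []
    for lab in labels_col:
        if lab not in group_labels:
            group_labels.append(lab)
    group = np.array([group_labels.index(lab) for lab in labels_col])
    n, J = len(df), len(item_cols)
    X = np.zeros((n, J), dtype=np.int8)
    obs = np.zeros((n, J), dtype=bool)
    for j, col in enumerate(item_cols):
        vals = df[col].str.strip()
        for i, v in enumerate(vals):
            if v == missing_code or v == "":
                continue
            if v not in ("0", "1"):
                raise ParameterError(
                    f"invalid cell value {v!r} at row {i + 1}, column "
                    f"{col!r} in {path} (expected 0, 1 or {missing_code!r})")
            X[i, j] = int(v)
            obs[i, j] = True
    return ResponseMatrix(X=X, observed=obs, group=group,
                          group_labels=group_labels, item_ids=item_cols)


def write_response_matrix(data: ResponseMatrix, path,
                          missing_code: str = "NA",
                          group_col: str = "group") -> None:
    """Write a ResponseMatrix to CSV; round-trips through
    :func:`read_response_matrix` exactly."""
    cells = np.where(data.observed, data.X.astype(object), missing_code)
    df = pd.DataFrame(cells, columns=data.item_ids)
    df.insert(0, group_col, [data.group_labels[g] for g in data.group])
    df.to_csv(path, index=False)


def read_maps(item_map_path, dimension_map_path) -> tuple[ItemBank, DimensionMap]:
    """Read the item map (item_id, dimension[, alpha, beta]) and dimension
    map (dimension, higher_order) CSVs.

    Items without fixed parameters get placeholder values (alpha 1, beta 0)
    -- the bank then serves as a skeleton whose parameters are estimated.
    """
    im = pd.read_csv(item_map_path)
    dm = pd.read_csv(dimension_map_path)
    for col in ("item_id", "dimension"):
        if col not in im.columns:
            raise ConfigurationError(f"item map must have a {col!r} column")
    for col in ("dimension", "higher_order"):
        if col not in dm.columns:
            raise ConfigurationError(f"dimension map must have a {col!r} column")
    dm = dm.sort_values("dimension")
    dims_list = dm["dimension"].astype(int).tolist()
    D = len(dims_list)
    if dims_list != list(range(1, D + 1)):
        raise ConfigurationError("dimension map must list dimensions 1..D")
    loading = dm["higher_order"].astype(int).to_numpy() - 1
    H = int(loading.max()) + 1
    dim_map = DimensionMap(D=D, H=H, loading=loading)
    item_dim = im["dimension"].astype(int).to_numpy()
    if np.any((item_dim < 1) | (item_dim > D)):
        bad = im["item_id"][(item_dim < 1) | (item_dim > D)].tolist()
        raise ConfigurationError(f"items mapped to unknown dimensions: {bad}")
    counts = np.bincount(item_dim - 1, minlength=D)
    if np.any(counts == 0):
        empty = [d + 1 for d in np.flatnonzero(counts == 0)]
        raise ConfigurationError(f"dimensions with zero items: {empty}")
    alpha = (im["alpha"].astype(float).to_numpy() if "alpha" in im.columns
             else np.ones(len(im)))
    beta = (im["beta"].astype(float).to_numpy() if "beta" in im.columns
            else np.zeros(len(im)))
    bank = ItemBank(item_id=im["item_id"].astype(str).tolist(),
                    dimension=item_dim - 1, discrimination=alpha,
                    difficulty=beta)
    return bank, dim_map


def write_maps(items: ItemBank, dims: DimensionMap, item_map_path,
               dimension_map_path) -> None:
    pd.DataFrame({
        "item_id": items.item_id,
        "dimension": items.dimension + 1,
        "alpha": items.discrimination,
        "beta": items.difficulty,
    }).to_csv(item_map_path, index=False)
    pd.DataFrame({
        "dimension": np.arange(dims.D) + 1,
        "higher_order": dims.loading + 1,
    }).to_csv(dimension_map_path, index=False)


def example_maps() -> tuple[ItemBank, DimensionMap]:
    """A shippable 49-item, 5-dimension example layout.

    Mirrors an integrative-data-analysis instrument pool: 15/6/13/5/10
    items on dimensions 1-5, dimensions 1-3 loading on the first
    second-order construct and 4-5 on the second.
    """
    counts = [15, 6, 13, 5, 10]
    dim = np.concatenate([np.full(c, d) for d, c in enumerate(counts)])
    ids = [f"d{d + 1}_item{k + 1}" for d, c in enumerate(counts)
           for k in range(c)]
    bank = ItemBank(item_id=ids, dimension=dim,
                    discrimination=np.ones(sum(counts)),
                    difficulty=np.zeros(sum(counts)))
    return bank, DimensionMap(D=5, H=2, loading=np.array([0, 0, 0, 1, 1]))


def check_items_covered(data: ResponseMatrix, items: ItemBank) -> None:
    """Every item in the data must appear in the item map."""
    known = set(items.item_id)
    missing = [i for i in data.item_ids if i not in known]
    if missing:
        raise ConfigurationError(f"items in data but not in item map: {missing}")


def write_draws(draws, path) -> None:
    """Tidy long-format draw storage: chain, iteration, parameter, value.

    Covers structural and item parameters plus the deviance trace (person
    traits are summarised, not stored long-form)."""
    params = draws.parameter_dict(include_items=True)
    params["deviance"] = draws.deviance
    params["deviance_complete"] = draws.deviance_complete
    C, K = draws.deviance.shape
    frames = []
    for name, arr in params.items():
        frames.append(pd.DataFrame({
            "chain": np.repeat(np.arange(C) + 1, K),
            "iteration": np.tile(np.arange(K) + 1, C),
            "parameter": name,
            "value": arr.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_draws(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(summary, path) -> None:
    """FitSummary as a delimited table plus a short plain-text report."""
    path = Path(path)
    summary.table.to_csv(path)
    report = path.with_suffix(".txt")
    lines = [
        "Model fit summary",
        f"  Dbar = {summary.dbar:.2f}",
        f"  pD   = {summary.p_d:.2f}",
        f"  DIC  = {summary.dic:.2f}",
        f"  max Gelman-Rubin = {summary.max_gelman_rubin:.4f} "
        f"(threshold {summary.gr_threshold})",
        f"  converged: {summary.converged}",
    ]
    if summary.ppp is not None:
        flagged = summary.flagged_items()
        lo, hi = summary.ppp_bounds
        lines.append(f"  PPMC: {len(summary.ppp)} items checked, "
                     f"{len(flagged)} outside [{lo}, {hi}]")
        if flagged:
            lines.append(f"  flagged items: {flagged}")
    report.write_text("\n".join(lines) + "\n")


def write_implied_matrices(implied, group_labels, outdir) -> None:
    """One labelled CSV per group, mirroring a correlation-table layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    D = implied.matrices.shape[1]
    names = [f"theta{d + 1}" for d in range(D)]
    for g, lab in enumerate(group_labels):
        pd.DataFrame(implied.matrices[g], index=names, columns=names).to_csv(
            outdir / f"implied_{implied.scale}_group_{lab}.csv")


@dataclass
class RunConfig:
    """Resolved configuration for a CLI run."""

    data_path: str | None = None
    item_map_path: str | None = None
    dimension_map_path: str | None = None
    output_dir: str = "hoirt_output"
    anchor_group: str | int = 0
    missing_code: str = "NA"
    group_col: str = "group"
    n_per_group: list[int] = field(default_factory=lambda: [1000, 1000, 1000])
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    ppmc_reps: int = 500

    def __post_init__(self) -> None:
        if self.missing_code in ("0", "1"):
            raise ConfigurationError("missing code must differ from 0/1")


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    prior_raw = raw.pop("priors", {}) or {}
    for key in ("alpha_4beta", "beta_4beta"):
        if key in prior_raw:
            prior_raw[key] = FourBeta(**prior_raw[key])
    for key in ("sigma2_bounds", "lambda_bounds"):
        if key in prior_raw:
            prior_raw[key] = tuple(prior_raw[key])
    mcmc_raw = raw.pop("mcmc", {}) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(priors=PriorConfig(**prior_raw),
                     mcmc=MCMCConfig(**mcmc_raw), **raw)
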