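"""Association statistics between clinical ADA rate and sequence features.

The panel-level analyses: Spearman correlations of ADA rate against
mismatch load and usage/frequency products (overall and within origin
strata), a Welch t-test of mismatch load between human-origin and
humanized antibodies, and a multivariable OLS of ADA rate on the
log2 usage product controlling for target class, disease category and
approval year among human-origin antibodies.

ADA rates are handled on the percent scale throughout; usage products
enter the regression after a log2 transform with an automatic
pseudocount (half the smallest positive value) when zeros are present.
Spearman statistics are computed on untransformed values — rank-based
measures are invariant to monotone transforms, which are applied only
for display.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "OriginComparison",
    "auto_pseudocount",
    "log_transform",
    "correlate",
    "compare_origins",
    "multivariable_regression",
    "report",
]

EXACT_PERMUTATION_MAX_N = 8  # n! alignments enumerated for the exact Spearman p


def auto_pseudocount(values) -> float:
    """Half the smallest positive value; 0 when no zeros are present."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    if not (arr == 0).any():
        return 0.0
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("all values are zero; no pseudocount can be derived")
    return float(positive.min() / 2)


def log_transform(values, pseudocount: float | str = "auto") -> np.ndarray:
    """log2(value + c), with c chosen automatically when zeros occur."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    c = auto_pseudocount(arr) if pseudocount == "auto" else float(pseudocount)
    if ((arr + c) <= 0).any():
        raise ValueError("pseudocount too small: log of non-positive value")
    return np.log2(arr + c)


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    subset: str  # "all" | "human" | "humanized"
    n: int
    spearman_rho: float
    p_value: float


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        rho = np.corrcoef(rx, perm)[0, 1]
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate(
    records: pd.DataFrame,
    predictor: str,
    subset: str = "all",
    outcome: str = "ada_rate",
) -> AssociationResult:
    """Spearman correlation between a predictor and the ADA rate.

    ``subset`` restricts to one origin stratum.  P-values use the
    t-approximation except at very small n, where the permutation
    distribution is enumerated exactly.  A constant predictor yields an
    undefined (NaN) rho with a warning.
    """
    if subset not in ("all", "human", "humanized"):
        raise ValueError(f"unknown subset {subset!r}")
    data = records if subset == "all" else records[records["origin"] == subset]
    cols = [predictor] if predictor == outcome else [predictor, outcome]
    data = data[cols].dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 records with {predictor} and {outcome}; have {n}")
    x = data[predictor].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"{predictor} ({subset}): constant input, rho undefined", stacklevel=2)
        return AssociationResult(predictor, subset, n, float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(x, y, rho)
    return AssociationResult(predictor, subset, n, float(rho), float(p))


@dataclass(frozen=True)
class OriginComparison:
    t_statistic: float
    p_value: float
    mean_human: float
    mean_humanized: float
    n_human: int
    n_humanized: int


def compare_origins(records: pd.DataFrame, column: str = "total_mismatches") -> OriginComparison:
    """Welch two-sample t-test of mismatch load: human vs humanized."""
    human = records.loc[records["origin"] == "human", column].dropna()
    humanized = records.loc[records["origin"] == "humanized", column].dropna()
    if len(human) < 2 or len(humanized) < 2:
        raise ValueError("both origin groups need at least 2 records")
    t, p = stats.ttest_ind(human, humanized, equal_var=False)
    return OriginComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_human=float(human.mean()),
        mean_humanized=float(humanized.mean()),
        n_human=len(human),
        n_humanized=len(humanized),
    )


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Treatment coding with the most frequent level as reference."""
    counts = series.value_counts()
    reference = counts.index[0]
    levels = [lv for lv in sorted(series.unique()) if lv != reference]
    frame = pd.DataFrame(
        {f"{prefix}[{lv}]": (series == lv).astype(float) for lv in levels},
        index=series.index,
    )
    return frame


def multivariable_regression(
    records: pd.DataFrame,
    usage_col: str = "usage_product",
    outcome: str = "ada_rate",
    pseudocount: float | str = "auto",
) -> pd.DataFrame:
    """OLS of ADA rate on log2 usage product with covariate control.

    Restricted to human-origin antibodies.  Covariates: dummy-coded
    target class and disease category (reference = most frequent level)
    and approval year; rows lacking an approval year are dropped with a
    warning.  Returns one row per term: estimate, standard error, p.
    """
    data = records[records["origin"] == "human"].copy()
    n_missing = data["approval_year"].isna().sum()
    if n_missing:
        warnings.warn(f"dropping {n_missing} records without approval year", stacklevel=2)
        data = data.dropna(subset=["approval_year"])
    data = data.dropna(subset=[usage_col, outcome])
    y = data[outcome].astype(float)
    design = pd.concat(
        [
            pd.Series(
                log_transform(data[usage_col], pseudocount),
                index=data.index,
                name=f"log2_{usage_col}",
            ),
            _dummies(data["target_class"].astype(str), "target_class"),
            _dummies(data["disease_category"].astype(str), "disease_category"),
            data["approval_year"].astype(float),
        ],
        axis=1,
    )
    design = sm.add_constant(design, prepend=True, has_constant="add")
    if len(data) <= design.shape[1]:
        raise ValueError(
            f"{len(data)} records cannot identify {design.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        aliased = _aliased_columns(design)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {
            "term": design.columns,
            "estimate": fit.params.values,
            "se": fit.bse.values,
            "p": fit.pvalues.values,
        }
    )


def _aliased_columns(design: pd.DataFrame) -> list[str]:
    """Columns that do not increase the design rank when added in order."""
    aliased = []
    rank = 0
    kept: list[int] = []
    arr = design.to_numpy()
    for j, name in enumerate(design.columns):
        trial = arr[:, kept + [j]]
        new_rank = np.linalg.matrix_rank(trial)
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
        else:
            aliased.append(name)
    return aliased


def report(
    records: pd.DataFrame,
    results: Sequence[AssociationResult],
    outdir: str | Path,
    regression: pd.DataFrame | None = None,
    origin_comparison: OriginComparison | None = None,
    figures: bool = False,
) -> dict[str, Path]:
    """Write the association outputs (CSVs, optionally summary figures)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    assoc = pd.DataFrame(
        {
            "predictor": [r.predictor for r in results],
            "subset": [r.subset for r in results],
            "n": [r.n for r in results],
            "spearman_rho": [r.spearman_rho for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    written["associations"] = outdir / "associations.csv"
    assoc.to_csv(written["associations"], index=False, float_format="%.6g")
    if regression is not None:
        written["regression"] = outdir / "regression.csv"
        regression.to_csv(written["regression"], index=False, float_format="%.6g")
    if origin_comparison is not None:
        written["origin_comparison"] = outdir / "origin_comparison.csv"
        pd.DataFrame([origin_comparison.__dict__]).to_csv(
            written["origin_comparison"], index=False, float_format="%.6g"
        )
    if figures:
        written.update(_figures(records, outdir))
    return written


def _figures(records: pd.DataFrame, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    if "total_mismatches" in records:
        fig, ax = plt.subplots(figsize=(5, 4))
        for origin, group in records.groupby("origin"):
            ax.hist(group["total_mismatches"], bins=20, alpha=0.6, label=origin)
        ax.set_xlabel("total mismatches to closest germline")
        ax.set_ylabel("antibodies")
        ax.legend()
        written["mismatch_hist"] = outdir / "mismatch_histogram.png"
        fig.savefig(written["mismatch_hist"], dpi=120, bbox_inches="tight")
        plt.close(fig)
    if "usage_product" in records:
        fig, ax = plt.subplots(figsize=(5, 4))
        x = log_transform(records["usage_product"], "auto")
        ax.scatter(x, records["ada_rate"], c=records["origin"].map(
            {"human": "tab:blue", "humanized": "tab:orange"}))
        ax.set_xlabel("log2 V-usage product (heavy x light)")
        ax.set_ylabel("clinical ADA rate (%)")
        written["usage_scatter"] = outdir / "usage_vs_ada.png"
        fig.savefig(written["usage_scatter"], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return written
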