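"""Benchmark statistics for mutation and conformational-change predictions.

The evaluation toolkit: seeded bootstrap resampling (10000 replicates by
default), linear regression through the origin and its RMSE, classification
of mutations into stabilizing / neutral / destabilizing by the +-0.5
kcal/mol experimental bands, self-consistency bias/error of forward-vs-back
mutation predictions against the line y = -x, least-squares combination of
two predictors against a reshuffled-random baseline, and the sparse
integer-exponent search over the four force-constant weights.

The through-origin regression is used throughout because a protein compared
to itself must predict exactly zero change; an intercept would break that.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .contacts import InteractionMatrix, build_contact_model
from .enm_core import ModelKind, ParameterSet, compute_modes, diagonalize
from .observables import MutationRecord, overlap, entropy_difference

logger = logging.getLogger("encom")

__all__ = [
    "RegressionResult",
    "BootstrapResult",
    "SelfConsistencyResult",
    "CombinationResult",
    "bootstrap",
    "rmse_through_origin",
    "classify_mutations",
    "self_consistency",
    "combine_models",
    "parameter_search",
    "read_mutation_table",
    "read_pair_table",
    "DegenerateFitError",
]


class DegenerateFitError(ValueError):
    """Through-origin regression with an all-zero predictor."""


@dataclass
class RegressionResult:
    slope: float
    rmse: float
    n: int


@dataclass
class BootstrapResult:
    """Bootstrapped statistic: point value, replicate average and spread."""

    point: float
    estimate: float
    stderr: float
    median: float
    ci_low: float
    ci_high: float
    n_iter: int


@dataclass
class SelfConsistencyResult:
    bias: float
    error: float
    n_pairs: int
    bias_stderr: float = float("nan")
    error_stderr: float = float("nan")


@dataclass
class CombinationResult:
    coefficients: tuple[float, float]
    delta_rmse: float
    ratio: float
    rmse_combined: float
    rmse_random: float


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def rmse_through_origin(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Zero-intercept least squares of y on x: slope k = sum(xy)/sum(x^2),
    RMSE = sqrt(mean((y - k x)^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateFitError("all predictors are zero")
    k = float(np.dot(x, y)) / sxx
    rmse = float(np.sqrt(np.mean((y - k * x) ** 2)))
    return RegressionResult(slope=k, rmse=rmse, n=x.size)


def _rmse_statistic(sample: np.ndarray) -> float:
    # bootstrap resamples may draw only zero predictors; the through-origin
    # fit then degenerates to slope 0 and the residual is y itself
    try:
        return rmse_through_origin(sample[:, 0], sample[:, 1]).rmse
    except DegenerateFitError:
        return float(np.sqrt(np.mean(sample[:, 1] ** 2)))


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda s: float(np.mean(s)),
    "median": lambda s: float(np.median(s)),
    "rmse_through_origin": _rmse_statistic,
    "correlation":
        lambda s: float(np.corrcoef(s[:, 0], s[:, 1])[0, 1]),
}


def bootstrap(values: np.ndarray,
              statistic: str | Callable[[np.ndarray], float] = "mean",
              n_iter: int = 10000, seed: int = 0) -> BootstrapResult:
    """Seeded bootstrap (resampling with replacement) of a statistic.

    ``values`` is a vector for scalar statistics or an (n, 2) array of
    (predicted, experimental) pairs for ``rmse_through_origin`` and
    ``correlation``.  Results are bit-reproducible for a given seed.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty sample")
    stat = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.integers(0, n, size=n)
        reps[it] = stat(values[idx])
    return BootstrapResult(
        point=stat(values),
        estimate=float(np.mean(reps)),
        stderr=float(np.std(reps, ddof=1)) if n_iter > 1 else 0.0,
        median=float(np.median(reps)),
        ci_low=float(np.percentile(reps, 2.5)),
        ci_high=float(np.percentile(reps, 97.5)),
        n_iter=n_iter,
    )


def classify_mutations(records: Iterable[MutationRecord] | np.ndarray
                       ) -> dict[str, int]:
    """Counts per experimental class with the closed neutral band [-0.5, 0.5]
    kcal/mol (stabilizing < -0.5, destabilizing > 0.5)."""
    counts = {"stabilizing": 0, "neutral": 0, "destabilizing": 0}
    for item in records:
        if isinstance(item, MutationRecord):
            cls = item.exp_class
        else:
            v = float(item)
            cls = ("stabilizing" if v < -0.5
                   else "destabilizing" if v > 0.5 else "neutral")
        counts[cls] += 1
    return counts


def self_consistency(fwd: np.ndarray, rev: np.ndarray,
                     n_iter: int = 10000, seed: int = 0
                     ) -> SelfConsistencyResult:
    """Bias and error of forward/back prediction pairs against y = -x.

    A thermodynamically consistent predictor satisfies
    ddG(A->B) = -ddG(B->A); each pair's deviation is d = fwd + rev.  The
    bias is the signed mean distance from the line (mean(d)/sqrt(2)) and the
    error the RMS distance (sqrt(mean(d^2))/sqrt(2)); both come with
    bootstrap standard errors.
    """
    fwd = np.asarray(fwd, float)
    rev = np.asarray(rev, float)
    if fwd.shape != rev.shape or fwd.ndim != 1:
        raise ValueError("forward and back vectors must have equal length")
    d = fwd + rev
    root2 = math.sqrt(2.0)
    bias = float(np.mean(d)) / root2
    error = float(np.sqrt(np.mean(d ** 2))) / root2
    if n_iter > 0 and d.size > 1:
        b_bias = bootstrap(d, lambda s: float(np.mean(s)) / root2,
                           n_iter=n_iter, seed=seed)
        b_err = bootstrap(d, lambda s: float(np.sqrt(np.mean(s ** 2))) / root2,
                          n_iter=n_iter, seed=seed + 1)
        return SelfConsistencyResult(bias, error, d.size,
                                     b_bias.stderr, b_err.stderr)
    return SelfConsistencyResult(bias, error, d.size)


# ---------------------------------------------------------------------------
# Linear combination of two predictors
# ---------------------------------------------------------------------------

def _rescale(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Calibrate raw predictions onto the experimental scale through the
    origin (slope absorbs the arbitrary model units)."""
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        return x.copy()
    return x * (float(np.dot(x, y)) / sxx)


def combine_models(pred_encom: np.ndarray, pred_other: np.ndarray,
                   y_exp: np.ndarray, n_iter: int = 10000,
                   seed: int = 0) -> CombinationResult:
    """Least-squares two-model combination versus a reshuffled baseline.

    Per bootstrap sample: both predictors are rescaled through the origin
    onto the experimental scale, a two-coefficient zero-intercept model is
    fitted by SVD least squares, and its RMSE is compared to that of the
    random model (a seeded permutation of the experimental values used as
    predictions).  Reports bootstrap-averaged delta RMSE (combined minus
    random; negative is better than random) and the coefficient ratio
    (first model relative to second).
    """
    x1 = np.asarray(pred_encom, float)
    x2 = np.asarray(pred_other, float)
    y = np.asarray(y_exp, float)
    if not (x1.shape == x2.shape == y.shape) or y.ndim != 1:
        raise ValueError("inputs must be aligned vectors")
    rng = np.random.default_rng(seed)
    y_random = rng.permutation(y)

    def fit(sample_idx: np.ndarray) -> tuple[float, float, float, float]:
        xs1, xs2, ys = x1[sample_idx], x2[sample_idx], y[sample_idx]
        yr = y_random[sample_idx]
        A = np.column_stack([_rescale(xs1, ys), _rescale(xs2, ys)])
        if np.linalg.matrix_rank(A) < 2:
            logger.warning("collinear predictors; minimum-norm coefficients")
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        resid = ys - A @ coef
        rmse_comb = float(np.sqrt(np.mean(resid ** 2)))
        try:
            rmse_rand = rmse_through_origin(yr, ys).rmse
        except DegenerateFitError:
            rmse_rand = float(np.sqrt(np.mean(ys ** 2)))
        return float(coef[0]), float(coef[1]), rmse_comb, rmse_rand

    n = y.size
    full = fit(np.arange(n))
    deltas = np.empty(n_iter)
    ratios = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.integers(0, n, size=n)
        c1, c2, rc, rr = fit(idx)
        deltas[it] = rc - rr
        ratios[it] = abs(c1) / abs(c2) if c2 != 0 else np.inf
    finite = np.isfinite(ratios)
    ratio = float(np.mean(ratios[finite])) if finite.any() else float("inf")
    return CombinationResult(
        coefficients=(full[0], full[1]),
        delta_rmse=float(np.mean(deltas)),
        ratio=ratio,
        rmse_combined=full[2],
        rmse_random=full[3],
    )


# ---------------------------------------------------------------------------
# Parameter search
# ---------------------------------------------------------------------------

def _zscores(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def parameter_search(bundle, exponents: Sequence[float],
                     seed: int = 0, n_iter: int = 200,
                     top_fraction: float = 0.5,
                     eps: InteractionMatrix | None = None) -> pd.DataFrame:
    """Sparse exhaustive search over integer log10 force-constant weights.

    Every combination of the given log10 exponents for the four alpha
    weights is evaluated on the bundle's tasks.  Stage one scores each grid
    point by the sum of Z-scores (over the grid population) of the
    bootstrapped-median through-origin RMSE on the stabilizing and
    destabilizing mutation subsets (lower is better); the best
    ``top_fraction`` advance.  Stage two adds Z-scores of the mean best
    overlap on domain and loop tasks (higher is better) and ranks by the
    combined score.  Deterministic under a fixed seed.
    """
    exponents = list(exponents)
    if not exponents:
        raise ValueError("empty exponent grid")
    eps = eps or InteractionMatrix.default()

    # Contact models do not depend on alpha: compute once per structure.
    contact_cache: dict[int, object] = {}

    def contacts_for(structure):
        key = id(structure)
        if key not in contact_cache:
            contact_cache[key] = build_contact_model(structure, eps)
        return contact_cache[key]

    grid = list(itertools.product(exponents, repeat=4))
    rows = []
    for gi, expo in enumerate(grid):
        alpha = tuple(10.0 ** e for e in expo)
        params = ParameterSet(alpha=alpha, model_kind=ModelKind.ENCOM)

        scores, ddg = [], []
        for wt, mut, rec in bundle.mutations:
            d_wt = compute_modes(wt, params, contacts_for(wt))
            d_mut = compute_modes(mut, params, contacts_for(mut))
            scores.append(-entropy_difference(d_wt, d_mut))
            ddg.append(rec.ddg_exp)
        scores = np.array(scores)
        ddg = np.array(ddg)

        rmse_by_class = {}
        for cls, mask_fn in [("stabilizing", lambda v: v < -0.5),
                             ("destabilizing", lambda v: v > 0.5)]:
            mask = mask_fn(ddg)
            if mask.sum() >= 2 and np.any(scores[mask] != 0):
                # same seed for every grid point: scale-degenerate parameter
                # sets must produce bit-identical bootstrap medians
                boot = bootstrap(np.column_stack([scores[mask], ddg[mask]]),
                                 "rmse_through_origin", n_iter=n_iter,
                                 seed=seed)
                rmse_by_class[cls] = boot.median
            else:
                rmse_by_class[cls] = float(np.sqrt(np.mean(ddg[mask] ** 2))) \
                    if mask.any() else np.nan

        rows.append({
            "log_a1": expo[0], "log_a2": expo[1],
            "log_a3": expo[2], "log_a4": expo[3],
            "rmse_stabilizing": rmse_by_class["stabilizing"],
            "rmse_destabilizing": rmse_by_class["destabilizing"],
        })

    df = pd.DataFrame(rows)
    df["z_rmse"] = (_zscores(df["rmse_stabilizing"].to_numpy())
                    + _zscores(df["rmse_destabilizing"].to_numpy()))

    n_keep = max(1, math.ceil(top_fraction * len(df)))
    # low RMSE is good: keep the lowest z_rmse
    selected = df.nsmallest(n_keep, "z_rmse", keep="all").index.to_numpy()

    ov_domain = np.full(len(df), np.nan)
    ov_loop = np.full(len(df), np.nan)
    for gi in selected:
        expo = grid[gi]
        alpha = tuple(10.0 ** e for e in expo)
        params = ParameterSet(alpha=alpha, model_kind=ModelKind.ENCOM)
        vals = {"domain": [], "loop": []}
        for start, target, label in bundle.overlaps:
            decomp = compute_modes(start, params, contacts_for(start))
            obs = overlap(decomp, start, target)
            vals[label].append(obs.best_overlap)
        ov_domain[gi] = np.mean(vals["domain"]) if vals["domain"] else np.nan
        ov_loop[gi] = np.mean(vals["loop"]) if vals["loop"] else np.nan
    df["overlap_domain"] = ov_domain
    df["overlap_loop"] = ov_loop

    sel_mask = df.index.isin(selected)
    z_dom = np.full(len(df), np.nan)
    z_loop = np.full(len(df), np.nan)
    z_dom[sel_mask] = _zscores(df.loc[sel_mask, "overlap_domain"].to_numpy())
    z_loop[sel_mask] = _zscores(df.loc[sel_mask, "overlap_loop"].to_numpy())
    df["z_overlap"] = z_dom + z_loop
    df["score"] = df["z_overlap"] - df["z_rmse"]
    df["selected"] = sel_mask
    df = df.sort_values(["score", "log_a1", "log_a2", "log_a3", "log_a4"],
                        ascending=[False, True, True, True, True],
                        na_position="last").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# Benchmark table I/O (S3/S4-style TSV layouts)
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ["pdb_id", "chain", "wt_res", "position", "mut_res",
                    "ddg_exp"]
PAIR_COLUMNS = ["pair_id", "ddg_fwd", "ddg_rev"]


def read_mutation_table(path, exclusions: set[str] | None = None
                        ) -> pd.DataFrame:
    """Read a mutation benchmark TSV (one mutation per row).

    Expected columns: pdb_id, chain, wt_res, position, mut_res, ddg_exp
    (kcal/mol).  ``exclusions`` drops rows whose mutation id
    (pdbid_chain_WTposMUT) appears in the set.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    df["mutation_id"] = (df["pdb_id"].astype(str) + "_" + df["chain"].astype(str)
                         + "_" + df["wt_res"].astype(str)
                         + df["position"].astype(str)
                         + df["mut_res"].astype(str))
    if exclusions:
        before = len(df)
        df = df[~df["mutation_id"].isin(exclusions)].reset_index(drop=True)
        logger.info("excluded %d of %d mutations", before - len(df), before)
    return df


def read_pair_table(path, exclusions: set[str] | None = None) -> pd.DataFrame:
    """Read a forward/back prediction pair TSV (pair_id, ddg_fwd, ddg_rev)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    if exclusions:
        df = df[~df["pair_id"].astype(str).isin(exclusions)].reset_index(drop=True)
    return df


def read_exclusion_list(path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
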