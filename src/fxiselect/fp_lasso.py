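"""Fractional-polynomial LASSO selection with lambda-ratio robustness ranking.

Every protein is expanded into a first-degree fractional-polynomial basis
(powers -2, -1, -0.5, 0, 0.5, 1, 2, 3; power 0 meaning natural log, applied
to min-shifted positive values). The expanded features enter an L1-penalized
least-squares model in which clinical covariates are unpenalized — this is
implemented exactly via Frisch-Waugh-Lovell residualization: projecting the
outcome and penalized features onto the orthogonal complement of the
covariate span leaves the penalized coefficient path unchanged while the
covariates are always in the model.

For each penalized feature the entry lambda — the largest lambda on the path
at which its coefficient is nonzero — is tracked; a protein's entry lambda
is the max over its features. The lambda ratio (entry lambda over the
CV-optimal lambda) ranks selected proteins by robustness and is invariant
under rescaling of the outcome, because the whole grid is proportional to
lambda_max which itself scales with the outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path
from sklearn.linear_model import lasso_path as _sk_lasso_path
from sklearn.model_selection import KFold

from fxiselect.preprocess import stratify_fxi

logger = logging.getLogger(__name__)

#: conventional first-degree fractional-polynomial power set (0 = natural log)
DEFAULT_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: covariates adjusted for in the models (best-effort clinical list);
#: only columns actually present in the cohort are used
DEFAULT_COVARIATES = (
    "sex",
    "age",
    "bmi",
    "history_dvt",
    "history_pe",
    "recent_immobilization",
    "recent_surgery",
    "recent_trauma",
    "thrombophilia",
    "atrial_fibrillation",
    "congestive_heart_failure",
    "coronary_artery_disease",
    "chronic_kidney_disease",
    "chronic_liver_disease",
    "chronic_pulmonary_disease",
    "doac_user",
    "thrombin_inhibitor",
    "heparin",
    "vka",
)

#: default APTT elongation threshold in seconds (configurable)
DEFAULT_APTT_THRESHOLD = 38.0


@dataclass(frozen=True)
class FPConfig:
    """Fractional-polynomial basis configuration."""

    powers: tuple[float, ...] = DEFAULT_POWERS
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.powers:
            raise ValueError("powers must be nonempty")
        if 1.0 not in self.powers:
            raise ValueError("powers must include 1 (identity term)")


@dataclass
class FPBasis:
    """Expanded feature matrix with feature -> (protein, power) mapping."""

    X: np.ndarray  # n x m, centered/scaled when standardized
    feature_ids: list[str]
    feature_protein: np.ndarray  # m, protein id per feature
    feature_power: np.ndarray  # m
    protein_ids: list[str]
    shifts: dict[str, float]
    center: np.ndarray
    scale: np.ndarray
    dropped: list[tuple[str, float, str]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class PathResult:
    """Coefficients along a decreasing lambda grid, with per-feature entry lambda."""

    lambda_grid: np.ndarray  # decreasing
    coefs: np.ndarray  # m x len(grid), penalized features
    covariate_coefs: np.ndarray  # q x len(grid), intercept first
    covariate_names: list[str]
    entry_lambda: np.ndarray  # m, NaN when a feature never enters


@dataclass
class CVResult:
    lambda_opt: float
    opt_index: int
    lambda_grid: np.ndarray
    cv_mse_curve: np.ndarray
    cv_r2: float
    k: int
    seed: int


@dataclass
class ProteinSelection:
    """Per-protein selection flags, entry lambdas and lambda ratios.

    ``table`` is indexed by protein id with columns ``selected``,
    ``direction``, ``entry_lambda``, ``lambda_ratio`` and ``rank`` (1-based
    for selected proteins, <NA> otherwise), ordered by descending
    lambda ratio with identifier tie-breaks.
    """

    table: pd.DataFrame
    lambda_opt: float
    cv_r2: float
    covariates: list[str]
    n_obs: int
    n_excluded: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="protein")

    def manifest(self) -> dict:
        return {
            "lambda_opt": self.lambda_opt,
            "cv_r2": self.cv_r2,
            "n_selected": int(self.table["selected"].sum()),
            "n_obs": self.n_obs,
            "n_excluded": self.n_excluded,
            "covariates": list(self.covariates),
            **self.provenance,
        }


@dataclass
class SelectionOverlap:
    shared: list[str]
    only_a: list[str]
    only_b: list[str]

    def counts(self) -> dict:
        return {
            "shared": len(self.shared),
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
        }


# ---------------------------------------------------------------------------
# basis expansion
# ---------------------------------------------------------------------------


def fp_expand(matrix: pd.DataFrame, config: FPConfig = FPConfig()) -> FPBasis:
    """Expand each protein column into one feature per fractional power.

    Values are min-shifted to be >= 1 (x - min + 1) before applying powers;
    power 0 maps to the natural log. Zero-variance features are dropped with
    a warning and recorded.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("protein matrix must be finite (impute first)")
    proteins = list(matrix.columns)
    cols, fids, fprot, fpow = [], [], [], []
    shifts: dict[str, float] = {}
    dropped: list[tuple[str, float, str]] = []
    for j, pid in enumerate(proteins):
        x = values[:, j]
        shift = 1.0 - x.min()
        shifts[pid] = shift
        xs = x + shift
        for p in config.powers:
            z = np.log(xs) if p == 0 else xs**p
            if z.std() < 1e-12:
                dropped.append((pid, p, "zero variance"))
                continue
            cols.append(z)
            fids.append(f"{pid}^{p:g}")
            fprot.append(pid)
            fpow.append(p)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance FP features", stacklevel=2)
    X = np.column_stack(cols) if cols else np.empty((len(matrix), 0))
    center = X.mean(axis=0) if X.size else np.empty(0)
    scale = X.std(axis=0) if X.size else np.empty(0)
    if config.standardize and X.size:
        X = (X - center) / scale
    return FPBasis(
        X=X,
        feature_ids=fids,
        feature_protein=np.asarray(fprot, dtype=object),
        feature_power=np.asarray(fpow, dtype=float),
        protein_ids=proteins,
        shifts=shifts,
        center=center,
        scale=scale,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# penalized path
# ---------------------------------------------------------------------------


def _covariate_design(
    covariates: pd.DataFrame | np.ndarray | None, n: int
) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = ["intercept"] + [str(c) for c in covariates.columns]
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = ["intercept"] + [f"cov{i}" for i in range(C.shape[1])]
    return np.column_stack([np.ones(n), C]), names


def _projector(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the covariate column space (rank-robust, SVD)."""
    u, s, _ = np.linalg.svd(C, full_matrices=False)
    tol = s.max() * max(C.shape) * np.finfo(float).eps if s.size else 0.0
    return u[:, s > tol]


def _residualize(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    return A - Q @ (Q.T @ A)


#: smallest-to-largest lambda ratio; 0.01 is the conventional default when
#: the feature count exceeds the sample size, which FP expansion guarantees
DEFAULT_EPS = 1e-2


def make_lambda_grid(
    lam_max: float, n_lambdas: int = 100, eps: float = DEFAULT_EPS
) -> np.ndarray:
    return lam_max * np.logspace(0.0, np.log10(eps), n_lambdas)


def _solve_path(MX: np.ndarray, My: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Coordinate-descent path on the residualized problem.

    The FP basis is strongly collinear by construction, so the small-lambda
    tail can stop short of full convergence; those lambdas sit far below
    lambda_opt and do not affect selection. Warnings are converted to a log
    record instead of spamming stderr.
    """
    if not MX.size:
        return np.empty((0, len(grid)))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        _, coefs, _ = _sk_lasso_path(
            np.asfortranarray(MX),
            My,
            alphas=grid,
            precompute=True,
            tol=1e-4,
            max_iter=3000,
        )
    n_warn = sum(issubclass(w.category, ConvergenceWarning) for w in caught)
    if n_warn:
        logger.debug("coordinate descent not fully converged at %d lambdas", n_warn)
    return coefs


def _entry_from_coefs(grid: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Per feature, the largest grid lambda with a nonzero coefficient."""
    m = coefs.shape[0]
    entry = np.full(m, np.nan)
    nz = coefs != 0
    for j in range(m):
        idx = np.flatnonzero(nz[j])
        if idx.size:
            entry[j] = grid[idx.min()]
    return entry


def _refine_entries(
    MX: np.ndarray,
    My: np.ndarray,
    grid: np.ndarray,
    coefs: np.ndarray,
) -> np.ndarray:
    """Exact entry lambdas from the LARS homotopy on the residualized problem.

    The piecewise-linear LASSO path has knots exactly where features join
    (or leave) the active set; the knot preceding a feature's first nonzero
    coefficient is its entry lambda to machine precision. Intended for small
    problems — grid-based entry detection is the default for large designs.
    Entries below the grid floor keep their grid-based value (NaN if never
    active on the grid).
    """
    alphas, _, lars_coefs = lars_path(MX, My, method="lasso", alpha_min=0.0)
    entry = _entry_from_coefs(grid, coefs)
    for j in range(coefs.shape[0]):
        nz = np.flatnonzero(lars_coefs[j] != 0)
        if nz.size == 0:
            continue
        t = nz.min()
        knot = float(alphas[t - 1]) if t > 0 else float(alphas[0])
        if np.isfinite(entry[j]) or knot >= grid[-1]:
            entry[j] = knot
    return entry


def lasso_path(
    basis: FPBasis,
    covariates: pd.DataFrame | np.ndarray | None,
    y,
    n_lambdas: int = 100,
    eps: float = DEFAULT_EPS,
    grid: np.ndarray | None = None,
    refine_entry: bool = False,
) -> PathResult:
    """L1-penalized least-squares path with unpenalized covariates.

    Objective (scikit-learn / glmnet convention):
    ``(1/2n) ||y - X b - C g||^2 + lambda ||b||_1`` with ``g`` unpenalized.
    The grid runs from lambda_max (all penalized coefficients zero) down to
    ``eps * lambda_max`` over ``n_lambdas`` log-spaced points.
    """
    X = basis.X
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.var(y) == 0:
        raise ValueError("degenerate outcome: zero variance")
    C, cov_names = _covariate_design(covariates, n)
    Q = _projector(C)
    My = _residualize(Q, y)
    MX = _residualize(Q, X)
    if np.var(My) == 0:
        raise ValueError("outcome fully explained by covariates")
    if grid is None:
        lam_max = float(np.max(np.abs(MX.T @ My)) / n) if MX.size else 1.0
        if lam_max <= 0:
            raise ValueError("all penalized features orthogonal to outcome")
        grid = make_lambda_grid(lam_max, n_lambdas=n_lambdas, eps=eps)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    coefs = _solve_path(MX, My, grid)
    if refine_entry:
        entry = _refine_entries(MX, My, grid, coefs)
    else:
        entry = _entry_from_coefs(grid, coefs)
    # covariate coefficients recovered per lambda on the original scale
    resid = y[:, None] - (X @ coefs if X.size else 0.0)
    gamma, *_ = np.linalg.lstsq(C, resid, rcond=None)
    return PathResult(
        lambda_grid=grid,
        coefs=coefs,
        covariate_coefs=gamma,
        covariate_names=cov_names,
        entry_lambda=entry,
    )


def cv_select_lambda(
    basis: FPBasis,
    covariates: pd.DataFrame | np.ndarray | None,
    y,
    k: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    eps: float = DEFAULT_EPS,
    grid: np.ndarray | None = None,
) -> CVResult:
    """Tenfold (by default) CV of the path MSE on a grid shared across folds.

    ``lambda_opt`` minimizes the mean out-of-fold MSE (exact minimum, not
    the 1-SE rule); ``cv_r2 = 1 - MSE(lambda_opt) / Var(y)``. Fold splits
    are deterministic for a fixed seed.
    """
    X = basis.X
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} folds require at least {k} observations, have {n}")
    C, _ = _covariate_design(covariates, n)
    if grid is None:
        Q = _projector(C)
        My = _residualize(Q, y)
        MX = _residualize(Q, X)
        lam_max = float(np.max(np.abs(MX.T @ My)) / n) if MX.size else 1.0
        grid = make_lambda_grid(lam_max, n_lambdas=n_lambdas, eps=eps)
    grid = np.asarray(grid, dtype=float)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    sq_err = np.zeros((n, len(grid)))
    for train, test in folds.split(y):
        C_tr, C_te = C[train], C[test]
        Q = _projector(C_tr)
        My = _residualize(Q, y[train])
        MX = _residualize(Q, X[train])
        coefs = _solve_path(MX, My, grid)
        resid_tr = y[train][:, None] - (X[train] @ coefs if X.size else 0.0)
        gamma, *_ = np.linalg.lstsq(C_tr, resid_tr, rcond=None)
        pred = (X[test] @ coefs if X.size else 0.0) + C_te @ gamma
        sq_err[test] = (y[test][:, None] - pred) ** 2
    curve = sq_err.mean(axis=0)
    opt = int(np.argmin(curve))  # first minimum = largest lambda on ties
    cv_r2 = float(1.0 - curve[opt] / np.var(y))
    return CVResult(
        lambda_opt=float(grid[opt]),
        opt_index=opt,
        lambda_grid=grid,
        cv_mse_curve=curve,
        cv_r2=cv_r2,
        k=k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# selection and ranking
# ---------------------------------------------------------------------------


def _direction(x: np.ndarray, y: np.ndarray) -> str:
    rho = stats.spearmanr(x, y).statistic
    return "-" if (np.isfinite(rho) and rho < 0) else "+"


def select_and_rank(
    path: PathResult,
    cv: CVResult,
    basis: FPBasis,
    raw: pd.DataFrame,
    y,
) -> ProteinSelection:
    """Aggregate feature-level path results to the protein level.

    A protein is selected iff any of its FP features has a nonzero
    coefficient at lambda_opt; its entry lambda is the max over its
    features' entry lambdas; the lambda ratio divides by lambda_opt.
    Direction is the sign of the marginal Spearman correlation of the raw
    protein column with the outcome. Ranking: descending lambda ratio,
    ties broken by protein identifier.
    """
    if len(path.lambda_grid) != len(cv.lambda_grid) or not np.allclose(
        path.lambda_grid, cv.lambda_grid
    ):
        raise ValueError("path and CV must share one lambda grid")
    y = np.asarray(y, dtype=float)
    coef_opt = path.coefs[:, cv.opt_index] if path.coefs.size else np.empty(0)
    records = []
    for pid in basis.protein_ids:
        mask = basis.feature_protein == pid
        if not mask.any():
            records.append((pid, False, "+", np.nan, np.nan))
            continue
        sel = bool(np.any(coef_opt[mask] != 0)) if coef_opt.size else False
        entries = path.entry_lambda[mask]
        entry = float(np.nanmax(entries)) if np.isfinite(entries).any() else np.nan
        ratio = entry / cv.lambda_opt if sel else np.nan
        direction = _direction(raw[pid].to_numpy(dtype=float), y)
        records.append((pid, sel, direction, entry, ratio))
    table = pd.DataFrame(
        records,
        columns=["protein", "selected", "direction", "entry_lambda", "lambda_ratio"],
    ).set_index("protein")
    table = table.sort_values(
        by=["selected", "lambda_ratio", "protein"],
        ascending=[False, False, True],
        na_position="last",
        kind="mergesort",
    )
    rank = pd.array(
        [i + 1 if s else pd.NA for i, s in enumerate(table["selected"])],
        dtype="Int64",
    )
    table["rank"] = rank
    return ProteinSelection(
        table=table,
        lambda_opt=cv.lambda_opt,
        cv_r2=cv.cv_r2,
        covariates=path.covariate_names[1:],
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# timepoint models and sensitivity analyses
# ---------------------------------------------------------------------------


def _build_covariates(
    cohort: pd.DataFrame, covariate_cols, include_fxi_ag: bool
) -> pd.DataFrame:
    cols = [c for c in covariate_cols if c in cohort.columns]
    C = cohort[cols].astype(float)
    if include_fxi_ag and "fxi_ag" in cohort.columns:
        C = C.assign(fxi_ag=cohort["fxi_ag"].astype(float))
    return C


def fit_timepoint_model(
    cohort: pd.DataFrame,
    proteins: pd.DataFrame,
    covariate_cols=DEFAULT_COVARIATES,
    fp_config: FPConfig = FPConfig(),
    seed: int = 0,
    k: int = 10,
    n_lambdas: int = 100,
    eps: float = DEFAULT_EPS,
    include_fxi_ag: bool = False,
) -> ProteinSelection:
    """Full pipeline for one timepoint sample.

    ``cohort`` must already have passed :func:`~fxiselect.preprocess.apply_exclusions`.
    The FP basis is built from raw (shifted) protein values; covariates enter
    unpenalized. Deterministic for fixed seed.
    """
    idx = cohort.index.intersection(proteins.index)
    if len(idx) < len(cohort):
        warnings.warn(
            f"{len(cohort) - len(idx)} cohort rows missing protein data", stacklevel=2
        )
    cohort = cohort.loc[idx]
    prot = proteins.loc[idx]
    y = cohort["fxi_c"].to_numpy(dtype=float)
    C = _build_covariates(cohort, covariate_cols, include_fxi_ag)
    basis = fp_expand(prot, fp_config)
    path = lasso_path(basis, C, y, n_lambdas=n_lambdas, eps=eps)
    cv = cv_select_lambda(
        basis, C, y, k=k, seed=seed, grid=path.lambda_grid
    )
    sel = select_and_rank(path, cv, basis, prot, y)
    sel.provenance = {
        "seed": seed,
        "k_folds": k,
        "n_lambdas": n_lambdas,
        "eps": eps,
        "powers": list(fp_config.powers),
        "standardize": fp_config.standardize,
        "lambda_max": float(path.lambda_grid[0]),
        "include_fxi_ag": include_fxi_ag,
        "n_features": basis.n_features,
        "n_dropped_features": len(basis.dropped),
    }
    return sel


def sensitivity_no_doac(
    cohort: pd.DataFrame, proteins: pd.DataFrame, **kwargs
) -> ProteinSelection:
    """Re-run the model restricted to non-users of DOACs."""
    if "doac_user" not in cohort.columns:
        raise KeyError("cohort must contain a 'doac_user' flag")
    keep = ~cohort["doac_user"].astype(bool)
    n_excluded = int((~keep).sum())
    sub = cohort[keep]
    k = kwargs.get("k", 10)
    if len(sub) < k:
        raise ValueError(
            f"only {len(sub)} non-DOAC observations; need at least {k} for {k}-fold CV"
        )
    sel = fit_timepoint_model(sub, proteins, **kwargs)
    sel.n_excluded = n_excluded
    logger.info("DOAC sensitivity: excluded %d observations", n_excluded)
    return sel


def sensitivity_aptt(
    cohort: pd.DataFrame,
    proteins: pd.DataFrame,
    aptt_threshold: float = DEFAULT_APTT_THRESHOLD,
    **kwargs,
) -> ProteinSelection:
    """Re-run the model excluding normal/high-FXI:C subjects with elongated APTT.

    Low-FXI:C subjects are retained regardless of APTT (a long APTT is
    expected there); only the discordant normal/high stratum is removed.
    """
    for col in ("aptt", "fxi_c"):
        if col not in cohort.columns:
            raise KeyError(f"cohort must contain {col!r}")
    strata = stratify_fxi(cohort["fxi_c"])
    discordant = strata.isin(["normal", "high"]) & (
        cohort["aptt"].astype(float) > aptt_threshold
    )
    n_excluded = int(discordant.sum())
    sub = cohort[~discordant]
    k = kwargs.get("k", 10)
    if len(sub) < k:
        raise ValueError(
            f"only {len(sub)} observations after APTT exclusion; need >= {k}"
        )
    sel = fit_timepoint_model(sub, proteins, **kwargs)
    sel.n_excluded = n_excluded
    logger.info(
        "APTT sensitivity (threshold %.1f s): excluded %d observations",
        aptt_threshold,
        n_excluded,
    )
    return sel


def overlap_selections(a: ProteinSelection, b: ProteinSelection) -> SelectionOverlap:
    """Shared and model-specific selected proteins."""
    sa, sb = set(a.selected), set(b.selected)
    return SelectionOverlap(
        shared=sorted(sa & sb),
        only_a=sorted(sa - sb),
        only_b=sorted(sb - sa),
    )
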