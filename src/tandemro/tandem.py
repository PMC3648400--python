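"""The tandem regression-outlier method core.

Stage 1 ("filter"): single-descriptor least-squares screens over
property-ordered subsamples find the descriptor that dominates the bulk of
the activity signal,

    Y = b0 + b_ch * X_ch,                       ranked by r^2.

Stage 2 ("detector"): with the filter descriptor fixed (Jurs_RNCG by
default), every electrotopological-state descriptor is tried one at a time
in a two-predictor context equation

    Y = b0 + b_f * filter + b_ES * ES,

and the equations are ranked by fit R^2. The top-ranked ES symbols name the
key structural modifications of the analog series and the sign of b_ES
gives their tendency of impact on activity. One ES descriptor per equation
is deliberate: top-ranked ES columns are typically strongly dependent
(Count/Sum of one type, co-occurring ring symbols), and forcing them into a
joint fit flips coefficient signs — the dependency diagnostics here
demonstrate exactly that failure mode.

Y is the negative log10 of EC50 in molar units (pEC50).
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityError",
    "DegenerateResponseError",
    "load_activities",
    "fit_least_squares",
    "screen_single_descriptors",
    "subset_by_property",
    "monitor_table",
    "DominanceScreen",
    "DominanceResults",
    "ContextEquationModel",
    "ContextEquationResults",
    "DependencyReport",
]

_COLLINEAR_TOL = 1e-9


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"rank-deficient design: collinear column(s) {self.columns}"
        )


class DegenerateResponseError(ValueError):
    """The response is constant, so no fit quality can be defined."""


# ---------------------------------------------------------------------------
# activity ingestion


def load_activities(source, ec50_column: str = "ec50_molar") -> pd.DataFrame:
    """Activity table: compound id -> EC50 (molar) and pEC50 = -log10(EC50).

    ``source`` is a CSV/TSV path or a DataFrame with an ``id`` column (or id
    index) and an EC50 column. Indeterminate activities — missing,
    non-positive, or flagged truthy in an optional ``uncertain`` column — are
    dropped with a logged count (also in ``df.attrs["n_excluded"]``).
    """
    if isinstance(source, (str, Path)):
        sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep)
    else:
        df = source.copy()
    if "id" in df.columns:
        df = df.set_index("id")
    if ec50_column not in df.columns:
        if "ec50" in df.columns:
            ec50_column = "ec50"
        else:
            raise ValueError(
                f"activity table needs an {ec50_column!r} column; "
                f"found {list(df.columns)}"
            )
    ec50 = pd.to_numeric(df[ec50_column], errors="coerce")
    bad = ~np.isfinite(ec50) | (ec50 <= 0)
    if "uncertain" in df.columns:
        bad |= df["uncertain"].fillna(False).astype(bool)
    n_excluded = int(bad.sum())
    if n_excluded:
        logger.info(
            "dropped %d indeterminate/uncertain activity values", n_excluded
        )
    out = pd.DataFrame(
        {"ec50_molar": ec50[~bad], "pEC50": -np.log10(ec50[~bad])}
    )
    out.index.name = "id"
    out.attrs["n_excluded"] = n_excluded
    return out


# ---------------------------------------------------------------------------
# least squares


def fit_least_squares(X, y, add_intercept: bool = True):
    """Ordinary least squares with an explicit collinearity check.

    ``X`` is a DataFrame or 2-D array of predictor columns; an intercept is
    prepended by default. Returns ``(beta, r2)`` where ``beta`` includes the
    intercept first. Raises :class:`CollinearityError` (naming the offending
    columns, found by pivoted QR) for rank-deficient designs and
    :class:`DegenerateResponseError` for a constant response.
    """
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"x{k}" for k in range(np.atleast_2d(np.asarray(X)).shape[-1])]
    )
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n != yv.shape[0]:
        raise ValueError("X and y row counts differ")
    design = np.column_stack([np.ones(n), Xv]) if add_intercept else Xv
    if n <= design.shape[1]:
        raise ValueError(
            f"need more rows ({n}) than fitted coefficients ({design.shape[1]})"
        )
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0.0:
        raise DegenerateResponseError("constant response: SST = 0")

    # pivoted QR names the columns that add no new direction
    from scipy.linalg import qr

    _, R, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, design.shape[1]) * np.finfo(float).eps
    deficient = [piv[k] for k in range(len(diag)) if diag[k] <= tol]
    if deficient:
        offenders = [
            names[j - 1] if add_intercept and j > 0 else "intercept"
            for j in deficient
        ]
        raise CollinearityError(offenders)

    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    sse = float(((yv - design @ beta) ** 2).sum())
    return beta, 1.0 - sse / sst


def _screen_arrays(X: np.ndarray, y: np.ndarray):
    """Vectorised simple regressions of y on each column of X.

    Returns (beta0, beta1, r2, constant_mask). For a single predictor the
    fit r^2 is identically the squared Pearson correlation.
    """
    xm = X.mean(axis=0)
    xc = X - xm
    sxx = (xc**2).sum(axis=0)
    ym = y.mean()
    yc = y - ym
    syy = float((yc**2).sum())
    if syy == 0.0:
        raise DegenerateResponseError("constant response: SST = 0")
    scale = np.abs(X).max(axis=0)
    constant = sxx <= (np.finfo(float).eps * len(y) * np.maximum(scale, 1.0)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = xc.T @ yc
        beta1 = np.where(constant, np.nan, sxy / sxx)
        r2 = np.where(constant, np.nan, sxy**2 / (sxx * syy))
    beta0 = ym - beta1 * xm
    return beta0, beta1, r2, constant


def screen_single_descriptors(
    descriptors: pd.DataFrame, activities: pd.Series
) -> pd.DataFrame:
    """Stage-1 screen: one simple regression per descriptor, ranked by r^2.

    Constant descriptors are excluded (named in ``attrs["excluded"]``).
    Ties in r^2 break lexicographically by descriptor name so ranks are
    reproducible.
    """
    D, y = _align(descriptors, activities)
    if len(y) < 3:
        raise ValueError("need at least 3 compounds to screen")
    beta0, beta1, r2, constant = _screen_arrays(D.to_numpy(float), y.to_numpy(float))
    excluded = list(D.columns[constant])
    if excluded:
        logger.info("screen: excluded constant descriptors %s", excluded)
    res = pd.DataFrame(
        {"beta0": beta0, "beta_ch": beta1, "r2": r2},
        index=pd.Index(D.columns, name="descriptor"),
    ).loc[~constant]
    if res.empty:
        raise ValueError("no usable (non-constant) descriptor to screen")
    res = res.iloc[np.lexsort((res.index.to_numpy(), -res["r2"].to_numpy()))]
    res["rank"] = np.arange(1, len(res) + 1)
    res.attrs["excluded"] = excluded
    return res


def subset_by_property(
    descriptors: pd.DataFrame,
    activities: pd.Series,
    prop: str,
    size: int,
    order: str = "desc",
):
    """Top-``size`` compounds after sorting by one property.

    Sorting is stable, so tied property values keep input order; ``order``
    picks the sort direction (descending by default).
    """
    if size < 3:
        raise ValueError("subset size must be at least 3")
    D, y = _align(descriptors, activities)
    if size > len(D):
        raise ValueError(f"subset size {size} exceeds compound count {len(D)}")
    if prop not in D.columns:
        raise KeyError(f"unknown property {prop!r}")
    idx = D[prop].sort_values(ascending=(order == "asc"), kind="stable").index[:size]
    return D.loc[idx], y.loc[idx]


def _align(descriptors: pd.DataFrame, activities) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(activities, pd.DataFrame):
        activities = activities["pEC50"]
    common = descriptors.index.intersection(activities.index)
    if len(common) == 0:
        raise ValueError("descriptor matrix and activity table share no ids")
    if len(common) < len(descriptors) or len(common) < len(activities):
        logger.info(
            "aligning on %d shared ids (descriptors %d, activities %d)",
            len(common), len(descriptors), len(activities),
        )
    return descriptors.loc[common], activities.loc[common].astype(float)


# ---------------------------------------------------------------------------
# stage 1: dominance screening


class DominanceScreen:
    """Stage-1 model: does one descriptor dominate across ordered subsamples?

    For each data size, one subsample per pool property is drawn (compounds
    sorted by that property, top-n taken) and screened with single-descriptor
    regressions; the rank-1 descriptor of each subsample is tallied. The
    result reports, per size, the modal dominant descriptor and how often the
    focal descriptor (Jurs_RNCG by default) is dominant, near-dominant
    (rank <= ``near_rank``), or represented by its family pattern.

    Parameters
    ----------
    descriptors, activities : aligned by compound id.
    focal : descriptor whose dominance is tallied.
    family : fnmatch pattern for the focal descriptor's family.
    sizes : data sizes; default 10, 20, ... up to the compound count.
    near_rank : rank threshold for "near dominant".
    subset_order : "desc" (default) or "asc" property ordering.
    """

    def __init__(
        self,
        descriptors: pd.DataFrame,
        activities,
        focal: str = "Jurs_RNCG",
        family: str = "Jurs_*",
        sizes: list[int] | None = None,
        near_rank: int = 4,
        subset_order: str = "desc",
    ):
        self.descriptors, self.activities = _align(descriptors, activities)
        if focal not in self.descriptors.columns:
            raise KeyError(f"focal descriptor {focal!r} not in the matrix")
        self.focal = focal
        self.family = family
        n = len(self.descriptors)
        self.sizes = list(sizes) if sizes is not None else list(range(10, n + 1, 10))
        if not self.sizes or max(self.sizes) > n:
            raise ValueError(f"sizes must be non-empty and <= {n}")
        self.near_rank = near_rank
        self.subset_order = subset_order

    @property
    def pool(self) -> list[str]:
        """Properties used to order subsamples: all non-constant columns."""
        D = self.descriptors
        return [c for c in D.columns if D[c].nunique() > 1]

    def fit(self) -> "DominanceResults":
        rows = []
        pool = self.pool
        for size in self.sizes:
            dominant: list[str] = []
            focal_dom = focal_near = family_dom = 0
            skipped = 0
            for prop in pool:
                Dsub, ysub = subset_by_property(
                    self.descriptors, self.activities, prop, size,
                    order=self.subset_order,
                )
                try:
                    screen = screen_single_descriptors(Dsub, ysub)
                except (ValueError, DegenerateResponseError) as exc:
                    skipped += 1
                    logger.info("size %d, property %s skipped: %s", size, prop, exc)
                    continue
                top = screen.index[0]
                dominant.append(top)
                if top == self.focal:
                    focal_dom += 1
                if fnmatch.fnmatch(top, self.family):
                    family_dom += 1
                if self.focal in screen.index:
                    if int(screen.loc[self.focal, "rank"]) <= self.near_rank:
                        focal_near += 1
            modal = (
                pd.Series(dominant).mode().iloc[0] if dominant else ""
            )
            rows.append(
                {
                    "size": size,
                    "modal_dominant": modal,
                    "focal_dominant": focal_dom,
                    "focal_near_dominant": focal_near,
                    "family_dominant": family_dom,
                    "total_subsets": len(pool) - skipped,
                }
            )
        return DominanceResults(self, pd.DataFrame(rows).set_index("size"))


@dataclass
class DominanceResults:
    """Per-size dominance tally (the shape of the stage-1 summary table)."""

    model: DominanceScreen
    table: pd.DataFrame

    @property
    def focal_fraction(self) -> pd.Series:
        """Fraction of subsamples per size where the focal descriptor is rank 1."""
        return self.table["focal_dominant"] / self.table["total_subsets"]

    def trend(self) -> float:
        """Spearman correlation between size and focal-dominant frequency."""
        from scipy.stats import spearmanr

        rho = spearmanr(self.table.index.to_numpy(), self.focal_fraction).statistic
        return float(rho)

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        focal = self.model.focal
        out["frequency"] = [
            f"{r.focal_dominant}/{r.family_dominant}/{r.total_subsets}"
            for r in self.table.itertuples()
        ]
        out.attrs["focal"] = focal
        return out


# ---------------------------------------------------------------------------
# stage 2: context equations


class ContextEquationModel:
    """Stage-2 model: rank single-ES context equations around a fixed filter.

    Each candidate equation is ``pEC50 ~ 1 + filter + ES`` with exactly one
    ES descriptor; equations are ranked by R^2 (ties broken by name) and the
    sign of the ES coefficient is the reported tendency of that structural
    modification. ES columns that are constant or collinear with the filter
    are excluded with a logged reason.
    """

    def __init__(
        self,
        descriptors: pd.DataFrame,
        activities,
        filter_descriptor: str = "Jurs_RNCG",
    ):
        self.descriptors, self.activities = _align(descriptors, activities)
        if filter_descriptor not in self.descriptors.columns:
            raise KeyError(f"filter descriptor {filter_descriptor!r} not present")
        if self.descriptors[filter_descriptor].nunique() <= 1:
            raise ValueError(
                f"filter descriptor {filter_descriptor!r} is constant"
            )
        if len(self.activities) < 4:
            raise ValueError("need at least 4 compounds for context equations")
        self.filter_descriptor = filter_descriptor

    @classmethod
    def from_molecules(
        cls, mols, activities, filter_descriptor: str = "Jurs_RNCG", pool=None
    ) -> "ContextEquationModel":
        from .charges import build_descriptor_matrix

        D = build_descriptor_matrix(mols, pool=pool)
        return cls(D, activities, filter_descriptor=filter_descriptor)

    @property
    def es_columns(self) -> list[str]:
        return [
            c
            for c in self.descriptors.columns
            if c.startswith(("ES_Count_", "ES_Sum_")) and c != self.filter_descriptor
        ]

    def fit(self) -> "ContextEquationResults":
        D, y = self.descriptors, self.activities.to_numpy(float)
        f = D[self.filter_descriptor].to_numpy(float)
        rows = []
        excluded: dict[str, str] = {}
        for col in self.es_columns:
            x = D[col].to_numpy(float)
            if np.ptp(x) == 0.0:
                excluded[col] = "constant column"
                continue
            r_f = np.corrcoef(f, x)[0, 1]
            if abs(r_f) >= 1.0 - _COLLINEAR_TOL:
                excluded[col] = (
                    f"collinear with filter {self.filter_descriptor} (r={r_f:+.6f})"
                )
                continue
            beta, r2 = fit_least_squares(np.column_stack([f, x]), y)
            rows.append(
                {
                    "es_descriptor": col,
                    "beta0": beta[0],
                    "beta_filter": beta[1],
                    "beta_es": beta[2],
                    "r2": r2,
                    "sign": "+" if beta[2] >= 0 else "-",
                }
            )
        for col, why in excluded.items():
            logger.info("context equations: excluded %s (%s)", col, why)
        if not rows:
            raise ValueError("no usable ES descriptor for context equations")
        eq = pd.DataFrame(rows).set_index("es_descriptor")
        eq = eq.iloc[np.lexsort((eq.index.to_numpy(), -eq["r2"].to_numpy()))]
        eq["rank"] = np.arange(1, len(eq) + 1)
        return ContextEquationResults(self, eq, excluded)


@dataclass
class ContextEquationResults:
    """Ranked context equations with ES coefficient signs."""

    model: ContextEquationModel
    equations: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)

    def summary(self, k: int = 12) -> pd.DataFrame:
        """Monitor table: the top-k ES descriptors with rank and sign."""
        return monitor_table(self.equations, k=k)

    def sign(self, es_descriptor: str) -> str:
        return str(self.equations.loc[es_descriptor, "sign"])

    def top(self, k: int = 12) -> list[str]:
        return list(self.equations.index[:k])

    def dependency_diagnostics(
        self, k: int = 12, rare_support: int = 3
    ) -> "DependencyReport":
        """Diagnose dependencies among the top-k ES descriptors.

        Reports (1) their pairwise Pearson correlations, (2) Count/Sum pairs
        of the same atom type (description dependency on the identical
        modification), (3) a deliberately combined joint fit with a SIGN-FLIP
        flag wherever a joint-fit coefficient contradicts the single-equation
        sign, and (4) per-descriptor support (compounds with a nonzero
        value), flagging rare-moiety "analog outlier" descriptors carried by
        at most ``rare_support`` compounds.
        """
        top = self.top(k)
        if len(top) < 2:
            raise ValueError("need at least 2 top ES descriptors to diagnose")
        D = self.model.descriptors
        y = self.model.activities.to_numpy(float)
        corr = D[top].corr()

        def _type_of(name: str) -> str:
            return name.split("_", 2)[2]

        pairs = sorted(
            {
                tuple(sorted((a, b)))
                for a in top
                for b in top
                if a != b and _type_of(a) == _type_of(b)
            }
        )

        cols = [self.model.filter_descriptor] + top
        X = D[cols].to_numpy(float)
        design = np.column_stack([np.ones(len(X)), X])
        singular = np.linalg.matrix_rank(design) < design.shape[1]
        # minimum-norm solution still yields reportable signs when singular
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        combined = pd.Series(beta[2:], index=top, name="beta_combined")
        flips = [
            name
            for name in top
            if ("+" if combined[name] >= 0 else "-") != self.sign(name)
        ]
        support = (D[top] != 0).sum(axis=0)
        rare = list(support.index[support <= rare_support])
        return DependencyReport(
            correlations=corr,
            count_sum_pairs=pairs,
            combined_coefficients=combined,
            combined_singular=bool(singular),
            sign_flips=flips,
            support=support,
            rare_descriptors=rare,
        )


@dataclass
class DependencyReport:
    correlations: pd.DataFrame
    count_sum_pairs: list[tuple[str, str]]
    combined_coefficients: pd.Series
    combined_singular: bool
    sign_flips: list[str]
    support: pd.Series
    rare_descriptors: list[str]

    def summary(self) -> str:
        lines = ["dependency diagnostics"]
        lines.append(
            "  description-dependent Count/Sum pairs: "
            + (", ".join(f"{a}~{b}" for a, b in self.count_sum_pairs) or "none")
        )
        lines.append(
            "  combined-fit sign flips: " + (", ".join(self.sign_flips) or "none")
        )
        if self.combined_singular:
            lines.append("  combined design is singular (dependency evidence)")
        lines.append(
            "  rare-moiety descriptors: "
            + (", ".join(self.rare_descriptors) or "none")
        )
        return "\n".join(lines)


def monitor_table(equations: pd.DataFrame, k: int = 12) -> pd.DataFrame:
    """Top-k rows of a ranked context-equation table: name, rank, sign."""
    if equations.empty:
        raise ValueError("empty equation table")
    cols = ["rank", "sign"] + (["r2"] if "r2" in equations.columns else [])
    return equations.sort_values("rank").head(k)[cols]
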