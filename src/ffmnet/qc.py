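"""Two-step quality control of a targeted-metabolomics dataset.

Step one works at the metabolite level: reference-blood replicates
(measured several times per plate) give a per-plate coefficient of
variation (CV) for every metabolite, and metabolites whose mean CV over
plates exceeds 25% are removed, as are metabolites with more than 5%
missing values.

Step two works at the data-point/subject level: a concentration is an
outlier if it lies outside mean ± 5 SD of its metabolite over the whole
cohort; outliers on strongly correlated metabolites (|r| ≥ 0.70) count as
one *independent* outlier; subjects with more than three independent
outliers are dropped, otherwise only the outlying cells are blanked.
Remaining missing values are filled by chained-equations regression
imputation.

All threshold comparisons are strict ("bigger than", "exceeded", "more
than"), so values exactly at a threshold are kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel_io import ConcentrationMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReferenceReplicates:
    """Reference-sample replicate measurements, replicates x metabolites.

    ``values`` is indexed by a (plate, replicate) MultiIndex; columns are
    metabolite names.  A CV is defined for a metabolite on a plate only if
    that plate holds at least two replicates.
    """

    values: pd.DataFrame

    @property
    def plates(self) -> list:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QcReport:
    """Complete record of a QC pass; sufficient to replay the transformation."""

    excluded_metabolites: list[tuple[str, str]] = field(default_factory=list)
    excluded_subjects: list[tuple[object, int]] = field(default_factory=list)
    outlier_cells: list[tuple[object, str, float, float]] = field(default_factory=list)
    imputed_cells: list[tuple[object, str, float]] = field(default_factory=list)
    mean_cv: pd.Series | None = None
    seed: int | None = None


def compute_cv(refs: ReferenceReplicates) -> tuple[pd.DataFrame, pd.Series]:
    """Per-plate CV (sample SD / mean) and its unweighted mean over plates.

    Plates with mean 0 give an undefined CV and are excluded from the mean
    with a warning; a metabolite with fewer than two replicates on every
    plate raises.
    """
    grouped = refs.values.groupby(level=0, sort=False)
    counts = grouped.count()
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    defined = counts >= 2
    if not defined.any().any() or (~defined.any()).any():
        bad = list(defined.columns[~defined.any()])
        raise ValueError(
            f"fewer than 2 replicates on every plate for: {bad}"
        )
    cv = sds / means
    cv = cv.where(defined)
    zero_mean = defined & (means == 0)
    if zero_mean.any().any():
        warnings.warn(
            "plates with zero mean concentration give undefined CVs and "
            "are excluded from the mean CV", stacklevel=2,
        )
        cv = cv.where(~zero_mean)
    mean_cv = cv.mean(axis=0, skipna=True)
    return cv, mean_cv


def filter_by_cv(
    matrix: ConcentrationMatrix,
    refs: ReferenceReplicates,
    threshold: float = 0.25,
) -> tuple[ConcentrationMatrix, list[tuple[str, str]], pd.Series]:
    """Remove metabolites whose mean reference CV is strictly above ``threshold``."""
    _, mean_cv = compute_cv(refs)
    entries = []
    keep = []
    for name in matrix.panel.names:
        if name not in mean_cv.index:
            logger.warning("no reference CV for %r; metabolite kept", name)
            keep.append(name)
        elif mean_cv[name] > threshold:
            entries.append((name, "cv"))
        else:
            keep.append(name)
    return matrix.subset_metabolites(keep), entries, mean_cv


def filter_by_missingness(
    matrix: ConcentrationMatrix, threshold: float = 0.05
) -> tuple[ConcentrationMatrix, list[tuple[str, str]]]:
    """Remove metabolites whose missing fraction strictly exceeds ``threshold``."""
    frac = matrix.values.isna().mean(axis=0)
    dropped = list(frac.index[frac > threshold])
    keep = [n for n in matrix.panel.names if n not in dropped]
    return matrix.subset_metabolites(keep), [(n, "missingness") for n in dropped]


def detect_outliers(matrix: ConcentrationMatrix, k: float = 5.0) -> pd.DataFrame:
    """Cells strictly outside mean ± k·SD of their metabolite.

    Mean and SD are computed per metabolite over all subjects in a single
    pass, candidate included.  Returns a DataFrame with columns
    (subject, metabolite, value, z).
    """
    vals = matrix.values
    rows = []
    for name in vals.columns:
        col = vals[name]
        obs = col.dropna()
        if len(obs) < 3:
            warnings.warn(
                f"metabolite {name!r} has <3 observed values; outlier "
                "detection skipped", stacklevel=2,
            )
            continue
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"metabolite {name!r} has zero variance; no outliers",
                stacklevel=2,
            )
            continue
        z = (col - mu) / sd
        flagged = z.abs() > k
        for subj in col.index[flagged.fillna(False)]:
            rows.append((subj, name, float(col[subj]), float(z[subj])))
    return pd.DataFrame(rows, columns=["subject", "metabolite", "value", "z"])


def independent_outlier_groups(
    matrix: ConcentrationMatrix,
    outlier_cells: pd.DataFrame,
    r_threshold: float = 0.70,
) -> pd.Series:
    """Number of independent outliers per subject.

    Two flagged metabolites of one subject are dependent when the Pearson
    correlation of their full concentration columns (pairwise complete,
    over all subjects) is ≥ ``r_threshold`` in absolute value; the
    independent count is the number of connected components of the
    dependency graph on that subject's flagged metabolites.
    """
    counts = pd.Series(0, index=matrix.values.index, dtype=int)
    if outlier_cells.empty:
        return counts
    flagged_mets = sorted(outlier_cells["metabolite"].unique())
    corr = matrix.values[flagged_mets].corr(min_periods=2)
    for subj, grp in outlier_cells.groupby("subject"):
        mets = list(grp["metabolite"].unique())
        g = nx.Graph()
        g.add_nodes_from(mets)
        for i, a in enumerate(mets):
            for b in mets[i + 1:]:
                r = corr.loc[a, b]
                if pd.notna(r) and abs(r) >= r_threshold:
                    g.add_edge(a, b)
        counts.loc[subj] = nx.number_connected_components(g)
    return counts


def apply_outlier_policy(
    matrix: ConcentrationMatrix,
    counts: pd.Series,
    outlier_cells: pd.DataFrame,
    max_independent: int = 3,
) -> tuple[ConcentrationMatrix, list[tuple[object, int]]]:
    """Drop subjects with more than ``max_independent`` independent
    outliers; blank the flagged cells of everyone else."""
    dropped = [
        (subj, int(c)) for subj, c in counts.items() if c > max_independent
    ]
    drop_set = {s for s, _ in dropped}
    vals = matrix.values.copy()
    for row in outlier_cells.itertuples(index=False):
        if row.subject not in drop_set:
            vals.loc[row.subject, row.metabolite] = np.nan
    keep = [s for s in vals.index if s not in drop_set]
    plates = (
        matrix.plate_of_subject.loc[keep]
        if matrix.plate_of_subject is not None else None
    )
    out = ConcentrationMatrix(vals.loc[keep], matrix.panel, plates)
    return out, dropped


def impute_missing(
    matrix: ConcentrationMatrix,
    seed: int,
    n_predictors: int = 10,
    n_sweeps: int = 5,
) -> tuple[ConcentrationMatrix, list[tuple[object, str, float]]]:
    """Chained-equations regression imputation (single completed dataset).

    Metabolites with missing cells are visited in decreasing-missingness
    order; each is regressed on its ``n_predictors`` most-correlated
    predictors (current completed values), and missing cells are filled
    with the linear prediction plus a residual-SD noise draw.  Five sweeps
    by default.  Ill-conditioned fits fall back to the metabolite mean.
    Imputed concentrations are floored at half the smallest observed
    positive value of their metabolite (a negative concentration is not
    physical, and an exact zero would poison downstream ratios).
    """
    vals = matrix.values
    if (vals.isna().mean(axis=0) > 0.5).any():
        bad = list(vals.columns[vals.isna().mean(axis=0) > 0.5])
        raise ValueError(f"metabolites with <50% observed values: {bad}")
    rng = np.random.default_rng(seed)
    miss = vals.isna()
    if not miss.any().any():
        return matrix, []
    raw = vals.to_numpy()
    miss_np = miss.to_numpy()
    col_means = np.nanmean(raw, axis=0)
    comp = np.where(miss_np, col_means, raw)
    with np.errstate(invalid="ignore"):
        pos = np.where(raw > 0, raw, np.nan)
    floor = 0.5 * np.nanmin(pos, axis=0)
    floor = np.where(np.isfinite(floor), floor, 0.0)
    n_missing = miss_np.sum(axis=0)
    # decreasing-missingness visit order over columns with missing cells
    order = np.argsort(-n_missing, kind="stable")
    order = order[n_missing[order] > 0]
    for _ in range(n_sweeps):
        corr = np.abs(np.corrcoef(comp, rowvar=False))
        np.fill_diagonal(corr, -np.inf)
        for j in order:
            cand = np.argsort(-corr[j], kind="stable")
            preds = cand[cand != j][:n_predictors]
            obs = ~miss_np[:, j]
            X = np.column_stack([np.ones(int(obs.sum())), comp[obs][:, preds]])
            y = raw[obs, j]
            try:
                beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
                if rank < X.shape[1] or not np.all(np.isfinite(beta)):
                    raise np.linalg.LinAlgError("rank deficient")
                resid = y - X @ beta
                dof = max(len(y) - X.shape[1], 1)
                sigma = float(np.sqrt((resid @ resid) / dof))
                Xm = np.column_stack([
                    np.ones(int((~obs).sum())), comp[~obs][:, preds]])
                filled = Xm @ beta + rng.normal(0.0, sigma, Xm.shape[0])
            except np.linalg.LinAlgError:
                logger.warning(
                    "ill-conditioned imputation model for %r; "
                    "falling back to metabolite mean", vals.columns[j],
                )
                filled = np.full(int((~obs).sum()), col_means[j])
            comp[~obs, j] = np.maximum(filled, floor[j])
    completed = pd.DataFrame(comp, index=vals.index, columns=vals.columns)
    ii, jj = np.where(miss.to_numpy())
    entries = [
        (vals.index[i], vals.columns[j], float(completed.iloc[i, j]))
        for i, j in zip(ii, jj)
    ]
    out = ConcentrationMatrix(completed, matrix.panel, matrix.plate_of_subject)
    return out, entries


def run_qc(
    matrix: ConcentrationMatrix,
    refs: ReferenceReplicates,
    seed: int = 0,
    cv_threshold: float = 0.25,
    missing_threshold: float = 0.05,
    outlier_k: float = 5.0,
    r_threshold: float = 0.70,
    max_independent: int = 3,
) -> tuple[ConcentrationMatrix, QcReport]:
    """Full QC pass in the fixed order: CV filter → missingness filter →
    outlier detection → subject policy → imputation.

    Deterministic given (matrix, refs, seed); the returned
    :class:`QcReport` records every exclusion, blanked cell and imputed
    value.
    """
    report = QcReport(seed=seed)
    matrix, cv_entries, mean_cv = filter_by_cv(matrix, refs, cv_threshold)
    report.excluded_metabolites.extend(cv_entries)
    report.mean_cv = mean_cv
    matrix, miss_entries = filter_by_missingness(matrix, missing_threshold)
    report.excluded_metabolites.extend(miss_entries)
    cells = detect_outliers(matrix, outlier_k)
    report.outlier_cells = list(cells.itertuples(index=False, name=None))
    counts = independent_outlier_groups(matrix, cells, r_threshold)
    matrix, dropped = apply_outlier_policy(matrix, counts, cells, max_independent)
    report.excluded_subjects = dropped
    matrix, imputed = impute_missing(matrix, seed)
    report.imputed_cells = imputed
    assert not matrix.values.isna().any().any()
    return matrix, report
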