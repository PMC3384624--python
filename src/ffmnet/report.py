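"""Tabular result artefacts: trait tables, stratified comparisons,
quintile summaries and boxplot-ready long-format exports.

Composite traits (sums of published metabolite groups) are defined here
and can be fed to the association scan as extra traits:

    Σ BCAAs          = Val + Ile + Leu
    Σ aromatic AAs   = Tyr + Phe + Trp
    Σ glucogenic AAs = Ala + Gly + Ser
    Σ PC ae          = all acyl-alkyl phosphatidylcholines
    Σ lysoPC         = all lyso-phosphatidylcholines

All files are TSV with numbers at 6 significant digits, so two runs with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_io import ConcentrationMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

COMPOSITE_AA = {
    "Sum BCAAs": ("Val", "Ile", "Leu"),
    "Sum aromatic AAs": ("Tyr", "Phe", "Trp"),
    "Sum glucogenic AAs": ("Ala", "Gly", "Ser"),
}


def composite_traits(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Composite µmol/l traits; a composite is emitted only when every
    constituent survived QC."""
    values, panel = matrix.values, matrix.panel
    out = pd.DataFrame(index=values.index)
    for name, members in COMPOSITE_AA.items():
        if all(m in values.columns for m in members):
            out[name] = values[list(members)].sum(axis=1)
        else:
            logger.info("composite %r skipped (missing constituents)", name)
    for name, cls in (("Sum PC ae", "PC_ae"), ("Sum lysoPC", "lysoPC")):
        members = [m.name for m in panel.metabolites if m.chem_class == cls
                   and m.name in values.columns]
        if members:
            out[name] = values[members].sum(axis=1)
    return out


def quintile_assign(series: pd.Series) -> pd.Series:
    """Quintile labels 1–5 with near-equal sizes (differ by ≤1).

    Ranks are taken with ties broken by position (subject order), so
    boundary values fall into the lower quintile.
    """
    n = len(series)
    order = np.lexsort((np.arange(n), series.to_numpy()))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    q = (rank * 5) // n + 1
    return pd.Series(q, index=series.index, name="quintile")


def quintile_table(pheno: pd.DataFrame, by: pd.Series) -> pd.DataFrame:
    """Cohort characteristics (mean ± SD, or %) by quintile of ``by``."""
    q = quintile_assign(by)
    rows = {}
    continuous = [c for c in ("age", "weight_kg", "height_m", "bmi",
                              "ffm_kg", "ffmi", "bfmi") if c in pheno.columns]
    for k in range(1, 6):
        sub = pheno[q == k]
        row: dict[str, object] = {
            "n": len(sub),
            "range_low": float(by[q == k].min()),
            "range_high": float(by[q == k].max()),
        }
        for c in continuous:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        if "sex" in pheno.columns:
            row["pct_male"] = 100.0 * (sub["sex"] == 1).mean()
        if "activity" in pheno.columns:
            row["pct_active"] = 100.0 * (sub["activity"] == "active").mean()
        rows[k] = row
    return pd.DataFrame(rows).T.rename_axis("quintile")


def trait_table(assoc_results: pd.DataFrame,
                values: pd.DataFrame) -> pd.DataFrame:
    """Published-style trait table: raw mean/SD plus association columns."""
    out = assoc_results.copy()
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    out.insert(1, "mean", out["trait"].map(means))
    out.insert(2, "sd", out["trait"].map(sds))
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def stratified_table(stratified: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side per-stratum beta / p / adjusted R²."""
    pieces = []
    for label, df in stratified.items():
        piece = df.set_index("trait")[["beta", "p", "r2_adj"]]
        piece.columns = [f"{label}_{c}" for c in piece.columns]
        pieces.append(piece)
    return pd.concat(pieces, axis=1).rename_axis("trait").reset_index()


def boxplot_long(values: pd.Series, by: pd.Series,
                 value_name: str = "value") -> pd.DataFrame:
    """Long-format (quintile, value) table, ready for a grouped boxplot."""
    q = quintile_assign(by)
    return pd.DataFrame({
        "quintile": q, value_name: values.loc[q.index],
    }).reset_index()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def summary_tables(
    out_dir,
    assoc_results: pd.DataFrame | None = None,
    ratio_results: pd.DataFrame | None = None,
    stratified: dict[str, pd.DataFrame] | None = None,
    matrix: ConcentrationMatrix | None = None,
    pheno: pd.DataFrame | None = None,
) -> list[Path]:
    """Write every available result table under ``out_dir``; returns paths.

    Empty inputs still produce headers-only files, so downstream tooling
    can rely on the schemas.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if assoc_results is not None:
        values = matrix.values if matrix is not None else pd.DataFrame()
        path = out_dir / "trait_associations.tsv"
        _write(trait_table(assoc_results, values), path)
        written.append(path)
    if ratio_results is not None:
        path = out_dir / "ratio_associations.tsv"
        _write(ratio_results.sort_values("p", kind="mergesort")
               if not ratio_results.empty else ratio_results, path)
        written.append(path)
    if stratified:
        path = out_dir / "stratified_comparison.tsv"
        _write(stratified_table(stratified), path)
        written.append(path)
    if pheno is not None and matrix is not None:
        comp = composite_traits(matrix)
        if "Sum BCAAs" in comp.columns:
            path = out_dir / "characteristics_by_bcaa_quintile.tsv"
            _write(quintile_table(pheno, comp["Sum BCAAs"]).reset_index(), path)
            written.append(path)
            if "ffmi" in pheno.columns:
                path = out_dir / "bcaa_by_ffmi_quintile_long.tsv"
                _write(boxplot_long(comp["Sum BCAAs"], pheno["ffmi"],
                                    "sum_bcaa_umol_l"), path)
                written.append(path)
    return written
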