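"""Data model and I/O for metabolite panels, concentrations and phenotypes.

A *panel* is the ordered list of metabolites a targeted-metabolomics kit
quantifies, each assigned to a chemical class (amino acids, biogenic
amines, acylcarnitines, lyso-, diacyl- and acyl-alkyl-phosphatidylcholines,
sphingomyelins, hexose).  Two presets ship with the package, named after
the Biocrates AbsoluteIDQ kits they emulate: ``p180`` (186 metabolites)
and ``p150`` (163 metabolites).

Concentration matrices are subjects x metabolites tables in µmol/l;
phenotype tables carry the anthropometry (age, sex, height, weight, fat
free mass, fat mass, activity, batch) from which the derived indices

    FFMI = fat free mass / height²      (kg/m²)
    BFMI = fat mass      / height²      (kg/m²)

are computed.  All I/O is plain TSV.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHEM_CLASSES = (
    "amino_acid",
    "biogenic_amine",
    "acylcarnitine",
    "lysoPC",
    "PC_aa",
    "PC_ae",
    "sphingomyelin",
    "hexose",
)

#: phenotype columns a reader accepts; height_cm is converted to metres
PHENOTYPE_COLUMNS = (
    "age", "sex", "height_m", "weight_kg", "ffm_kg", "fm_kg",
    "activity", "batch",
)

EXCLUSION_FLAGS = (
    "mi", "stroke", "diabetes", "cancer", "ace_inhibitor", "anti_lipidemic",
)


class PanelMismatchError(ValueError):
    """Concentration file header does not match the panel."""


@dataclass(frozen=True)
class MetaboliteDescriptor:
    """One metabolite of a targeted panel.

    ``carbons``/``double_bonds`` describe the lipid side chain (the Cx:y
    suffix of the name) and are ``None`` for non-lipid analytes.
    """

    name: str
    chem_class: str
    carbons: int | None = None
    double_bonds: int | None = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(f"unknown chemical class {self.chem_class!r}")
        for v in (self.carbons, self.double_bonds):
            if v is not None and v < 0:
                raise ValueError("carbons/double_bonds must be non-negative")


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered metabolite panel with chemical-class assignments."""

    metabolites: tuple[MetaboliteDescriptor, ...]
    panel_name: str = "custom"

    def __post_init__(self) -> None:
        names = [m.name for m in self.metabolites]
        if len(names) != len(set(names)):
            raise ValueError("metabolite names must be unique within a panel")

    def __len__(self) -> int:
        return len(self.metabolites)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    def class_of(self, name: str) -> str:
        return self._class_map()[name]

    def _class_map(self) -> dict[str, str]:
        return {m.name: m.chem_class for m in self.metabolites}

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.metabolites:
            out[m.chem_class] = out.get(m.chem_class, 0) + 1
        return out

    def subset(self, names: Iterable[str]) -> "PanelDefinition":
        """Panel restricted to ``names``, original order preserved."""
        keep = set(names)
        return PanelDefinition(
            tuple(m for m in self.metabolites if m.name in keep),
            panel_name=self.panel_name,
        )


@dataclass
class ConcentrationMatrix:
    """Subjects x metabolites concentrations in µmol/l.

    ``values`` is a DataFrame indexed by subject id with one column per
    panel metabolite, in panel order; missing measurements are NaN.
    """

    values: pd.DataFrame
    panel: PanelDefinition
    plate_of_subject: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.panel.names:
            raise PanelMismatchError(
                "matrix columns do not match panel order"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate subject ids: {list(dupes[:5])}")
        bad = (self.values < 0).any()
        if bad.any():
            raise ValueError(
                f"negative concentrations in columns: {list(bad[bad].index)}"
            )

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    def subset_metabolites(self, names: Sequence[str]) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values[list(names)].copy(), self.panel.subset(names),
            self.plate_of_subject,
        )

    def subset_subjects(self, subjects: Sequence) -> "ConcentrationMatrix":
        plates = (
            self.plate_of_subject.loc[list(subjects)]
            if self.plate_of_subject is not None else None
        )
        return ConcentrationMatrix(
            self.values.loc[list(subjects)].copy(), self.panel, plates,
        )


def load_panel_preset(name: str) -> PanelDefinition:
    """Load a packaged panel preset (``"p180"`` or ``"p150"``)."""
    if name not in ("p180", "p150"):
        raise ValueError(f"no packaged panel preset named {name!r}")
    ref = importlib.resources.files("ffmnet.data") / f"{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_panel(path, panel_name=name)


def read_panel(path, panel_name: str | None = None) -> PanelDefinition:
    """Read a panel definition TSV (name, chem_class, carbons, double_bonds)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chem_class": str})
    mets = []
    for row in df.itertuples(index=False):
        carbons = int(row.carbons) if pd.notna(row.carbons) else None
        dbl = int(row.double_bonds) if pd.notna(row.double_bonds) else None
        mets.append(MetaboliteDescriptor(row.name, row.chem_class, carbons, dbl))
    return PanelDefinition(tuple(mets), panel_name=panel_name or str(path))


def read_concentrations(path, panel: PanelDefinition) -> ConcentrationMatrix:
    """Read a subjects x metabolites TSV into a :class:`ConcentrationMatrix`.

    The first column must be ``subject_id``; remaining columns must be
    exactly the panel's metabolites (any order — the result is aligned to
    panel order).  Empty cells and ``NA`` are missing; other unparseable
    cells are coerced to missing and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["", "NA"])
    if df.columns[0] != "subject_id":
        raise ValueError("first column must be 'subject_id'")
    df = df.set_index("subject_id")
    file_cols, panel_cols = set(df.columns), set(panel.names)
    if file_cols != panel_cols:
        missing = sorted(panel_cols - file_cols)
        extra = sorted(file_cols - panel_cols)
        raise PanelMismatchError(
            f"header/panel mismatch: missing {missing}, unexpected {extra}"
        )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate subject ids: {list(dupes[:5])}")
    raw_missing = int(df.isna().to_numpy().sum())
    values = df.apply(pd.to_numeric, errors="coerce")[panel.names]
    coerced = int(values.isna().to_numpy().sum()) - raw_missing
    if coerced:
        logger.warning("coerced %d unparseable cells to missing", coerced)
    neg = (values < 0)
    if neg.any().any():
        r, c = np.argwhere(neg.to_numpy())[0]
        raise ValueError(
            f"negative concentration at subject {values.index[r]!r}, "
            f"metabolite {values.columns[c]!r}"
        )
    return ConcentrationMatrix(values, panel)


def write_concentrations(matrix: ConcentrationMatrix, path) -> None:
    """Write a concentration matrix back to TSV (missing cells empty).

    Uses full repr precision so read -> write -> read round-trips
    bit-identically.
    """
    out = matrix.values.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep="", float_format=None)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV indexed by subject id.

    Accepts ``height_cm`` (converted to metres) or ``height_m``.  Validates
    positivity of height/age and the body-composition budget
    ffm + fm <= 1.05 x weight.
    """
    df = pd.read_csv(path, sep="\t").set_index("subject_id")
    if "height_cm" in df.columns:
        df["height_m"] = df.pop("height_cm") / 100.0
    validate_phenotypes(df)
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    if (pheno["height_m"] <= 0).any():
        raise ValueError("height must be positive")
    if "age" in pheno.columns and (pheno["age"] <= 0).any():
        raise ValueError("age must be positive")
    cols = {"ffm_kg", "fm_kg", "weight_kg"}
    if cols.issubset(pheno.columns):
        over = pheno["ffm_kg"] + pheno["fm_kg"] > pheno["weight_kg"] * 1.05
        if over.any():
            raise ValueError(
                "ffm + fm exceeds weight by more than 5% for subjects "
                f"{list(pheno.index[over][:5])}"
            )


def compute_indices(pheno: pd.DataFrame) -> pd.DataFrame:
    """Derived anthropometric indices per subject.

    Returns a DataFrame with ``ffmi``, ``bfmi``, ``bmi`` (kg/m²) and
    ``fat_pct`` (%).  BMI = weight/h², FFMI = ffm/h², BFMI = fm/h², so
    BMI = FFMI + BFMI exactly when weight = ffm + fm.
    """
    if (pheno["height_m"] <= 0).any():
        raise ValueError("height must be positive")
    h2 = pheno["height_m"] ** 2
    out = pd.DataFrame(index=pheno.index)
    out["ffmi"] = pheno["ffm_kg"] / h2
    out["bfmi"] = pheno["fm_kg"] / h2
    out["bmi"] = pheno["weight_kg"] / h2
    out["fat_pct"] = 100.0 * pheno["fm_kg"] / pheno["weight_kg"]
    return out


def weight_stable_filter(pheno: pd.DataFrame,
                         max_rate: float = 0.005) -> pd.Index:
    """Subjects whose annualised relative weight change stayed within
    ``max_rate`` (default 0.5%/year, boundary inclusive).

    Requires ``weight_baseline_kg``, ``weight_followup_kg`` and
    ``years_elapsed`` columns.
    """
    if (pheno["years_elapsed"] <= 0).any():
        raise ValueError("years_elapsed must be positive")
    rate = (
        (pheno["weight_followup_kg"] - pheno["weight_baseline_kg"]).abs()
        / pheno["weight_baseline_kg"] / pheno["years_elapsed"]
    )
    return pheno.index[rate <= max_rate]


def exclusion_filter(pheno: pd.DataFrame) -> pd.Index:
    """Drop subjects with any clinical/medication exclusion flag.

    Flag columns (``mi``, ``stroke``, ``diabetes``, ``cancer``,
    ``ace_inhibitor``, ``anti_lipidemic``) are optional; a missing column
    or cell is treated as flag absent (logged).
    """
    flagged = pd.Series(False, index=pheno.index)
    for col in EXCLUSION_FLAGS:
        if col not in pheno.columns:
            logger.info("exclusion flag column %r absent; treated as unset", col)
            continue
        flagged |= pheno[col].fillna(0).astype(bool)
    kept = pheno.index[~flagged]
    if len(kept) == 0 and len(pheno):
        warnings.warn("all subjects carry an exclusion flag", stacklevel=2)
    return kept
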