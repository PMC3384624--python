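"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a targeted serum-metabolomics study of body
composition (the KORA S4/F4 design): log-normally distributed metabolite
concentrations whose log-scale dependence follows a class-structured
sparse precision matrix (a planted Gaussian graphical model), phenotype
effects of stated standardized size planted on the log scale, additive
log-scale batch shifts, injected gross outliers (6–9 SD displacements,
so a ±5 SD detector must catch them), completely-at-random missingness,
and plate-replicated reference samples with tunable coefficients of
variation.  Everything is a pure function of ``(config, seed)`` and the
planted structure is returned as :class:`GroundTruth`, so every
downstream stage is testable without external data.

Default population parameters follow the published S4 cohort
descriptives: n = 965, sex-specific FFMI 19.71 ± 1.66 (men) /
16.99 ± 1.85 (women) kg/m², age ≈ N(63.2, 5.5²) truncated to [51, 80],
and marginal concentration means/SDs taken from the published per-
metabolite table where available.  Twenty low-abundance species are
assigned a reference CV of 0.35 so that the CV filter removes exactly
20 metabolites, leaving a 166-metabolite post-QC panel as in S4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import ConcentrationMatrix, PanelDefinition, load_panel_preset
from .qc import ReferenceReplicates

__all__ = [
    "SimulationConfig", "GroundTruth", "CohortDataset",
    "generate_phenotypes", "generate_precision_matrix",
    "generate_concentrations", "generate_reference_replicates",
    "generate_cohort", "marginal_partial_corr",
    "DEFAULT_EFFECTS", "DEFAULT_MARGINALS",
    "DEFAULT_HIGH_CV",
]

#: planted standardized effects of FFMI (per kg/m², transformed scale);
#: values are the published non-obese stratum estimates
DEFAULT_EFFECTS: dict[str, float] = {
    "Val": 0.14, "Ile": 0.13, "Leu": 0.13, "Ala": 0.12, "Tyr": 0.14,
    "Phe": 0.10, "C5": 0.14, "C3": 0.13, "C0": 0.09,
    "PC aa C38:3": 0.08, "PC ae C42:3": -0.16, "PC ae C36:2": -0.09,
    "lysoPC a C18:1": -0.07, "lysoPC a C18:2": -0.07,
}

#: marginal (mean, SD) targets in µmol/l for metabolites with published
#: values; hexose from the published serum-glucose subgroup figures
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "Val": (227.26, 53.13), "Glu": (80.13, 32.04), "Ile": (72.14, 20.22),
    "Leu": (160.51, 44.33), "Ala": (417.99, 101.4), "Tyr": (72.09, 20.06),
    "Phe": (76.73, 17.19), "C5": (0.16, 0.06), "C3": (0.47, 0.15),
    "C0": (40.52, 8.49), "C18": (0.06, 0.01),
    "PC aa C38:3": (57.77, 14.01), "PC ae C42:3": (0.85, 0.19),
    "PC ae C36:2": (15.33, 3.88), "lysoPC a C18:2": (28.46, 9.04),
    "lysoPC a C18:1": (21.61, 6.1), "H1": (5180.0, 760.0),
}

#: class-typical (mean, SD) fallbacks in µmol/l
CLASS_MARGINALS: dict[str, tuple[float, float]] = {
    "amino_acid": (100.0, 30.0),
    "biogenic_amine": (2.0, 0.8),
    "acylcarnitine": (0.15, 0.05),
    "lysoPC": (15.0, 5.0),
    "PC_aa": (30.0, 10.0),
    "PC_ae": (5.0, 1.5),
    "sphingomyelin": (15.0, 5.0),
    "hexose": (5180.0, 760.0),
}

#: low-abundance species given a high reference CV by default so the CV
#: filter has real work to do (20 names, as excluded from S4)
DEFAULT_HIGH_CV: tuple[str, ...] = (
    "C3:1", "C4:1", "C5:1", "C5:1-DC", "C5-M-DC", "C6:1", "C7-DC", "C9",
    "C10:2", "C12-DC", "C14:2-OH", "C16:2-OH", "DOPA", "Dopamine",
    "Histamine", "Nitro-Tyr", "PEA", "Spermine",
    "lysoPC a C26:1", "lysoPC a C28:1",
)

# sex-specific population parameters (men, women)
_FFMI_MEAN, _FFMI_SD = (19.71, 16.99), (1.66, 1.85)
_BFMI_MEAN, _BFMI_SD = (8.34, 11.24), (2.29, 3.08)
_HEIGHT_MEAN, _HEIGHT_SD = (1.7226, 1.5933), (0.0635, 0.0596)
_ACTIVE_P = (0.39, 0.47)
_AGE_MEAN, _AGE_SD, _AGE_RANGE = 63.2, 5.5, (51.0, 80.0)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_subjects: int = 965
    panel: PanelDefinition | None = None          # None -> packaged p180
    seed: int = 0
    effect_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    gamma_age: float = 0.05
    gamma_sex: float = 0.05
    within_class_density: float = 0.05
    partial_corr_range: tuple[float, float] = (0.3, 0.6)
    batch_count: int = 3
    batch_sd: float = 0.05
    outlier_rate: float = 0.001
    missing_rate: float = 0.002
    n_plates: int = 10
    n_reference_replicates: int = 5
    base_cv: float = 0.07
    high_cv: float = 0.5
    high_cv_metabolites: tuple[str, ...] = DEFAULT_HIGH_CV
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    exclusion_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.outlier_rate, self.missing_rate,
                  self.within_class_density, self.exclusion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")

    def resolved_panel(self) -> PanelDefinition:
        return self.panel if self.panel is not None else load_panel_preset("p180")

    def target_cv(self) -> pd.Series:
        panel = self.resolved_panel()
        cv = pd.Series(self.base_cv, index=panel.names)
        for name in self.high_cv_metabolites:
            if name in cv.index:
                cv[name] = self.high_cv
        return cv


@dataclass
class GroundTruth:
    """Planted structure the simulator emits alongside the data."""

    true_betas: pd.Series
    true_precision: pd.DataFrame
    true_partial_corr: pd.DataFrame
    outlier_mask: pd.DataFrame
    missing_mask: pd.DataFrame
    true_cv: pd.Series


def marginal_partial_corr(
    precision: pd.DataFrame, kept: list[str]
) -> pd.DataFrame:
    """Partial correlations among ``kept`` after marginalising the rest.

    Dropping variables from a Gaussian graphical model changes the
    remaining full-order partial correlations; the exact marginal
    precision is the Schur complement Ω_AA − Ω_AB Ω_BB⁻¹ Ω_BA.  Use this
    to obtain ground-truth edges for a post-QC metabolite subset.
    """
    names = list(precision.index)
    dropped = [n for n in names if n not in set(kept)]
    A = precision.loc[kept, kept].to_numpy()
    if dropped:
        B = precision.loc[kept, dropped].to_numpy()
        D = precision.loc[dropped, dropped].to_numpy()
        A = A - B @ np.linalg.solve(D, B.T)
    d = np.sqrt(np.diag(A))
    pc = -A / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pd.DataFrame(pc, index=kept, columns=kept)


@dataclass
class CohortDataset:
    """Concentrations + phenotypes + reference replicates + ground truth."""

    concentrations: ConcentrationMatrix
    phenotypes: pd.DataFrame
    reference_replicates: ReferenceReplicates
    truth: GroundTruth


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def generate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Phenotype table with sex-specific anthropometry.

    Sex ~ Bernoulli(0.5) (1 = male); FFMI and BFMI sex-specific normal;
    heights sex-specific normal; fat free / fat mass back-computed from
    the indices; weight = ffm + fm.  Also emits baseline/follow-up
    weights over 7 years (small random drift) for the weight-stability
    filter and all-false exclusion flags unless ``exclusion_rate > 0``.
    """
    rng = _rng(config, 1)
    n = config.n_subjects
    sex = rng.integers(0, 2, n)                      # 1 = male
    i = 1 - sex                                      # parameter row index
    a, b = (np.array(_AGE_RANGE) - _AGE_MEAN) / _AGE_SD
    age = stats.truncnorm.rvs(a, b, loc=_AGE_MEAN, scale=_AGE_SD,
                              size=n, random_state=rng)
    height = rng.normal(np.take(_HEIGHT_MEAN, i), np.take(_HEIGHT_SD, i))
    ffmi = rng.normal(np.take(_FFMI_MEAN, i), np.take(_FFMI_SD, i))
    bfmi = np.maximum(
        rng.normal(np.take(_BFMI_MEAN, i), np.take(_BFMI_SD, i)), 1.0)
    ffm = ffmi * height ** 2
    fm = bfmi * height ** 2
    weight = ffm + fm
    activity = rng.random(n) < np.take(_ACTIVE_P, i)
    batch = rng.integers(0, config.batch_count, n)
    drift = rng.normal(0.0, 0.003, n)                # fraction per year
    pheno = pd.DataFrame({
        "age": age, "sex": sex, "height_m": height, "weight_kg": weight,
        "ffm_kg": ffm, "fm_kg": fm, "ffmi": ffmi, "bfmi": bfmi,
        "bmi": weight / height ** 2,
        "activity": np.where(activity, "active", "inactive"),
        "batch": batch,
        "weight_baseline_kg": weight,
        "weight_followup_kg": weight * (1 + drift * 7.0),
        "years_elapsed": 7.0,
    }, index=pd.Index([f"S{k:04d}" for k in range(n)], name="subject_id"))
    for flag in ("mi", "stroke", "diabetes", "cancer", "ace_inhibitor",
                 "anti_lipidemic"):
        pheno[flag] = rng.random(n) < config.exclusion_rate
    return pheno


def generate_precision_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Block-structured sparse precision matrix on the log scale.

    Within each chemical class, edges are drawn independently at
    ``within_class_density``; each edge's partial correlation magnitude is
    uniform over ``partial_corr_range`` with random sign.  An edge is only
    placed while both endpoints keep their absolute off-diagonal row sum
    below a diagonal-dominance budget, which guarantees positive
    definiteness *without* shrinking the drawn magnitudes (a diagonal
    ridge would push every planted value toward the detection boundary);
    a ridge remains as a fallback for extreme configurations.  The
    returned edge list carries the implied partial correlations of the
    final matrix.
    """
    panel = config.resolved_panel()
    names = panel.names
    m = len(names)
    rng = _rng(config, 2)
    omega = np.eye(m)
    cls = np.array([panel.class_of(n) for n in names])
    lo, hi = config.partial_corr_range
    row_budget = 0.9
    row_sum = np.zeros(m)
    for c in pd.unique(cls):
        idx = np.where(cls == c)[0]
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1:]:
                if rng.random() < config.within_class_density:
                    rho = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                    if (row_sum[a] + abs(rho) > row_budget
                            or row_sum[b] + abs(rho) > row_budget):
                        continue
                    omega[a, b] = omega[b, a] = -rho
                    row_sum[a] += abs(rho)
                    row_sum[b] += abs(rho)
    ridge, budget = 0.0, 2.0
    while True:
        w = np.linalg.eigvalsh(omega + ridge * np.eye(m))
        if w[0] > 1e-4:
            break
        ridge += (1e-4 - w[0]) + 1e-6
        if ridge > budget:
            raise RuntimeError("could not reach SPD within ridge budget")
    omega = omega + ridge * np.eye(m)
    d = np.sqrt(np.diag(omega))
    pcorr = -omega / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    omega_df = pd.DataFrame(omega, index=names, columns=names)
    pcorr_df = pd.DataFrame(pcorr, index=names, columns=names)
    edges = [
        (names[a], names[b], float(pcorr[a, b]))
        for a in range(m) for b in range(a + 1, m)
        if omega[a, b] != 0.0
    ]
    return omega_df, edges, pcorr_df


def _marginal_targets(config: SimulationConfig) -> pd.DataFrame:
    panel = config.resolved_panel()
    rows = []
    for met in panel.metabolites:
        mean, sd = config.marginals.get(
            met.name, CLASS_MARGINALS[met.chem_class])
        rows.append((met.name, mean, sd))
    return pd.DataFrame(rows, columns=["name", "mean", "sd"]).set_index("name")


def generate_concentrations(
    config: SimulationConfig,
    pheno: pd.DataFrame,
    truth_precision: pd.DataFrame,
) -> tuple[ConcentrationMatrix, GroundTruth]:
    """Concentrations in µmol/l with planted effects, outliers, missingness.

    The latent log-scale vector per subject is
    ``z = β·FFMI_c + γ_age·age_z + γ_sex·sex_z + batch shift + ε`` with
    ``ε`` drawn from the correlation form of ``truth_precision⁻¹`` and
    scaled so each latent coordinate has unit variance; the latent value
    is then mapped to ``exp(μ_j + σ_j·z_j)`` with ``μ_j, σ_j`` chosen so
    the marginal mean/SD match the configured µmol/l targets.  Outliers
    replace raw values with mean ± U(6,9)·SD; missingness is MCAR.
    """
    panel = config.resolved_panel()
    names = panel.names
    if list(truth_precision.index) != names:
        raise ValueError("precision matrix does not match panel")
    n, m = len(pheno), len(names)
    rng = _rng(config, 3)

    sigma = np.linalg.inv(truth_precision.to_numpy())
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    L = np.linalg.cholesky(corr)
    eps = rng.standard_normal((n, m)) @ L.T

    betas = pd.Series(0.0, index=names)
    for k, v in config.effect_table.items():
        if k in betas.index:
            betas[k] = v
    ffmi_c = (pheno["ffmi"] - pheno["ffmi"].mean()).to_numpy()
    age_z = ((pheno["age"] - pheno["age"].mean())
             / pheno["age"].std(ddof=0)).to_numpy()
    sex_z = ((pheno["sex"] - pheno["sex"].mean())
             / max(pheno["sex"].std(ddof=0), 1e-12)).to_numpy()
    signal = (
        np.outer(ffmi_c, betas.to_numpy())
        + np.outer(age_z, np.full(m, config.gamma_age))
        + np.outer(sex_z, np.full(m, config.gamma_sex))
    )
    var_signal = (
        betas.to_numpy() ** 2 * ffmi_c.var()
        + config.gamma_age ** 2 + config.gamma_sex ** 2
    )
    noise_scale = np.sqrt(np.clip(1.0 - var_signal, 0.1, None))
    batch_shift = rng.normal(0.0, config.batch_sd, (config.batch_count, m))
    latent = signal + eps * noise_scale + batch_shift[pheno["batch"].to_numpy()]

    targets = _marginal_targets(config)
    mean_t = targets["mean"].to_numpy()
    sd_t = targets["sd"].to_numpy()
    sig2 = np.log1p((sd_t / mean_t) ** 2)
    mu = np.log(mean_t) - sig2 / 2.0
    raw = np.exp(mu + np.sqrt(sig2) * latent)

    # gross outliers: displace to mean ± U(6,9)·SD on the raw scale
    out_mask = rng.random((n, m)) < config.outlier_rate
    if out_mask.any():
        col_mean = raw.mean(axis=0)
        col_sd = raw.std(axis=0, ddof=1)
        ii, jj = np.where(out_mask)
        k = rng.uniform(6.0, 9.0, ii.size)
        sign = rng.choice([-1.0, 1.0], ii.size)
        disp = col_mean[jj] + sign * k * col_sd[jj]
        disp = np.where(disp <= 0, col_mean[jj] + k * col_sd[jj], disp)
        raw[ii, jj] = disp

    miss_mask = rng.random((n, m)) < config.missing_rate
    raw = np.where(miss_mask, np.nan, raw)
    out_mask = out_mask & ~miss_mask

    values = pd.DataFrame(raw, index=pheno.index, columns=names)
    matrix = ConcentrationMatrix(values, panel)
    dd = np.sqrt(np.diag(truth_precision.to_numpy()))
    pcorr = -truth_precision.to_numpy() / np.outer(dd, dd)
    np.fill_diagonal(pcorr, 1.0)
    truth = GroundTruth(
        true_betas=betas,
        true_precision=truth_precision,
        true_partial_corr=pd.DataFrame(pcorr, index=names, columns=names),
        outlier_mask=pd.DataFrame(out_mask, index=pheno.index, columns=names),
        missing_mask=pd.DataFrame(miss_mask, index=pheno.index, columns=names),
        true_cv=config.target_cv(),
    )
    return matrix, truth


def generate_reference_replicates(config: SimulationConfig) -> ReferenceReplicates:
    """Plate-replicated reference-sample measurements.

    Per plate and metabolite, replicates are log-normal around a common
    reference level with dispersion set so the coefficient of variation
    matches the configured target (zero CV gives identical replicates).
    """
    panel = config.resolved_panel()
    targets = _marginal_targets(config)
    cv = config.target_cv().to_numpy()
    rng = _rng(config, 4)
    level = targets["mean"].to_numpy()
    sig2 = np.log1p(cv ** 2)
    mu = np.log(level) - sig2 / 2.0
    idx = pd.MultiIndex.from_product(
        [range(config.n_plates), range(config.n_reference_replicates)],
        names=["plate", "replicate"],
    )
    z = rng.standard_normal((len(idx), len(panel)))
    vals = np.exp(mu + np.sqrt(sig2) * z)
    return ReferenceReplicates(
        pd.DataFrame(vals, index=idx, columns=panel.names))


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Full cohort: phenotypes, concentrations, reference replicates, truth."""
    pheno = generate_phenotypes(config)
    omega, _, _ = generate_precision_matrix(config)
    matrix, truth = generate_concentrations(config, pheno, omega)
    refs = generate_reference_replicates(config)
    plates = pd.Series(
        np.arange(len(pheno)) % config.n_plates, index=pheno.index)
    matrix.plate_of_subject = plates
    return CohortDataset(matrix, pheno, refs, truth)
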