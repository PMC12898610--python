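"""Synthetic genotype--phenotype cohort generator.

Emulates the statistical structure the analysis pipeline assumes for a
case--control plasma-complement study: fixed group sizes (default 50 cases,
121 controls), Hardy--Weinberg genotypes with optional LD pairs via a
Gaussian copula on latent normal liabilities, genotype frequencies tilted in
cases according to planted disease odds ratios, additive pQTL effects on
log2 protein levels, demographic covariate effects, case--control protein
shifts (optionally concentrated in heterozygote carriers of two index
markers, which is what makes genotype-stratified ROC informative), one
shared latent factor driving inter-protein correlation, and survey scores
linearly linked to protein levels.

``SimConfig()`` with no arguments is a null generator (no planted effects);
``default_study_config()`` returns the study conditions used throughout the
tests and the acceptance script.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ALL_MEASURES,
    ANALYTES,
    FUNCTIONAL_GROUPS,
    MFI_SUBSCALES,
    RATIO,
    SF36_SUBSCALES,
    SURVEY_SCORES,
    Cohort,
    DataError,
    GenotypeMatrix,
    observed_maf,
)
from .io import log2_transform

log = logging.getLogger(__name__)

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class PlantedSnp:
    """A named variant with fixed annotation, MAF and disease effect."""

    rsid: str
    chrom: str
    pos: int
    gene: str
    functional_group: str
    consequence: str
    maf: float
    risk_or: float = 1.0  # disease odds ratio per minor-allele copy
    major_allele: str = "G"
    minor_allele: str = "A"


@dataclass
class SimConfig:
    """Generator parameters.  Defaults describe a null cohort."""

    n_case: int = 50
    n_control: int = 121
    n_snps: int = 60
    maf_range: tuple = (0.05, 0.5)
    planted_snps: list = field(default_factory=list)
    ld_pairs: list = field(default_factory=list)  # (rsid_i, rsid_j, r)
    pqtl_effects: list = field(default_factory=list)  # (rsid, analyte, beta)
    covariate_effects: dict = field(default_factory=dict)  # analyte -> {bmi, sex, age}
    group_shifts: dict = field(default_factory=dict)  # analyte -> case - control, log2
    het_extra_shifts: dict = field(default_factory=dict)  # extra case shift in het carriers
    het_markers: tuple = ()  # two rsids defining heterozygote carriership
    latent_loadings: dict = field(default_factory=dict)  # analyte -> loading on shared factor
    noise_sd: dict = field(default_factory=dict)  # analyte -> residual SD (log2)
    intercepts: dict = field(default_factory=dict)  # analyte -> log2 level at covariates = 0
    survey_baselines: dict = field(default_factory=dict)  # score -> (control mean, case offset, sd)
    survey_links: dict = field(default_factory=dict)  # (score, analyte) -> slope per log2 unit
    female_fraction: float = 0.75
    age_mean: float = 50.0
    age_sd: float = 10.0
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    bmi_case_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for a, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd for {a} must be > 0")
        for i, j, r in self.ld_pairs:
            if abs(r) > 1:
                raise ValueError(f"LD correlation |r| > 1 for ({i}, {j})")


@dataclass
class GroundTruth:
    """Planted parameters as realized in one generated cohort."""

    pqtl_effects: pd.DataFrame  # rsid, analyte, beta
    group_shifts: dict
    het_extra_shifts: dict
    het_markers: tuple
    covariate_effects: dict
    snp_truth: pd.DataFrame  # configured vs realized MAFs, case/control freqs
    het_fraction_case: float
    het_fraction_control: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "pqtl_effect", "key1": r.rsid, "key2": r.analyte, "value": r.beta}
            for r in self.pqtl_effects.itertuples()
        ]
        for a, v in self.group_shifts.items():
            rows.append({"kind": "group_shift", "key1": a, "key2": "", "value": v})
        for a, v in self.het_extra_shifts.items():
            rows.append({"kind": "het_extra_shift", "key1": a, "key2": "", "value": v})
        for a, effs in self.covariate_effects.items():
            for c, v in effs.items():
                rows.append({"kind": "covariate_effect", "key1": a, "key2": c, "value": v})
        for r in self.snp_truth.itertuples():
            rows.append({"kind": "realized_maf", "key1": r.Index, "key2": "", "value": r.realized_maf})
        rows.append({"kind": "het_fraction", "key1": "case", "key2": "", "value": self.het_fraction_case})
        rows.append({"kind": "het_fraction", "key1": "control", "key2": "", "value": self.het_fraction_control})
        return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    cohort: Cohort
    genotypes: GenotypeMatrix
    raw_proteins: pd.DataFrame
    surveys: pd.DataFrame
    disease_table: pd.DataFrame
    tss_table: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def panel(self):
        return log2_transform(self.raw_proteins)


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

# Marginal case - control shifts of log2 levels (ME/CFS minus NF group means).
_GROUP_SHIFTS = {
    "CRP": 1.087, "C3": 0.215, "C3a": 0.16, "C5a": 0.094, "Bb": -0.022,
    "FactorB": 0.143, "FactorD": 0.094, "FactorH": 0.128, "SC5b9": 0.039,
}

# Control-group mean log2 level per analyte (native units).
_CONTROL_MEANS = {
    "CRP": 0.318, "C3": 0.324, "C3a": 9.90, "C5a": 4.218, "Bb": -0.077,
    "FactorB": 8.242, "FactorD": 1.233, "FactorH": 8.299, "SC5b9": 7.113,
}

# Total log2 SD targets per analyte (control group).
_TOTAL_SD = {
    "CRP": 1.71, "C3": 0.31, "C3a": 0.58, "C5a": 0.40, "Bb": 0.45,
    "FactorB": 0.35, "FactorD": 0.29, "FactorH": 0.29, "SC5b9": 0.60,
}

# Demographic slopes in log2 units: BMI per kg/m2, sex as male offset, age per year.
_COVARIATE_EFFECTS = {
    "CRP": {"bmi": 0.169, "sex": -0.645},
    "C3": {"bmi": 0.033},
    "C3a": {"bmi": 0.036},
    "C5a": {"bmi": 0.025},
    "FactorB": {"bmi": 0.026, "sex": -0.159},
    "FactorD": {"bmi": 0.020, "age": 0.011},
    "FactorH": {"bmi": 0.023},
}

# Loading on the single shared latent factor, as a fraction of total SD.
_LOADING_FRACTION = {
    "CRP": 0.5, "C3": 0.5, "C3a": 0.5, "FactorB": 0.5, "FactorD": 0.5,
    "FactorH": 0.5, "C5a": 0.15, "SC5b9": 0.15, "Bb": 0.1,
}

_PLANTED_SNPS = [
    PlantedSnp("rs9332739", "6", 31_903_000, "C2", "complement", "missense", 0.05, 2.2, "G", "C"),
    PlantedSnp("rs4151667", "6", 31_913_000, "CFB", "complement", "missense", 0.055, 2.1, "T", "A"),
    PlantedSnp("rs641153", "6", 31_914_000, "CFB", "complement", "missense", 0.12, 0.625, "G", "A"),
    PlantedSnp("rs800292", "1", 196_642_000, "CFH", "complement", "missense", 0.23, 1.8, "G", "A"),
    PlantedSnp("rs1061170", "1", 196_659_000, "CFH", "complement", "missense", 0.35, 0.59, "T", "C"),
    PlantedSnp("rs10801555", "1", 196_655_000, "CFH", "complement", "intronic", 0.34, 0.62, "G", "A"),
    PlantedSnp("rs6108", "14", 94_770_000, "SERPINA5", "metabolic", "utr3", 0.30, 1.5, "G", "A"),
    PlantedSnp("rs3020729", "2", 86_863_000, "CD8A", "cell_surface", "utr3", 0.40, 0.67, "T", "C"),
    PlantedSnp("rs1801058", "4", 3_006_000, "GRK4", "apoptosis_signaling", "missense", 0.25, 0.71, "C", "T"),
    PlantedSnp("rs9550987", "13", 24_144_000, "TNFRSF19", "apoptosis_signaling", "missense", 0.20, 1.6, "C", "T"),
    PlantedSnp("rs2277680", "17", 4_634_000, "CXCL16", "cytokine_chemokine", "missense", 0.30, 0.71, "G", "A"),
    PlantedSnp("rs17611", "9", 123_775_000, "C5", "complement", "missense", 0.45, 1.0, "C", "T"),
    PlantedSnp("rs17759529", "2", 162_848_000, "DPP4", "cell_surface", "intronic", 0.30, 1.0, "A", "G"),
]

# Additive per-minor-allele effects on log2 protein levels.
_PQTL_EFFECTS = [
    ("rs9332739", "Bb", -0.36),
    ("rs9332739", "FactorB", -0.23),
    ("rs641153", "FactorB", 0.24),
    ("rs641153", "FactorD", -0.11),
    ("rs800292", "Bb", -0.19),
    ("rs1061170", "Bb", 0.11),
    ("rs6108", "C3", 0.07),
    ("rs3020729", "CRP", -0.67),
    ("rs3020729", "C3", -0.10),
    ("rs1801058", "C3", -0.07),
    ("rs9550987", "C3", 0.09),
    ("rs9550987", "FactorH", 0.07),
    ("rs2277680", "FactorH", -0.06),
    ("rs2277680", "FactorB", -0.08),
    ("rs17611", "C5a", -0.30),
    ("rs17759529", "C3", 0.15),
    ("rs17759529", "CRP", 0.30),
]

# High-LD pairs; dosage-scale r values chosen within what the copula can
# realize at these allele frequencies.
_LD_PAIRS = [("rs9332739", "rs4151667", 0.90), ("rs1061170", "rs10801555", 0.90)]

_SURVEY_BASELINES = {"cdc_si": (20.0, 30.0, 12.0)}
_SURVEY_BASELINES.update({s: (8.0, 6.0, 2.5) for s in MFI_SUBSCALES})
_SURVEY_BASELINES.update({s: (52.0, -18.0, 8.0) for s in SF36_SUBSCALES})

_SURVEY_LINKS = {
    ("cdc_si", "C3"): 4.0,
    ("cdc_si", "CRP"): 1.0,
    ("mfi_GF", "C3"): 1.5,
    ("mfi_PF", "C3"): 1.2,
    ("mfi_GF", "FactorD"): 1.0,
    ("sf36_GH", "C3"): -5.0,
    ("sf36_V", "CRP"): -1.0,
    ("sf36_GH", RATIO): 2.0,
}

# Transcription start sites of the genes encoding each analyte (GRCh37-like
# coordinates, used for cis/trans calls on the simulated annotation).
_TSS_ROWS = [
    ("CRP", "CRP", "1", 159_682_000),
    ("C3", "C3", "19", 6_677_000),
    ("C3a", "C3", "19", 6_677_000),
    ("C5a", "C5", "9", 123_714_000),
    ("Bb", "CFB", "6", 31_913_000),
    ("FactorB", "CFB", "6", 31_913_000),
    ("FactorD", "CFD", "19", 859_000),
    ("FactorH", "CFH", "1", 196_621_000),
    ("SC5b9", "C9", "5", 39_284_000),
    (RATIO, "CFB", "6", 31_913_000),
]


def default_study_config(seed: int = 0, n_snps: int = 150) -> SimConfig:
    """Study conditions: 50 cases / 121 controls with the documented
    demographic slopes, group shifts, planted pQTLs and LD pairs.

    The extra C3 shift concentrated in heterozygote carriers of the two
    index markers is sized so that the within-carrier case--control
    separation corresponds to an expected AUC near 0.84 while the marginal
    C3 shift stays at +0.215 log2 units.
    """
    noise = {}
    loadings = {}
    for a in ANALYTES:
        sd = _TOTAL_SD[a]
        loadings[a] = _LOADING_FRACTION[a] * sd
        effs = _COVARIATE_EFFECTS.get(a, {})
        var = sd**2 - loadings[a] ** 2
        var -= (effs.get("bmi", 0.0) * 5.0) ** 2
        var -= (effs.get("age", 0.0) * 10.0) ** 2
        var -= effs.get("sex", 0.0) ** 2 * 0.25 * 0.75
        noise[a] = float(np.sqrt(max(var, (0.25 * sd) ** 2)))
    intercepts = {}
    for a in ANALYTES:
        effs = _COVARIATE_EFFECTS.get(a, {})
        intercepts[a] = (
            _CONTROL_MEANS[a]
            - effs.get("bmi", 0.0) * 27.0
            - effs.get("age", 0.0) * 50.0
            - effs.get("sex", 0.0) * 0.25
        )
    return SimConfig(
        n_case=50,
        n_control=121,
        n_snps=n_snps,
        planted_snps=list(_PLANTED_SNPS),
        ld_pairs=list(_LD_PAIRS),
        pqtl_effects=list(_PQTL_EFFECTS),
        covariate_effects={a: dict(v) for a, v in _COVARIATE_EFFECTS.items()},
        group_shifts=dict(_GROUP_SHIFTS),
        het_extra_shifts={"C3": 0.50},
        het_markers=("rs9332739", "rs800292"),
        latent_loadings=loadings,
        noise_sd=noise,
        intercepts=intercepts,
        survey_baselines=dict(_SURVEY_BASELINES),
        survey_links=dict(_SURVEY_LINKS),
        bmi_case_offset=2.0,
        seed=seed,
    )


def default_tss_table() -> pd.DataFrame:
    return pd.DataFrame(
        _TSS_ROWS, columns=["analyte", "gene", "chrom", "tss"]
    ).set_index("analyte")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lower, size):
    draws = rng.normal(mean, sd, size=size)
    bad = draws <= lower
    while bad.any():
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = draws <= lower
    return draws


def _tilted_freq(p: float, odds_ratio: float) -> float:
    """Minor-allele frequency among cases given an allelic odds ratio."""
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


def _dosage_corr_given_latent(rho: float, p1: float, p2: float) -> float:
    """Correlation of two HWE dosages thresholded from N(0,1) liabilities
    with latent correlation rho (computed via bivariate normal rectangles)."""
    from scipy.stats import multivariate_normal, norm

    def thresholds(p):
        return norm.ppf((1.0 - p) ** 2), norm.ppf(1.0 - p**2)

    t1 = thresholds(p1)
    t2 = thresholds(p2)
    cov = [[1.0, rho], [rho, 1.0]]
    e_prod = 0.0
    for a in t1:
        for b in t2:
            # P(z1 >= a, z2 >= b)
            joint = multivariate_normal.cdf([a, b], mean=[0, 0], cov=cov)
            e_prod += 1.0 - norm.cdf(a) - norm.cdf(b) + joint
    mu1, mu2 = 2 * p1, 2 * p2
    sd1 = np.sqrt(2 * p1 * (1 - p1))
    sd2 = np.sqrt(2 * p2 * (1 - p2))
    return (e_prod - mu1 * mu2) / (sd1 * sd2)


def _latent_rho(p1: float, p2: float, target_r: float) -> float:
    """Latent-normal correlation achieving a target dosage correlation;
    infeasible targets are capped with a warning (best effort)."""
    from scipy.optimize import brentq

    if target_r == 0:
        return 0.0
    lim = 0.999
    reachable = _dosage_corr_given_latent(np.sign(target_r) * lim, p1, p2)
    if abs(reachable) < abs(target_r):
        warnings.warn(
            f"LD r={target_r:.3f} infeasible for MAFs ({p1:.3f}, {p2:.3f}); "
            f"using maximum achievable {reachable:.3f}"
        )
        return float(np.sign(target_r) * lim)
    return float(
        brentq(
            lambda rho: _dosage_corr_given_latent(rho, p1, p2) - target_r,
            0.0 if target_r > 0 else -lim,
            lim if target_r > 0 else 0.0,
            xtol=1e-4,
        )
    )


def _ld_correlation_matrix(rsids, ld_pairs, freqs) -> np.ndarray:
    idx = {r: i for i, r in enumerate(rsids)}
    m = len(rsids)
    corr = np.eye(m)
    for a, b, r in ld_pairs:
        if a not in idx or b not in idx:
            raise DataError(f"LD pair references unknown SNP: ({a}, {b})")
        rho = _latent_rho(freqs[idx[a]], freqs[idx[b]], r)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        warnings.warn("LD correlation matrix not PSD; projecting to nearest PSD")
        w, v = np.linalg.eigh(corr)
        corr = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        chol = np.linalg.cholesky(corr)
    return chol


def _dosages_from_latent(z: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Threshold standard-normal liabilities into HWE genotype dosages."""
    p = freqs
    t_lower = stats.norm.ppf((1.0 - p) ** 2)
    t_upper = stats.norm.ppf(1.0 - p**2)
    return (z >= t_lower).astype(float) + (z >= t_upper).astype(float)


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimulatedCohort:
    """Generate one cohort; identical config + seed gives identical output."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_case, n_control = config.n_case, config.n_control
    n = n_case + n_control

    ids = [f"S{i + 1:04d}" for i in range(n)]
    group = np.array(["case"] * n_case + ["control"] * n_control)
    is_case = group == "case"

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = _truncated_normal(rng, config.age_mean, config.age_sd, 18.0, n)
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 15.0, n)
    bmi = bmi + config.bmi_case_offset * is_case

    cohort = Cohort(
        pd.DataFrame(
            {"group": group, "age": age, "sex": sex, "bmi": bmi},
            index=pd.Index(ids, name="id"),
        )
    )

    # --- SNP table -------------------------------------------------------
    planted = list(config.planted_snps)
    n_background = max(config.n_snps - len(planted), 0)
    lo, hi = config.maf_range
    group_weights = np.array([20, 69, 57, 82, 50, 70, 11], dtype=float)
    group_weights /= group_weights.sum()
    background = []
    for i in range(n_background):
        gene = f"SYNG{i // 2 + 1:04d}"
        nts = rng.choice(len(_NUCLEOTIDES), size=2, replace=False)
        background.append(
            PlantedSnp(
                rsid=f"rs9{i + 1:06d}",
                chrom=str(int(rng.integers(1, 23))),
                pos=int(rng.integers(1, 150_000_000)),
                gene=gene,
                functional_group=str(
                    rng.choice(FUNCTIONAL_GROUPS, p=group_weights)
                ),
                consequence="intronic",
                maf=float(rng.uniform(lo, hi)),
                risk_or=1.0,
                major_allele=_NUCLEOTIDES[nts[0]],
                minor_allele=_NUCLEOTIDES[nts[1]],
            )
        )
    snps = planted + background
    rsids = [s.rsid for s in snps]
    if len(set(rsids)) != len(rsids):
        raise DataError("duplicate rsids in simulated SNP set")
    for rsid, analyte, _ in config.pqtl_effects:
        if rsid not in set(rsids):
            raise DataError(f"pqtl effect references unknown SNP {rsid}")
        if analyte not in ALL_MEASURES:
            raise DataError(f"pqtl effect references unknown analyte {analyte}")

    # --- genotypes: copula with per-group allele frequencies -------------
    freq_control = np.array([s.maf for s in snps])
    freq_case = np.array([_tilted_freq(s.maf, s.risk_or) for s in snps])
    chol = _ld_correlation_matrix(rsids, config.ld_pairs, freq_control)
    z = rng.standard_normal((n, len(rsids))) @ chol.T
    dosages = np.empty((n, len(rsids)))
    dosages[is_case] = _dosages_from_latent(z[is_case], freq_case)
    dosages[~is_case] = _dosages_from_latent(z[~is_case], freq_control)

    dosage_df = pd.DataFrame(dosages, index=cohort.ids, columns=rsids)

    # --- heterozygote carriership for the index markers ------------------
    if config.het_markers:
        a, b = config.het_markers
        het = (dosage_df[a] == 1) | (dosage_df[b] == 1)
    else:
        het = pd.Series(False, index=cohort.ids)
    het_frac_case = float(het[is_case].mean()) if n_case else 0.0
    het_frac_control = float(het[~is_case].mean()) if n_control else 0.0

    # --- log2 protein levels ---------------------------------------------
    male = (sex == "male").astype(float)
    latent = rng.standard_normal(n)
    log2_levels = {}
    for a in ANALYTES:
        effs = config.covariate_effects.get(a, {})
        extra = config.het_extra_shifts.get(a, 0.0)
        marginal = config.group_shifts.get(a, 0.0)
        base = marginal - het_frac_case * extra
        y = np.full(n, config.intercepts.get(a, 0.0))
        y += effs.get("bmi", 0.0) * bmi
        y += effs.get("age", 0.0) * age
        y += effs.get("sex", 0.0) * male
        y += base * is_case
        y += extra * (is_case & het.to_numpy())
        y += config.latent_loadings.get(a, 0.0) * latent
        y += rng.normal(0.0, config.noise_sd.get(a, 1.0), size=n)
        log2_levels[a] = y
    for rsid, analyte, beta in config.pqtl_effects:
        if analyte == RATIO:
            continue  # the ratio is derived, not generated
        log2_levels[analyte] = log2_levels[analyte] + beta * dosages[:, rsids.index(rsid)]
    raw = pd.DataFrame(
        {a: np.power(2.0, log2_levels[a]) for a in ANALYTES}, index=cohort.ids
    )

    # --- recode sites whose realized minor allele differs from configured -
    # Keeps dosages counting the in-sample minor allele (ties break to the
    # lexicographically smaller nucleotide); planted betas for recoded sites
    # change sign in the ground truth accordingly.
    alleles = {s.rsid: (s.major_allele, s.minor_allele) for s in snps}
    flipped: set = set()
    for s in snps:
        freq = observed_maf(dosage_df[s.rsid])
        major, minor = alleles[s.rsid]
        if freq > 0.5 or (freq == 0.5 and str(minor) > str(major)):
            dosage_df[s.rsid] = 2.0 - dosage_df[s.rsid]
            alleles[s.rsid] = (minor, major)
            flipped.add(s.rsid)
    effects = [
        (r, a, -b if r in flipped else b) for r, a, b in config.pqtl_effects
    ]

    snp_ann = pd.DataFrame(
        [
            {
                "rsid": s.rsid,
                "chrom": s.chrom,
                "pos": s.pos,
                "gene": s.gene,
                "functional_group": s.functional_group,
                "consequence": s.consequence,
                "major_allele": alleles[s.rsid][0],
                "minor_allele": alleles[s.rsid][1],
                "maf": observed_maf(dosage_df[s.rsid]),
            }
            for s in snps
        ]
    ).set_index("rsid")
    genotypes = GenotypeMatrix(dosage_df, snp_ann)

    # --- survey scores ----------------------------------------------------
    log2_df = pd.DataFrame(log2_levels, index=cohort.ids)
    log2_df[RATIO] = log2_df["Bb"] - log2_df["C3"]
    centered = log2_df - log2_df.mean()
    surveys = {}
    for score in SURVEY_SCORES:
        base_mean, case_off, sd = config.survey_baselines.get(score, (0.0, 0.0, 1.0))
        y = np.full(n, base_mean) + case_off * is_case
        for (sc, analyte), slope in config.survey_links.items():
            if sc == score:
                y = y + slope * centered[analyte].to_numpy()
        y = y + rng.normal(0.0, sd, size=n)
        if score.startswith("mfi_"):
            y = np.clip(y, 4.0, 20.0)
        elif score == "cdc_si":
            y = np.clip(y, 0.0, None)
        surveys[score] = y
    survey_df = pd.DataFrame(surveys, index=cohort.ids)

    # --- disease-association table ---------------------------------------
    rows = []
    for s in snps:
        if s.risk_or == 1.0:
            continue
        # OR is configured per copy of the configured minor allele; express
        # the row with respect to the risk nucleotide and label it against
        # the final (in-sample) minor/major assignment.
        if s.risk_or >= 1.0:
            risk_nt, odds = s.minor_allele, s.risk_or
        else:
            risk_nt, odds = s.major_allele, 1.0 / s.risk_or
        label = "minor" if risk_nt == alleles[s.rsid][1] else "major"
        rows.append((s.rsid, label, risk_nt, odds))
    disease = pd.DataFrame(rows, columns=["rsid", "risk_allele", "risk_nt", "odds_ratio"])

    flip_mask = np.array([r in flipped for r in rsids])
    snp_truth = pd.DataFrame(
        {
            "configured_maf": np.where(flip_mask, 1.0 - freq_control, freq_control),
            "case_freq": np.where(flip_mask, 1.0 - freq_case, freq_case),
            "realized_maf": [observed_maf(dosage_df[r]) for r in rsids],
            "risk_or": [s.risk_or for s in snps],
        },
        index=pd.Index(rsids, name="rsid"),
    )
    truth = GroundTruth(
        pqtl_effects=pd.DataFrame(effects, columns=["rsid", "analyte", "beta"]),
        group_shifts=dict(config.group_shifts),
        het_extra_shifts=dict(config.het_extra_shifts),
        het_markers=tuple(config.het_markers),
        covariate_effects={a: dict(v) for a, v in config.covariate_effects.items()},
        snp_truth=snp_truth,
        het_fraction_case=het_frac_case,
        het_fraction_control=het_frac_control,
    )
    return SimulatedCohort(
        cohort=cohort,
        genotypes=genotypes,
        raw_proteins=raw,
        surveys=survey_df,
        disease_table=disease,
        tss_table=default_tss_table(),
        ground_truth=truth,
    )


def write_simulated(sim: SimulatedCohort, outdir) -> dict:
    """Write the pipeline's five input files plus ground truth to a directory."""
    from pathlib import Path

    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "proteins": outdir / "proteins_raw.csv",
        "surveys": outdir / "surveys.csv",
        "genotypes": outdir / "genotypes.tsv",
        "annotation": outdir / "snp_annotation.tsv",
        "disease": outdir / "disease_associations.tsv",
        "tss": outdir / "analyte_tss.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    cio.write_subjects(sim.cohort, paths["subjects"])
    raw = sim.raw_proteins.copy()
    raw.index.name = "id"
    raw.to_csv(paths["proteins"], float_format="%.17g")
    sv = sim.surveys.copy()
    sv.index.name = "id"
    sv.to_csv(paths["surveys"], float_format="%.17g")
    cio.write_genotypes_tsv(sim.genotypes, paths["genotypes"])
    cio.write_annotation_tsv(sim.genotypes, paths["annotation"])
    sim.disease_table.to_csv(paths["disease"], sep="\t", index=False, float_format="%.17g")
    sim.tss_table.reset_index().to_csv(paths["tss"], sep="\t", index=False)
    sim.ground_truth.to_frame().to_csv(
        paths["ground_truth"], sep="\t", index=False, float_format="%.17g"
    )
    return {k: str(v) for k, v in paths.items()}
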