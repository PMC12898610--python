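"""Core domain containers shared by every analysis stage.

The pipeline works on four aligned tables: a subject/cohort table, a
genotype dosage matrix with per-SNP annotation, a log2 protein panel and a
survey-score table.  Thin dataclass wrappers around pandas DataFrames keep
the alignment invariants in one place while leaving the underlying frames
directly usable with statsmodels/scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The nine measured plasma analytes, in panel order.
ANALYTES = (
    "CRP",
    "C3",
    "C3a",
    "C5a",
    "Bb",
    "FactorB",
    "FactorD",
    "FactorH",
    "SC5b9",
)

#: Derived index of alternative-pathway activity: log2 Bb - log2 C3.
RATIO = "BbC3ratio"

#: All analytes carried through the analyses (measured + derived ratio).
ALL_MEASURES = ANALYTES + (RATIO,)

#: Native concentration unit per analyte (log2 is taken of these).
DEFAULT_UNITS = {
    "CRP": "mg/L",
    "C3": "mg/mL",
    "C3a": "ng/mL",
    "C5a": "ng/mL",
    "Bb": "ug/mL",
    "FactorB": "ug/mL",
    "FactorD": "ug/mL",
    "FactorH": "ug/mL",
    "SC5b9": "ng/mL",
    RATIO: "log2 ratio",
}

#: The seven curated functional groups used to annotate pQTL hits.
FUNCTIONAL_GROUPS = (
    "complement",
    "cytokine_chemokine",
    "transcription_immunomodulator",
    "cell_surface",
    "metabolic",
    "apoptosis_signaling",
    "structure_adhesion",
)

COVARIATES = ("age", "sex", "bmi")

#: MFI-20 subscales and SF-36 subscales carried in the survey table.
MFI_SUBSCALES = ("mfi_GF", "mfi_PF", "mfi_RA", "mfi_RM", "mfi_MF")
SF36_SUBSCALES = (
    "sf36_PF",
    "sf36_RP",
    "sf36_BP",
    "sf36_GH",
    "sf36_V",
    "sf36_SF",
    "sf36_RE",
    "sf36_MH",
)
SURVEY_SCORES = ("cdc_si",) + MFI_SUBSCALES + SF36_SUBSCALES

SUBGROUP_LABELS = ("CFShet", "CFSrem", "NFhet", "NFrem")


class DataError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass
class Cohort:
    """Subject table: index = subject id; columns group, age, sex, bmi.

    ``group`` takes values ``case``/``control``; ``sex`` takes
    ``male``/``female``.  Ages and BMIs must be positive.
    """

    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.subjects
        required = {"group", "age", "sex", "bmi"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"cohort table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate subject ids: {dups}")
        bad_group = set(df["group"]) - {"case", "control"}
        if bad_group:
            raise DataError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(df["sex"]) - {"male", "female"}
        if bad_sex:
            raise DataError(f"unknown sex labels: {sorted(bad_sex)}")
        if (df["age"] <= 0).any():
            raise DataError("ages must be > 0")
        if (df["bmi"] <= 0).any():
            raise DataError("BMIs must be > 0")

    @property
    def ids(self) -> pd.Index:
        return self.subjects.index

    @property
    def is_case(self) -> pd.Series:
        return self.subjects["group"].eq("case")

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return len(self.subjects) - self.n_case

    def covariate_frame(self) -> pd.DataFrame:
        """Numeric covariates for model design: age, bmi, sex (male=1)."""
        df = self.subjects
        return pd.DataFrame(
            {
                "age": df["age"].astype(float),
                "bmi": df["bmi"].astype(float),
                "sex": df["sex"].eq("male").astype(float),
            },
            index=df.index,
        )


@dataclass
class ProteinPanel:
    """Per-subject log2 analyte levels (including the derived Bb/C3 ratio)."""

    values: pd.DataFrame
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self) -> None:
        cols = set(self.values.columns)
        missing = set(ALL_MEASURES) - cols
        if missing:
            raise DataError(f"protein panel missing analytes: {sorted(missing)}")
        vals = self.values[list(ALL_MEASURES)].to_numpy(dtype=float)
        if not np.isfinite(vals[~np.isnan(vals)]).all():
            raise DataError("protein panel contains non-finite values")
        bb_c3 = self.values["Bb"] - self.values["C3"]
        ratio = self.values[RATIO]
        ok = np.isclose(bb_c3, ratio, atol=1e-9) | (bb_c3.isna() & ratio.isna())
        if not ok.all():
            raise DataError("BbC3ratio is not log2(Bb) - log2(C3)")

    @property
    def ids(self) -> pd.Index:
        return self.values.index


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (subjects x SNPs) plus per-SNP annotation.

    Dosages count copies of the in-sample minor allele and live in
    {0, 1, 2, NaN}.  ``snps`` is indexed by rsid with columns chrom, pos,
    gene, functional_group, consequence, major_allele, minor_allele, maf.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snps.index):
            raise DataError("dosage columns do not match SNP annotation order")
        if self.snps.index.has_duplicates:
            raise DataError("duplicate rsids in SNP annotation")
        arr = self.dosages.to_numpy(dtype=float)
        obs = arr[~np.isnan(arr)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise DataError("dosages must be 0, 1, 2 or missing")
        if "maf" in self.snps.columns:
            maf = self.snps["maf"].to_numpy(dtype=float)
            if np.nanmax(maf, initial=0.0) > 0.5 + 1e-12:
                raise DataError("minor allele frequency exceeds 0.5")

    @property
    def rsids(self) -> pd.Index:
        return self.snps.index

    def dosage(self, rsid: str) -> pd.Series:
        if rsid not in self.dosages.columns:
            raise KeyError(f"unknown rsid: {rsid}")
        return self.dosages[rsid]


def observed_maf(dosages: pd.Series | np.ndarray) -> float:
    """Frequency of the counted allele among non-missing calls."""
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    return float(arr.sum() / (2.0 * arr.size))


def validate_surveys(surveys: pd.DataFrame) -> pd.DataFrame:
    """Check survey-score ranges (MFI subscales bounded in [4, 20])."""
    missing = set(SURVEY_SCORES) - set(surveys.columns)
    if missing:
        raise DataError(f"survey table missing scores: {sorted(missing)}")
    for col in MFI_SUBSCALES:
        vals = surveys[col].dropna()
        if ((vals < 4) | (vals > 20)).any():
            raise DataError(f"{col} outside the [4, 20] MFI subscale range")
    return surveys
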