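"""Readers, writers and the log2 preprocessing step.

File dialects (all plain text):

* genotypes: VCF v4.x (biallelic, GT field) or TSV with subjects as rows,
  rsIDs as columns and additive dosages 0/1/2/NA;
* SNP annotation: TSV with rsid, chrom, pos, gene, functional_group,
  consequence and (for the TSV dialect) the two allele nucleotides;
* subjects / raw proteins / surveys: CSV keyed by subject id;
* result tables: TSV with fixed, kind-specific headers that round-trip
  bit-exactly for strings/ints and to 1e-12 for floats.

Minor alleles are always re-determined in this sample: for every site the
less frequent allele among non-missing calls becomes the counted allele and
dosages are recoded accordingly (ties at 0.5 break to the lexicographically
smaller nucleotide).
"""

from __future__ import annotations

import logging

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ALL_MEASURES,
    ANALYTES,
    DEFAULT_UNITS,
    FUNCTIONAL_GROUPS,
    RATIO,
    Cohort,
    DataError,
    GenotypeMatrix,
    ProteinPanel,
    observed_maf,
    validate_surveys,
)

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("rsid", "chrom", "pos", "gene", "functional_group", "consequence")


class ParseError(DataError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# genotype input
# ---------------------------------------------------------------------------

def _read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ParseError(f"annotation {path} missing columns: {sorted(missing)}")
    if ann["rsid"].duplicated().any():
        dups = ann.loc[ann["rsid"].duplicated(), "rsid"].tolist()
        raise ParseError(f"annotation has duplicate rsids: {dups}")
    bad = set(ann["functional_group"].dropna()) - set(FUNCTIONAL_GROUPS)
    if bad:
        raise ParseError(f"unknown functional groups: {sorted(bad)}")
    return ann.set_index("rsid")


def _parse_vcf_text(path: Path):
    """Minimal parser for plain uncompressed VCF with GT calls.

    Returns (sample_ids, list of (rsid, chrom, pos, ref, alt, alt_dosages)).
    Multi-allelic records are skipped with a warning; malformed lines raise
    ParseError with the line number.
    """
    samples = None
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ParseError(f"{path}:{lineno}: VCF has no sample columns")
                samples = fields[9:]
                continue
            if samples is None:
                raise ParseError(f"{path}:{lineno}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ParseError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, got {len(fields)}"
                )
            chrom, pos, rsid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                log.warning("skipping multi-allelic site %s at %s:%s", rsid, chrom, pos)
                continue
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {pos!r}") from exc
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: record lacks GT field") from exc
            dosages = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dosages.append(np.nan)
                    continue
                try:
                    dosages.append(float(sum(int(a) for a in alleles)))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad genotype {gt!r}") from exc
            sites.append((rsid, chrom, pos_i, ref, alt, np.array(dosages)))
    if samples is None:
        raise ParseError(f"{path}: no #CHROM header found")
    return samples, sites


def _parse_vcf_cyvcf2(path):
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    sites = []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning(
                "skipping multi-allelic site %s at %s:%s", var.ID, var.CHROM, var.POS
            )
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dosages = np.where(gts == 3, 2.0, gts)
        dosages[gts == 2] = np.nan
        sites.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                      var.REF, var.ALT[0], dosages))
    return samples, sites


def read_genotypes(path, format: str, annotation_path, strict: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix and recode every site to minor-allele dosages.

    The minor allele is the less frequent allele *in this sample* (ties at
    0.5 break to the lexicographically smaller nucleotide).  ``strict``
    requires the annotation to cover every variant.
    """
    ann = _read_annotation(annotation_path)
    if format == "vcf":
        path = Path(path)
        if path.suffix == ".gz":  # bgzipped VCFs need htslib
            samples, sites = _parse_vcf_cyvcf2(path)
        else:
            samples, sites = _parse_vcf_text(path)
        records = {}
        allele_info = {}
        for rsid, chrom, pos, ref, alt, dosages in sites:
            records[rsid] = dosages
            allele_info[rsid] = (chrom, pos, ref, alt)
        dosage_df = pd.DataFrame(records, index=pd.Index(samples, name="id"))
        alleles = {r: (allele_info[r][2], allele_info[r][3]) for r in records}
        coords = {r: (allele_info[r][0], allele_info[r][1]) for r in records}
    elif format == "tsv":
        dosage_df = pd.read_csv(path, sep="\t", index_col=0)
        dosage_df.index.name = "id"
        bad = dosage_df.stack().pipe(lambda s: s[~s.isin([0, 1, 2])])
        if len(bad):
            subj, rsid = bad.index[0]
            raise ParseError(f"{path}: invalid dosage {bad.iloc[0]!r} for {subj}/{rsid}")
        # TSV dosages nominally count the annotated minor allele.
        alleles = {}
        coords = {}
        for rsid in dosage_df.columns:
            if rsid in ann.index and {"major_allele", "minor_allele"} <= set(ann.columns):
                alleles[rsid] = (ann.at[rsid, "major_allele"], ann.at[rsid, "minor_allele"])
            else:
                alleles[rsid] = ("A", "B")  # allele identities unknown for bare TSVs
            if rsid in ann.index:
                coords[rsid] = (ann.at[rsid, "chrom"], int(ann.at[rsid, "pos"]))
    else:
        raise ValueError(f"unknown genotype format: {format!r}")

    rows = []
    recoded = {}
    for rsid in dosage_df.columns:
        if rsid not in ann.index:
            if strict:
                raise DataError(f"variant {rsid} absent from annotation (strict mode)")
            log.warning("variant %s has no annotation; keeping with empty fields", rsid)
        other, counted = alleles.get(rsid, ("A", "B"))  # counted allele = dosage allele
        dos = dosage_df[rsid].astype(float)
        freq = observed_maf(dos)
        flip = freq > 0.5 or (freq == 0.5 and str(counted) > str(other))
        if flip:
            dos = 2.0 - dos
            counted, other = other, counted
            freq = 1.0 - freq
        recoded[rsid] = dos
        meta = ann.loc[rsid] if rsid in ann.index else None
        chrom, pos = coords.get(
            rsid,
            (meta["chrom"], int(meta["pos"])) if meta is not None else ("", -1),
        )
        rows.append(
            {
                "rsid": rsid,
                "chrom": str(chrom),
                "pos": int(pos),
                "gene": meta["gene"] if meta is not None else "",
                "functional_group": meta["functional_group"] if meta is not None else "",
                "consequence": meta["consequence"] if meta is not None else "",
                "major_allele": str(other),
                "minor_allele": str(counted),
                "maf": freq,
            }
        )
    snps = pd.DataFrame(rows).set_index("rsid")
    return GenotypeMatrix(pd.DataFrame(recoded, index=dosage_df.index), snps)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.dosages.copy()
    df.index.name = "id"
    out = df.astype("Int64")
    out.to_csv(path, sep="\t", na_rep="NA")


def write_annotation_tsv(genotypes: GenotypeMatrix, path) -> None:
    genotypes.snps.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# subject / protein / survey / disease tables
# ---------------------------------------------------------------------------

def read_subjects(path) -> Cohort:
    df = pd.read_csv(path, index_col="id")
    return Cohort(df)


def write_subjects(cohort: Cohort, path) -> None:
    out = cohort.subjects.copy()
    out.index.name = "id"
    out.to_csv(path)


def read_raw_proteins(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="id")
    missing = set(ANALYTES) - set(df.columns)
    if missing:
        raise DataError(f"protein table missing analytes: {sorted(missing)}")
    return df[list(ANALYTES)]


def read_surveys(path) -> pd.DataFrame:
    return validate_surveys(pd.read_csv(path, index_col="id"))


def read_disease_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "risk_allele", "risk_nt", "odds_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"disease table missing columns: {sorted(missing)}")
    if df["rsid"].duplicated().any():
        raise DataError("disease table has duplicate rsid rows")
    if (df["odds_ratio"] <= 0).any():
        raise DataError("odds ratios must be > 0")
    return df


def read_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"analyte", "gene", "chrom", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"TSS table missing columns: {sorted(missing)}")
    return df.set_index("analyte")


# ---------------------------------------------------------------------------
# log2 preprocessing
# ---------------------------------------------------------------------------

def log2_transform(raw: pd.DataFrame, floor=0.01, units=None) -> ProteinPanel:
    """log2-transform raw concentrations with a detection floor.

    ``floor`` may be a scalar or a per-analyte mapping; values below the
    floor (including exact zeros) are clamped to it before the log so the
    transform is always finite.  Negative concentrations are rejected with
    the subject and analyte named.  The Bb/C3 ratio column is derived as
    log2(Bb) - log2(C3).
    """
    raw = raw[list(ANALYTES)]
    if isinstance(floor, dict):
        floors = {a: float(floor.get(a, 0.01)) for a in ANALYTES}
    else:
        floors = {a: float(floor) for a in ANALYTES}
    if any(f <= 0 for f in floors.values()):
        raise ValueError("detection floors must be positive")
    neg = raw < 0
    if neg.any().any():
        stacked = raw.where(neg).stack()
        subj, analyte = stacked.index[0]
        raise DataError(
            f"negative concentration for subject {subj!r}, analyte {analyte!r}"
        )
    vals = {}
    for a in ANALYTES:
        vals[a] = np.log2(raw[a].clip(lower=floors[a]).astype(float))
    df = pd.DataFrame(vals, index=raw.index)
    df[RATIO] = df["Bb"] - df["C3"]
    return ProteinPanel(df, units=dict(units) if units else dict(DEFAULT_UNITS))


def write_panel(panel: ProteinPanel, path) -> None:
    out = panel.values.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# tidy result tables
# ---------------------------------------------------------------------------

#: Column schema per result kind: name -> (columns, float columns).
RESULT_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "pqtl": (
        ("rsid", "analyte", "beta", "se", "f_statistic", "p_fvr",
         "p_bonferroni", "n_used", "cis_trans"),
        ("beta", "se", "f_statistic", "p_fvr", "p_bonferroni"),
    ),
    "covariate_screen": (
        ("analyte", "covariate", "coefficient", "std_error", "adjusted_r2",
         "f_statistic", "p_value", "selected"),
        ("coefficient", "std_error", "adjusted_r2", "f_statistic", "p_value"),
    ),
    "roc": (
        ("stratum", "analyte", "covariates", "n_case", "n_control", "auc",
         "se", "ci_lower", "ci_upper", "p_vs_half", "passes_filters"),
        ("auc", "se", "ci_lower", "ci_upper", "p_vs_half"),
    ),
    "enrichment": (
        ("analyte", "functional_group", "level", "observed_count",
         "observed_proportion", "expected_proportion", "enrichment_score"),
        ("observed_proportion", "expected_proportion", "enrichment_score"),
    ),
    "association": (
        ("analyte", "model", "term", "beta", "se", "p_value", "n_used"),
        ("beta", "se", "p_value"),
    ),
}


def write_results(records: pd.DataFrame, path, kind: str) -> None:
    """Write a tidy TSV with the fixed header for ``kind``.

    Floats are serialised with 17 significant digits so the matching reader
    restores them to within 1e-12; an empty frame yields a header-only file.
    """
    if kind not in RESULT_SCHEMAS:
        raise ValueError(f"unknown result kind: {kind!r}")
    columns, _ = RESULT_SCHEMAS[kind]
    if len(records) == 0:
        records = pd.DataFrame(columns=list(columns))
    missing = set(columns) - set(records.columns)
    if missing:
        raise DataError(f"{kind} records missing columns: {sorted(missing)}")
    records[list(columns)].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path, kind: str) -> pd.DataFrame:
    if kind not in RESULT_SCHEMAS:
        raise ValueError(f"unknown result kind: {kind!r}")
    columns, floats = RESULT_SCHEMAS[kind]
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != tuple(columns):
        raise ParseError(f"{path}: header does not match {kind} schema")
    for col in floats:
        df[col] = df[col].astype(float)
    return df
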