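"""Tabular ingestion, result serialization and the seeded fixture generator.

Feature tables are tab-delimited with an `id` column followed by one column
per feature; genotype columns hold additive minor-allele counts (0/1/2,
blank for missing) and exposure columns hold arbitrary numerics — both
"gene" and "environment" features flow through the same screen and tests.
Phenotype tables are tab-delimited `id`, `disease` (0/1) and/or `trait`
(continuous).  VCF input (read-only, biallelic sites) is converted to
additive minor-allele dosages; internal feature indices are 0-based while
VCF positions stay 1-based in the site names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .permfdr import FdrEstimate
from .screening import ScreenRecord
from .simmodel import PopulationModel, sample_case_control, simulate_population
from .testing import TestRecord

__all__ = [
    "FeatureTable",
    "PhenotypeTable",
    "read_feature_table",
    "write_feature_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "screen_records_frame",
    "test_records_frame",
    "fdr_estimates_frame",
    "write_run_manifest",
    "generate_fixtures",
]

logger = logging.getLogger("twostage")

FeatureKind = Literal["genotype", "exposure"]


@dataclass(frozen=True)
class FeatureTable:
    """Individuals x features matrix with ids, names and per-column kinds."""

    ids: tuple[str, ...]
    features: np.ndarray  # float matrix, NaN = missing
    feature_names: tuple[str, ...]
    feature_kinds: tuple[FeatureKind, ...]

    def __post_init__(self) -> None:
        n, p = self.features.shape
        if len(self.ids) != n:
            raise ValueError("ids must match the number of rows")
        if len(self.feature_names) != p or len(self.feature_kinds) != p:
            raise ValueError("names/kinds must match the number of columns")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        for j, kind in enumerate(self.feature_kinds):
            if kind == "genotype":
                col = self.features[:, j]
                vals = col[~np.isnan(col)]
                if not np.isin(vals, [0.0, 1.0, 2.0]).all():
                    raise ValueError(
                        f"genotype column {self.feature_names[j]!r} has values "
                        "outside {0, 1, 2}"
                    )

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-individual disease status (0/1) and/or continuous trait."""

    ids: tuple[str, ...]
    disease: np.ndarray | None = None
    trait: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.disease is None and self.trait is None:
            raise ValueError("at least one of disease/trait must be present")
        for name, vec in (("disease", self.disease), ("trait", self.trait)):
            if vec is not None and len(vec) != len(self.ids):
                raise ValueError(f"{name} length does not match ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")


def _infer_kind(col: np.ndarray) -> FeatureKind:
    vals = col[~np.isnan(col)]
    return "genotype" if vals.size and np.isin(vals, [0.0, 1.0, 2.0]).all() else "exposure"


def read_feature_table(
    path: str | Path, format: Literal["delimited", "vcf"] = "delimited"
) -> FeatureTable:
    """Read a feature table from delimited text or VCF.

    Delimited: tab-separated, header `id<TAB>name1<TAB>...`; malformed
    numeric entries raise with the offending line number.  VCF: biallelic
    sites only (multiallelic sites skipped with a logged count); genotypes
    become additive dosages oriented to the sample minor allele.
    """
    if format == "vcf":
        return _read_vcf(path)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    ids = tuple(df["id"].astype(str))
    names = tuple(df.columns[1:])
    mat = np.empty((len(ids), len(names)))
    for j, name in enumerate(names):
        col = df[name]
        try:
            mat[:, j] = pd.to_numeric(col).to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(col, errors="coerce")
            row = int(np.flatnonzero(bad.isna() & col.notna())[0])
            raise ValueError(
                f"{path}: malformed value {col.iloc[row]!r} in column "
                f"{name!r}, line {row + 2}"
            ) from None
    keep = ~np.all(np.isnan(mat), axis=0)
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        logger.warning("dropping all-missing feature columns: %s", dropped)
        mat = mat[:, keep]
        names = tuple(n for n, k in zip(names, keep) if k)
    kinds = tuple(_infer_kind(mat[:, j]) for j in range(mat.shape[1]))
    return FeatureTable(ids=ids, features=mat, feature_names=names, feature_kinds=kinds)


def _read_vcf(path: str | Path) -> FeatureTable:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    ids = tuple(vcf.samples)
    cols: list[np.ndarray] = []
    names: list[str] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=missing/unknown
        raw = np.asarray(var.gt_types, dtype=float)
        gt = np.where(raw == 2, np.nan, np.where(raw == 3, 2.0, raw))
        alt_freq = np.nanmean(gt) / 2.0 if np.isfinite(gt).any() else np.nan
        if np.isnan(alt_freq):
            logger.warning("dropping all-missing site %s:%s", var.CHROM, var.POS)
            continue
        if alt_freq > 0.5:
            gt = 2.0 - gt  # orient dosage to the sample minor allele
            logger.info("site %s:%s flipped to minor-allele dosage", var.CHROM, var.POS)
        names.append(f"{var.CHROM}:{var.POS}")
        cols.append(gt)
    if n_multi:
        logger.warning("skipped %d multiallelic sites", n_multi)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic sites")
    mat = np.column_stack(cols)
    return FeatureTable(
        ids=ids,
        features=mat,
        feature_names=tuple(names),
        feature_kinds=tuple("genotype" for _ in names),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(table.features, columns=list(table.feature_names))
    # genotypes serialize as bare integers, exposures keep full precision
    for name, kind in zip(table.feature_names, table.feature_kinds):
        if kind == "genotype":
            df[name] = df[name].astype("Int64")
    df.insert(0, "id", list(table.ids))
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    disease = trait = None
    if "disease" in df.columns:
        vals = df["disease"].to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0])
        if not ok.all():
            raise ValueError(f"{path}: disease must be coded 0/1")
        disease = vals
    if "trait" in df.columns:
        trait = df["trait"].to_numpy(dtype=float)
    return PhenotypeTable(ids=tuple(df["id"].astype(str)), disease=disease, trait=trait)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"id": list(table.ids)})
    if table.disease is not None:
        df["disease"] = pd.array(table.disease, dtype="float").astype("Int64")
    if table.trait is not None:
        df["trait"] = table.trait
    df.to_csv(path, sep="\t", index=False)


def align_tables(
    features: FeatureTable, phenotypes: PhenotypeTable
) -> tuple[FeatureTable, PhenotypeTable]:
    """Inner-join the two tables on id; drop rows with missing phenotype."""
    pheno_idx = {i: k for k, i in enumerate(phenotypes.ids)}
    keep_rows = [k for k, i in enumerate(features.ids) if i in pheno_idx]
    if len(keep_rows) < len(features.ids):
        logger.warning(
            "dropping %d individuals without phenotype rows",
            len(features.ids) - len(keep_rows),
        )
    ids = tuple(features.ids[k] for k in keep_rows)
    order = [pheno_idx[i] for i in ids]
    disease = phenotypes.disease[order] if phenotypes.disease is not None else None
    trait = phenotypes.trait[order] if phenotypes.trait is not None else None
    missing = np.zeros(len(ids), dtype=bool)
    if disease is not None:
        missing |= np.isnan(disease)
    if trait is not None:
        missing |= np.isnan(trait)
    if missing.any():
        logger.warning("dropping %d individuals with missing phenotype", missing.sum())
    rows = np.asarray(keep_rows)[~missing]
    ids = tuple(i for i, m in zip(ids, missing) if not m)
    feats = FeatureTable(
        ids=ids,
        features=features.features[rows],
        feature_names=features.feature_names,
        feature_kinds=features.feature_kinds,
    )
    pheno = PhenotypeTable(
        ids=ids,
        disease=disease[~missing].astype(np.int8) if disease is not None else None,
        trait=trait[~missing] if trait is not None else None,
    )
    return feats, pheno


# ---------------------------------------------------------------------------
# result serialization (stable column orders; golden-file tested)

def screen_records_frame(
    records: Sequence[ScreenRecord], feature_names: Sequence[str] | None = None
) -> pd.DataFrame:
    name = (lambda j: feature_names[j]) if feature_names else (lambda j: f"f{j}")
    return pd.DataFrame(
        [
            dict(
                j=rec.pair[0],
                k=rec.pair[1],
                feature_j=name(rec.pair[0]),
                feature_k=name(rec.pair[1]),
                scheme=rec.scheme,
                n=rec.n,
                r=rec.r,
                t=rec.t_stat,
                df=rec.df,
                p=rec.p_value,
                screenable=rec.screenable,
            )
            for rec in records
        ],
        columns=["j", "k", "feature_j", "feature_k", "scheme", "n", "r", "t",
                 "df", "p", "screenable"],
    )


def test_records_frame(
    records: Sequence[TestRecord], feature_names: Sequence[str] | None = None
) -> pd.DataFrame:
    name = (lambda j: feature_names[j]) if feature_names else (lambda j: f"f{j}")
    return pd.DataFrame(
        [
            dict(
                j=rec.pair[0],
                k=rec.pair[1],
                feature_j=name(rec.pair[0]),
                feature_k=name(rec.pair[1]),
                test_kind=rec.test_kind,
                intercept=rec.coefficients[0],
                beta1=rec.coefficients[1],
                beta2=rec.coefficients[2],
                beta3=rec.coefficients[3],
                statistic=rec.statistic,
                df=rec.df,
                p=rec.p_value,
                adjusted_p=rec.adjusted_p,
            )
            for rec in records
        ],
        columns=["j", "k", "feature_j", "feature_k", "test_kind", "intercept",
                 "beta1", "beta2", "beta3", "statistic", "df", "p", "adjusted_p"],
    )


def fdr_estimates_frame(estimates: Sequence[FdrEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                threshold=e.threshold,
                n_observed=e.n_observed,
                mean_null=e.mean_null,
                fdr_hat=e.fdr_hat,
                mc_se=e.mc_se,
                n_perm=e.n_perm,
                undefined=e.undefined,
            )
            for e in estimates
        ],
        columns=["threshold", "n_observed", "mean_null", "fdr_hat", "mc_se",
                 "n_perm", "undefined"],
    )


def write_run_manifest(path: str | Path, *, command: str, seed: int | None,
                       config: dict, outputs: Sequence[str]) -> None:
    """Machine-readable record sufficient to reproduce a CLI run exactly."""
    from . import __version__

    manifest = dict(
        command=command,
        seed=seed,
        config=config,
        outputs=list(outputs),
        versions=dict(twostage=__version__, numpy=np.__version__,
                      pandas=pd.__version__),
    )
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# fixtures

def generate_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the small deterministic datasets used across the test suite.

    Four scenarios, each a (features, phenotypes) TSV pair ascertained as
    500 cases + 500 controls from a simulated population:

    - null: no genetic effects at all
    - main_effects: strong equal main effects, no interaction
    - interaction_only: no main effects, strong interaction (the classic
      case-only signal: dependence among cases)
    - headline: the flagship configuration (RR 2.0, exp(b3) = 1.1)
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenarios = {
        "null": PopulationModel(np.log(0.05)),
        "main_effects": PopulationModel(np.log(0.05), beta1=np.log(2), beta2=np.log(2)),
        "interaction_only": PopulationModel(np.log(0.05), beta3=np.log(3)),
        "headline": PopulationModel(
            np.log(0.05), beta1=np.log(2), beta2=np.log(2), beta3=np.log(1.1)
        ),
    }
    paths: dict[str, Path] = {}
    ss = np.random.SeedSequence(seed).generate_state(len(scenarios), dtype=np.uint32)
    for (name, model), sub_seed in zip(scenarios.items(), ss):
        pop = simulate_population(model, 40_000, int(sub_seed))
        sample = sample_case_control(pop, 500, 500, int(sub_seed) + 1)
        ids = tuple(f"ind{i:04d}" for i in range(sample.n))
        feats = FeatureTable(
            ids=ids,
            features=sample.genotypes.astype(float),
            feature_names=("snp1", "snp2"),
            feature_kinds=("genotype", "genotype"),
        )
        pheno = PhenotypeTable(ids=ids, disease=sample.disease.astype(float))
        fpath = outdir / f"{name}.features.tsv"
        ppath = outdir / f"{name}.phenotypes.tsv"
        write_feature_table(feats, fpath)
        write_phenotype_table(pheno, ppath)
        paths[name] = fpath
        paths[f"{name}.phenotypes"] = ppath
    return paths
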