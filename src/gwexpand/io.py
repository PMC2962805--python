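"""Readers and writers for the formats the tool touches.

Genotypes come in as plain TSV (rows = samples, columns = SNPs, entries in
{0,1,2,NA}) or VCF (dosage = ALT-allele count at biallelic SNP records;
anything multi-allelic or non-SNP is skipped with a counted warning).
Cohort membership lives in a manifest TSV (sample id, role).  Summaries go
out in a Table-shaped TSV at 1-decimal percent precision, with a
full-precision sidecar.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import TEST_NAMES, ExperimentSummary
from .ibs_mds import classical_mds, ibs_matrix
from .simulate import (
    MISSING,
    GenotypeMatrix,
    SimulationConfig,
    simulate_replicate,
)

logger = logging.getLogger("gwexpand")

__all__ = [
    "CohortManifest",
    "read_genotypes",
    "write_genotypes",
    "read_manifest",
    "write_manifest",
    "write_summary",
    "read_summary_sidecar",
    "make_fixture",
]


@dataclass
class CohortManifest:
    """Per-sample role assignment: case, control, or an external cohort name."""

    table: pd.DataFrame  # columns: sample_id, role, plus optional covariates

    def __post_init__(self) -> None:
        t = self.table
        if "sample_id" not in t.columns or "role" not in t.columns:
            raise ValueError("manifest needs 'sample_id' and 'role' columns")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id {dup.iloc[0]!r} in manifest")
        if not (t["role"] == "case").any() or not (t["role"] == "control").any():
            raise ValueError("manifest must contain at least one case and one control")

    @property
    def roles(self) -> pd.Series:
        return self.table.set_index("sample_id")["role"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty genotype matrix")
    vals = np.full(df.shape, MISSING, dtype=np.int8)
    arr = df.to_numpy()
    for code in ("0", "1", "2"):
        vals[arr == code] = int(code)
    bad = ~np.isin(arr, ("0", "1", "2", "NA"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: malformed entry {arr[i, j]!r} at data row {i + 1}, "
            f"column {df.columns[j]!r}"
        )
    return GenotypeMatrix(vals, [str(s) for s in df.index],
                          [str(c) for c in df.columns])


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only real-data workflows need it

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        dose = np.full(len(samples), MISSING, dtype=np.int8)
        dose[gt == 0] = 0
        dose[gt == 1] = 1
        dose[gt == 3] = 2
        cols.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_skipped:
        logger.warning("skipped %d multi-allelic/non-SNP VCF records", n_skipped)
    if not cols:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(np.column_stack(cols), samples, ids)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from TSV or VCF (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    arr = G.values.astype(object)
    arr[G.values == MISSING] = "NA"
    pd.DataFrame(arr, index=G.sample_ids, columns=G.snp_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

KNOWN_ROLE_PREFIXES = ("case", "control", "external")


def read_manifest(path: str | Path) -> CohortManifest:
    t = pd.read_csv(path, sep="\t", dtype=str)
    manifest = CohortManifest(t)
    bad = ~t["role"].str.startswith(KNOWN_ROLE_PREFIXES)
    if bad.any():
        raise ValueError(f"unknown role {t['role'][bad].iloc[0]!r} in {path}")
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["fst", "test", "rate_pct", "mean_or", "or_5_95", "n_reps"]


def write_summary(summaries: list[ExperimentSummary], path: str | Path) -> None:
    """Table-shaped TSV (1-decimal percents) plus a full-precision sidecar."""
    path = Path(path)
    rows, raw = [], []
    for s in summaries:
        for t in TEST_NAMES:
            rows.append({
                "fst": s.fst[0] if s.fst else 0.0,
                "test": t,
                "rate_pct": f"{100 * s.rejection_rate[t]:.1f}%",
                "mean_or": f"{s.mean_or[t]:.2f}",
                "or_5_95": f"{s.or_p5[t]:.2f}-{s.or_p95[t]:.2f}",
                "n_reps": s.n_reps,
            })
            raw.append({
                "fst": s.fst[0] if s.fst else 0.0,
                "test": t,
                "rejection_rate": repr(s.rejection_rate[t]),
                "mean_or": repr(s.mean_or[t]),
                "or_p5": repr(s.or_p5[t]),
                "or_p95": repr(s.or_p95[t]),
                "n_reps": s.n_reps,
                "n_degenerate": s.n_degenerate[t],
                "prop_gt3_axes": "" if s.prop_gt3_axes is None else repr(s.prop_gt3_axes),
            })
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)
    pd.DataFrame(raw).to_csv(path.with_suffix(path.suffix + ".full"),
                             sep="\t", index=False)


def read_summary_sidecar(path: str | Path) -> pd.DataFrame:
    """Full-precision summary sidecar back as a DataFrame."""
    path = Path(path)
    df = pd.read_csv(path.with_suffix(path.suffix + ".full"), sep="\t",
                     float_precision="round_trip")
    for c in ("rejection_rate", "mean_or", "or_p5", "or_p95"):
        df[c] = df[c].astype(float)
    return df


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Deterministic miniature on-disk datasets for tests and demos.

    ``two-pop``: 10+10 source samples plus a 20-sample external cohort at
    Fst 0.1, 200 null SNPs — small but structured enough for the first MDS
    axis to separate the cohorts.  ``homogeneous``: same sizes at Fst 0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "two-pop":
        fst = (0.1,)
    elif kind == "homogeneous":
        fst = (0.0,)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    cfg = SimulationConfig(
        n_cases=10, n_controls=10, external_cohort_sizes=(20,),
        n_null_snps=200, fst=fst, seed=int(seed),
    )
    data = simulate_replicate(cfg)
    geno_path = out_dir / f"{kind}.geno.tsv"
    manifest_path = out_dir / f"{kind}.manifest.tsv"
    write_genotypes(data.null_genotypes, geno_path)
    manifest = CohortManifest(pd.DataFrame({
        "sample_id": data.null_genotypes.sample_ids,
        "role": data.cohort_label,
    }))
    write_manifest(manifest, manifest_path)
    return {"genotypes": geno_path, "manifest": manifest_path}
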