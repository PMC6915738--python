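"""File formats and run manifests.

Canonical tabular dialect: tab-separated, header row, UTF-8, '.' decimal;
gzip is transparent (pandas infers compression from the filename).  Matrices
are written with row ids in the first column.  A minimal VCF reader (GT
field only, diploid; dosage = count of non-reference alleles) is provided as
an alternative genotype input.  Every pipeline output directory receives a
single JSON run manifest recording the command, configuration echo, seed,
package version and input/output file digests.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["id", "chromosome", "position"]
ANNOTATION_COLUMNS = [
    "feature_id",
    "level",
    "transcript_cluster_id",
    "chromosome",
    "start",
    "end",
]
ASSOCIATION_COLUMNS = ["snp_id", "feature_id", "beta", "t", "p", "fdr", "detected"]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a samples-by-columns numeric matrix (first column = row ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix_tsv(df: pd.DataFrame, path, float_format=None) -> None:
    # the default (shortest round-trip repr) preserves values exactly
    df.to_csv(path, sep="\t", float_format=float_format)


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in SNP_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP map {path} lacks columns {missing}")
    return df[SNP_MAP_COLUMNS + [c for c in df.columns if c not in SNP_MAP_COLUMNS]]


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} lacks columns {missing}")
    return df


def read_associations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("snp_id", "feature_id", "p") if c not in df.columns]
    if missing:
        raise ValueError(f"association table {path} lacks columns {missing}")
    return df


def write_associations(records: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write an association table plus a JSON sidecar with m/q/seed metadata."""
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if meta is not None:
        sidecar = Path(str(path).removesuffix(".gz")).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def read_vcf_dosage(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal VCF genotype input: GT field only, diploid, unphased use.

    Returns (individuals-by-SNP dosage frame, SNP map).  Dosage is the
    count of non-reference alleles; missing calls become NaN (to be handled
    by :func:`mreqtl.fixtures.maf_complete_filter`).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, positions, columns = [], [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ids.append(vid)
        chroms.append(str(var.CHROM).removeprefix("chr"))
        positions.append(var.POS)
        gts = var.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        columns.append((alleles > 0).sum(axis=1) + np.where(np.isnan(alleles).any(axis=1), np.nan, 0.0))
    geno = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=samples,
        columns=ids,
    )
    geno.index.name = "individual"
    snp_map = pd.DataFrame({"id": ids, "chromosome": chroms, "position": positions})
    return geno, snp_map


def save_matrices_npz(path, **arrays) -> None:
    """Binary container for large matrices (scratch use)."""
    np.savez_compressed(path, **arrays)


def load_matrices_npz(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        return {k: data[k] for k in data.files}


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    command: str,
    config: dict,
    seed: Optional[int],
    inputs: Iterable = (),
    outputs: Iterable = (),
) -> Path:
    """Write the single JSON run manifest of a pipeline output directory."""
    from mreqtl import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
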