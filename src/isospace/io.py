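"""Readers and writers: TSV matrices, annotation tables, result bundles.

All tabular formats are UTF-8 tab-separated files with a header row; matrix
files carry sample ids in the header and probe ids in the first column.
Genomic coordinates in annotation files are 1-based inclusive and converted
to 0-based half-open intervals on BED output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    REQUIRED_ANNOTATION_COLUMNS,
    ValidationError,
    as_probe_matrix,
)


def read_probe_matrix(path) -> pd.DataFrame:
    """Read a probe × sample intensity TSV.

    Rejects empty files, non-numeric cells (named by probe/sample), NaNs and
    negative values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty probe matrix file") from exc
    if df.empty:
        raise ValidationError(f"{path}: probe matrix has no data rows")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric or missing value at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValidationError(
            f"{path}: negative intensity at probe {numeric.index[r]!r}, "
            f"sample {numeric.columns[c]!r}"
        )
    return as_probe_matrix(numeric)


def write_probe_matrix(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t")
    return path


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, probeset_id, gene_id, ...)."""
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "probeset_id": str})
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"{path}: annotation missing columns {missing}")
    return ann


def _bed_lines(structure: pd.DataFrame, annotation: pd.DataFrame) -> list[str]:
    ann = annotation.set_index("probe_id")
    lines = []
    for t in structure.columns:
        for probe in structure.index[structure[t] == 1]:
            row = ann.loc[probe]
            if pd.isna(row.get("chrom")) or pd.isna(row.get("start")):
                continue
            start0 = int(row["start"]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(row["end"])
            strand = row.get("strand", ".")
            lines.append(f"{row['chrom']}\t{start0}\t{end}\t{t}:{probe}\t0\t{strand}")
    return lines


def write_gene_result(result, out_dir) -> Path:
    """Write a GeneResult bundle: G/G̃/T/affinity TSVs plus report.json.

    A BED track of per-transcript probe intervals is emitted only when the
    annotation carries genomic coordinates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.structure.to_csv(out / "G.tsv", sep="\t")
    result.continuous_structure.to_csv(out / "Gtilde.tsv", sep="\t")
    result.concentrations.to_csv(out / "T.tsv", sep="\t")
    result.affinities.to_csv(out / "affinities.tsv", sep="\t")
    report = {
        "gene_id": result.gene_id,
        "n_transcripts": result.n_transcripts,
        "n_probes": int(result.structure.shape[0]),
        "n_samples": int(result.concentrations.shape[1]),
        "diagnostics": _jsonable(result.diagnostics),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    if result.annotation is not None and "chrom" in result.annotation.columns:
        lines = _bed_lines(result.structure, result.annotation)
        if lines:
            (out / "transcripts.bed").write_text("\n".join(lines) + "\n")
    return out


def read_gene_result_structures(result_dir):
    """Read back (G, G̃, T, affinities) written by :func:`write_gene_result`."""
    out = Path(result_dir)
    G = pd.read_csv(out / "G.tsv", sep="\t", index_col=0)
    Gt = pd.read_csv(out / "Gtilde.tsv", sep="\t", index_col=0)
    T = pd.read_csv(out / "T.tsv", sep="\t", index_col=0)
    a = pd.read_csv(out / "affinities.tsv", sep="\t", index_col=0)["affinity"]
    return G, Gt, T, a


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
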