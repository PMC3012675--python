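"""Shared domain containers, input validation and transcript-column matching.

The central objects of the deconvolution model ``Y ≈ diag(A)·G·T`` are plain
numpy arrays / pandas frames:

* ``Y`` — non-negative probe × sample intensity matrix (``pd.DataFrame`` with
  probe ids as index, sample ids as columns, or a 2-d array);
* ``G`` — binary probe × transcript structure ("property") matrix;
* ``A`` — per-probe affinity vector (diagonal of the affinity matrix);
* ``T`` — non-negative transcript × sample concentration matrix.

Because an NMF-based estimate carries no intrinsic transcript order, any
comparison of an estimated structure with a reference must first resolve the
column permutation; :func:`match_transcript_columns` does this by optimal
assignment under per-column L1 distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

REQUIRED_ANNOTATION_COLUMNS = ("probe_id", "probeset_id", "gene_id")
OPTIONAL_ANNOTATION_COLUMNS = ("exon_label", "chrom", "start", "end", "strand")


class ValidationError(ValueError):
    """Raised when a probe matrix / annotation pair is inconsistent."""


@dataclass
class GeneBundle:
    """Validated inputs for a single gene.

    Attributes
    ----------
    intensities : pd.DataFrame
        Probe × sample matrix, rows ordered as in the input.
    annotation : pd.DataFrame
        One row per probe, in the same order as ``intensities``.
    probesets : dict[str, list[str]]
        Probeset id → ordered probe ids; a partition of the probes.
    """

    intensities: pd.DataFrame
    annotation: pd.DataFrame
    probesets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def probeset_indices(self) -> list[np.ndarray]:
        """Row-index arrays of the probeset partition (matrix order)."""
        pos = {p: i for i, p in enumerate(self.intensities.index)}
        return [np.array([pos[p] for p in probes]) for probes in self.probesets.values()]


def as_probe_matrix(Y) -> pd.DataFrame:
    """Coerce input to a validated probe × sample DataFrame.

    Entries must be finite and non-negative, with at least two probes and two
    samples.
    """
    if isinstance(Y, pd.DataFrame):
        df = Y.copy()
    else:
        arr = np.asarray(Y, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("probe matrix must be 2-dimensional")
        df = pd.DataFrame(
            arr,
            index=[f"p{i + 1}" for i in range(arr.shape[0])],
            columns=[f"s{j + 1}" for j in range(arr.shape[1])],
        )
    values = df.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValidationError(
            f"probe matrix must be at least 2x2, got {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("probe matrix contains non-finite entries")
    if np.any(values < 0):
        raise ValidationError("probe matrix contains negative entries")
    if df.index.has_duplicates:
        raise ValidationError("duplicated probe ids in probe matrix")
    return df


def validate_gene_inputs(Y, annotation: pd.DataFrame) -> GeneBundle:
    """Check a probe matrix against its annotation and build the probeset map.

    Raises
    ------
    ValidationError
        If a probe of ``Y`` is missing from the annotation, a probe id is
        duplicated, or a probeset ends up empty.
    """
    df = as_probe_matrix(Y)
    ann = pd.DataFrame(annotation).copy()
    missing_cols = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ValidationError(f"annotation missing required columns: {missing_cols}")
    dup = ann["probe_id"][ann["probe_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"annotation has duplicated probe ids: {sorted(set(dup))}")
    known = set(ann["probe_id"])
    unknown = [p for p in df.index if p not in known]
    if unknown:
        raise ValidationError(f"probes missing from annotation: {unknown}")
    ann = ann.set_index("probe_id", drop=False).loc[df.index].reset_index(drop=True)
    genes = sorted(set(ann["gene_id"]))
    if len(genes) > 1:
        raise ValidationError(f"annotation spans multiple genes: {genes}")
    probesets: dict[str, list[str]] = {}
    for pid, probe in zip(ann["probeset_id"], ann["probe_id"]):
        probesets.setdefault(str(pid), []).append(probe)
    for pid, probes in probesets.items():
        if not probes:
            raise ValidationError(f"probeset {pid!r} is empty")
    return GeneBundle(intensities=df, annotation=ann, probesets=probesets)


def _pad_columns(M: np.ndarray, width: int) -> np.ndarray:
    if M.shape[1] == width:
        return M
    out = np.zeros((M.shape[0], width), dtype=float)
    out[:, : M.shape[1]] = M
    return out


def match_transcript_columns(G_hat, G_ref) -> np.ndarray:
    """Permutation aligning predicted transcript columns to a reference.

    The predicted structure (continuous or binary) is resorted so that it
    becomes maximally similar to the reference, with similarity measured as
    total per-column L1 distance and solved by optimal (Hungarian) assignment.
    When column counts differ, the narrower matrix is zero-padded; indices of
    the permutation that are >= the original predicted column count refer to
    padded (unmatched) columns.

    Returns
    -------
    perm : ndarray of shape (max(n_hat, n_ref),)
        ``G_hat_padded[:, perm]`` is aligned column-by-column with the
        (padded) reference.  The same permutation must be applied to the rows
        of the corresponding concentration matrix.
    """
    A = np.asarray(G_hat, dtype=float)
    B = np.asarray(G_ref, dtype=float)
    if A.ndim != 2 or B.ndim != 2:
        raise ValidationError("structure matrices must be 2-dimensional")
    if A.shape[0] != B.shape[0]:
        raise ValidationError(
            f"probe count mismatch: predicted {A.shape[0]} vs reference {B.shape[0]}"
        )
    width = max(A.shape[1], B.shape[1])
    A = _pad_columns(A, width)
    B = _pad_columns(B, width)
    # cost[r, p] = L1 distance between reference column r and predicted column p
    cost = np.abs(B.T[:, None, :] - A.T[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(width, dtype=int)
    perm[rows] = cols
    return perm


def align_to_reference(G_hat, G_ref, T_hat=None):
    """Reorder predicted columns (and concentration rows) to match a reference.

    Returns the aligned structure with the reference's column count; if
    ``T_hat`` is given, its rows are permuted identically (padded rows are
    zero).
    """
    A = np.asarray(G_hat, dtype=float)
    B = np.asarray(G_ref, dtype=float)
    perm = match_transcript_columns(A, B)
    width = len(perm)
    A_pad = _pad_columns(A, width)
    G_aligned = A_pad[:, perm][:, : B.shape[1]]
    if T_hat is None:
        return G_aligned
    T = np.asarray(T_hat, dtype=float)
    T_pad = np.zeros((width, T.shape[1]))
    T_pad[: T.shape[0]] = T
    T_aligned = T_pad[perm][: B.shape[1]]
    return G_aligned, T_aligned
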