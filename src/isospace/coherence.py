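"""Probeset coherence correction and final discretization.

Affymetrix probes come in sets targeting the same exon (or exon fragment), so
all probes of a probeset must share one hybridization pattern: within the
structure matrix, the rows of a probeset should be identical.  The correction
replaces each probeset block of the continuous structure by the closest
rank-one block — every row becomes the column-mean vector of the block — and
the final binary structure is obtained by thresholding (rounding the means at
the default threshold 0.5, ties rounding up).

Note that a real splicing event that cuts *through* a probeset (e.g. a novel
donor site inside an exon) is invisible to this correction; it treats the
probeset as a unit.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import ValidationError


def _check_partition(n_rows: int, probeset_rows) -> list[np.ndarray]:
    blocks = [np.asarray(b, dtype=int) for b in probeset_rows]
    seen = np.concatenate(blocks) if blocks else np.array([], dtype=int)
    if len(seen) != n_rows or len(np.unique(seen)) != n_rows:
        raise ValidationError(
            "probeset partition must assign every probe row exactly once"
        )
    return blocks


def probeset_column_means(G_tilde, probeset_rows) -> np.ndarray:
    """Replace each probeset block by its column-mean row (rank-1, continuous).

    This is the continuous form of the coherence correction: all rows of a
    probeset become identical, but values stay in [0, 1] so a threshold can
    still be swept afterwards.
    """
    G = np.asarray(G_tilde, dtype=float)
    blocks = _check_partition(G.shape[0], probeset_rows)
    out = np.empty_like(G)
    for rows in blocks:
        out[rows] = G[rows].mean(axis=0)[None, :]
    return out


def enforce_probeset_coherence(G_tilde, probeset_rows) -> np.ndarray:
    """Closest rank-1 binary block per probeset: round the column means.

    A mean of exactly 0.5 rounds up.
    """
    means = probeset_column_means(G_tilde, probeset_rows)
    return np.floor(means + 0.5)


def threshold_structure(G_tilde, th: float = 0.5, drop_empty: bool = True):
    """Binarize the continuous structure at ``th``.

    Returns ``(G, kept_columns)``.  Columns left all-zero at this threshold
    are dropped with a warning when ``drop_empty`` is set (the transcript is
    unsupported at this threshold); ``kept_columns`` are the surviving
    original column indices.
    """
    if not 0 < th < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    G = (np.asarray(G_tilde, dtype=float) > th).astype(float)
    kept = np.arange(G.shape[1])
    if drop_empty:
        nonzero = G.sum(axis=0) > 0
        if not nonzero.all():
            warnings.warn(
                f"dropping {int((~nonzero).sum())} transcript column(s) "
                f"unsupported at threshold {th}"
            )
            kept = kept[nonzero]
            G = G[:, nonzero]
    return G, kept


def estimate_concentrations(H_tilde, kept_columns=None, permutation=None) -> np.ndarray:
    """Concentration matrix from the adapted ``H̃`` factor.

    Under the model identification ``W̃·H̃ = (Ã·G̃)·T̃`` the concentrations are
    simply the rows of ``H̃`` (in relative units; the overall scale is not
    identifiable).  ``kept_columns`` restricts rows to the transcripts that
    survived thresholding; ``permutation`` applies the same reorder used to
    match structure columns to a reference.
    """
    T = np.asarray(H_tilde, dtype=float).copy()
    if kept_columns is not None:
        kept = np.asarray(kept_columns, dtype=int)
        if kept.size and kept.max() >= T.shape[0]:
            raise ValidationError("kept_columns exceed concentration row count")
        T = T[kept]
    if permutation is not None:
        perm = np.asarray(permutation, dtype=int)
        if perm.size != T.shape[0]:
            raise ValidationError(
                "permutation length does not match transcript row count"
            )
        T = T[perm]
    return T
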