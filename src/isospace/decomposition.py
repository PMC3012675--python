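"""Scikit-learn style estimators for isoform deconvolution.

:class:`SpaceDecomposition` runs the full per-gene procedure on a probe ×
sample intensity matrix: homoscedastic rescale → bi-cross-validated outlier
correction → transcript-count estimation (unless fixed) → NMF → diagonal
gauge fixing (Adapt) → affinity/structure split → probeset coherence →
thresholding → concentration extraction.  :class:`TranscriptCountEstimator`
exposes the rank-estimation stage alone.

Both follow sklearn conventions (``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``random_state``) and compose with
sklearn model-selection utilities.  Note one deliberate deviation from the
``(n_samples, n_features)`` convention: the input matrix is probe × sample,
the natural orientation of the deconvolution model, and ``transform`` returns
a transcript × sample concentration matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import adapt, bicrossval, coherence, nmf, preprocess
from .model import ValidationError, as_probe_matrix


def _child_rngs(random_state, n):
    ss = np.random.SeedSequence(random_state)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


class TranscriptCountEstimator(BaseEstimator):
    """Estimate the number of transcript isoforms of one gene.

    Bi-cross-validation with a Wilcoxon selection rule: among candidate
    internal dimensions, pick the smallest whose reconstruction-error
    distribution is not significantly larger than that of the best one.

    Parameters
    ----------
    max_transcripts : int, default 6
        Candidate-rank ceiling (performance of the deconvolution degrades
        beyond 4–5 isoforms, and the ceiling also caps runtime).
    n_resamples : int, default 250
        Number of random four-block splits.
    alpha : float, default 0.05
        One-sided significance level of the rank-sum selection test.
    power : float, default 0.7
        Exponent of the homoscedastic rescale applied first.
    outlier_correction : bool, default True
        Repair outlier intensities (same resampling machinery) before rank
        estimation.
    outlier_c : float, default 3.0
        Robust-distance multiplier of the outlier flag (c · MAD rule).

    Attributes
    ----------
    n_transcripts_ : int
        Estimated isoform count.
    error_table_ : ndarray of shape (n_resamples, k_max)
        Per-resample reconstruction errors by candidate rank.
    outlier_mask_ : ndarray or None
        Boolean mask of corrected entries.
    """

    def __init__(
        self,
        max_transcripts: int = 6,
        n_resamples: int = bicrossval.DEFAULT_RESAMPLES,
        alpha: float = 0.05,
        power: float = preprocess.DEFAULT_POWER,
        outlier_correction: bool = True,
        outlier_c: float = 3.0,
        random_state=None,
    ):
        self.max_transcripts = max_transcripts
        self.n_resamples = n_resamples
        self.alpha = alpha
        self.power = power
        self.outlier_correction = outlier_correction
        self.outlier_c = outlier_c
        self.random_state = random_state

    def fit(self, X, y=None):
        df = as_probe_matrix(X)
        Y = df.to_numpy(dtype=float)
        rng_out, rng_bcv = _child_rngs(self.random_state, 2)
        Ys, _ = preprocess.homoscedastic_rescale(Y, self.power)
        if self.outlier_correction:
            Ys, self.outlier_mask_, _ = bicrossval.detect_and_correct_outliers(
                Ys, self.n_resamples, self.outlier_c, rng_out
            )
        else:
            self.outlier_mask_ = None
        self.error_table_ = bicrossval.bcv_error_table(
            Ys, self.max_transcripts, self.n_resamples, rng_bcv
        )
        self.n_transcripts_ = bicrossval.estimate_num_transcripts(
            self.error_table_, self.alpha
        )
        self.n_features_in_ = Y.shape[1]
        return self

    def predict(self, X=None):
        """Return the fitted transcript count (X is ignored; one gene per fit)."""
        if not hasattr(self, "n_transcripts_"):
            raise ValidationError("estimator is not fitted")
        return self.n_transcripts_


class SpaceDecomposition(BaseEstimator):
    """Isoform structure and concentration deconvolution of one gene.

    Factorizes a non-negative probe × sample matrix as
    ``Y ≈ diag(A)·G·T`` with binary structure ``G``, per-probe affinities
    ``A`` and non-negative concentrations ``T``, resolving the NMF scaling
    ambiguity so that the factors match this model.

    Parameters
    ----------
    n_transcripts : int or None, default None
        Fixed internal dimension; estimated by bi-cross-validation when None.
    outlier_correction, adapt, coherence : bool
        The three structural improvements over a plain NMF; disabling all of
        them (``improvements="off"`` in the pipeline wrapper) reproduces the
        baseline factorization with a simple row-max split.
    threshold : float, default 0.5
        Binarization threshold for the final structure (the Hamming-optimal
        operating point).
    n_iter : int, default 3000
        NMF iteration budget.
    fill_floor : float, default 1e-3
        Floor applied to the continuous structure ("filled" matrix) so
        log-domain steps stay defined.

    Attributes
    ----------
    n_transcripts_ : int
    affinities_ : ndarray — per-probe affinities, original intensity units.
    continuous_structure_ : ndarray in [0, 1] — after coherence when enabled.
    structure_ : ndarray — binary probe × transcript matrix.
    kept_transcripts_ : ndarray — column indices surviving thresholding.
    concentrations_ : ndarray — transcript × sample, relative units.
    loss_ : float — final NMF Frobenius loss (rescaled domain).
    loss_trace_ : ndarray — per-iteration loss of the best restart.
    outlier_mask_ : ndarray or None — entries repaired before factorization.
    """

    def __init__(
        self,
        n_transcripts: int | None = None,
        max_transcripts: int = 6,
        power: float = preprocess.DEFAULT_POWER,
        outlier_correction: bool = True,
        adapt: bool = True,
        coherence: bool = True,
        threshold: float = 0.5,
        fill_floor: float = 1e-3,
        n_iter: int = nmf.DEFAULT_N_ITER,
        n_restarts: int = 1,
        n_resamples: int = bicrossval.DEFAULT_RESAMPLES,
        alpha: float = 0.05,
        outlier_c: float = 3.0,
        random_state=None,
    ):
        self.n_transcripts = n_transcripts
        self.max_transcripts = max_transcripts
        self.power = power
        self.outlier_correction = outlier_correction
        self.adapt = adapt
        self.coherence = coherence
        self.threshold = threshold
        self.fill_floor = fill_floor
        self.n_iter = n_iter
        self.n_restarts = n_restarts
        self.n_resamples = n_resamples
        self.alpha = alpha
        self.outlier_c = outlier_c
        self.random_state = random_state

    def fit(self, X, y=None, probesets=None):
        """Fit the deconvolution on one gene.

        Parameters
        ----------
        X : array-like or DataFrame, probe × sample, non-negative.
        probesets : sequence of row-index arrays, optional
            Probeset partition of the probes; required for the coherence
            correction (skipped, with the flag on, when absent).
        """
        df = as_probe_matrix(X)
        Y = df.to_numpy(dtype=float)
        m, n = Y.shape
        rng_out, rng_rank, rng_nmf = _child_rngs(self.random_state, 3)

        Ys, scale = preprocess.homoscedastic_rescale(Y, self.power)
        self.scale_ = scale

        if self.outlier_correction:
            Ys, self.outlier_mask_, _ = bicrossval.detect_and_correct_outliers(
                Ys, self.n_resamples, self.outlier_c, rng_out
            )
        else:
            self.outlier_mask_ = None

        cap = min(self.max_transcripts, min(m, n) - 1)
        if self.n_transcripts is not None:
            if not 1 <= self.n_transcripts <= min(m, n):
                raise ValidationError(
                    f"n_transcripts={self.n_transcripts} out of range for {m}x{n}"
                )
            k = int(self.n_transcripts)
        else:
            tbl = bicrossval.bcv_error_table(Ys, cap, self.n_resamples, rng_rank)
            k = bicrossval.estimate_num_transcripts(tbl, self.alpha)
            self.error_table_ = tbl
        self.n_transcripts_ = k

        res = nmf.nmf_factorize(Ys, k, self.n_iter, self.n_restarts, rng_nmf)
        self.loss_ = res.loss
        self.loss_trace_ = res.loss_trace
        W, H = res.W, res.H

        if self.adapt and k > 1:
            d = adapt.solve_scaling(W, self.fill_floor)
            W, H = adapt.apply_scaling(W, H, d)
            self.scaling_ = d
        else:
            self.scaling_ = np.ones(k)

        a_scaled = adapt.extract_affinities(W)
        G_cont = adapt.continuous_structure(W, a_scaled)
        G_cont = adapt.fill_structure(G_cont, self.fill_floor)
        if self.coherence and probesets is not None:
            G_cont = coherence.probeset_column_means(G_cont, probesets)
        self.continuous_structure_ = G_cont

        G_bin, kept = coherence.threshold_structure(G_cont, self.threshold)
        self.structure_ = G_bin
        self.kept_transcripts_ = kept
        self.concentrations_ = coherence.estimate_concentrations(H, kept)
        # affinity in original intensity units: undo the per-probe rescale
        self.affinities_ = a_scaled * scale
        self.probe_ids_ = list(df.index)
        self.sample_ids_ = list(df.columns)
        self.n_features_in_ = n
        return self

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).concentrations_

    def transform(self, X):
        """Deconvolve a new sample set with the fitted structure/affinities.

        Non-negative least squares of ``X[:, s] ≈ diag(A)·G·T[:, s]`` per
        sample; returns the transcript × sample concentration matrix.
        """
        if not hasattr(self, "structure_"):
            raise ValidationError("estimator is not fitted")
        df = as_probe_matrix(X)
        T, _, _ = adapt.deconvolve_known_structure(
            df.to_numpy(dtype=float), self.structure_, self.affinities_
        )
        return T
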