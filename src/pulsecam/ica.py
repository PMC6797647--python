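"""Blind source separation of the three detrended channel traces.

The cardiac pulsation contributes to all color channels with different
weights, while noise sources are largely channel-independent, so
independent component analysis concentrates the pulse into one component
and raises its signal-to-noise ratio.  Components are defined only up to
sign and order; everything downstream works on power spectra, which are
sign-invariant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .traces import ChannelTraces

__all__ = ["ComponentSet", "run_ica"]

logger = logging.getLogger(__name__)

# Relative singular-value threshold below which a channel direction is
# treated as numerically absent (e.g. three identical channels have rank 1).
_RANK_RTOL = 1e-8


@dataclass(frozen=True)
class ComponentSet:
    """Up to three unit-variance independent components plus provenance."""

    components: np.ndarray = field(repr=False)  # (k, n)
    fps: float
    mixing: np.ndarray = field(repr=False)  # (3, k)
    seed: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.components.ndim != 2:
            raise ValueError("components must be a (k, n) array")
        if self.components.shape[0] > 3:
            raise ValueError("at most 3 components from 3 channels")

    @property
    def k(self) -> int:
        return int(self.components.shape[0])

    @property
    def n(self) -> int:
        return int(self.components.shape[1])


def run_ica(
    traces: ChannelTraces,
    n_components: int = 3,
    max_iter: int = 2000,
    seed: int = 0,
) -> ComponentSet:
    """Stabilised fixed-point ICA on the detrended R, G, B traces.

    Uses the symmetric (parallel) FastICA variant with the log-cosh
    contrast.  If the whitened data's effective rank is below
    ``n_components`` (e.g. perfectly correlated channels), only the
    achievable number of components is returned, with a log note.
    Deterministic for a fixed seed.  Non-convergence within ``max_iter``
    is not fatal: the result carries ``converged=False``.
    """
    X = traces.as_matrix()
    n = X.shape[0]
    if n < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} samples for {n_components} "
            f"components, got {n}"
        )
    Xc = X - X.mean(axis=0)
    svals = np.linalg.svd(Xc, compute_uv=False)
    rank = int(np.sum(svals > _RANK_RTOL * svals[0])) if svals[0] > 0 else 0
    if rank == 0:
        raise ValueError("traces are constant; nothing to decompose")
    k = min(n_components, rank)
    if k < n_components:
        logger.info(
            "effective rank %d < requested %d components; returning %d", rank, n_components, k
        )

    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-4,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(Xc)  # (n, k), unit variance
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=k,
                    algorithm="parallel",
                    fun="logcosh",
                    whiten="unit-variance",
                    max_iter=max_iter,
                    tol=1e-4,
                    random_state=seed,
                )
                S = ica.fit_transform(Xc)
            logger.warning("ICA did not converge within %d iterations", max_iter)

    return ComponentSet(
        components=np.ascontiguousarray(S.T),
        fps=traces.fps,
        mixing=np.asarray(ica.mixing_),
        seed=seed,
        converged=converged,
    )
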