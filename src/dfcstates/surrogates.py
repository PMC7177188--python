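"""Phase-randomization null models for connectivity-state validation.

Two questions are answered against amplitude-preserving surrogates of the
dFC matrix (each connectivity pair's time course gets independent uniform
random Fourier phases, so power spectra — and hence variances and
autocorrelations — are preserved while any coordinated temporal structure
is destroyed):

* Are the estimated states meaningful? A state is retained when its rank-1
  reconstruction error on the true data falls below the 5th percentile of
  the errors of states estimated from surrogate data (10,000 surrogates at
  full scale; any smaller ensemble runs the identical code path).
* Is the cross-modal state match real? States are re-estimated from
  phase-randomized hemodynamic dFC data and correlated with the true
  electrophysiological states; the fraction of surrogates with any
  Bonferroni-significant pair calibrates the match test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .matching import _pearson_matrix
from .states import StateModel, fit_dictionary, per_state_error

__all__ = [
    "SurrogateEnsemble",
    "phase_randomize",
    "state_significance",
    "crossmodal_null",
]


@dataclass
class SurrogateEnsemble:
    """Null quantities accumulated over a surrogate ensemble."""

    n_surrogates: int
    null_errors: np.ndarray | None = None  # (n_surrogates, k)
    null_max_corrs: np.ndarray | None = None  # (n_surrogates,)
    master_seed: int = 0

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["n_surrogates"] = self.n_surrogates
            f.attrs["master_seed"] = self.master_seed
            if self.null_errors is not None:
                f.create_dataset("null_errors", data=self.null_errors)
            if self.null_max_corrs is not None:
                f.create_dataset("null_max_corrs", data=self.null_max_corrs)


def phase_randomize(C: np.ndarray, seed=0, shared_phases: bool = False) -> np.ndarray:
    """Amplitude-preserving phase randomization of each row of ``C``.

    Per row: FFT, add independent uniform(0, 2pi) phases to the positive
    frequencies (DC and, for even length, the Nyquist bin stay real),
    mirror them to keep Hermitian symmetry, inverse FFT. With
    ``shared_phases=True`` one phase vector is applied to every row, which
    additionally preserves the rows' cross-correlations (a stricter null).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite input to phase_randomize")
    n = C.shape[1]
    if n < 4:
        raise ValueError("rows must have at least 4 samples")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(C, axis=1)
    n_pos = spec.shape[1]
    # indices 1..(n_pos-1) are the positive frequencies; the last one is the
    # Nyquist bin when n is even and must stay real
    lo, hi = 1, n_pos - 1 if n % 2 == 0 else n_pos
    shape = (1, hi - lo) if shared_phases else (C.shape[0], hi - lo)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    spec[:, lo:hi] = spec[:, lo:hi] * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n, axis=1)


def state_significance(
    C_true: np.ndarray,
    model_true: StateModel,
    n_surr: int = 200,
    seed: int = 0,
    error_on_true: bool = False,
    max_iter: int = 200,
    nonneg: bool = False,
    n_restarts: int = 1,
) -> dict:
    """Per-state significance against the phase-randomization null.

    For each surrogate, states are re-estimated from the phase-randomized
    matrix with the same (k, lambda) as ``model_true`` and their per-state
    reconstruction errors pooled into one null distribution. A true state
    is meaningful when its error lies below the null's 5th percentile. By
    default the surrogate errors are computed on the surrogate matrix the
    states were fit to; ``error_on_true=True`` scores them against the true
    matrix instead.
    """
    if n_surr < 20:
        raise ValueError("need at least 20 surrogates for a 5th-percentile rule")
    k, lam = model_true.k, model_true.lam
    null_errors = np.empty((n_surr, k))
    for s in range(n_surr):
        ss = np.random.SeedSequence([seed, s])
        surr_seed, fit_seed = (int(x % 2**31) for x in ss.generate_state(2))
        C_surr = phase_randomize(C_true, seed=surr_seed)
        m = fit_dictionary(
            C_surr, k, lam, seed=fit_seed, max_iter=max_iter,
            nonneg=nonneg, n_restarts=n_restarts,
        )
        if error_on_true:
            null_errors[s] = per_state_error(m.D, m.A, C_true)
        else:
            null_errors[s] = m.E_per_state
    threshold = float(np.percentile(null_errors.ravel(), 5.0))
    E_true = per_state_error(model_true.D, model_true.A, C_true)
    meaningful = E_true < threshold
    return {
        "meaningful": meaningful,
        "E_true": E_true,
        "threshold": threshold,
        "ensemble": SurrogateEnsemble(
            n_surrogates=n_surr, null_errors=null_errors, master_seed=seed
        ),
    }


def crossmodal_null(
    C_fmri: np.ndarray,
    D_eeg_true: np.ndarray,
    k_opt: int,
    lam_opt: float,
    n_surr: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    max_iter: int = 200,
    nonneg: bool = False,
    n_restarts: int = 1,
    positive_only: bool = True,
) -> dict:
    """Cross-modal match null: states from phase-randomized hemodynamic data.

    Per surrogate: re-estimate states from the phase-randomized dFC matrix
    (with the same fit settings as the observed states), correlate every
    pair with the true electrophysiological state patterns, and test each
    at the Bonferroni-corrected level ``alpha / (k_a * k_b)``; with
    ``positive_only`` (the matching default) only positively correlated
    pairs count as a match. Returns the fraction of surrogates with at
    least one significant pair and the per-surrogate maximum correlation.
    """
    if n_surr < 1:
        raise ValueError("need at least one surrogate")
    D_eeg_true = np.asarray(D_eeg_true, dtype=float)
    k_eeg = D_eeg_true.shape[1]
    n_tests = k_opt * k_eeg
    null_max = np.empty(n_surr)
    any_sig = np.zeros(n_surr, dtype=bool)
    for s in range(n_surr):
        ss = np.random.SeedSequence([seed, s])
        surr_seed, fit_seed = (int(x % 2**31) for x in ss.generate_state(2))
        C_surr = phase_randomize(C_fmri, seed=surr_seed)
        m = fit_dictionary(
            C_surr, k_opt, lam_opt, seed=fit_seed, max_iter=max_iter,
            nonneg=nonneg, n_restarts=n_restarts,
        )
        r, p = _pearson_matrix(m.D.T, D_eeg_true.T)
        null_max[s] = float(r.max())
        sig = p < alpha / n_tests
        if positive_only:
            sig &= r > 0
        any_sig[s] = bool(sig.any())
    return {
        "fraction_significant": float(any_sig.mean()),
        "null_max_corrs": null_max,
        "any_significant": any_sig,
        "ensemble": SurrogateEnsemble(
            n_surrogates=n_surr, null_max_corrs=null_max, master_seed=seed
        ),
    }


def verdicts_to_json(result: dict, path: str | Path) -> None:
    """Serialize a significance result (booleans, thresholds, seed) to JSON."""
    payload = {}
    for key, val in result.items():
        if key == "ensemble":
            payload["n_surrogates"] = val.n_surrogates
            payload["master_seed"] = val.master_seed
        elif isinstance(val, np.ndarray):
            payload[key] = val.tolist()
        else:
            payload[key] = val
    Path(path).write_text(json.dumps(payload, indent=2))
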