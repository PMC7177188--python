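"""Connectivity-state estimation by l1-regularized dictionary learning.

The group dFC matrix ``C`` (connection pairs x windows) is factorized as
``C ~ D A``: the columns of the dictionary ``D`` are the connectivity
patterns of ``k`` recurring "brain states" and the rows of ``A`` are their
weight time-courses. ``D`` has unit-l2-norm columns and the weights carry
an l1 penalty with strength ``lambda``, so larger ``lambda`` yields
sparser state activations. Estimation alternates exact l1 sparse coding of
the weights (coordinate descent to KKT tolerance) with block coordinate
descent on the dictionary columns; the number of states ``k`` (grid 5..10)
and ``lambda`` (ten log-spaced values from 1 down to 0.1259) are selected
by a 5-5-fold nested cross-validation minimizing a Gaussian-residual BIC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "StateModel",
    "SelectionResult",
    "default_lambda_grid",
    "sparse_code",
    "kkt_residual",
    "update_dictionary",
    "fit_dictionary",
    "per_state_error",
    "bic_score",
    "nested_cv_select",
]

DEFAULT_K_GRID = tuple(range(5, 11))


def default_lambda_grid() -> np.ndarray:
    """Ten lambda values from 1 to ~0.1259 in decreasing exponential steps
    (10 ** 0, 10 ** -0.1, ..., 10 ** -0.9)."""
    return 10.0 ** (-np.arange(10) / 10.0)


@dataclass
class StateModel:
    """Fitted dictionary-learning model of connectivity states."""

    D: np.ndarray  # (M, k), unit-norm columns
    A: np.ndarray  # (k, T)
    k: int
    lam: float
    E_total: float  # ||C - D A||_F^2 at convergence
    E_per_state: np.ndarray  # E(i) = ||C - d_i a_i||_F^2
    seed: int
    n_iter: int
    objective_history: np.ndarray = field(repr=False, default=None)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("D", data=self.D)
            f.create_dataset("A", data=self.A)
            f.create_dataset("E_per_state", data=self.E_per_state)
            f.attrs.update(
                k=self.k, lam=self.lam, E_total=self.E_total, seed=self.seed, n_iter=self.n_iter
            )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "StateModel":
        with h5py.File(path, "r") as f:
            return cls(
                D=f["D"][()],
                A=f["A"][()],
                E_per_state=f["E_per_state"][()],
                k=int(f.attrs["k"]),
                lam=float(f.attrs["lam"]),
                E_total=float(f.attrs["E_total"]),
                seed=int(f.attrs["seed"]),
                n_iter=int(f.attrs["n_iter"]),
            )


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def sparse_code(
    C: np.ndarray,
    D: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
    A0: np.ndarray | None = None,
    nonneg: bool = False,
) -> np.ndarray:
    """l1 sparse coding: each column a_t minimizes
    ``0.5 * ||c_t - D a_t||^2 + lam * ||a_t||_1``.

    Solved by cyclic coordinate descent, vectorized across columns, iterated
    until the KKT residual falls below ``tol``. With ``lam = 0`` the exact
    least-squares solution is returned. ``nonneg=True`` additionally
    constrains the weights to be nonnegative.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != D.shape[0]:
        raise ValueError("C and D row dimensions differ")
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(D))):
        raise ValueError("non-finite inputs to sparse_code")
    k = D.shape[1]
    if lam == 0 and not nonneg:
        return np.linalg.lstsq(D, C, rcond=None)[0]
    G = D.T @ D
    B = D.T @ C
    A = np.zeros((k, C.shape[1])) if A0 is None else np.array(A0, dtype=float)
    diag = np.diag(G).copy()
    diag[diag <= 0] = 1.0
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(k):
            r_j = B[j] - G[j] @ A + G[j, j] * A[j]
            if nonneg:
                new = np.maximum(r_j - lam, 0.0) / diag[j]
            else:
                new = _soft(r_j, lam) / diag[j]
            step = np.abs(new - A[j]).max(initial=0.0)
            if step > delta:
                delta = step
            A[j] = new
        # the KKT check costs a sweep's worth of work; only run it once the
        # iterates have essentially stopped moving
        if delta <= tol and kkt_residual(G=G, B=B, A=A, lam=lam, nonneg=nonneg) <= tol:
            break
    else:
        warnings.warn("sparse_code hit max_sweeps before reaching KKT tolerance")
    return A


def kkt_residual(
    C: np.ndarray | None = None,
    D: np.ndarray | None = None,
    A: np.ndarray | None = None,
    lam: float = 0.0,
    G: np.ndarray | None = None,
    B: np.ndarray | None = None,
    nonneg: bool = False,
) -> float:
    """Max violation of the lasso optimality conditions for ``A``.

    At the optimum the gradient ``g = D^T(C - D A)`` satisfies
    ``g = lam * sign(a)`` on the support and ``|g| <= lam`` off it (for the
    nonnegative variant, ``g = lam`` on the support and ``g <= lam`` off).
    """
    if G is None or B is None:
        G = D.T @ D
        B = D.T @ C
    g = B - G @ A
    on = A != 0
    if nonneg:
        viol_on = np.abs(g[on] - lam) if on.any() else np.array([0.0])
        viol_off = np.maximum(g[~on] - lam, 0.0) if (~on).any() else np.array([0.0])
    else:
        viol_on = np.abs(g[on] - lam * np.sign(A[on])) if on.any() else np.array([0.0])
        viol_off = np.maximum(np.abs(g[~on]) - lam, 0.0) if (~on).any() else np.array([0.0])
    return float(max(viol_on.max(initial=0.0), viol_off.max(initial=0.0)))


def update_dictionary(C: np.ndarray, A: np.ndarray, D_prev: np.ndarray) -> np.ndarray:
    """Block coordinate descent on dictionary columns with unit-norm renorm.

    Each column is set to the exact minimizer of the residual over the unit
    sphere given the other columns and the weights, so the fit term never
    increases. A dead state (all-zero weight row) is re-seeded from the
    worst-reconstructed data column.
    """
    D = np.array(D_prev, dtype=float)
    k = D.shape[1]
    AAt = A @ A.T
    CAt = C @ A.T
    for j in range(k):
        if AAt[j, j] <= 1e-12:
            resid = C - D @ A
            worst = int(np.argmax((resid**2).sum(axis=0)))
            col = C[:, worst]
            norm = np.linalg.norm(col)
            if norm > 0:
                D[:, j] = col / norm
            continue
        b = CAt[:, j] - D @ AAt[:, j] + D[:, j] * AAt[j, j]
        norm = np.linalg.norm(b)
        if norm > 0:
            D[:, j] = b / norm
    return D


def _duplicate_atom(D: np.ndarray, A: np.ndarray, threshold: float = 0.75) -> int | None:
    """Index of the weaker atom of the most correlated near-duplicate pair,
    or None when all pairwise |corr| of dictionary columns stay below
    ``threshold``."""
    k = D.shape[1]
    if k < 2:
        return None
    Dc = D - D.mean(axis=0, keepdims=True)
    sd = np.linalg.norm(Dc, axis=0)
    sd[sd == 0] = 1.0
    G = np.abs((Dc / sd).T @ (Dc / sd))
    np.fill_diagonal(G, 0.0)
    i, j = np.unravel_index(np.argmax(G), G.shape)
    if G[i, j] <= threshold:
        return None
    return int(i if np.linalg.norm(A[i]) <= np.linalg.norm(A[j]) else j)


def _init_dictionary(C: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct nonzero data columns, drawn by seeded sampling, normalized.

    The first column is drawn uniformly; each further column is the
    candidate least correlated (in absolute value) with all columns chosen
    so far (farthest-point rule). This avoids seeding two dictionary atoms
    inside the same recurring pattern of the data, the dominant local
    minimum of alternating minimization.
    """
    norms = np.linalg.norm(C, axis=0)
    candidates = np.flatnonzero(norms > 0)
    if candidates.size < k:
        raise ValueError("not enough nonzero data columns to initialize the dictionary")
    U = C[:, candidates] / norms[candidates]
    chosen = [int(rng.integers(candidates.size))]
    max_sim = np.abs(U.T @ U[:, chosen[0]])
    for _ in range(k - 1):
        max_sim[chosen] = np.inf
        nxt = int(np.argmin(max_sim))
        chosen.append(nxt)
        max_sim = np.maximum(max_sim, np.abs(U.T @ U[:, nxt]))
    return U[:, chosen].copy()


def fit_dictionary(
    C: np.ndarray,
    k: int,
    lam: float,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    code_tol: float = 1e-4,
    nonneg: bool = False,
    n_restarts: int = 1,
) -> StateModel:
    """Alternating minimization of ``0.5 ||C - DA||_F^2 + lam * ||A||_1``.

    Deterministic given ``seed`` (which only controls the data-column
    initialization of ``D``). Iterates until the relative change of the
    reconstruction error falls below ``tol`` or ``max_iter`` alternations.
    During the alternations the weights are coded to the looser
    ``code_tol``; the returned ``A`` comes from a final strict (1e-6)
    coding pass against the converged dictionary.

    The orientation of a state is arbitrary under the objective (``d a``
    equals ``(-d)(-a)``), so unless ``nonneg`` constrains the weights, each
    returned state is sign-canonicalized to make its weight course sum
    nonnegative; this keeps patterns comparable across fits and modalities.

    ``n_restarts > 1`` runs that many independently initialized fits (seeds
    derived deterministically from ``seed``) and returns the one with the
    lowest penalized objective — the standard guard against the local
    minima of alternating minimization.
    """
    if n_restarts > 1:
        best: StateModel | None = None
        best_obj = np.inf
        for r in range(n_restarts):
            m = fit_dictionary(
                C, k, lam, seed=seed + 1000003 * r, max_iter=max_iter, tol=tol,
                code_tol=code_tol, nonneg=nonneg, n_restarts=1,
            )
            obj = 0.5 * m.E_total + lam * float(np.abs(m.A).sum())
            if obj < best_obj:
                best, best_obj = m, obj
        best.seed = seed
        return best
    C = np.asarray(C, dtype=float)
    M, T = C.shape
    if k > min(M, T):
        raise ValueError(f"k={k} exceeds min(M, T)={min(M, T)}")
    rng = np.random.default_rng(seed)
    D = _init_dictionary(C, k, rng)
    A = None
    E_prev = np.inf
    history = []
    n_iter = 0
    n_repairs = 0
    for n_iter in range(1, max_iter + 1):
        A = sparse_code(C, D, lam, tol=code_tol, A0=A, nonneg=nonneg)
        D = update_dictionary(C, A, D)
        resid = C - D @ A
        E = float((resid**2).sum())
        history.append(0.5 * E + lam * np.abs(A).sum())
        if E_prev < np.inf and abs(E_prev - E) <= tol * max(E_prev, 1e-30):
            # converged; repair near-duplicate atoms (two columns locked onto
            # the same pattern leave some structure unexplained) and continue
            j = _duplicate_atom(D, A) if n_repairs < 3 else None
            if j is None:
                E_prev = E
                break
            worst = int(np.argmax((resid**2).sum(axis=0)))
            col = C[:, worst]
            D[:, j] = col / (np.linalg.norm(col) or 1.0)
            A[j] = 0.0
            n_repairs += 1
            E_prev = np.inf
            continue
        E_prev = E
    # final coding pass so A is optimal for the returned D
    A = sparse_code(C, D, lam, A0=A, nonneg=nonneg)
    if not nonneg:
        flip = A.sum(axis=1) < 0
        D[:, flip] *= -1.0
        A[flip] *= -1.0
    E_total = float(((C - D @ A) ** 2).sum())
    return StateModel(
        D=D,
        A=A,
        k=k,
        lam=lam,
        E_total=E_total,
        E_per_state=per_state_error(D, A, C),
        seed=seed,
        n_iter=n_iter,
        objective_history=np.array(history),
    )


def per_state_error(
    D: np.ndarray | StateModel, A: np.ndarray | None = None, C: np.ndarray | None = None
) -> np.ndarray:
    """Rank-1 reconstruction error per state: E(i) = ||C - d_i a_i||_F^2."""
    if isinstance(D, StateModel):
        if A is None:
            raise ValueError("pass the data matrix as the second argument")
        D, A, C = D.D, D.A, A
    k = D.shape[1]
    out = np.empty(k)
    for i in range(k):
        out[i] = ((C - np.outer(D[:, i], A[i])) ** 2).sum()
    return out


def bic_score(model: StateModel, C_val: np.ndarray) -> float:
    """Gaussian-residual BIC of a trained model on held-out columns.

    The validation columns are sparse-coded against the trained dictionary
    at the model's lambda; then ``BIC = n ln(RSS / n) + p_eff ln(n)`` with
    ``n`` the number of entries of ``C_val`` and the effective parameter
    count ``p_eff = k M + nnz(A_val)``, crediting sparser solutions.
    """
    C_val = np.asarray(C_val, dtype=float)
    A_val = sparse_code(C_val, model.D, model.lam)
    rss = float(((C_val - model.D @ A_val) ** 2).sum())
    n = C_val.size
    p_eff = model.k * model.D.shape[0] + int(np.count_nonzero(A_val))
    if rss <= 0:
        warnings.warn("zero validation residual; BIC is -inf")
        return float("-inf")
    return n * np.log(rss / n) + p_eff * np.log(n)


@dataclass
class SelectionResult:
    """Outcome of the nested cross-validated (k, lambda) selection."""

    k_opt: int
    lam_opt: float
    fold_choices: list[tuple[int, float]]
    table: list[dict]
    recurrence: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k_opt": self.k_opt,
            "lam_opt": self.lam_opt,
            "fold_choices": [[k, lam] for k, lam in self.fold_choices],
            "recurrence": {f"{k},{lam}": n for (k, lam), n in self.recurrence.items()},
            "table": self.table,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _contiguous_folds(indices: np.ndarray, n_folds: int) -> list[np.ndarray]:
    return [f for f in np.array_split(indices, n_folds)]


def nested_cv_select(
    C: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    lam_grid: np.ndarray | None = None,
    outer: int = 5,
    inner: int = 5,
    seed: int = 0,
    participant_slices: list[slice] | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> SelectionResult:
    """5-5-fold nested cross-validated selection of (k, lambda) by BIC.

    Folds are contiguous column blocks within each participant (windows are
    temporally autocorrelated, so shuffling columns would leak). For every
    outer fold, the inner CV averages the BIC over inner splits of the
    outer-train columns for every grid pair and records the argmin; the
    final pair is the most recurrent across outer folds, ties broken toward
    smaller k, then larger lambda.
    """
    C = np.asarray(C, dtype=float)
    T = C.shape[1]
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty k grid")
    lam_grid = default_lambda_grid() if lam_grid is None else np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty lambda grid")
    if T < outer * inner:
        raise ValueError(f"T={T} columns cannot support {outer}x{inner} nested folds")
    slices = participant_slices or [slice(0, T)]
    per_participant = [np.arange(s.start, s.stop) for s in slices]
    outer_folds = [
        np.concatenate([_contiguous_folds(idx, outer)[f] for idx in per_participant])
        for f in range(outer)
    ]
    table: list[dict] = []
    fold_choices: list[tuple[int, float]] = []
    for f, val_idx in enumerate(outer_folds):
        train_idx_per_part = [np.setdiff1d(idx, val_idx) for idx in per_participant]
        inner_folds = [
            np.concatenate([_contiguous_folds(idx, inner)[g] for idx in train_idx_per_part])
            for g in range(inner)
        ]
        train_all = np.concatenate(train_idx_per_part)
        scores = np.zeros((len(k_grid), lam_grid.size))
        for g, inner_val in enumerate(inner_folds):
            inner_train = np.setdiff1d(train_all, inner_val)
            C_tr, C_va = C[:, inner_train], C[:, inner_val]
            for ki, k in enumerate(k_grid):
                for li, lam in enumerate(lam_grid):
                    fit_seed = int(
                        np.random.SeedSequence([seed, f, g, ki, li]).generate_state(1)[0] % 2**31
                    )
                    model = fit_dictionary(C_tr, k, lam, seed=fit_seed, max_iter=max_iter, tol=tol)
                    bic = bic_score(model, C_va)
                    scores[ki, li] += bic
                    table.append(
                        {"outer": f, "inner": g, "k": k, "lam": float(lam), "bic": float(bic)}
                    )
        scores /= inner
        # argmin with ties toward smaller k then larger lambda (grid order)
        ki, li = np.unravel_index(np.argmin(scores), scores.shape)
        fold_choices.append((k_grid[ki], float(lam_grid[li])))
    recurrence: dict[tuple[int, float], int] = {}
    for pair in fold_choices:
        recurrence[pair] = recurrence.get(pair, 0) + 1
    best = max(recurrence.items(), key=lambda kv: (kv[1], -kv[0][0], kv[0][1]))
    k_opt, lam_opt = best[0]
    return SelectionResult(
        k_opt=k_opt,
        lam_opt=lam_opt,
        fold_choices=fold_choices,
        table=table,
        recurrence=recurrence,
    )
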