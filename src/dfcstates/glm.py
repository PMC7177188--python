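"""Task-network mapping with a general linear model on both modalities.

The hemodynamic modality is modelled with condition boxcars convolved with a
canonical double-gamma haemodynamic response function (HRF); the
electrophysiological source-strength series carries no haemodynamic delay, so
its boxcars enter the model raw. Voxelwise OLS fits yield contrast Z maps
which are cluster-thresholded (voxel Z > 2.7 by default) and combined across
subjects with a fixed-effects (Stouffer) rule. The module also correlates
dictionary-learning state weight time-courses with the task contrast, after
averaging the contrast within each sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats

from .dfc import WindowSpec

__all__ = [
    "TaskDesign",
    "DesignMatrix",
    "HRFParams",
    "boxcar_regressor",
    "hrf_kernel",
    "convolve_regressor",
    "build_design_matrix",
    "fit_glm",
    "contrast_z",
    "cluster_threshold",
    "group_map",
    "window_average_series",
    "state_task_correlation",
]


@dataclass
class TaskDesign:
    """Block task timing: (label, onset_s, duration_s) triples."""

    conditions: list[tuple[str, float, float]]
    run_length: float

    def __post_init__(self) -> None:
        by_label: dict[str, list[tuple[float, float]]] = {}
        for label, onset, dur in self.conditions:
            if onset < 0 or onset + dur > self.run_length + 1e-9:
                raise ValueError(f"block ({label}, {onset}, {dur}) outside the run")
            by_label.setdefault(label, []).append((onset, dur))
        for label, blocks in by_label.items():
            blocks = sorted(blocks)
            for (o1, d1), (o2, _) in zip(blocks, blocks[1:]):
                if o1 + d1 > o2 + 1e-9:
                    raise ValueError(f"overlapping blocks within condition {label!r}")

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for label, _, _ in self.conditions:
            seen.setdefault(label)
        return list(seen)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [(o, d, l) for l, o, d in self.conditions],
            columns=["onset", "duration", "label"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaskDesign":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        conditions = [(str(r.label), float(r.onset), float(r.duration)) for r in df.itertuples()]
        run_length = max(o + d for _, o, d in conditions)
        return cls(conditions=conditions, run_length=run_length)


@dataclass
class DesignMatrix:
    X: np.ndarray
    names: list[str]
    convolved: bool
    sample_interval: float

    def __post_init__(self) -> None:
        if np.any(np.all(self.X == 0, axis=0)):
            raise ValueError("design matrix contains an all-zero column")


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: peak at 6 s, undershoot at 16 s, 1:6 ratio."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


def boxcar_regressor(design: TaskDesign, condition: str, sample_interval: float) -> np.ndarray:
    """Unit boxcar for one condition, sampled on the modality's time grid.

    Onsets/offsets that fall between samples are snapped to the nearest
    sample. Raises if the condition never occurs (all-zero regressor).
    """
    n = int(round(design.run_length / sample_interval))
    out = np.zeros(n)
    found = False
    for label, onset, dur in design.conditions:
        if label != condition:
            continue
        found = True
        i0 = int(round(onset / sample_interval))
        i1 = int(round((onset + dur) / sample_interval))
        out[i0:i1] = 1.0
    if not found or not out.any():
        raise ValueError(f"condition {condition!r} produces an all-zero regressor")
    return out


def hrf_kernel(params: HRFParams = HRFParams(), dt: float = 1.0) -> np.ndarray:
    """Double-gamma HRF sampled at interval ``dt``, peak amplitude 1.

    Each lobe is a gamma density parametrized by its mode (peak_delay /
    undershoot_delay) and dispersion; the undershoot is scaled down by
    ``ratio``.
    """

    t = np.arange(0, params.length + dt / 2, dt)

    def lobe(delay: float, disp: float) -> np.ndarray:
        shape = 1.0 + delay / disp  # gamma mode = (shape - 1) * scale = delay
        return stats.gamma.pdf(t, a=shape, scale=disp)

    h = lobe(params.peak_delay, params.peak_dispersion)
    h = h - lobe(params.undershoot_delay, params.undershoot_dispersion) / params.ratio
    if h.sum() <= 0:
        raise ValueError("HRF kernel does not integrate to a positive value")
    return h / h.max()


def convolve_regressor(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the input length."""
    return np.convolve(series, kernel)[: len(series)]


def build_design_matrix(
    design: TaskDesign,
    sample_interval: float,
    convolve: bool,
    hrf_params: HRFParams = HRFParams(),
) -> DesignMatrix:
    """One regressor per condition; convolved with the HRF when requested."""
    cols = []
    kernel = hrf_kernel(hrf_params, dt=sample_interval) if convolve else None
    for label in design.labels:
        reg = boxcar_regressor(design, label, sample_interval)
        if kernel is not None:
            reg = convolve_regressor(reg, kernel)
        cols.append(reg)
    return DesignMatrix(
        X=np.column_stack(cols),
        names=design.labels,
        convolved=convolve,
        sample_interval=sample_interval,
    )


@dataclass
class GLMFit:
    betas: np.ndarray  # (n_regressors, n_voxels)
    sigma2: np.ndarray  # (n_voxels,) residual variance (RSS / dof)
    dof: int
    X: np.ndarray
    xtx_inv: np.ndarray = field(repr=False, default=None)


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> GLMFit:
    """Ordinary least squares per voxel/parcel (columns of ``Y``)."""
    Xm = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        raise ValueError("rank-deficient design matrix")
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    betas = xtx_inv @ Xm.T @ Y
    resid = Y - Xm @ betas
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GLMFit(betas=betas, sigma2=sigma2, dof=dof, X=Xm, xtx_inv=xtx_inv)


def contrast_z(fit: GLMFit, c: np.ndarray) -> np.ndarray:
    """Contrast t statistics converted to Z through the t CDF.

    The conversion maps the t tail probability through the standard-normal
    quantile, so Z maps from runs of different lengths are comparable.
    """
    c = np.asarray(c, dtype=float)
    if not c.any():
        raise ValueError("contrast vector is all zeros")
    effect = c @ fit.betas
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = effect / np.sqrt(var)
    tval = np.nan_to_num(tval, nan=0.0, posinf=np.inf, neginf=-np.inf)
    # symmetric, numerically stable tail mapping
    z = np.sign(tval) * stats.norm.isf(stats.t.sf(np.abs(tval), fit.dof))
    return np.clip(z, -40, 40)


def cluster_threshold(zmap: np.ndarray, z: float = 2.7, min_voxels: int = 10) -> np.ndarray:
    """Keep 26-connected supra-threshold clusters of at least ``min_voxels``."""
    supra = np.asarray(zmap) > z
    structure = np.ones((3,) * supra.ndim, dtype=bool)
    labelled, n = ndimage.label(supra, structure=structure)
    keep = np.zeros_like(supra)
    for i in range(1, n + 1):
        comp = labelled == i
        if comp.sum() >= min_voxels:
            keep |= comp
    return keep


def group_map(subject_zmaps: list[np.ndarray]) -> np.ndarray:
    """Fixed-effects (Stouffer) combination: mean(Z) * sqrt(n_subjects)."""
    if not subject_zmaps:
        raise ValueError("no subject maps")
    stack = np.stack(subject_zmaps)
    return stack.mean(axis=0) * np.sqrt(stack.shape[0])


def window_average_series(series: np.ndarray, window: WindowSpec, trim: bool = False) -> np.ndarray:
    """Average a sample-rate series within each sliding window (to T values)."""
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    rem = (n - window.length_samples) % window.step_samples
    if rem:
        if not trim:
            raise ValueError("window geometry does not cover the series; pass trim=True")
        series = series[rem:]
        n -= rem
    T = (n - window.length_samples) // window.step_samples + 1
    return np.array(
        [
            series[t * window.step_samples : t * window.step_samples + window.length_samples].mean()
            for t in range(T)
        ]
    )


def state_task_correlation(
    A: np.ndarray,
    contrast_series: np.ndarray,
    window: WindowSpec,
    alpha: float = 0.05,
    n_states_total: int | None = None,
    trim: bool = False,
    per_participant: int = 1,
) -> list[dict]:
    """Pearson correlation of each state weight course with the task contrast.

    ``contrast_series`` is sampled on the modality's time grid (convolved for
    the hemodynamic modality) and is window-averaged onto the T windows of
    ``A``; for group weight matrices (participants concatenated in time),
    ``per_participant`` splits the series into that many runs and windows
    each separately, since windows never span participants. Significance is
    Bonferroni-corrected over ``n_states_total`` (default: the number of
    states in ``A``). Degenerate (constant) weight courses are reported as
    non-significant with r = NaN.
    """
    A = np.asarray(A, dtype=float)
    contrast_series = np.asarray(contrast_series, dtype=float)
    if per_participant > 1:
        chunks = np.array_split(contrast_series, per_participant)
        x = np.concatenate([window_average_series(c, window, trim=trim) for c in chunks])
    else:
        x = window_average_series(contrast_series, window, trim=trim)
    if x.shape[0] != A.shape[1]:
        raise ValueError(
            f"contrast yields {x.shape[0]} windows but weights have {A.shape[1]} columns"
        )
    k = A.shape[0]
    n_tests = n_states_total if n_states_total is not None else k
    out = []
    for i in range(k):
        a = A[i]
        if np.std(a) == 0 or np.std(x) == 0:
            import warnings

            warnings.warn(f"state {i}: constant weight course, correlation undefined")
            out.append({"state": i, "r": float("nan"), "p": 1.0, "significant": False})
            continue
        r, p = stats.pearsonr(a, x)
        significant = bool(p < alpha / n_tests)
        out.append(
            {
                "state": i,
                "r": float(r),
                "p": float(p),
                "significant": significant,
                # a state expresses the task network only when its weights rise
                # with the task; mass conservation across states makes negative
                # correlations expected side effects, not task associations
                "task_associated": significant and r > 0,
            }
        )
    return out
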