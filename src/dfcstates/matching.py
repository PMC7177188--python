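"""Spatial similarity and mutually exclusive one-to-one assignment.

Two analyses share this machinery: (a) identifying resting-state networks
by Dice overlap between thresholded component maps (Z = 3.0) and network
templates, with a permutation null built from the full components-by-
templates similarity matrix (95th percentile); and (b) matching
connectivity states across modalities by the spatial (Pearson) correlation
of their vectorized connectivity patterns, Bonferroni-corrected over all
state pairs.

Non-exclusive best matches are resolved by the randomized greedy procedure:
the order of the smaller set is permuted (exhaustively when feasible, up to
``n_orderings`` random orderings otherwise), items are assigned greedily in
order to their best unassigned partner, and the ordering achieving the
highest average similarity wins. A brute-force optimal assignment is
provided as a testing oracle only — the greedy procedure itself is the
method under study.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "MapSet",
    "AssignmentResult",
    "dice",
    "similarity_matrix",
    "exclusive_assign",
    "brute_force_assign",
    "dice_null_threshold",
    "match_states",
    "identify_networks",
]


@dataclass
class MapSet:
    """A set of 3-D spatial maps (or flat patterns) on a common grid."""

    maps: list[np.ndarray]
    names: list[str]
    z_threshold: float = 3.0
    kind: str = "components"  # templates | components | state_patterns

    def __post_init__(self) -> None:
        if len(self.maps) != len(self.names):
            raise ValueError("one name per map required")
        shapes = {m.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError("maps must share a common grid")

    def __len__(self) -> int:
        return len(self.maps)

    def masks(self) -> list[np.ndarray]:
        """Binary masks after thresholding at ``z_threshold``."""
        return [m > self.z_threshold for m in self.maps]

    def vectors(self) -> np.ndarray:
        """(n_maps, n_voxels) matrix of flattened maps."""
        return np.stack([m.ravel() for m in self.maps])

    def to_nifti(self, out_dir: str | Path, affine: np.ndarray | None = None) -> Path:
        import nibabel as nib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4) if affine is None else affine
        files = []
        for name, vol in zip(self.names, self.maps):
            f = out_dir / f"{name}.nii"
            nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine).to_filename(f)
            files.append(f.name)
        manifest = {
            "kind": self.kind,
            "z_threshold": self.z_threshold,
            "names": self.names,
            "files": files,
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        return mpath

    @classmethod
    def from_nifti(cls, manifest_path: str | Path) -> "MapSet":
        import nibabel as nib

        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        maps = [
            np.asarray(nib.load(manifest_path.parent / f).get_fdata())
            for f in manifest["files"]
        ]
        return cls(
            maps=maps,
            names=manifest["names"],
            z_threshold=manifest["z_threshold"],
            kind=manifest["kind"],
        )


@dataclass
class AssignmentResult:
    """One-to-one assignment between two component sets."""

    pairs: list[tuple[int, int]]
    similarities: np.ndarray
    mean_similarity: float
    max_similarity: float
    n_orderings_evaluated: int
    p_values: np.ndarray | None = None
    null_threshold: float | None = None
    similarity_full: np.ndarray | None = field(repr=False, default=None)

    @property
    def significant(self) -> bool | None:
        if self.null_threshold is None:
            return None
        return self.mean_similarity > self.null_threshold

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [[int(r), int(c)] for r, c in self.pairs],
            "similarities": np.asarray(self.similarities).tolist(),
            "mean_similarity": self.mean_similarity,
            "max_similarity": self.max_similarity,
            "n_orderings_evaluated": self.n_orderings_evaluated,
            "p_values": None if self.p_values is None else np.asarray(self.p_values).tolist(),
            "null_threshold": self.null_threshold,
            "significant": self.significant,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binary masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a grid")
    na, nb = mask_a.sum(), mask_b.sum()
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * np.logical_and(mask_a, mask_b).sum() / (na + nb)


def _pearson_matrix(va: np.ndarray, vb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = va.shape[1]
    za = (va - va.mean(axis=1, keepdims=True)) / va.std(axis=1, keepdims=True)
    zb = (vb - vb.mean(axis=1, keepdims=True)) / vb.std(axis=1, keepdims=True)
    r = np.clip(za @ zb.T / n, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def similarity_matrix(
    set_a: MapSet | np.ndarray,
    set_b: MapSet | np.ndarray,
    metric: str = "dice",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Full pairwise similarity between two map/pattern sets.

    ``metric="dice"`` thresholds the maps first (MapSet input required);
    ``metric="pearson"`` correlates flattened patterns and also returns
    two-sided p-values from the t transform with length - 2 degrees of
    freedom. Plain arrays are interpreted as (n_maps, n_features).
    """
    if metric == "dice":
        if not isinstance(set_a, MapSet) or not isinstance(set_b, MapSet):
            raise ValueError("dice similarity requires MapSet inputs")
        masks_a, masks_b = set_a.masks(), set_b.masks()
        sim = np.array([[dice(ma, mb) for mb in masks_b] for ma in masks_a])
        return sim, None
    if metric == "pearson":
        va = set_a.vectors() if isinstance(set_a, MapSet) else np.asarray(set_a, dtype=float)
        vb = set_b.vectors() if isinstance(set_b, MapSet) else np.asarray(set_b, dtype=float)
        if va.shape[1] != vb.shape[1]:
            raise ValueError("pattern lengths differ between the two sets")
        return _pearson_matrix(va, vb)
    raise ValueError(f"unknown metric {metric!r}")


def _greedy(sim: np.ndarray, order: np.ndarray, over_rows: bool) -> list[tuple[int, int]]:
    pairs = []
    taken = np.zeros(sim.shape[1] if over_rows else sim.shape[0], dtype=bool)
    for i in order:
        row = sim[i] if over_rows else sim[:, i]
        avail = np.flatnonzero(~taken)
        if avail.size == 0:
            break
        best = avail[np.argmax(row[avail])]
        if not np.isfinite(row[best]):
            continue  # no admissible partner left for this item
        taken[best] = True
        pairs.append((int(i), int(best)) if over_rows else (int(best), int(i)))
    return pairs


def exclusive_assign(sim: np.ndarray, n_orderings: int = 10000, seed=0) -> AssignmentResult:
    """Randomized-ordering greedy mutually exclusive assignment.

    The smaller dimension is permuted; each item in order takes its
    best-similarity unassigned partner. All orderings are enumerated when
    their factorial does not exceed ``n_orderings``; otherwise that many
    seeded random orderings are drawn. Entries of ``-inf`` mark inadmissible
    pairs and are never assigned. The ordering with the most pairs, then
    the highest average similarity, wins (first found on ties).
    """
    sim = np.asarray(sim, dtype=float)
    if sim.size == 0:
        raise ValueError("empty similarity matrix")
    if np.any(np.isnan(sim)):
        raise ValueError("similarity matrix contains NaN")
    n_a, n_b = sim.shape
    over_rows = n_a <= n_b
    n_small = min(n_a, n_b)
    if math.factorial(n_small) <= n_orderings:
        orderings = [np.array(p) for p in itertools.permutations(range(n_small))]
    else:
        rng = np.random.default_rng(seed)
        orderings = [rng.permutation(n_small) for _ in range(n_orderings)]
    best_pairs: list[tuple[int, int]] = []
    best_key = (-1, -np.inf)
    for order in orderings:
        pairs = _greedy(sim, order, over_rows)
        if not pairs:
            continue
        vals = np.array([sim[r, c] for r, c in pairs])
        key = (len(pairs), vals.mean())
        if key > best_key:
            best_key, best_pairs = key, pairs
    if not best_pairs:
        return AssignmentResult(
            pairs=[],
            similarities=np.array([]),
            mean_similarity=float("nan"),
            max_similarity=float("nan"),
            n_orderings_evaluated=len(orderings),
            similarity_full=sim,
        )
    vals = np.array([sim[r, c] for r, c in best_pairs])
    return AssignmentResult(
        pairs=sorted(best_pairs),
        similarities=vals,
        mean_similarity=float(vals.mean()),
        max_similarity=float(vals.max()),
        n_orderings_evaluated=len(orderings),
        similarity_full=sim,
    )


def brute_force_assign(sim: np.ndarray) -> float:
    """Testing oracle: exact optimum of the mean similarity over all
    complete one-to-one assignments (exhaustive permutation search)."""
    sim = np.asarray(sim, dtype=float)
    n_a, n_b = sim.shape
    best = -np.inf
    if n_a <= n_b:
        for cols in itertools.permutations(range(n_b), n_a):
            best = max(best, np.mean([sim[i, c] for i, c in enumerate(cols)]))
    else:
        for rows in itertools.permutations(range(n_a), n_b):
            best = max(best, np.mean([sim[r, j] for j, r in enumerate(rows)]))
    return float(best)


def dice_null_threshold(sim_full: np.ndarray, percentile: float = 95.0) -> float:
    """Permutation-null threshold: the stated percentile of the full
    components-by-templates similarity matrix (linear interpolation)."""
    return float(np.percentile(np.asarray(sim_full).ravel(), percentile))


def identify_networks(
    components: MapSet,
    templates: MapSet,
    n_orderings: int = 10000,
    seed=0,
    percentile: float = 95.0,
) -> AssignmentResult:
    """Assign component maps to network templates by Dice overlap.

    Builds the full Dice matrix (all components x all templates), derives
    the permutation-null threshold from its ``percentile``, and resolves the
    assignment with the randomized exclusive procedure. The mean Dice over
    assigned templates is significant when it exceeds the null threshold.
    """
    sim, _ = similarity_matrix(components, templates, metric="dice")
    result = exclusive_assign(sim.T, n_orderings=n_orderings, seed=seed)  # templates are smaller
    # exclusive_assign saw (templates x components); report as such
    result.null_threshold = dice_null_threshold(sim, percentile)
    return result


def match_states(
    D_a: np.ndarray,
    D_b: np.ndarray,
    alpha: float = 0.05,
    n_orderings: int = 10000,
    seed=0,
    positive_only: bool = True,
) -> AssignmentResult:
    """One-to-one cross-modal match of state connectivity patterns.

    Patterns are the columns of the (M, k) dictionaries. The pairwise
    Pearson matrix is tested at the Bonferroni-corrected level
    ``alpha / (k_a * k_b)``; non-significant pairs are inadmissible, and by
    default so are anticorrelated ones — a match asserts that two states
    describe the *same* connectivity pattern, which requires a positive
    correlation (``positive_only=False`` admits any significant pair). An
    empty assignment (no admissible pair anywhere) is a valid outcome.
    """
    D_a = np.asarray(D_a, dtype=float)
    D_b = np.asarray(D_b, dtype=float)
    if D_a.shape[0] != D_b.shape[0]:
        raise ValueError("state pattern lengths differ between modalities")
    r, p = _pearson_matrix(D_a.T, D_b.T)
    k_a, k_b = r.shape
    sig = p < alpha / (k_a * k_b)
    if positive_only:
        sig &= r > 0
    masked = np.where(sig, r, -np.inf)
    if not sig.any():
        return AssignmentResult(
            pairs=[],
            similarities=np.array([]),
            mean_similarity=float("nan"),
            max_similarity=float("nan"),
            n_orderings_evaluated=0,
            p_values=p,
            similarity_full=r,
        )
    result = exclusive_assign(masked, n_orderings=n_orderings, seed=seed)
    result.p_values = np.array([p[i, j] for i, j in result.pairs])
    result.similarity_full = r
    return result
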