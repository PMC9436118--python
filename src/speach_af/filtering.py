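"""Quality filtering of model sets and coordinate PCA of the ensemble.

Models generated from one mutated MSA form a *set* (15 by default); sets are
the unit of quality control.  Filtering pools the per-model quality scores
(MolProbity scores read from a CSV, or the built-in clash proxy), takes the
pooled median M and spread S, and discards every set whose mean score exceeds
M + S — misfolded sets score high as a group.  "Spread" is the sample
standard deviation of the pooled scores by default; standard-error-of-mean
semantics are available behind a flag.

The surviving ensemble is then analyzed by PCA of superposed Cα deviations
from the iteratively refined mean; experimental references can be projected
onto the model-derived landscape without contributing to the covariance.
Finally an automated surrogate for manual outlier inspection prunes models
whose robust (PC1, PC2) distance is extreme, refitting until a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from speach_af.metrics import ModelEnsemble, iterative_mean, kabsch
from speach_af.structures import StructureModel, infer_element

__all__ = [
    "ScoreTable",
    "PCAResult",
    "filter_sets",
    "FilterStats",
    "relative_mp",
    "clash_pairs",
    "clash_proxy_score",
    "ensemble_pca",
    "prune_outliers",
]


@dataclass
class ScoreTable:
    """Per-model quality scores: rows of (model_id, set_id, score)."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"model_id", "set_id", "score"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"score table needs columns {sorted(required)}")
        if self.df.empty:
            raise ValueError("empty score table")
        if not np.isfinite(self.df["score"]).all():
            raise ValueError("non-finite scores in table")

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str, float]]) -> "ScoreTable":
        return cls(pd.DataFrame(rows, columns=["model_id", "set_id", "score"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class FilterStats:
    median: float
    scale: float
    semantics: str
    threshold: float
    per_set_mean: dict[str, float]


def filter_sets(
    table: ScoreTable, semantics: str = "sd"
) -> tuple[list[str], list[str], FilterStats]:
    """Discard sets whose mean score exceeds pooled-median + spread.

    ``semantics="sd"`` (default): spread = sample standard deviation of all
    pooled model scores; ``"sem"``: standard error of the pooled mean.
    Returns ``(kept_set_ids, discarded_set_ids, stats)``; set order follows
    first appearance in the table.
    """
    df = table.df
    scores = df["score"].to_numpy(dtype=float)
    median = float(np.median(scores))
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    if semantics == "sd":
        scale = sd
    elif semantics == "sem":
        scale = sd / np.sqrt(len(scores))
    else:
        raise ValueError(f"unknown semantics {semantics!r} (use 'sd' or 'sem')")
    threshold = median + scale
    per_set_mean = {
        str(s): float(g["score"].mean())
        for s, g in df.groupby("set_id", sort=False)
    }
    if len(per_set_mean) == 1:
        warnings.warn("only one set in table; the filter cannot discard it", stacklevel=2)
        kept, discarded = list(per_set_mean), []
    else:
        kept = [s for s, m in per_set_mean.items() if m <= threshold]
        discarded = [s for s, m in per_set_mean.items() if m > threshold]
    return kept, discarded, FilterStats(median, scale, semantics, threshold, per_set_mean)


def relative_mp(score: float, min_score: float) -> float:
    """Relative MolProbity score (MP − MPmin) / MPmin; 0 at the minimum."""
    if min_score <= 0:
        raise ValueError(f"min_score must be > 0, got {min_score}")
    return (score - min_score) / min_score


# van der Waals radii (Å) for heavy elements seen in protein models
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}
_VDW_DEFAULT = 1.70


def clash_pairs(
    model: StructureModel, overlap_threshold: float = 0.4
) -> list[tuple[int, str, int, str, float]]:
    """Non-bonded steric overlaps: heavy-atom pairs from non-adjacent residues
    closer than ``r_vdw_i + r_vdw_j − overlap_threshold``.

    Returns ``(res_pos_i, atom_i, res_pos_j, atom_j, distance)`` tuples with
    1-based sequence positions, i < j.
    """
    coords, radii, res_pos, names = [], [], [], []
    for i, res in enumerate(model.residues, start=1):
        for aname, x, y, z in res.atoms:
            coords.append((x, y, z))
            radii.append(_VDW.get(infer_element(aname), _VDW_DEFAULT))
            res_pos.append(i)
            names.append(aname)
    coords = np.array(coords)
    radii = np.array(radii)
    res_pos = np.array(res_pos)
    tree = cKDTree(coords)
    max_r = 2 * radii.max() - overlap_threshold
    out = []
    for a, b in tree.query_pairs(r=max_r):
        if abs(res_pos[a] - res_pos[b]) <= 1:  # same or adjacent residue: bonded
            continue
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < radii[a] + radii[b] - overlap_threshold:
            if res_pos[a] > res_pos[b] or (res_pos[a] == res_pos[b] and a > b):
                a, b = b, a
            out.append((int(res_pos[a]), names[a], int(res_pos[b]), names[b], d))
    return sorted(out)


def clash_proxy_score(model: StructureModel, overlap_threshold: float = 0.4) -> float:
    """Steric-clash count per 1000 heavy atoms (a clashscore-style proxy).

    This is NOT MolProbity: it counts van-der-Waals overlaps only, with no
    Ramachandran, rotamer or CaBLAM terms.  Use the ScoreTable CSV reader to
    plug in scores from an external validation tool instead.
    """
    n_atoms = sum(len(r.atoms) for r in model.residues)
    if n_atoms == 0:
        raise ValueError("model has no atoms")
    return len(clash_pairs(model, overlap_threshold)) * 1000.0 / n_atoms


@dataclass
class PCAResult:
    """PCA of superposed Cα deviations from the iterative mean structure.

    ``components`` are orthonormal rows over the flattened (3L) coordinate
    space; eigenvalues are coordinate variances (mean squared deviation along
    each component) in descending order, and their sum equals the total
    variance about the mean.  Component signs are fixed so each component's
    largest-magnitude entry is positive.
    """

    mean_coords: np.ndarray  # (L, 3)
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # (k, 3L)
    projections: dict[str, np.ndarray]  # model_id -> (k,)
    ref_projections: dict[str, np.ndarray] = field(default_factory=dict)
    total_variance: float = 0.0
    # aligned Cα coordinates retained so outlier pruning can refit (including
    # re-running the iterative superposition) without re-reading models
    _coords: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ref_coords: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def variance_share(self, k: int | None = None) -> np.ndarray:
        ev = self.eigenvalues[: k or len(self.eigenvalues)]
        return ev / self.eigenvalues.sum()

    def validate(self, rtol: float = 1e-6) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues not sorted descending")
        gram = self.components @ self.components.T
        if np.abs(gram - np.eye(len(gram))).max() > 1e-8:
            raise ValueError("components not orthonormal")
        if not np.isclose(self.eigenvalues.sum(), self.total_variance, rtol=rtol):
            raise ValueError("trace not conserved: sum(eigenvalues) != total variance")

    def to_frame(self, k: int = 2) -> pd.DataFrame:
        rows = [
            {"model_id": mid, "kind": "model", **{f"PC{i+1}": p[i] for i in range(k)}}
            for mid, p in self.projections.items()
        ]
        rows += [
            {"model_id": rid, "kind": "reference", **{f"PC{i+1}": p[i] for i in range(k)}}
            for rid, p in self.ref_projections.items()
        ]
        return pd.DataFrame(rows)


def _fit_pca(
    coords: dict[str, np.ndarray],
    ref_coords: dict[str, np.ndarray],
) -> PCAResult:
    """Iterative-mean superposition + SVD of flattened Cα deviations.

    References are superposed onto the fitted mean and projected but do not
    enter the covariance.
    """
    ids = list(coords)
    mean, aligned = iterative_mean(np.stack([coords[i] for i in ids]))
    n = len(ids)
    X = (aligned - mean[None]).reshape(n, -1)
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = svals**2 / n
    components = Vt
    # deterministic sign: largest-magnitude entry of each component positive
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
    projections = {mid: components @ X[i] for i, mid in enumerate(ids)}
    ref_projections = {}
    aligned_refs = {}
    for rid, rc in ref_coords.items():
        R, t = kabsch(rc, mean)
        rc_aligned = rc @ R.T + t
        aligned_refs[rid] = rc_aligned
        ref_projections[rid] = components @ (rc_aligned - mean).ravel()
    total_var = float((X**2).sum() / n)
    return PCAResult(
        mean_coords=mean,
        eigenvalues=eigenvalues,
        components=components,
        projections=projections,
        ref_projections=ref_projections,
        total_variance=total_var,
        _coords={mid: aligned[i] for i, mid in enumerate(ids)},
        _ref_coords=aligned_refs,
    )


def ensemble_pca(
    ensemble: ModelEnsemble,
    references: list[StructureModel] | None = None,
    positions: list[int] | None = None,
    ref_positions: list[int] | None = None,
    refs_in_covariance: bool = False,
) -> PCAResult:
    """PCA of the ensemble's superposed Cα coordinates.

    All models are superposed onto the iteratively refined mean; the
    covariance of the flattened deviations is eigen-decomposed.  References
    are superposed onto the same mean and projected, but by default do not
    contribute to the fitted covariance (set ``refs_in_covariance`` to pool
    them in).  ``positions`` / ``ref_positions`` select matching 1-based
    residue subsets when references differ in indexing.
    """
    if len(ensemble.models) < 3:
        raise ValueError("PCA needs at least 3 conformations")
    ids = [m.model_id for m in ensemble.models]
    stack = ensemble.ca_stack(positions)
    coords = {mid: stack[i] for i, mid in enumerate(ids)}
    refs = references or []
    rp = ref_positions or positions
    ref_coords = {r.model_id: r.ca_coords(rp) for r in refs}
    if refs_in_covariance and ref_coords:
        result = _fit_pca({**coords, **ref_coords}, {})
        # references were pooled into the fit; still expose them separately
        for rid in ref_coords:
            result.ref_projections[rid] = result.projections.pop(rid)
            result._ref_coords[rid] = result._coords.pop(rid)
        return result
    return _fit_pca(coords, ref_coords)


def prune_outliers(
    pca: PCAResult,
    k: float = 3.5,
    manual_exclude: list[str] | None = None,
    max_rounds: int = 50,
) -> tuple[list[str], list[str], PCAResult]:
    """Automated surrogate for manual PC1/PC2 outlier inspection.

    Iteratively removes models whose robust distance in the (PC1, PC2) plane
    — per-axis median/MAD standardization (MAD scaled to the normal s.d.),
    Euclidean in robust z — exceeds ``k``, refits the PCA on the survivors,
    and repeats until nothing is removed.  ``manual_exclude`` model ids are
    removed up front.  Every removal is recorded in the returned list.
    """
    coords = dict(pca._coords)
    removed: list[str] = []
    for mid in manual_exclude or []:
        if mid in coords:
            coords.pop(mid)
            removed.append(mid)
    if len(coords) < 4:
        raise ValueError("need at least 4 conformations to prune outliers")
    current = _fit_pca(coords, pca._ref_coords)
    for _ in range(max_rounds):
        ids = list(current.projections)
        P = np.stack([current.projections[i][:2] for i in ids])
        med = np.median(P, axis=0)
        mad = np.median(np.abs(P - med), axis=0) * 1.4826
        # fall back to s.d. (or unit) on degenerate axes so z stays finite
        sd = P.std(axis=0)
        scale = np.where(mad > 1e-12, mad, np.where(sd > 1e-12, sd, 1.0))
        z = (P - med) / scale
        dist = np.sqrt((z**2).sum(axis=1))
        offenders = [ids[i] for i in np.nonzero(dist > k)[0]]
        if not offenders:
            break
        if len(offenders) >= len(ids):
            raise ValueError("outlier pruning would remove every model")
        for mid in offenders:
            coords.pop(mid)
            removed.append(mid)
        if len(coords) < 3:
            raise ValueError("outlier pruning left fewer than 3 models")
        current = _fit_pca(coords, pca._ref_coords)
    kept = list(current.projections)
    return kept, removed, current
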