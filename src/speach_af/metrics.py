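"""Structural comparison over model ensembles.

Implements least-squares Cα superposition (Kabsch), ensemble RMSF about an
iteratively refined mean, and the TM-score with a *fixed* residue
correspondence — appropriate here because every comparison is between models
of the same sequence (or against an experimental structure of it), so no
alignment search is needed.  Experimental references with missing density are
handled through an explicit :class:`Correspondence` built by author-residue-
number intersection, optionally excluding regions (e.g. an unraveled helix).

TM-score of aligned pairs ``i`` with distances ``d_i`` after optimal
superposition, normalized by the reference length ``L``::

    TM = (1/L) * sum_i 1 / (1 + (d_i / d0(L))^2),   d0(L) = 1.24 (L-15)^(1/3) - 1.8

``d0`` is floored at 0.5 Å.  The maximization over superpositions follows the
standard scheme: superpositions seeded from contiguous fragments at several
lengths, each refined by iteratively re-superposing on the residue subset
within a distance cutoff until the subset is stable; the best score over all
seeds is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from speach_af.structures import StructureModel

__all__ = [
    "Correspondence",
    "ModelEnsemble",
    "kabsch",
    "superpose",
    "iterative_mean",
    "rmsf",
    "tm_d0",
    "tm_score",
    "tm_landscape",
]


@dataclass(frozen=True)
class Correspondence:
    """Paired 1-based sequence positions ``(pos_in_A, pos_in_B)`` used for
    superposition and scoring; strictly increasing in both coordinates."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("correspondence must be strictly increasing in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_positions(self) -> list[int]:
        return [a for a, _ in self.pairs]

    @property
    def b_positions(self) -> list[int]:
        return [b for _, b in self.pairs]

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        return cls(tuple((i, i) for i in range(1, n + 1)))

    @classmethod
    def by_author_number(
        cls,
        model_a: StructureModel,
        model_b: StructureModel,
        exclude_numbers: set[int] | None = None,
    ) -> "Correspondence":
        """Match residues by author number; positions lacking a Cα on either
        side, and excluded author numbers, are dropped."""
        exclude = exclude_numbers or set()
        idx_a = {
            r.number: i
            for i, r in enumerate(model_a.residues, start=1)
            if r.has_atom("CA") and r.number not in exclude
        }
        pairs = []
        for j, r in enumerate(model_b.residues, start=1):
            if r.number in idx_a and r.has_atom("CA") and r.number not in exclude:
                pairs.append((idx_a[r.number], j))
        return cls(tuple(pairs))


@dataclass
class ModelEnsemble:
    """Models grouped by mutation set and run seed, with optional quality scores."""

    models: list[StructureModel]
    set_of: dict[str, str] = field(default_factory=dict)
    seed_of: dict[str, int] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.models)

    def model(self, model_id: str) -> StructureModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    def validate(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate model_ids in ensemble")
        missing = [i for i in ids if i not in self.set_of]
        if missing:
            raise ValueError(f"models without a set_id: {missing[:5]}")

    def ca_stack(self, positions: list[int] | None = None) -> np.ndarray:
        """(n_models, L, 3) Cα coordinate stack over shared positions."""
        return np.stack([m.ca_coords(positions) for m in self.models])


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R @ x + t ≈ target.

    Least-squares over the given point pairs; reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ mc
    return R, t


def superpose(
    mobile: StructureModel, target: StructureModel, corr: Correspondence | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares Cα superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)``; the transform maps mobile
    coordinates as ``R @ x + t``.  Requires at least 3 non-collinear pairs.
    """
    if corr is None:
        if len(mobile) != len(target):
            raise ValueError("models differ in length; provide a Correspondence")
        corr = Correspondence.identity(len(mobile))
    if len(corr) < 3:
        raise ValueError(f"need >= 3 correspondence pairs, got {len(corr)}")
    xa = mobile.ca_coords(corr.a_positions)
    xb = target.ca_coords(corr.b_positions)
    for pts in (xa, xb):
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) coordinates: superposition is ill-defined")
    R, t = kabsch(xa, xb)
    d = xa @ R.T + t - xb
    rmsd = float(np.sqrt((d**2).sum(axis=1).mean()))
    return R, t, rmsd


def _superpose_stack(stack: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(stack)
    for i, coords in enumerate(stack):
        R, t = kabsch(coords, ref)
        out[i] = coords @ R.T + t
    return out


def iterative_mean(
    stack: np.ndarray, tol: float = 1e-4, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively refined mean structure of a (n, L, 3) Cα stack.

    All conformations are superposed on the first, averaged, re-superposed on
    the mean, and so on until the mean moves less than ``tol`` Å (max
    displacement) — the standard ensemble-averaging fixed point.
    Returns ``(mean (L,3), aligned stack (n,L,3))``.
    """
    ref = stack[0].copy()
    aligned = stack
    for _ in range(max_iter):
        aligned = _superpose_stack(stack, ref)
        mean = aligned.mean(axis=0)
        if np.abs(mean - ref).max() < tol:
            return mean, aligned
        ref = mean
    return ref, aligned


def rmsf(
    ensemble: ModelEnsemble | list[StructureModel],
    positions: list[int] | None = None,
) -> np.ndarray:
    """Per-residue root-mean-square fluctuation (Å) about the iterative mean.

    ``rmsf_i = sqrt(mean_models |x_i - <x_i>|^2)`` on Cα after all models are
    superposed onto the iteratively refined mean structure.
    """
    models = ensemble.models if isinstance(ensemble, ModelEnsemble) else ensemble
    if len(models) < 2:
        raise ValueError("rmsf needs at least 2 models")
    stack = np.stack([m.ca_coords(positions) for m in models])
    mean, aligned = iterative_mean(stack)
    dev = aligned - mean[None]
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def tm_d0(length: int, d0_min: float = 0.5) -> float:
    """TM-score distance scale d0 for a normalization length, floored at 0.5 Å."""
    if length <= 15:
        return d0_min
    return max(d0_min, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_sum(xa: np.ndarray, xb: np.ndarray, R: np.ndarray, t: np.ndarray, d0: float) -> float:
    d2 = ((xa @ R.T + t - xb) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d2 / d0**2)).sum())


def _refine_seed(
    xa: np.ndarray, xb: np.ndarray, seed: slice, d0: float, max_iter: int = 40
) -> tuple[float, np.ndarray, np.ndarray]:
    """Iterative-cutoff refinement from one fragment seed; returns the best
    (tm_sum, R, t) seen along the way."""
    R, t = kabsch(xa[seed], xb[seed])
    best = (_tm_sum(xa, xb, R, t, d0), R, t)
    prev_sel: np.ndarray | None = None
    for _ in range(max_iter):
        d = np.sqrt(((xa @ R.T + t - xb) ** 2).sum(axis=1))
        d_cut = d0
        sel = d < d_cut
        while sel.sum() < 3:
            d_cut += 0.5
            sel = d < d_cut
        if prev_sel is not None and np.array_equal(sel, prev_sel):
            break
        prev_sel = sel
        R, t = kabsch(xa[sel], xb[sel])
        s = _tm_sum(xa, xb, R, t, d0)
        if s > best[0]:
            best = (s, R, t)
    return best


def tm_score(
    model: StructureModel,
    reference: StructureModel,
    corr: Correspondence | None = None,
    norm_length: int | None = None,
) -> float:
    """TM-score of ``model`` against ``reference`` over a fixed correspondence.

    Normalized by the reference length by default (TM-score is asymmetric:
    swap arguments or pass ``norm_length`` for the other normalization).
    Requires a correspondence of at least 15 pairs (domain of the d0 formula).
    """
    if corr is None:
        if len(model) != len(reference):
            raise ValueError("models differ in length; provide a Correspondence")
        corr = Correspondence.identity(len(model))
    n = len(corr)
    if n < 15:
        raise ValueError(f"correspondence too short for TM-score: {n} < 15")
    L = norm_length if norm_length is not None else len(reference)
    d0 = tm_d0(L)
    xa = model.ca_coords(corr.a_positions)
    xb = reference.ca_coords(corr.b_positions)

    best = 0.0
    frag_lengths = []
    fl = n
    while fl >= 4:
        frag_lengths.append(fl)
        fl //= 2
    for L_frag in frag_lengths:
        stride = max(1, L_frag // 2)
        starts = list(range(0, n - L_frag + 1, stride))
        if starts[-1] != n - L_frag:
            starts.append(n - L_frag)
        for s in starts:
            score, _, _ = _refine_seed(xa, xb, slice(s, s + L_frag), d0)
            if score > best:
                best = score
    return best / L


def tm_landscape(
    ensemble: ModelEnsemble,
    ref_a: StructureModel,
    ref_b: StructureModel,
    corr_a: Correspondence | None = None,
    corr_b: Correspondence | None = None,
    corr_ab: Correspondence | None = None,
) -> pd.DataFrame:
    """TM-score of every model against two references, one row per model.

    Columns: ``model_id, set_id, tm_vs_a, tm_vs_b`` plus ``relative_mp`` when
    the ensemble carries quality scores.  The reference-vs-reference score
    (the dashed iso-line of the landscape plots) is stored in
    ``df.attrs["tm_ref_ab"]``.
    """
    rows = []
    for m in ensemble.models:
        rows.append(
            {
                "model_id": m.model_id,
                "set_id": ensemble.set_of.get(m.model_id, ""),
                "tm_vs_a": tm_score(m, ref_a, corr_a),
                "tm_vs_b": tm_score(m, ref_b, corr_b),
            }
        )
    df = pd.DataFrame(rows)
    if ensemble.scores:
        from speach_af.filtering import relative_mp

        mp_min = min(ensemble.scores.values())
        df["relative_mp"] = [
            relative_mp(ensemble.scores[m.model_id], mp_min) for m in ensemble.models
        ]
    df.attrs["tm_ref_ab"] = tm_score(ref_a, ref_b, corr_ab)
    return df
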