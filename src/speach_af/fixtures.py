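"""Synthetic inputs with the statistical structure the pipeline assumes.

The central fixture is a *hinge toy*: a two-domain protein whose
conformations vary along one or two rigid-body hinge modes, mimicking the
open↔closed transitions the pipeline is meant to sample.  Two antiparallel
arms of Cα-spaced backbone (N, CA, C, O plus a Cβ stub) are joined by a short
linker; arm B rotates about a hinge axis by an opening angle (mode 1) and
optionally out of plane (mode 2), and isotropic Gaussian noise is added to
every atom afterwards.  At small opening angles alternating Cβ stubs on the
two arms face each other ~3.2 Å apart, giving a genuine heavy-atom contact
interface that disappears as the hinge opens — so contact scanning, clash
counting, RMSF, PCA mode recovery and the mock folding backend all have
ground truth to recover.

Geometry is idealized (3.8 Å Cα spacing, stub side chains); these are
statistical stand-ins, not proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from speach_af.contact_scan import MutationSet
from speach_af.filtering import ScoreTable
from speach_af.msa import A3MAlignment
from speach_af.structures import Residue, StructureModel

__all__ = [
    "HingeToySpec",
    "hinge_model",
    "make_hinge_ensemble",
    "interface_positions",
    "make_synthetic_a3m",
    "make_score_table",
]

# residue name cycle for toy sequences; alanine-free so alanization is visible
_TOY_CYCLE = [
    "LEU", "LYS", "VAL", "GLU", "ILE", "PHE", "ASP", "ARG", "THR", "SER",
    "GLY", "ASN", "GLN", "HIS", "TRP", "TYR", "MET", "PRO", "CYS", "LEU",
]

_CA_SPACING = 3.8
_ARM_GAP = 6.4  # z offset between the two arms in the closed state
_CB_LEN = 1.6  # facing Cβ stubs end up 6.4 − 2×1.6 = 3.2 Å apart when closed


@dataclass(frozen=True)
class HingeToySpec:
    """Two-domain hinge toy: geometry and sampling parameters.

    angle_range / angle_range2 are hinge-angle ranges in degrees (opening and
    out-of-plane modes); models draw angles uniformly from them.  noise_sd is
    the isotropic per-atom Gaussian noise in Å applied after rigid placement.
    """

    n_per_domain: int = 20
    linker_length: int = 3
    angle_range: tuple[float, float] = (15.0, 45.0)
    angle_range2: tuple[float, float] = (-20.0, 20.0)
    noise_sd: float = 0.3
    modes: int = 1

    def __post_init__(self):
        lo, hi = self.angle_range
        if not (0.0 < lo < hi < 180.0):
            raise ValueError(f"angle_range must be within (0, 180): {self.angle_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.modes not in (1, 2):
            raise ValueError("modes must be 1 or 2")
        if self.n_per_domain < 4:
            raise ValueError("n_per_domain must be >= 4")

    @property
    def n_residues(self) -> int:
        return 2 * self.n_per_domain + self.linker_length

    @property
    def hinge_point(self) -> np.ndarray:
        return np.array([_CA_SPACING * self.n_per_domain + 2.8, 0.0, _ARM_GAP / 2])

    @property
    def closed_angle(self) -> float:
        """Opening angle (degrees) at which the arms are parallel (toy closed state)."""
        return 0.0


def _rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.radians(degrees) * axis).as_matrix()


def _backbone(ca: np.ndarray, u: np.ndarray, cb_z: float | None) -> list[tuple[str, np.ndarray]]:
    y = np.array([0.0, 1.0, 0.0])
    atoms = [
        ("N", ca - 1.45 * u),
        ("CA", ca),
        ("C", ca + 1.0 * u),
        ("O", ca + 1.0 * u + 1.23 * y),
    ]
    if cb_z is not None:
        atoms.append(("CB", ca + np.array([0.0, 0.0, cb_z])))
    return atoms


def _linker_backbone(ca: np.ndarray) -> list[tuple[str, np.ndarray]]:
    # linker runs roughly along z; N/C/O are splayed in y so that closely
    # stacked linker residues never produce steric overlaps in the toy
    return [
        ("N", ca + np.array([0.0, 1.3, 0.3])),
        ("CA", ca),
        ("C", ca + np.array([0.0, -1.3, 0.3])),
        ("O", ca + np.array([0.0, -2.5, 0.3])),
    ]


def _closed_conformation(spec: HingeToySpec) -> list[list[tuple[str, np.ndarray]]]:
    """Atom layout at opening angle 0, residue by residue (N→C)."""
    n, l = spec.n_per_domain, spec.linker_length
    residues = []
    ux = np.array([1.0, 0.0, 0.0])
    # arm A along +x at z=0; Cβ points up toward arm B on even x-index
    for i in range(1, n + 1):
        ca = np.array([_CA_SPACING * i, 0.0, 0.0])
        cb_z = _CB_LEN if i % 2 == 0 else -_CB_LEN
        residues.append(_backbone(ca, ux, cb_z))
    # linker climbs from arm A end to arm B end, offset outward in +x
    for j in range(1, l + 1):
        ca = np.array([_CA_SPACING * n + 2.8, 0.0, _ARM_GAP * j / (l + 1)])
        residues.append(_linker_backbone(ca))
    # arm B antiparallel along -x at z=ARM_GAP; Cβ points down on even x-index
    for k in range(1, n + 1):
        xi = n - k + 1
        ca = np.array([_CA_SPACING * xi, 0.0, _ARM_GAP])
        cb_z = -_CB_LEN if xi % 2 == 0 else _CB_LEN
        residues.append(_backbone(ca, -ux, cb_z))
    return residues


def interface_positions(spec: HingeToySpec) -> list[int]:
    """1-based positions whose Cβ stubs face the other arm in the closed state."""
    n, l = spec.n_per_domain, spec.linker_length
    pos = [i for i in range(1, n + 1) if i % 2 == 0]
    pos += [n + l + k for k in range(1, n + 1) if (n - k + 1) % 2 == 0]
    return sorted(pos)


def _toy_plddt(spec: HingeToySpec, i: int) -> float:
    """Confident domains, mid-confidence linker, floppy 2-residue termini."""
    n, l = spec.n_per_domain, spec.linker_length
    total = spec.n_residues
    if i <= 2 or i > total - 2:
        return 50.0
    if n < i <= n + l:
        return 70.0
    return 88.0


def hinge_model(
    spec: HingeToySpec,
    theta: float,
    phi: float = 0.0,
    noise_rng: np.random.Generator | None = None,
    model_id: str = "hinge",
) -> StructureModel:
    """One toy conformation at opening angle ``theta`` (degrees) and
    out-of-plane angle ``phi``; optional per-atom Gaussian noise."""
    layout = _closed_conformation(spec)
    hinge = spec.hinge_point
    # arm B carries both modes: opening about y (arms separate in z) and a
    # lateral sweep about z (arm B moves in y).  The two displacement fields
    # live in orthogonal coordinate planes, so they stay orthogonal even
    # after least-squares superposition redistributes motion to arm A.
    R = _rotation(np.array([0.0, 1.0, 0.0]), theta)
    if phi:
        R = _rotation(np.array([0.0, 0.0, 1.0]), phi) @ R
    n, l = spec.n_per_domain, spec.linker_length
    moving_start = n + l + 1  # arm B swings; the linker stays with arm A
    residues = []
    for i, atom_list in enumerate(layout, start=1):
        atoms = []
        for name, xyz in atom_list:
            p = xyz
            if i >= moving_start:
                p = R @ (p - hinge) + hinge
            if noise_rng is not None and spec.noise_sd > 0:
                p = p + noise_rng.normal(0.0, spec.noise_sd, 3)
            atoms.append((name, float(p[0]), float(p[1]), float(p[2])))
        residues.append(
            Residue(
                number=i,
                name=_TOY_CYCLE[(i - 1) % len(_TOY_CYCLE)],
                atoms=atoms,
                plddt=_toy_plddt(spec, i),
            )
        )
    return StructureModel(model_id=model_id, residues=residues)


def make_hinge_ensemble(
    spec: HingeToySpec,
    n_models: int,
    seed: int,
    angles: list[float] | None = None,
    id_prefix: str = "toy",
    return_angles: bool = False,
):
    """Sample toy conformations: hinge angles uniform over the spec ranges
    (or fixed via ``angles``), isotropic coordinate noise on every atom.
    Deterministic under ``seed``.  With ``return_angles`` the realized
    ``(theta, phi)`` draws are returned alongside the models, so recovery
    tests can compare against the exact generated variance."""
    rng = np.random.default_rng(seed)
    if angles is None:
        thetas = rng.uniform(*spec.angle_range, size=n_models)
    else:
        if len(angles) != n_models:
            raise ValueError("len(angles) must equal n_models")
        thetas = np.asarray(angles, dtype=float)
    if spec.modes == 2:
        phis = rng.uniform(*spec.angle_range2, size=n_models)
    else:
        phis = np.zeros(n_models)
    models = []
    for i in range(n_models):
        models.append(
            hinge_model(
                spec,
                float(thetas[i]),
                float(phis[i]),
                noise_rng=rng,
                model_id=f"{id_prefix}_{i:03d}",
            )
        )
    if return_angles:
        return models, thetas, phis
    return models


_AA = "ACDEFGHIKLMNPQRSTVWY"


def toy_query_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA.replace("A", ""))) for _ in range(length))


def make_synthetic_a3m(
    query_length: int,
    depth: int,
    identity: float = 0.7,
    gap_fraction: float = 0.1,
    insertion_rate: float = 0.05,
    seed: int = 0,
    query: str | None = None,
    colabfold_header: bool = False,
) -> A3MAlignment:
    """Random a3m with controllable gap and insertion structure.

    Homologs match the query with probability ``identity`` per match column,
    carry '-' with probability ``gap_fraction``, and gain 1-3 lowercase
    insertion letters after a column with probability ``insertion_rate``.
    Satisfies match-column conservation by construction; deterministic under
    ``seed``.
    """
    for name, v in (("identity", identity), ("gap_fraction", gap_fraction),
                    ("insertion_rate", insertion_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    if query is None:
        query = toy_query_sequence(query_length, rng)
    if len(query) != query_length:
        raise ValueError("query length mismatch")
    entries: list[tuple[str, str]] = [("query", query)]
    for s in range(1, depth):
        chars = []
        for c in query:
            if rng.random() < gap_fraction:
                chars.append("-")
            elif rng.random() < identity:
                chars.append(c)
            else:
                chars.append(rng.choice(list(_AA)))
            if rng.random() < insertion_rate:
                chars.extend(rng.choice(list(_AA.lower())) for _ in range(rng.integers(1, 4)))
        entries.append((f"seq{s}", "".join(chars)))
    preamble = [f"#{query_length}\t1"] if colabfold_header else []
    aln = A3MAlignment(entries=entries, preamble=preamble)
    aln.validate()
    return aln


def make_score_table(
    sets: list[str],
    base_mean: float = 1.75,
    base_sd: float = 0.08,
    outlier_sets: list[str] | None = None,
    outlier_shift: float = 0.0,
    models_per_set: int = 15,
    seed: int = 0,
) -> ScoreTable:
    """Gaussian per-model quality scores with optional shifted outlier sets.

    Defaults put the bulk of scores in ~[1.6, 1.9] the way MolProbity scores
    of mostly-well-folded predicted models behave; ``outlier_sets`` (must be
    a subset of ``sets``) are shifted upward by ``outlier_shift``.
    """
    outlier_sets = outlier_sets or []
    unknown = set(outlier_sets) - set(sets)
    if unknown:
        raise ValueError(f"outlier_sets not in sets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for set_id in sets:
        shift = outlier_shift if set_id in outlier_sets else 0.0
        for m in range(models_per_set):
            score = rng.normal(base_mean + shift, base_sd)
            rows.append((f"{set_id}_m{m:02d}", set_id, float(score)))
    return ScoreTable.from_rows(rows)
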