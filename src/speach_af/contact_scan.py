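"""Contact scanning: choose which residues to alanize.

The systematic mode trims the low-confidence termini off the model (both ends
are truncated where pLDDT falls below the mean over all residues), tiles the
remaining region with fixed-length windows (11 residues by default), and for
each window tabulates every residue pair (one inside the window, one outside)
whose closest heavy atoms lie within the contact cutoff (4 Å by default).
Partners too close in sequence to the window (within 4 residues by default)
are omitted so that local secondary structure is not destabilized.

The targeted mode instead takes two user-defined residue groups (e.g. the
N- and C-terminal halves of a transporter) and returns the residues mediating
inter-group contacts — or an explicit residue list passed through verbatim.

All positions here are 1-based sequence indices into the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from speach_af.structures import StructureModel

__all__ = [
    "ScanConfig",
    "MutationSet",
    "scan_region",
    "enumerate_windows",
    "window_contacts",
    "targeted_set",
    "scan_model",
]

MutateSide = Literal["both", "window-only", "partners-only"]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the systematic window scan.

    window_length: residues per window (the scan unit).
    contact_cutoff: heavy-atom distance defining a contact, Å.  4 Å spans
        polar and ionic interactions including water-mediated ones.
    sequence_exclusion: partners within this many residues of the window in
        primary sequence are omitted.
    stride: window step; defaults to window_length (non-overlapping tiling).
    mutate_side: which pair members enter the mutation set.
    """

    window_length: int = 11
    contact_cutoff: float = 4.0
    sequence_exclusion: int = 4
    stride: int | None = None
    mutate_side: MutateSide = "both"

    def __post_init__(self):
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")
        if self.sequence_exclusion < 0:
            raise ValueError("sequence_exclusion must be >= 0")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else self.window_length


@dataclass
class MutationSet:
    """A named set of 1-based query positions to mutate, with provenance."""

    set_id: str
    positions: tuple[int, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = tuple(sorted(set(int(p) for p in self.positions)))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def empty(self) -> bool:
        return len(self.positions) == 0

    def to_json(self) -> dict:
        return {
            "set_id": self.set_id,
            "positions": list(self.positions),
            "provenance": self.provenance,
        }

    @classmethod
    def from_json(cls, d: dict) -> "MutationSet":
        return cls(
            set_id=d["set_id"],
            positions=tuple(d["positions"]),
            provenance=d.get("provenance", {}),
        )


def scan_region(model: StructureModel) -> tuple[int, int]:
    """Trim low-confidence termini: first/last position with pLDDT >= mean.

    Only the ends are truncated; internal dips below the mean are kept.
    Returns an inclusive 1-based ``(start, end)``.
    """
    plddt = model.plddt_array()
    mean = float(plddt.mean())
    ok = plddt >= mean
    if not ok.any():
        raise ValueError(
            f"model {model.model_id}: no residue reaches the mean pLDDT "
            f"({mean:.2f}) — degenerate model"
        )
    start = int(np.argmax(ok)) + 1
    end = int(len(ok) - np.argmax(ok[::-1]))
    return start, end


def enumerate_windows(
    region: tuple[int, int], config: ScanConfig | None = None
) -> list[tuple[int, int]]:
    """Tile ``region`` (inclusive, 1-based) with windows, N- to C-terminal.

    The final window is re-anchored at ``end - window_length + 1`` so the
    region is covered exactly with no short trailing window; a region shorter
    than one window yields a single window spanning it.
    """
    config = config or ScanConfig()
    start, end = region
    if start > end:
        raise ValueError(f"invalid region {region}")
    w = config.window_length
    if end - start + 1 <= w:
        return [(start, end)]
    windows = []
    pos = start
    while pos + w - 1 <= end:
        windows.append((pos, pos + w - 1))
        pos += config.effective_stride
    if windows[-1][1] < end:
        last = (end - w + 1, end)
        if last != windows[-1]:
            windows.append(last)
    return windows


def _heavy_atom_table(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """All heavy-atom coordinates and their residue 1-based sequence indices."""
    coords = []
    res_idx = []
    for i, res in enumerate(model.residues, start=1):
        c = res.coords()
        coords.append(c)
        res_idx.append(np.full(len(c), i))
    return np.vstack(coords), np.concatenate(res_idx)


def _contact_pairs(
    model: StructureModel,
    group_a: set[int],
    group_b: set[int],
    cutoff: float,
) -> set[tuple[int, int]]:
    """Residue pairs (a in group_a, b in group_b) with min heavy-atom distance <= cutoff."""
    coords, res_idx = _heavy_atom_table(model)
    mask_a = np.isin(res_idx, list(group_a))
    mask_b = np.isin(res_idx, list(group_b))
    if not mask_a.any() or not mask_b.any():
        return set()
    tree_b = cKDTree(coords[mask_b])
    idx_a = res_idx[mask_a]
    idx_b = res_idx[mask_b]
    pairs = set()
    neighbor_lists = tree_b.query_ball_point(coords[mask_a], r=cutoff)
    for k, neighbors in enumerate(neighbor_lists):
        for j in neighbors:
            pairs.add((int(idx_a[k]), int(idx_b[j])))
    return pairs


def window_contacts(
    model: StructureModel,
    window: tuple[int, int],
    config: ScanConfig | None = None,
    set_id: str | None = None,
) -> MutationSet:
    """Tabulate the contact residues of one window.

    A pair (i in window, j outside) qualifies when the minimum over heavy-atom
    pairs of their distance is <= ``contact_cutoff`` and j is more than
    ``sequence_exclusion`` residues away from every window position.  The
    returned set contains, per ``config.mutate_side``, the window members
    and/or partners of qualifying pairs.  A set with no qualifying pair is
    returned empty (callers exclude it from mutagenesis).
    """
    config = config or ScanConfig()
    start, end = window
    n = len(model.residues)
    if not (1 <= start <= end <= n):
        raise ValueError(f"window {window} out of range for model of length {n}")
    window_set = set(range(start, end + 1))
    outside = {
        j
        for j in range(1, n + 1)
        if j not in window_set
        and min(abs(j - w) for w in (start, end)) > config.sequence_exclusion
    }
    # distance to the window interval: positions between start and end are in
    # the window itself; outside it the closest window residue is an endpoint
    pairs = _contact_pairs(model, window_set, outside, config.contact_cutoff)
    members: set[int] = set()
    for i, j in pairs:
        if config.mutate_side in ("both", "window-only"):
            members.add(i)
        if config.mutate_side in ("both", "partners-only"):
            members.add(j)
    return MutationSet(
        set_id=set_id or f"win_{start:04d}_{end:04d}",
        positions=tuple(sorted(members)),
        provenance={"mode": "window", "window": [start, end]},
    )


def scan_model(
    model: StructureModel, config: ScanConfig | None = None
) -> tuple[list[MutationSet], list[MutationSet]]:
    """Full systematic scan: region → windows → contact sets.

    Returns ``(emitted, empty)``: non-empty mutation sets in N→C window
    order, and the empty (contact-free, excluded) ones for the log.
    """
    config = config or ScanConfig()
    region = scan_region(model)
    emitted, empty = [], []
    for window in enumerate_windows(region, config):
        mset = window_contacts(model, window, config)
        (empty if mset.empty else emitted).append(mset)
    return emitted, empty


def targeted_set(
    model: StructureModel,
    group_a: list[int] | None = None,
    group_b: list[int] | None = None,
    cutoff: float = 4.0,
    positions: list[int] | None = None,
    set_id: str = "targeted",
) -> MutationSet:
    """Targeted mutation set: interface contacts between two groups, or an
    explicit residue list (``positions``) passed through verbatim.

    In interface mode the result is every residue of either group that
    participates in an inter-group heavy-atom contact within ``cutoff``.
    """
    if positions is not None:
        n = len(model.residues)
        bad = [p for p in positions if not (1 <= p <= n)]
        if bad:
            raise ValueError(f"positions out of range 1..{n}: {bad}")
        return MutationSet(
            set_id=set_id, positions=tuple(positions), provenance={"mode": "list"}
        )
    if group_a is None or group_b is None:
        raise ValueError("provide either positions= or both group_a and group_b")
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap at positions {sorted(set_a & set_b)[:5]}")
    pairs = _contact_pairs(model, set_a, set_b, cutoff)
    members = {i for i, _ in pairs} | {j for _, j in pairs}
    return MutationSet(
        set_id=set_id,
        positions=tuple(sorted(members)),
        provenance={
            "mode": "interface",
            "group_a": sorted(set_a),
            "group_b": sorted(set_b),
            "cutoff": cutoff,
        },
    )
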