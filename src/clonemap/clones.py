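"""DBSCAN clone detection and clone statistics.

A clone is a set of same-color cells in which every member has another
member within ε = 50 µm (density connectivity); cells with no same-color
neighbor within ε are singlets and are excluded from clone statistics.
With minPts = 2 the core/border distinction of DBSCAN collapses, so the
partition equals single-linkage connected components at cutoff ε per color
and is fully deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .core_model import CellRecord, ImageStack, StudyTable

SINGLET = "SINGLET"


@dataclass(frozen=True)
class CloneParams:
    epsilon: float = 50.0    # µm neighborhood radius
    min_cells: int = 2       # minimum cells per clone
    metric: str = "3d"       # "3d" or "xy" coordinates

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_cells < 2:
            raise ValueError("min_cells must be ≥ 2")
        if self.metric not in ("3d", "xy"):
            raise ValueError("metric must be '3d' or 'xy'")


@dataclass
class CloneSet:
    """Clone partition of one stack: assignment, member lists, imaged volume."""

    assignment: dict[str, str] = field(default_factory=dict)  # cell_id -> clone_id | SINGLET
    clones: dict[str, list[CellRecord]] = field(default_factory=dict)
    imaged_volume: float = 0.0  # mm³
    n_cells: int = 0

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_singlets(self) -> int:
        return sum(1 for v in self.assignment.values() if v == SINGLET)

    def clone_sizes(self) -> list[int]:
        return sorted(len(m) for m in self.clones.values())


def detect_clones(stack: ImageStack, params: CloneParams = CloneParams()) -> CloneSet:
    """Run DBSCAN independently per reporter color; noise points are singlets."""
    out = CloneSet(imaged_volume=stack.volume_mm3, n_cells=len(stack.cells))
    by_color: dict[str, list[int]] = {}
    for i, c in enumerate(stack.cells):
        by_color.setdefault(c.color, []).append(i)
    pos = stack.positions(params.metric)
    for color, idx in sorted(by_color.items()):
        pts = pos[idx]
        if len(pts) == 1:
            out.assignment[stack.cells[idx[0]].cell_id] = SINGLET
            continue
        labels = DBSCAN(eps=params.epsilon,
                        min_samples=params.min_cells).fit(pts).labels_
        for local, lab in zip(idx, labels):
            cell = stack.cells[local]
            if lab < 0:
                out.assignment[cell.cell_id] = SINGLET
            else:
                clone_id = f"{stack.image_id}:{color}:{lab}"
                out.assignment[cell.cell_id] = clone_id
                out.clones.setdefault(clone_id, []).append(cell)
    return out


def clone_density(cloneset: CloneSet) -> float:
    """Clones per mm³ of imaged volume (singlets excluded)."""
    if cloneset.imaged_volume <= 0:
        raise ValueError("imaged volume must be positive")
    return cloneset.n_clones / cloneset.imaged_volume


def singlet_fraction(cloneset: CloneSet) -> float:
    """Fraction of labeled cells with no same-color neighbor within ε."""
    if cloneset.n_cells == 0:
        raise ValueError("empty stack")
    return cloneset.n_singlets / cloneset.n_cells


@dataclass
class CloneSizeSummary:
    mean_size: Optional[float]
    sizes: list[int]
    n_clones: int


def clone_size_summary(clonesets: Sequence[CloneSet]) -> CloneSizeSummary:
    """Unweighted mean over all clones of a (condition, timepoint) group."""
    sizes: list[int] = []
    for cs in clonesets:
        sizes.extend(len(m) for m in cs.clones.values())
    if not sizes:
        return CloneSizeSummary(mean_size=None, sizes=[], n_clones=0)
    return CloneSizeSummary(mean_size=float(np.mean(sizes)),
                            sizes=sorted(sizes), n_clones=len(sizes))


def proliferation_index(members: Sequence[CellRecord]) -> Fraction:
    """Ki-67⁺ members / clone size, as an exact rational fraction."""
    if not members:
        raise ValueError("clone has no members")
    for c in members:
        if c.ki67 is None:
            raise ValueError(f"cell {c.cell_id} has no Ki-67 flag")
    positive = sum(1 for c in members if c.ki67)
    return Fraction(positive, len(members))


def clone_table(stack: ImageStack, cloneset: CloneSet) -> pd.DataFrame:
    """Tidy per-clone table: clone_id, color, size, proliferation index
    (NaN when any member lacks a Ki-67 flag)."""
    rows = []
    for clone_id, members in sorted(cloneset.clones.items()):
        try:
            pi = float(proliferation_index(members))
        except ValueError:
            pi = np.nan
        rows.append({"image_id": stack.image_id, "mouse_id": stack.mouse_id,
                     "condition": stack.condition, "timepoint": stack.timepoint,
                     "clone_id": clone_id, "color": members[0].color,
                     "size": len(members), "proliferation_index": pi})
    return pd.DataFrame(rows, columns=["image_id", "mouse_id", "condition",
                                       "timepoint", "clone_id", "color",
                                       "size", "proliferation_index"])


def group_summary(study: StudyTable,
                  params: CloneParams = CloneParams()) -> pd.DataFrame:
    """Clone statistics averaged per hemisphere-condition per mouse, then the
    group rows (one per condition × timepoint) as unweighted mouse means."""
    per_mouse: dict[tuple[str, str, str], dict] = {}
    group_sizes: dict[tuple[str, str], list[int]] = {}
    for s in study.stacks:
        cs = detect_clones(s, params)
        key = (s.mouse_id, s.condition, s.timepoint)
        rec = per_mouse.setdefault(key, {"n_clones": 0, "volume": 0.0,
                                         "sizes": [], "n_cells": 0,
                                         "n_singlets": 0})
        rec["n_clones"] += cs.n_clones
        rec["volume"] += cs.imaged_volume
        rec["sizes"].extend(len(m) for m in cs.clones.values())
        rec["n_cells"] += cs.n_cells
        rec["n_singlets"] += cs.n_singlets
        group_sizes.setdefault((s.condition, s.timepoint), []).extend(
            len(m) for m in cs.clones.values())
    rows = []
    for (mouse, cond, tp), rec in sorted(per_mouse.items()):
        rows.append({
            "level": "mouse", "mouse_id": mouse, "condition": cond,
            "timepoint": tp, "n_clones": rec["n_clones"],
            "clones_per_mm3": rec["n_clones"] / rec["volume"] if rec["volume"] else np.nan,
            "mean_clone_size": float(np.mean(rec["sizes"])) if rec["sizes"] else np.nan,
            "singlet_fraction": rec["n_singlets"] / rec["n_cells"] if rec["n_cells"] else np.nan,
        })
    frame = pd.DataFrame(rows)
    for (cond, tp), sizes in sorted(group_sizes.items()):
        sub = frame[(frame["condition"] == cond) & (frame["timepoint"] == tp)]
        rows.append({
            "level": "group", "mouse_id": "", "condition": cond,
            "timepoint": tp, "n_clones": int(sub["n_clones"].sum()),
            "clones_per_mm3": float(sub["clones_per_mm3"].mean()),
            "mean_clone_size": float(np.mean(sizes)) if sizes else np.nan,
            "singlet_fraction": float(sub["singlet_fraction"].mean()),
        })
    return pd.DataFrame(rows, columns=["level", "mouse_id", "condition",
                                       "timepoint", "n_clones",
                                       "clones_per_mm3", "mean_clone_size",
                                       "singlet_fraction"])
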