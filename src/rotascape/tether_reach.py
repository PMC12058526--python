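"""Tether-reach analysis: which swivel angles keep catalytic sites in range.

The carrier-protein domain (ACP) is attached to the static wing near its
anchor residue and delivers substrates on a phosphopantetheine arm with a
finite reach budget (default 80 A).  As the condensing wing swivels by the
landscape angle alpha about the inter-wing pivot axis, the catalytic sites
it carries sweep circles; a site is *accessible* at a given alpha when the
anchor-to-site distance is within the reach budget.  The scan reports the
distance-vs-alpha profile per site, the maximal contiguous accessible
alpha-intervals, and their intersection -- the alpha range in which the arm
can engage every site at once.

Geometry is the toy version of the real measurement: only the alpha
rotation is scanned by default (beta = gamma = 0), matching how the
distance profiles are usually plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rotation_core import axis_angle_matrix, wrap_angle

DEFAULT_MAX_REACH = 80.0  # Angstrom; estimated maximum stretch of the Ppant arm


@dataclass
class TetherModel:
    """Anchor/site coordinates (A), pivot frame, and the reach budget."""

    anchor: np.ndarray
    sites: dict[str, np.ndarray]
    pivot_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pivot_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    max_reach: float = DEFAULT_MAX_REACH

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.pivot_point = np.asarray(self.pivot_point, dtype=float)
        self.pivot_axis = np.asarray(self.pivot_axis, dtype=float)
        self.sites = {k: np.asarray(v, dtype=float) for k, v in self.sites.items()}
        n = np.linalg.norm(self.pivot_axis)
        if abs(n - 1.0) >= 1e-9:
            raise ValueError(f"pivot_axis must be unit length (|axis| = {n:.9g})")
        if self.max_reach <= 0:
            raise ValueError("max_reach must be positive")


def _resolve_selector(structure, selector: str):
    """'chain/resnum/atom' -> list of matching gemmi atoms' positions."""
    try:
        chain_want, res_want, atom_want = selector.split("/")
    except ValueError:
        raise ValueError(f"selector {selector!r} must be 'chain/resnum/atom'") from None
    matches = []
    for model in structure:
        for chain in model:
            if chain.name != chain_want:
                continue
            for residue in chain:
                if str(residue.seqid.num) != res_want:
                    continue
                for atom in residue:
                    if atom.name == atom_want:
                        pos = atom.pos
                        matches.append((f"{chain.name}/{residue.seqid.num}/{atom.name}",
                                        np.array([pos.x, pos.y, pos.z])))
        break  # first model only
    return matches


def load_sites(structure_path, anchor_selector: str, site_selectors: dict[str, str],
               pivot_point=(0.0, 0.0, 0.0), pivot_axis=(0.0, 0.0, 1.0),
               max_reach: float = DEFAULT_MAX_REACH) -> TetherModel:
    """Build a TetherModel from a PDB or mmCIF structure.

    Selectors are ``chain/resnum/atomname`` strings (e.g. ``A/2112/CA`` for
    the anchor C-alpha, ``A/161/SG`` for a catalytic cysteine thiol); each
    must resolve to exactly one atom.
    """
    import gemmi

    structure = gemmi.read_structure(str(structure_path))

    def one(selector: str) -> np.ndarray:
        matches = _resolve_selector(structure, selector)
        if len(matches) == 0:
            raise ValueError(f"no atom matched selector {selector!r}")
        if len(matches) > 1:
            raise ValueError(
                f"selector {selector!r} is ambiguous: matched "
                + ", ".join(name for name, _ in matches)
            )
        return matches[0][1]

    return TetherModel(
        anchor=one(anchor_selector),
        sites={name: one(sel) for name, sel in site_selectors.items()},
        pivot_point=np.asarray(pivot_point, dtype=float),
        pivot_axis=np.asarray(pivot_axis, dtype=float),
        max_reach=max_reach,
    )


def distance_at_alpha(model: TetherModel, site: str, alpha: float) -> float:
    """Anchor-to-site distance (A) after swivelling the site by alpha.

    The site rides the condensing body, rotated by alpha about the pivot
    axis through the pivot point; the anchor stays on the static body.
    Periodic in alpha with period 360.
    """
    if site not in model.sites:
        raise KeyError(f"unknown site {site!r}; have {sorted(model.sites)}")
    rot = axis_angle_matrix(model.pivot_axis, wrap_angle(alpha))
    moved = model.pivot_point + rot @ (model.sites[site] - model.pivot_point)
    return float(np.linalg.norm(moved - model.anchor))


def _accessible_intervals(alphas: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    """Maximal contiguous accessible alpha-intervals, merged across the +/-180 seam."""
    if not flags.any():
        return []
    if flags.all():
        return [(-180.0, 180.0)]
    runs = []
    start = None
    for a, f in zip(alphas, flags):
        if f and start is None:
            start = a
        elif not f and start is not None:
            runs.append((start, prev))
            start = None
        prev = a
    if start is not None:
        runs.append((start, alphas[-1]))
    # the alpha axis is a circle: merge a run ending at the last sample with
    # one starting at the first
    if len(runs) > 1 and flags[0] and flags[-1]:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])
    return runs


def reach_scan(model: TetherModel, step: float = 1.0) -> dict:
    """Sample distances over alpha in (-180, 180] and find accessible ranges.

    Returns a dict with a tidy ``table`` (DataFrame of alpha, one distance
    and one accessible flag per site), per-site ``intervals``, and the
    ``engage_all`` intersection intervals where every site is in reach.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = max(1, int(round(360.0 / step)))
    alphas = -180.0 + step * np.arange(1, n + 1)

    axis, pivot, anchor = model.pivot_axis, model.pivot_point, model.anchor
    cols = {"alpha": alphas}
    flags_all = np.ones(n, dtype=bool)
    intervals = {}
    rots = np.stack([axis_angle_matrix(axis, a) for a in alphas])
    for name, site in model.sites.items():
        moved = pivot + np.einsum("nij,j->ni", rots, site - pivot)
        dist = np.linalg.norm(moved - anchor, axis=1)
        acc = dist <= model.max_reach
        cols[f"dist_{name}"] = dist
        cols[f"accessible_{name}"] = acc
        intervals[name] = _accessible_intervals(alphas, acc)
        flags_all &= acc
    cols["accessible_all"] = flags_all
    return {
        "table": pd.DataFrame(cols),
        "intervals": intervals,
        "engage_all": _accessible_intervals(alphas, flags_all),
        "max_reach": model.max_reach,
        "step": step,
    }
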