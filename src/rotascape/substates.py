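"""Recombine symmetry-expanded per-monomer classes into dimeric substates.

Focused classification of C2 symmetry-expanded particles labels each
monomer independently: the condensing wing by its ACP engagement (five
functional groups) and the modifying wing by whether its Psi-domains are
resolved.  Converting the two expanded copies of each particle back into
one dimer gives a dimeric substate: an *unordered* pair of condensing
labels -- 5 groups give 5*6/2 = 15 combinations -- crossed with a *sided*
modifying combination (both / one side / the other side / neither resolved,
4 combinations), for 15 x 4 = 60 substates in total.

The asymmetry is deliberate: condensing pairs are counted unordered while
modifying combinations keep track of which side of the canonical condensing
pair carries the resolved Psi-domain.  ``collapse_sides=True`` gives the
symmetric 3-combination alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

from .landscape import build_landscape, compute_orientations

#: the five condensing-wing functional groups (ACP engagement states)
CONDENSING_LABELS = ("ACP-KS", "ACP-MAT", "ACP-in-transition", "no-ACP", "dynamic-MAT")
#: the two modifying-wing states (Psi-domain resolution)
MODIFYING_LABELS = ("psi-resolved", "psi-unresolved")

MODIFYING_COMBOS = ("both", "side-A-only", "side-B-only", "neither")
MODIFYING_COMBOS_COLLAPSED = ("both", "one-side", "neither")


def _generic_labels(k: int, prefix: str = "group") -> tuple[str, ...]:
    if k == len(CONDENSING_LABELS):
        return CONDENSING_LABELS
    return tuple(f"{prefix}{i + 1}" for i in range(k))


def enumerate_condensing_combos(k: int, labels=None) -> list[tuple[str, str]]:
    """All unordered pairs (with repetition) of k condensing groups: k(k+1)/2."""
    if k < 1:
        raise ValueError("need at least one monomer group")
    labels = tuple(labels) if labels is not None else _generic_labels(k)
    if len(labels) != k:
        raise ValueError(f"got {len(labels)} labels for k={k}")
    return list(combinations_with_replacement(sorted(labels), 2))


def enumerate_modifying_combos(collapse_sides: bool = False) -> list[str]:
    """Sided Psi-domain combinations: both / side-A-only / side-B-only / neither.

    With ``collapse_sides`` the two one-sided combinations merge, giving the
    symmetric 3-member set.
    """
    return list(MODIFYING_COMBOS_COLLAPSED if collapse_sides else MODIFYING_COMBOS)


@dataclass(frozen=True)
class DimericSubstate:
    """One dimer-level functional state."""

    condensing_pair: tuple[str, str]   # canonical lexicographic order
    modifying_combo: str

    def __post_init__(self):
        if tuple(sorted(self.condensing_pair)) != tuple(self.condensing_pair):
            raise ValueError("condensing_pair must be in lexicographic order")
        if self.modifying_combo not in MODIFYING_COMBOS + MODIFYING_COMBOS_COLLAPSED:
            raise ValueError(f"unknown modifying combo {self.modifying_combo!r}")

    @property
    def id(self) -> str:
        return f"{self.condensing_pair[0]}+{self.condensing_pair[1]}|{self.modifying_combo}"


def enumerate_full_substates(k: int, labels=None,
                             collapse_sides: bool = False) -> list[DimericSubstate]:
    """Cartesian product of condensing pairs and modifying combos: k(k+1)/2 x 4."""
    return [
        DimericSubstate(condensing_pair=pair, modifying_combo=combo)
        for pair in enumerate_condensing_combos(k, labels)
        for combo in enumerate_modifying_combos(collapse_sides)
    ]


def _check_labels(cond: str, mod: str, condensing_labels, side: str) -> None:
    if cond is None or mod is None or str(cond) in ("nan", "None") or str(mod) in ("nan", "None"):
        raise ValueError(f"missing class label on {side} expansion copy")
    if cond not in condensing_labels:
        raise ValueError(f"unknown condensing label {cond!r} (expected one of {condensing_labels})")
    if mod not in MODIFYING_LABELS:
        raise ValueError(f"unknown modifying label {mod!r} (expected one of {MODIFYING_LABELS})")


def assign_substate(labels_copy0: tuple[str, str], labels_copy1: tuple[str, str],
                    condensing_labels=CONDENSING_LABELS) -> DimericSubstate:
    """Combine the (condensing, modifying) labels of a particle's two C2 copies.

    The condensing labels are sorted into the canonical pair; side A is the
    copy whose condensing label sorts first, and the modifying combination
    is keyed to that side.  When both condensing labels are equal the sides
    are interchangeable and the copy with a resolved Psi-domain (if exactly
    one) is taken as side A, keeping the assignment deterministic and
    invariant under swapping the input copies.
    """
    c0, m0 = labels_copy0
    c1, m1 = labels_copy1
    _check_labels(c0, m0, condensing_labels, "first")
    _check_labels(c1, m1, condensing_labels, "second")

    # rank resolved < unresolved so the equal-condensing tie-break is total
    sides = sorted([(c0, MODIFYING_LABELS.index(m0), m0),
                    (c1, MODIFYING_LABELS.index(m1), m1)])
    (ca, _, ma), (cb, _, mb) = sides
    resolved_a = ma == "psi-resolved"
    resolved_b = mb == "psi-resolved"
    if resolved_a and resolved_b:
        combo = "both"
    elif resolved_a:
        combo = "side-A-only"
    elif resolved_b:
        combo = "side-B-only"
    else:
        combo = "neither"
    return DimericSubstate(condensing_pair=(ca, cb), modifying_combo=combo)


def assign_substates_table(table) -> "pd.Series":
    """Substate id per dimer for a C2-expanded, fully labelled particle table.

    Expects the paired table to carry ``class_cond`` and ``class_mod``
    columns and both expansion copies of every particle.  Returns a Series
    indexed by particle_id.
    """
    import pandas as pd

    df = table.df
    for col in ("class_cond", "class_mod"):
        if col not in df.columns:
            raise ValueError(f"table has no {col!r} column; run focused classification first")
    ids = {}
    for pid, group in df.groupby("particle_id", sort=False):
        if len(group) != 2:
            raise ValueError(
                f"particle {pid!r} has {len(group)} expansion copies, expected 2"
            )
        rows = group.sort_values("expansion_index")
        labels = [(r.class_cond, r.class_mod) for r in rows.itertuples()]
        ids[pid] = assign_substate(labels[0], labels[1]).id
    return pd.Series(ids, name="substate_id")


def substate_landscape(table, substate: DimericSubstate, bin_width: float = 2.0,
                       smooth_sigma: float = 1.0, canonicalize_flag: bool = True):
    """Landscape restricted to the particles of one dimeric substate.

    Orientations come from expansion copy 0 of each matching dimer (the two
    copies are C2-equivalent; canonicalization makes the choice immaterial).
    """
    assignments = assign_substates_table(table)
    matching = set(assignments.index[assignments == substate.id])
    if not matching:
        raise ValueError(f"no particles assigned to substate {substate.id!r}")
    mask = table.df["particle_id"].isin(matching) & (table.df["expansion_index"] == 0)
    sub = type(table)(table.df[mask].reset_index(drop=True),
                      provenance=dict(table.provenance), optics=table.optics)
    orients = compute_orientations(sub, canonicalize_flag=canonicalize_flag)
    return build_landscape(orients, bin_width=bin_width, smooth_sigma=smooth_sigma)
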