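"""Read, pair and write per-particle metadata from two focused refinements.

Each rigid body of the complex is refined separately from the same particle
stack, so every particle ends up with two ZYZ Euler triples.  This module
joins the two STAR tables on the particle identifier (the image name, which
focused refinements of one stack preserve) into a single
:class:`ParticleTable` whose rows carry both triples side by side.

Column layout of the paired DataFrame: ``particle_id``, ``micrograph``,
``rot_mod``/``tilt_mod``/``psi_mod``, ``rot_cond``/``tilt_cond``/``psi_cond``,
``expansion_index`` (0/1 for the two C2 copies), optional ``class_mod`` /
``class_cond`` / ``optics_group``, plus any passthrough columns prefixed
``extra_mod_`` / ``extra_cond_``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._star import read_star, write_star

logger = logging.getLogger("rotascape")

#: default RELION column names; override via ``column_map``
DEFAULT_COLUMNS = {
    "id": "rlnImageName",
    "micrograph": "rlnMicrographName",
    "rot": "rlnAngleRot",
    "tilt": "rlnAngleTilt",
    "psi": "rlnAnglePsi",
    "class": "rlnClassNumber",
    "optics": "rlnOpticsGroup",
}

ANGLE_COLUMNS = ("rot", "tilt", "psi")


class ColumnError(KeyError):
    """A required STAR column is absent."""


@dataclass
class ParticleTable:
    """Paired particle metadata plus provenance of its source files."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    optics: pd.DataFrame | None = None  # passed through untouched on write

    def __len__(self) -> int:
        return len(self.df)

    def euler_mod(self) -> np.ndarray:
        """(n, 3) array of (rot, tilt, psi) for the modifying body."""
        return self.df[["rot_mod", "tilt_mod", "psi_mod"]].to_numpy(float)

    def euler_cond(self) -> np.ndarray:
        return self.df[["rot_cond", "tilt_cond", "psi_cond"]].to_numpy(float)


def _particles_block(blocks, path):
    if "particles" in blocks:
        return blocks["particles"], blocks.get("optics")
    # legacy single-block layout: take the first loop block
    for name, tab in blocks.items():
        if isinstance(tab, pd.DataFrame) and name != "optics":
            return tab, blocks.get("optics")
    raise ValueError(f"{path}: no particles data block found")


def read_particle_star(path, column_map: dict | None = None) -> ParticleTable:
    """Read one body's refinement STAR into a half-table.

    Half-table columns: ``particle_id``, ``micrograph``, ``rot``, ``tilt``,
    ``psi``, optional ``class_label`` / ``optics_group``, and passthrough
    ``extra_*`` columns.  Angles are degrees, read verbatim (no wrapping).
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    blocks = read_star(path)
    particles, optics = _particles_block(blocks, path)

    required = [cols["id"], cols["rot"], cols["tilt"], cols["psi"]]
    missing = [c for c in required if c not in particles.columns]
    if missing:
        raise ColumnError(f"{path}: missing required column(s) {missing}")

    if len(particles) == 0:
        warnings.warn(f"{path}: particles block is empty", stacklevel=2)

    out = pd.DataFrame({
        "particle_id": particles[cols["id"]].astype(str),
        "rot": particles[cols["rot"]].astype(float),
        "tilt": particles[cols["tilt"]].astype(float),
        "psi": particles[cols["psi"]].astype(float),
    })
    if cols["micrograph"] in particles.columns:
        out["micrograph"] = particles[cols["micrograph"]].astype(str)
    if cols["class"] in particles.columns:
        out["class_label"] = particles[cols["class"]]
    if cols["optics"] in particles.columns:
        out["optics_group"] = particles[cols["optics"]]
    handled = {cols[k] for k in ("id", "micrograph", "rot", "tilt", "psi", "class", "optics")}
    for col in particles.columns:
        if col not in handled:
            out[f"extra_{col}"] = particles[col]
    # expansion_index: symmetry-expanded stacks repeat each image name once
    # per asymmetric unit; number repeats in file order
    out["expansion_index"] = out.groupby("particle_id").cumcount()
    table = ParticleTable(out, provenance={"path": str(path), "columns": cols}, optics=optics)
    return table


def pair_refinements(table_mod: ParticleTable, table_cond: ParticleTable,
                     join_key: str = "particle_id") -> ParticleTable:
    """Inner-join the two half-tables so each row carries both Euler triples.

    The join is on ``(join_key, expansion_index)``; unmatched counts on each
    side are logged and recorded in provenance.  Input row order does not
    affect the resulting pair set.
    """
    if len(table_mod) == 0 or len(table_cond) == 0:
        raise ValueError("cannot pair: at least one input table is empty")
    keys = [join_key, "expansion_index"]
    for name, tab in (("modifying", table_mod), ("condensing", table_cond)):
        dup = tab.df.duplicated(subset=keys)
        if dup.any():
            raise ValueError(
                f"{name} table has {int(dup.sum())} duplicate {keys} entries; "
                "cannot join unambiguously"
            )

    mod = table_mod.df.rename(columns=lambda c: c if c in keys else f"{c}_mod")
    cond = table_cond.df.rename(columns=lambda c: c if c in keys else f"{c}_cond")
    merged = mod.merge(cond, on=keys, how="inner")
    if len(merged) == 0:
        raise ValueError(
            "no shared identifiers between the two refinements -- are these "
            "focused refinements of the same particle stack?"
        )
    n_unmatched_mod = len(table_mod) - len(merged)
    n_unmatched_cond = len(table_cond) - len(merged)
    if n_unmatched_mod or n_unmatched_cond:
        logger.info("pairing dropped %d modifying / %d condensing unmatched rows",
                    n_unmatched_mod, n_unmatched_cond)

    merged = merged.rename(columns={
        "micrograph_mod": "micrograph",
        "class_label_mod": "class_mod",
        "class_label_cond": "class_cond",
        "optics_group_mod": "optics_group",
    }).drop(columns=["micrograph_cond", "optics_group_cond"], errors="ignore")
    prov = {
        "mod": table_mod.provenance,
        "cond": table_cond.provenance,
        "n_unmatched_mod": n_unmatched_mod,
        "n_unmatched_cond": n_unmatched_cond,
    }
    return ParticleTable(merged.reset_index(drop=True), provenance=prov,
                         optics=table_mod.optics)


def write_particle_star(table: ParticleTable, path, body: str = "condensing",
                        column_map: dict | None = None) -> Path:
    """Write the selected body's angles as a reconstruction-ready STAR file.

    Angle columns are the chosen body's triples copied verbatim; passthrough
    (``extra_``) columns and any optics block are preserved so external
    reconstruction tools can consume the file directly.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty particle table")
    if body not in ("modifying", "condensing"):
        raise ValueError(f"body must be 'modifying' or 'condensing', got {body!r}")
    suffix = "_mod" if body == "modifying" else "_cond"
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = table.df

    def pick(name: str):
        # paired tables carry per-body suffixes; half-tables the bare name
        for cand in (name + suffix, name):
            if cand in df.columns:
                return df[cand]
        return None

    out = pd.DataFrame({cols["id"]: df["particle_id"]})
    if "micrograph" in df.columns:
        out[cols["micrograph"]] = df["micrograph"]
    for key in ANGLE_COLUMNS:
        out[cols[key]] = pick(key).astype(float)
    for cand in (f"class{suffix}", "class_label"):
        if cand in df.columns:
            out[cols["class"]] = df[cand]
            break
    if "optics_group" in df.columns:
        out[cols["optics"]] = df["optics_group"]
    for col in df.columns:
        if col.startswith("extra_") and (col.endswith(suffix) or "_" not in col[6:]):
            base = col[len("extra_"):]
            base = base[:-len(suffix)] if base.endswith(suffix) else base
            out[base] = df[col]

    blocks = {}
    if table.optics is not None:
        blocks["optics"] = table.optics
    blocks["particles"] = out
    write_star(blocks, path)
    return Path(path)
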