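"""Charged-group identification and salt-bridge / hydrogen-bond analysis.

A protonation hypothesis names which basic sites carry a formal +1
charge (arginine guanidinium, lysine ammonium, free N-terminus) and
whether the phosphate is deprotonated (−1) or neutral.  For each model
structure the minimum heavy-atom distance between the phosphate oxygens
and each basic site is measured and classified with the conventional
4 Å criterion:

- distance < 4 Å, phosphate −1, partner charged  -> salt bridge
- distance < 4 Å, phosphate neutral, partner charged -> ionic hydrogen bond
- distance < 4 Å, partner not formally charged -> (non-ionic) hydrogen bond
- distance ≥ 4 Å -> no interaction

Distances are measured between heavy atoms only (terminal phosphate
oxygens; ammonium NZ; the three guanidinium nitrogens NE/NH1/NH2; the
backbone N of residue 1), avoiding dependence on hydrogen placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .ccs import Structure

#: site kind -> PDB atom names holding the formal charge (heavy atoms).
SITE_ATOMS = {
    "lys_ammonium": ("NZ",),
    "arg_guanidinium": ("NE", "NH1", "NH2"),
    "n_terminus": ("N",),
}

#: terminal phosphate oxygens under both common PDB naming conventions.
PHOSPHATE_ATOMS = ("O1P", "O2P", "O3P", "OP1", "OP2", "OP3")

DEFAULT_THRESHOLD = 4.0  # Å, strict "<"

CLASSIFICATIONS = ("salt_bridge", "ionic_hydrogen_bond", "hydrogen_bond", "none")


@dataclass(frozen=True)
class BasicSite:
    """One potential interaction partner of the phosphate group."""

    name: str  # e.g. "R6", "K11", "NT"
    residue: int  # 1-based residue index
    kind: str  # key of SITE_ATOMS
    charged: bool  # formally protonated under this hypothesis

    def __post_init__(self) -> None:
        if self.kind not in SITE_ATOMS:
            raise ValueError(f"unknown site kind {self.kind!r}")


@dataclass(frozen=True)
class ProtonationPattern:
    """A protonation hypothesis for a doubly charged phosphopeptide ion."""

    name: str
    sites: tuple[BasicSite, ...]
    phosphosite: int
    phosphate_charge: int  # -1 (deprotonated) or 0 (neutral)

    @property
    def total_charge(self) -> int:
        return sum(1 for s in self.sites if s.charged) + self.phosphate_charge


def charged_atoms(s: Structure, pattern: ProtonationPattern) -> dict[str, np.ndarray]:
    """Coordinates of the charge-bearing heavy atoms of every group.

    Returns a map from group name ("POx" for the phosphate, else the
    basic-site name) to an (n, 3) coordinate array.
    """
    out: dict[str, np.ndarray] = {}
    mask = (s.res_ids == pattern.phosphosite) & np.isin(
        s.atom_names, PHOSPHATE_ATOMS
    )
    if not mask.any():
        raise ValueError(
            f"no phosphate oxygens found on residue {pattern.phosphosite}"
        )
    out["POx"] = s.coords[mask]
    for site in pattern.sites:
        names = SITE_ATOMS[site.kind]
        m = (s.res_ids == site.residue) & np.isin(s.atom_names, names)
        if not m.any():
            raise ValueError(
                f"site {site.name}: no atoms {names} on residue {site.residue}"
            )
        out[site.name] = s.coords[m]
    return out


def min_group_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance over all cross pairs of two atom sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty atom set")
    return float(cdist(np.atleast_2d(a), np.atleast_2d(b)).min())


def classify(
    distance: float,
    phosphate_charge: int,
    partner_charged: bool,
    threshold: float = DEFAULT_THRESHOLD,
) -> str:
    """Classify one phosphate/basic-site contact by the distance criterion."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if distance >= threshold:
        return "none"
    if not partner_charged:
        return "hydrogen_bond"
    return "salt_bridge" if phosphate_charge == -1 else "ionic_hydrogen_bond"


@dataclass(frozen=True)
class InteractionRecord:
    """Phosphate-to-basic-site proximity in one structure."""

    structure: str
    site: str
    min_distance: float
    classification: str
    contact: bool  # the printed Y/N cell


@dataclass
class InteractionMatrix:
    """Structures x basic sites contact matrix (printed-table shape)."""

    pattern: ProtonationPattern
    records: list[InteractionRecord]
    threshold: float = DEFAULT_THRESHOLD

    @property
    def structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.structure, None)
        return list(seen)

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.pattern.sites]

    def contact_frame(self) -> pd.DataFrame:
        """Y/N cells as a boolean DataFrame (rows = structures)."""
        df = pd.DataFrame(False, index=self.structures, columns=self.site_names)
        for r in self.records:
            df.loc[r.structure, r.site] = r.contact
        return df

    def distance_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.nan, index=self.structures, columns=self.site_names)
        for r in self.records:
            df.loc[r.structure, r.site] = r.min_distance
        return df

    def to_text(self) -> str:
        """Delimited Y/N + distance table."""
        lines = ["structure\t" + "\t".join(self.site_names)]
        dist = self.distance_frame()
        yn = self.contact_frame()
        for s in self.structures:
            cells = [
                f"{'Y' if yn.loc[s, c] else 'N'} ({dist.loc[s, c]:.2f} A)"
                for c in self.site_names
            ]
            lines.append(s + "\t" + "\t".join(cells))
        return "\n".join(lines)


def interaction_table(
    structures: list[Structure],
    pattern: ProtonationPattern,
    threshold: float = DEFAULT_THRESHOLD,
) -> InteractionMatrix:
    """Distance analysis of model structures under one hypothesis.

    One row per structure, one column per basic site; a cell is Y iff
    the minimum phosphate-to-site heavy-atom distance is below the
    threshold.
    """
    if not structures:
        raise ValueError("no structures given")
    records = []
    for s in structures:
        groups = charged_atoms(s, pattern)
        for site in pattern.sites:
            d = min_group_distance(groups["POx"], groups[site.name])
            cls = classify(d, pattern.phosphate_charge, site.charged, threshold)
            records.append(
                InteractionRecord(s.label, site.name, d, cls, d < threshold)
            )
    return InteractionMatrix(pattern, records, threshold)
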