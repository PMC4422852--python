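"""Theoretical ECD/CID fragment ions, peak assignment and cleavage coverage.

Electron capture dissociation of an [M + 2H]2+ peptide ion produces
N-terminal c-type and C-terminal z-type fragments (plus the surviving
charge-reduced species).  This module generates the theoretical ion
ladder for a (phospho)peptide, matches it against a centroided peak
list, converts matched intensities into the relative-abundance statistic
(percent of total fragment ion abundance, charge-reduced species
included), and maps which backbone cleavage sites are covered by
assigned fragments — the "gap" pattern that diagnoses noncovalent
phosphate/side-chain interactions.

Cleavage sites are 1-based: site ``s`` lies between residues ``s`` and
``s + 1``; an N-terminal fragment at site ``s`` comprises residues
``1..s`` and a C-terminal fragment of length ``j`` covers site
``N − j``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from pyteomics import mass as _pmass

from .constants import ACETYL, CO, H, H2O, H3PO4, NH2, NH3, PHOSPHO, PROTON

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.calculate_mass(composition=comp)
    for aa, comp in _pmass.std_aa_comp.items()
    if len(aa) == 1 and aa.isupper()
}

#: Modification name -> monoisotopic delta (Da).
MOD_DELTAS = {"phospho": PHOSPHO, "acetyl": ACETYL}

#: Residues that can carry a phosphate group.
PHOSPHORYLATABLE = frozenset("STY")

#: Ion species the assignment engine understands.  ``c_rad``/``z_rad``
#: are the radical species (c•, z•); ``z_prime`` is z• + H (z′).
ION_TYPES = (
    "a",
    "b",
    "c",
    "c_rad",
    "y",
    "z_rad",
    "z_prime",
    "M+H",
    "M+2H_red",
)

N_TERMINAL_TYPES = frozenset({"a", "b", "c", "c_rad"})
C_TERMINAL_TYPES = frozenset({"y", "z_rad", "z_prime"})
PRECURSOR_TYPES = frozenset({"M+H", "M+2H_red"})

#: Tie-break precedence when one peak matches several ions at equal ppm.
TYPE_PRECEDENCE = ("c", "c_rad", "z_rad", "z_prime", "y", "b", "a", "M+2H_red", "M+H")


class PeptideError(ValueError):
    """Raised for malformed peptide strings or invalid modifications."""


@dataclass(frozen=True)
class AnnotatedPeptide:
    """A peptide sequence with a modification map and computed mass.

    Parameters
    ----------
    sequence:
        Plain one-letter residue string (modifications stripped).
    mods:
        Map of 1-based residue index -> modification name.  Index 0 is
        reserved for the N-terminal acetyl.
    """

    sequence: str
    mods: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise PeptideError(f"unknown residue {aa!r}")
        for idx, name in self.mods.items():
            if name not in MOD_DELTAS:
                raise PeptideError(f"unknown modification {name!r}")
            if name == "phospho":
                if not 1 <= idx <= len(self.sequence):
                    raise PeptideError(f"phosphosite index {idx} out of range")
                if self.sequence[idx - 1] not in PHOSPHORYLATABLE:
                    raise PeptideError(
                        f"phospho on {self.sequence[idx - 1]}{idx}: not S/T/Y"
                    )
            elif name == "acetyl" and idx != 0:
                raise PeptideError("acetyl is N-terminal only (index 0)")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mass(self) -> float:
        """Monoisotopic neutral mass M (Da)."""
        m = sum(RESIDUE_MASS[aa] for aa in self.sequence) + H2O
        m += sum(MOD_DELTAS[name] for name in self.mods.values())
        return m

    @property
    def phosphosites(self) -> tuple[int, ...]:
        return tuple(sorted(i for i, n in self.mods.items() if n == "phospho"))

    def prefix_mass(self, site: int) -> float:
        """Sum of residue + modification masses over residues ``1..site``."""
        m = sum(RESIDUE_MASS[aa] for aa in self.sequence[:site])
        m += sum(
            MOD_DELTAS[n] for i, n in self.mods.items() if 0 <= i <= site
        )
        return m

    def suffix_mass(self, site: int) -> float:
        """Sum of residue + modification masses over residues ``site+1..N``."""
        m = sum(RESIDUE_MASS[aa] for aa in self.sequence[site:])
        m += sum(MOD_DELTAS[n] for i, n in self.mods.items() if i > site)
        return m


_TOKEN = re.compile(r"p?[A-Z]")


def build_peptide(text: str) -> AnnotatedPeptide:
    """Parse a sequence string such as ``"APLpSFRGSLPKSYVK"``.

    ``pS``/``pT``/``pY`` mark phosphosites; an ``Ac-`` prefix marks
    N-terminal acetylation.
    """
    mods: dict[int, str] = {}
    if text.startswith("Ac-"):
        mods[0] = "acetyl"
        text = text[3:]
    residues = []
    pos = 0
    for tok in _TOKEN.finditer(text):
        if tok.start() != pos:
            raise PeptideError(f"cannot parse {text!r} at offset {pos}")
        pos = tok.end()
        t = tok.group()
        if t.startswith("p"):
            mods[len(residues) + 1] = "phospho"
            t = t[1]
        residues.append(t)
    if pos != len(text) or not residues:
        raise PeptideError(f"cannot parse {text!r}")
    return AnnotatedPeptide("".join(residues), mods)


@dataclass(frozen=True)
class TheoreticalIon:
    """One theoretical fragment (or precursor-derived) ion."""

    ion_type: str
    site: int | None  # cleavage site 1..N-1; None for precursor species
    charge: int
    neutral_loss: float
    mz: float

    @property
    def label(self) -> str:
        if self.ion_type in PRECURSOR_TYPES:
            base = self.ion_type
        else:
            n = self.site
            base = f"{self.ion_type}{n}"
        if self.neutral_loss:
            base += "-H3PO4" if abs(self.neutral_loss - H3PO4) < 1e-6 else "-loss"
        if self.charge > 1:
            base += f"^{self.charge}+"
        return base


def _fragment_length(ion: TheoreticalIon, n_residues: int) -> int | None:
    """Length index printed in the field's cN/zN notation (c_i has i = site,
    z_j has j = N − site)."""
    if ion.site is None:
        return None
    if ion.ion_type in N_TERMINAL_TYPES:
        return ion.site
    return n_residues - ion.site


def neutral_fragment_mass(
    pep: AnnotatedPeptide, ion_type: str, site: int
) -> float:
    """Neutral mass of a backbone fragment of ``pep`` cleaved at ``site``."""
    if not 1 <= site <= pep.length - 1:
        raise ValueError(f"site {site} outside 1..{pep.length - 1}")
    if ion_type in N_TERMINAL_TYPES:
        b = pep.prefix_mass(site)
        if ion_type == "b":
            return b
        if ion_type == "a":
            return b - CO
        c = b + NH3
        return c if ion_type == "c" else c - H
    if ion_type in C_TERMINAL_TYPES:
        y = pep.suffix_mass(site) + H2O
        if ion_type == "y":
            return y
        z_rad = y - NH2
        return z_rad if ion_type == "z_rad" else z_rad + H
    raise ValueError(f"{ion_type!r} is not a site-bearing ion type")


def theoretical_ions(
    pep: AnnotatedPeptide,
    types: tuple[str, ...] = ("c", "c_rad", "z_rad", "z_prime"),
    charges: tuple[int, ...] = (1,),
    losses: tuple[float, ...] = (0.0,),
) -> list[TheoreticalIon]:
    """Enumerate every requested (type, site, charge, loss) combination.

    m/z = (neutral + charge·m_p − loss) / charge; the charge-reduced
    species ``M+2H_red`` is the intact precursor carrying two protons
    observed at charge 1 after electron capture.
    """
    unknown = set(types) - set(ION_TYPES)
    if unknown:
        raise ValueError(f"unknown ion types {sorted(unknown)}")
    if any(z < 1 for z in charges):
        raise ValueError("charges must be >= 1")
    out: list[TheoreticalIon] = []
    for t in types:
        if t in PRECURSOR_TYPES:
            # M+H singly protonated; M+2H_red keeps both protons at z=1
            neutral = pep.mass + (PROTON if t == "M+2H_red" else 0.0)
            for loss in losses:
                mz = neutral + PROTON - loss
                if mz > 0:
                    out.append(TheoreticalIon(t, None, 1, loss, mz))
            continue
        for site in range(1, pep.length):
            neutral = neutral_fragment_mass(pep, t, site)
            for z in charges:
                for loss in losses:
                    mz = (neutral + z * PROTON - loss) / z
                    if mz > 0:
                        out.append(TheoreticalIon(t, site, z, loss, mz))
    return out


def ion_by_label(
    pep: AnnotatedPeptide, label: str, charge: int = 1
) -> TheoreticalIon:
    """Build the ion named in cN/zN table notation.

    ``"c12"`` (even-electron c), ``"c12_rad"`` (c•), ``"z11_rad"`` (z•),
    ``"z11"`` (z′, the H-attached even-electron form printed as plain z),
    ``"y9"``, ``"M+H"``, ``"M+2H_red"``; a ``"-H3PO4"`` suffix adds the
    phosphoric-acid neutral loss.
    """
    loss = 0.0
    if label.endswith("-H3PO4"):
        loss = H3PO4
        label = label[: -len("-H3PO4")]
    if label in PRECURSOR_TYPES:
        neutral = pep.mass + (PROTON if label == "M+2H_red" else 0.0)
        return TheoreticalIon(label, None, 1, loss, neutral + PROTON - loss)
    m = re.fullmatch(r"([abcyz])(\d+)(_rad)?", label)
    if not m:
        raise ValueError(f"cannot parse ion label {label!r}")
    letter, num, rad = m.group(1), int(m.group(2)), bool(m.group(3))
    if letter in "abc":
        ion_type = {"a": "a", "b": "b", "c": "c_rad" if rad else "c"}[letter]
        site = num
    else:
        # printed plain z is the even-electron z' species
        ion_type = "y" if letter == "y" else ("z_rad" if rad else "z_prime")
        site = pep.length - num
    neutral = neutral_fragment_mass(pep, ion_type, site)
    return TheoreticalIon(
        ion_type, site, charge, loss, (neutral + charge * PROTON - loss) / charge
    )


# ---------------------------------------------------------------------------
# peak lists and assignment


@dataclass
class PeakList:
    """Centroided peaks: m/z values with intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity shapes differ")
        if len(self.mz) and (self.mz <= 0).any():
            raise ValueError("m/z values must be positive")
        if len(self.intensity) and (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


def read_peaklist(path: str | Path, label: str | None = None) -> PeakList:
    """Read a two-column delimited text peak list (header optional)."""
    mzs, inten = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\t\s]+", line)
        try:
            m, i = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            continue  # header line
        mzs.append(m)
        inten.append(i)
    return PeakList(np.array(mzs), np.array(inten), label or Path(path).stem)


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(peaks.mz, peaks.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")


@dataclass(frozen=True)
class FragmentAssignment:
    """A theoretical ion matched to an observed peak."""

    ion: TheoreticalIon
    observed_mz: float
    intensity: float
    ppm_error: float
    relative_abundance: float = float("nan")


def assign_peaks(
    peaks: PeakList,
    ions: list[TheoreticalIon],
    tol_ppm: float = 5.0,
) -> list[FragmentAssignment]:
    """Match each peak to the nearest theoretical ion within ``tol_ppm``.

    One peak yields at most one assignment; ties at equal |ppm| are
    broken by ion-type precedence (c > c• > z• > z′ > y > b > a).
    Unmatched peaks are silently dropped.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    prec = {t: i for i, t in enumerate(TYPE_PRECEDENCE)}
    out = []
    for mz_obs, inten in zip(peaks.mz, peaks.intensity):
        best = None
        for ion in ions:
            ppm = (mz_obs - ion.mz) / ion.mz * 1e6
            if abs(ppm) > tol_ppm:
                continue
            key = (abs(ppm), prec.get(ion.ion_type, len(prec)))
            if best is None or key < best[0]:
                best = (key, ion, ppm)
        if best is not None:
            _, ion, ppm = best
            out.append(FragmentAssignment(ion, mz_obs, inten, ppm))
    return out


def relative_abundance(
    assignments: list[FragmentAssignment],
) -> list[FragmentAssignment]:
    """Express each intensity as percent of the summed assigned intensity.

    The denominator includes every assigned species — charge-reduced
    precursor included — so the values sum to exactly 100.
    """
    total = sum(a.intensity for a in assignments)
    if not assignments or total <= 0:
        raise ValueError("need at least one assignment with positive intensity")
    return [
        replace(a, relative_abundance=100.0 * a.intensity / total)
        for a in assignments
    ]


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageMap:
    """Assigned-fragment counts per backbone cleavage site."""

    site_cover: np.ndarray  # counts at sites 1..N-1 (index 0 = site 1)
    n_residues: int

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Maximal runs of zero-count sites, as inclusive (start, end)."""
        gaps = []
        run = None
        for s in range(1, self.n_residues):
            if self.site_cover[s - 1] == 0:
                run = (run[0], s) if run else (s, s)
            elif run:
                gaps.append(run)
                run = None
        if run:
            gaps.append(run)
        return gaps

    def count_at(self, site: int) -> int:
        if not 1 <= site <= self.n_residues - 1:
            raise IndexError(f"site {site} outside 1..{self.n_residues - 1}")
        return int(self.site_cover[site - 1])


def coverage_map(
    assignments: list[FragmentAssignment], pep: AnnotatedPeptide
) -> CoverageMap:
    """Count assigned site-bearing fragments per cleavage site.

    a/b/c ions at site ``i`` increment site ``i``; y/z ions of length
    ``j`` increment site ``N − j``.  Precursor-derived species (M+H,
    charge-reduced) increment nothing.
    """
    cover = np.zeros(pep.length - 1, dtype=int)
    for a in assignments:
        if a.ion.site is not None:
            cover[a.ion.site - 1] += 1
    return CoverageMap(cover, pep.length)


@dataclass(frozen=True)
class GapReport:
    """Cleavage sites separating two residues and their fragment support."""

    sites: tuple[int, ...]
    n_fragments: int
    uncovered_sites: tuple[int, ...]


def gap_between(cov: CoverageMap, res_a: int, res_b: int) -> GapReport:
    """Fragment support at the cleavages separating residues a and b.

    The cleavages whose products would separate residue ``res_a`` from
    residue ``res_b`` are the sites ``res_a <= s < res_b``; if a
    noncovalent contact ties the two residues together, fragments at
    those sites cannot separate and the count is zero.
    """
    if not (1 <= res_a < res_b <= cov.n_residues):
        raise IndexError(
            f"need 1 <= {res_a} < {res_b} <= {cov.n_residues}"
        )
    sites = tuple(range(res_a, res_b))
    count = int(sum(cov.site_cover[s - 1] for s in sites))
    zeros = tuple(s for s in sites if cov.site_cover[s - 1] == 0)
    return GapReport(sites, count, zeros)
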