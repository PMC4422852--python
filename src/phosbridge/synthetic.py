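"""Seeded synthetic fixtures for every pipeline stage.

All generators are deterministic functions of (parameters, seed), and
each plants a ground truth the corresponding analysis stage must
recover: coarse-grained conformers with specified sub-4 Å contacts
(distance analysis), drift times from a known power law (calibration),
peak lists realizing specified fragment abundances (assignment and
coverage), and Gaussian-mixture arrival-time profiles (peak detection).

Conformer realism is deliberately minimal — a persistent random walk of
Cα atoms carrying named charged pseudo-atoms, no force field — because
the claims under test concern distances, CCS filtering, clustering and
classification, not conformational energetics.  Residue and atom naming
follows PDB conventions (SEP for phosphoserine, NZ, NE/NH1/NH2, O1P-O3P)
so force-field-derived PDB files are drop-in compatible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .calibration import CalibrantEntry
from .ccs import Structure
from .constants import PROTON
from .fragments import AnnotatedPeptide, PeakList, build_peptide, ion_by_label
from .interactions import PHOSPHATE_ATOMS, SITE_ATOMS

CA_STEP = 3.8  # Å, consecutive Cα spacing


@dataclass(frozen=True)
class ContactSpec:
    """A planted (or explicitly absent) phosphate/basic-site contact."""

    pair: tuple[int, int]  # residue indices, order free
    distance: float  # Å, target minimum distance when present
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and not self.distance < 4.0:
            raise ValueError("planted contacts must be < 4 Å")
        if not self.present and self.distance < 6.0:
            raise ValueError("absent contacts must allow >= 6 Å clearance")


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _triad(center: np.ndarray, spread: float, rng: np.random.Generator) -> np.ndarray:
    """Three points on a small circle around ``center`` (guanidinium N,
    phosphate O geometry stand-in)."""
    e1 = _unit(rng)
    e2 = np.cross(e1, _unit(rng))
    e2 /= np.linalg.norm(e2)
    ang = 2 * np.pi * np.arange(3) / 3
    return center + spread * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)


def _build_single_conformer(
    pep: AnnotatedPeptide,
    contacts: list[ContactSpec],
    rng: np.random.Generator,
    scale: float,
    label: str,
    min_clearance: float = 6.0,
    max_retries: int = 50,
) -> Structure:
    seq = pep.sequence
    n = pep.length
    psites = set(pep.phosphosites)

    for _attempt in range(max_retries):
        # persistent random walk of Cα atoms
        ca = np.zeros((n, 3))
        d = _unit(rng)
        for i in range(1, n):
            d = d + 0.9 * _unit(rng)
            d /= np.linalg.norm(d)
            ca[i] = ca[i - 1] + CA_STEP * scale * d

        elements, coords, res_ids, res_names, atom_names = [], [], [], [], []

        def add(el, xyz, rid, rname, aname):
            elements.append(el)
            coords.append(np.asarray(xyz, dtype=float))
            res_ids.append(rid)
            res_names.append(rname)
            atom_names.append(aname)

        group_index: dict[int, list[int]] = {}

        for i, aa in enumerate(seq, start=1):
            rname = (
                "SEP" if i in psites else protein_letters_1to3[aa].upper()
            )
            if i == 1:
                add("N", ca[0] + 1.45 * _unit(rng), 1, rname, "N")
                group_index.setdefault(1, []).append(len(coords) - 1)
            add("C", ca[i - 1], i, rname, "CA")
            if aa == "K":
                add("N", ca[i - 1] + 2.5 * _unit(rng), i, rname, "NZ")
                group_index.setdefault(i, []).append(len(coords) - 1)
            elif aa == "R":
                center = ca[i - 1] + 2.5 * _unit(rng)
                for name, xyz in zip(("NE", "NH1", "NH2"), _triad(center, 1.15, rng)):
                    add("N", xyz, i, rname, name)
                    group_index.setdefault(i, []).append(len(coords) - 1)
            if i in psites:
                p = ca[i - 1] + 3.0 * _unit(rng)
                add("P", p, i, rname, "P")
                for name, xyz in zip(("O1P", "O2P", "O3P"), _triad(p, 1.5, rng)):
                    add("O", xyz, i, rname, name)
                    group_index.setdefault(i, []).append(len(coords) - 1)

        coords = np.array(coords)
        charged_names = set(PHOSPHATE_ATOMS) | {
            a for names in SITE_ATOMS.values() for a in names
        }

        def group_coords(res: int) -> np.ndarray:
            idx = [
                j
                for j in group_index.get(res, [])
                if atom_names[j] in charged_names
            ]
            if not idx:
                raise ValueError(f"residue {res} carries no charged group")
            return np.array(idx)

        def min_dist(ia: np.ndarray, ib: np.ndarray) -> tuple[float, int, int]:
            diffs = coords[ia][:, None, :] - coords[ib][None, :, :]
            dmat = np.sqrt((diffs**2).sum(axis=2))
            k = np.unravel_index(np.argmin(dmat), dmat.shape)
            return float(dmat[k]), ia[k[0]], ib[k[1]]

        def mover(a: int, b: int) -> tuple[int, int]:
            """Move the non-phosphate partner (or b) toward/away from a."""
            return (b, a) if b in psites else (a, b)

        ok = True
        # satisfy planted contacts by translating the mobile group
        for spec in contacts:
            if not spec.present:
                continue
            anchor, mobile = mover(*spec.pair)
            ia, ib = group_coords(anchor), group_coords(mobile)
            for _ in range(20):
                dmin, ja, jb = min_dist(ia, ib)
                if abs(dmin - spec.distance) <= 0.05:
                    break
                direction = coords[jb] - coords[ja]
                norm = np.linalg.norm(direction)
                direction = _unit(rng) if norm < 1e-9 else direction / norm
                shift = coords[ja] + spec.distance * direction - coords[jb]
                coords[ib] += shift
            else:
                ok = False
            if not ok:
                break
        if not ok:
            continue

        # push every unplanted phosphate/basic pair beyond the clearance
        planted = {tuple(sorted(s.pair)) for s in contacts if s.present}
        basic_res = [
            r for r in group_index if r not in psites
        ]
        for ps in psites:
            ip = group_coords(ps)
            for r in basic_res:
                if tuple(sorted((ps, r))) in planted:
                    continue
                ir = group_coords(r)
                for _ in range(20):
                    dmin, jp, jr = min_dist(ip, ir)
                    if dmin >= min_clearance:
                        break
                    away = coords[jr] - coords[jp]
                    norm = np.linalg.norm(away)
                    away = _unit(rng) if norm < 1e-9 else away / norm
                    coords[ir] += (min_clearance + 0.5 - dmin) * away
                else:
                    ok = False
            if not ok:
                break
        if not ok:
            continue

        # verify nothing broke anything else
        violated = False
        for spec in contacts:
            a, b = spec.pair
            dmin, _, _ = min_dist(group_coords(a), group_coords(b))
            if spec.present and abs(dmin - spec.distance) > 0.1:
                violated = True
            if not spec.present and dmin < min_clearance:
                violated = True
        for ps in psites:
            for r in basic_res:
                if tuple(sorted((ps, r))) in planted:
                    continue
                dmin, _, _ = min_dist(group_coords(ps), group_coords(r))
                if dmin < min_clearance:
                    violated = True
        if violated:
            continue

        return Structure(
            np.array(elements),
            coords,
            np.array(res_ids),
            np.array(res_names),
            np.array(atom_names),
            label,
        )
    raise RuntimeError(
        f"could not satisfy contact geometry after {max_retries} retries"
    )


def gen_conformers(
    sequence: str,
    n: int,
    contacts: list[ContactSpec] | None = None,
    seed: int = 0,
    spread: float = 0.0,
    out_dir: str | Path | None = None,
) -> list[Structure]:
    """Generate ``n`` coarse-grained conformers with planted contacts.

    Each structure is a Cα random walk carrying charged pseudo-atom
    groups; every present :class:`ContactSpec` is satisfied to ±0.1 Å
    and every other phosphate/basic pair is kept ≥ 6 Å apart.
    ``spread`` scales the chain step per structure by a uniform factor
    in [1 − spread, 1 + spread], spreading the ensemble's CCS around its
    center.  Deterministic per seed; with ``out_dir`` each conformer is
    also written as a PDB file.
    """
    pep = build_peptide(sequence)
    contacts = list(contacts or [])
    valid = set(range(1, pep.length + 1))
    for spec in contacts:
        if not set(spec.pair) <= valid:
            raise ValueError(f"contact pair {spec.pair} outside 1..{pep.length}")
    out = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        scale = 1.0 + spread * rng.uniform(-1.0, 1.0)
        s = _build_single_conformer(pep, contacts, rng, scale, f"conf_{i:04d}")
        out.append(s)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in out:
            write_pdb(s, out_dir / f"{s.label}.pdb")
    return out


def structure_to_pdb(s: Structure) -> str:
    """Render a structure as standard fixed-column PDB text."""
    lines = []
    for i in range(len(s)):
        name = s.atom_names[i]
        name_field = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = s.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {name_field}"
            f" {s.res_names[i]:>3s} A{int(s.res_ids[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {s.elements[i]:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(s: Structure, path: str | Path) -> None:
    Path(path).write_text(structure_to_pdb(s))


# ---------------------------------------------------------------------------
# calibration fixtures


@dataclass
class CalibrantTable:
    """Synthetic calibrant set with its generating ground truth."""

    entries: list[CalibrantEntry]
    true_A: float
    true_X: float
    edc_coefficient: float


def gen_calibrants(
    A: float,
    X: float,
    edc_coefficient: float,
    n: int = 20,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> CalibrantTable:
    """Peptide-like calibrants whose drift times invert a known power law.

    Masses are sampled over a tryptic-peptide range (600-2500 Da,
    charges 1-3) with literature-style CCS on a mass power law plus 2%
    scatter; the corrected drift time is t′ = (Ω′/A)^(1/X) with
    multiplicative log-normal noise of ``noise_frac``, and the measured
    drift time adds back the EDC flight term.
    """
    if A <= 0 or X <= 0:
        raise ValueError("A and X must be positive")
    if n < 3:
        raise ValueError("need at least 3 calibrants")
    rng = np.random.default_rng(seed)
    entries = []
    for _ in range(n):
        m = rng.uniform(600.0, 2500.0)
        z = int(rng.integers(1, 4))
        ccs = 10.0 * m**0.5 * float(np.exp(rng.normal(0.0, 0.02)))
        from .calibration import reduced_ccs

        t_prime = (reduced_ccs(ccs, z, m) / A) ** (1.0 / X)
        if noise_frac > 0:
            t_prime *= float(np.exp(rng.normal(0.0, noise_frac)))
        mz = (m + z * PROTON) / z
        t_d = t_prime + edc_coefficient * np.sqrt(mz) / 1000.0
        entries.append(CalibrantEntry(m, z, float(t_d), float(ccs)))
    return CalibrantTable(entries, A, X, edc_coefficient)


def write_calibrants(table: CalibrantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mass\tcharge\tdrift_time_ms\tccs_A2\n")
        for e in table.entries:
            fh.write(f"{e.mass:.4f}\t{e.charge}\t{e.drift_time:.6f}\t{e.ccs:.4f}\n")


# ---------------------------------------------------------------------------
# spectra and profiles


def gen_peaklist(
    pep: AnnotatedPeptide,
    abundances: dict[str, float],
    total_intensity: float = 1e6,
    n_decoys: int = 0,
    seed: int = 0,
    decoy_min_ppm: float = 5.0,
    label: str = "synthetic",
) -> PeakList:
    """A peak list realizing the given relative abundances exactly.

    ``abundances`` maps ion labels (``"c12"``, ``"z11_rad"``,
    ``"M+2H_red"``, ``"...-H3PO4"``) to percent values summing to at
    most 100; the unlisted remainder is assigned to the charge-reduced
    species, so a full-spectrum relative-abundance computation returns
    the listed values unchanged.  Optional decoy peaks are placed at
    least ``decoy_min_ppm`` from every theoretical singly charged ion.
    """
    if any(v < 0 for v in abundances.values()):
        raise ValueError("abundances must be non-negative")
    total_pct = sum(abundances.values())
    if total_pct > 100.0 + 1e-9:
        raise ValueError(f"abundances sum to {total_pct:.4f} > 100")
    shares = dict(abundances)
    remainder = 100.0 - total_pct
    if remainder > 1e-12:
        shares["M+2H_red"] = shares.get("M+2H_red", 0.0) + remainder
    mzs, intens = [], []
    for lab, pct in sorted(shares.items()):
        if pct <= 0:
            continue
        mzs.append(ion_by_label(pep, lab).mz)
        intens.append(total_intensity * pct / 100.0)
    if n_decoys > 0:
        from .constants import H3PO4
        from .fragments import ION_TYPES, theoretical_ions

        all_mz = np.array(
            [i.mz for i in theoretical_ions(pep, ION_TYPES, (1, 2), (0.0, H3PO4))]
        )
        rng = np.random.default_rng(seed)
        lo, hi = 0.9 * min(mzs), 1.1 * max(mzs)
        med = float(np.median(intens))
        placed = 0
        while placed < n_decoys:
            cand = rng.uniform(lo, hi)
            if (np.abs(cand - all_mz) / all_mz * 1e6 < decoy_min_ppm).any():
                continue
            mzs.append(float(cand))
            intens.append(med * rng.uniform(0.05, 0.5))
            placed += 1
    order = np.argsort(mzs)
    return PeakList(np.array(mzs)[order], np.array(intens)[order], label)


def gen_atd(
    peaks: list[tuple[float, float, float]],
    axis: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Arrival-time-style profile: sum of Gaussians on a CCS axis.

    ``peaks`` is a list of (center, width, height).  The default axis
    spans the peaks with 6-sigma margins at 0.5 Å² steps; ``noise`` adds
    seeded white noise of that standard deviation (fraction of the
    maximum height).
    """
    if not peaks:
        raise ValueError("no peaks specified")
    if any(w <= 0 for _, w, _ in peaks):
        raise ValueError("widths must be positive")
    if axis is None:
        lo = min(c - 6 * w for c, w, _ in peaks)
        hi = max(c + 6 * w for c, w, _ in peaks)
        axis = np.arange(lo, hi + 0.5, 0.5)
    axis = np.asarray(axis, dtype=float)
    y = np.zeros_like(axis)
    for c, w, h in peaks:
        y += h * np.exp(-0.5 * ((axis - c) / w) ** 2)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise * max(h for _, _, h in peaks), size=axis.shape)
    return axis, y
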