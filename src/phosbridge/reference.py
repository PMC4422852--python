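"""Published reference data for the six study (phospho)peptides.

The study peptides are APLSFRGSLPKSYVK and its Arg6->Leu analogue, each
unmodified or phosphorylated at Ser4 or Ser12; they are denoted R6pS4,
R6pS12, R6(unmod), L6pS4, L6pS12, L6(unmod).  This module holds, as
plain data, the printed experimental inputs the pipeline consumes:

- ``TABLE2_ABUNDANCE``: ECD fragment relative abundances (% of total
  fragment ion abundance, charge-reduced species included; means of
  three replicate spectra).  The printed tables list only the major
  fragments, so columns sum below 100; the unprinted remainder is
  carried by the charge-reduced species when spectra are synthesized.
- ``TABLE3_CCS``: TWIMS collision cross sections of the least compact
  conformer with percent deviations from the random-coil trendline and
  (for the phosphopeptides) from the unmodified peptide.
- ``TABLE4_CONTACTS``: the published distance analysis of model
  structures — Y/N (<4 Å) contacts between the phosphoserine and each
  basic site, per conformer CCS, protonation hypothesis and cluster
  representative.
- ``ATD_PEAKS``: conformer CCS values read off the mobility profiles.

Transcription notes: the plain ``zN`` rows of the abundance table are
the even-electron z′ species (labelled ``zN`` here) and ``zN_rad`` the
z• radicals; column membership of rows the source renders ambiguously
was fixed by the stated coverage gaps (R6pS4 empty at sites 4-10,
R6pS12 at sites 6-11) and the accompanying narrative.
"""

from __future__ import annotations

from .interactions import BasicSite, ProtonationPattern

#: peptide key -> sequence string with pS markers.
SEQUENCES: dict[str, str] = {
    "R6pS4": "APLpSFRGSLPKSYVK",
    "R6pS12": "APLSFRGSLPKpSYVK",
    "R6unmod": "APLSFRGSLPKSYVK",
    "L6pS4": "APLpSFLGSLPKSYVK",
    "L6pS12": "APLSFLGSLPKpSYVK",
    "L6unmod": "APLSFLGSLPKSYVK",
}

#: ECD fragment relative abundances (%), ion label -> percent.
TABLE2_ABUNDANCE: dict[str, dict[str, float]] = {
    "R6pS4": {
        "z12_rad-H3PO4": 0.82,
        "z12-H3PO4": 0.42,
        "z12_rad": 2.06,
        "z12": 1.39,
        "z13_rad": 0.54,
        "z13": 0.92,
        "c11_rad": 2.34,
        "c11": 3.63,
        "c12_rad": 3.16,
        "c12": 7.39,
        "c13": 2.83,
        "c14": 5.27,
        "M+2H_red-H3PO4": 3.61,
        "M+H": 1.61,
        "M+2H_red": 16.86,
    },
    "R6pS12": {
        "y10": 0.37,
        "z10_rad": 4.65,
        "z10": 5.82,
        "z11_rad": 3.92,
        "z11": 4.58,
        "z12_rad": 0.64,
        "z12": 0.26,
        "z13_rad": 1.42,
        "z13": 0.35,
        "c12_rad": 3.24,
        "c12": 6.51,
        "c13": 0.40,
        "c14": 4.34,
        "M+2H_red-H3PO4": 1.68,
        "M+H": 1.12,
        "M+2H_red": 13.16,
    },
    "R6unmod": {
        "y9": 0.70,
        "z7_rad": 0.59,
        "z7": 2.73,
        "z8": 0.78,
        "z9": 0.18,
        "z10_rad": 5.41,
        "z10": 4.44,
        "z11_rad": 4.36,
        "z11": 3.75,
        "z12_rad": 1.42,
        "z12": 1.16,
        "z13_rad": 0.26,
        "z13": 0.65,
        "c6_rad": 0.15,
        "c6": 0.33,
        "c7_rad": 0.51,
        "c7": 0.75,
        "c8_rad": 0.84,
        "c8": 1.25,
        "c10_rad": 0.43,
        "c10": 1.35,
        "c11_rad": 1.51,
        "c11": 2.25,
        "c12_rad": 1.31,
        "c12": 6.38,
        "c13": 1.97,
        "c14": 2.96,
        "M+H": 1.39,
        "M+2H_red": 11.47,
    },
    "L6pS4": {
        "z10_rad": 2.73,
        "z10": 0.92,
        "z11_rad": 1.25,
        "z11": 4.17,
        "z12_rad": 0.82,
        "z12": 0.66,
        "z13_rad": 0.98,
        "c11_rad": 3.21,
        "c11": 3.90,
        "c12_rad": 2.53,
        "c12": 5.34,
        "c13": 2.60,
        "c14": 5.48,
        "M+2H_red-H3PO4": 3.09,
        "M+H": 2.23,
        "M+2H_red": 15.33,
    },
    "L6pS12": {
        "z10_rad": 5.73,
        "z10": 3.62,
        "z11_rad": 1.24,
        "z11": 1.36,
        "z12_rad": 1.54,
        "z12": 1.15,
        "c11_rad": 2.63,
        "c11": 2.29,
        "c12_rad": 4.72,
        "c12": 6.87,
        "c13": 1.85,
        "c14": 5.11,
        "M+2H_red-H3PO4": 3.97,
        "M+H": 2.49,
        "M+2H_red": 11.39,
    },
    "L6unmod": {
        "z7_rad": 5.14,
        "z7": 5.53,
        "z8": 1.83,
        "z9": 4.15,
        "z10": 4.30,
        "z11_rad": 3.71,
        "z11": 2.72,
        "z12_rad": 2.30,
        "z12": 1.60,
        "c11_rad": 2.10,
        "c11": 6.34,
        "c12": 4.69,
        "c13": 2.18,
        "c14": 5.11,
        "M+H": 1.04,
        "M+2H_red": 8.69,
    },
}

#: TWIMS results: CCS of the least compact conformer (Å²), percent
#: deviation from the random-coil trendline, and (phosphopeptides only)
#: the deviation relative to the unmodified counterpart.
TABLE3_CCS: dict[str, dict[str, float | None]] = {
    "L6pS4": {"ccs": 346.0, "delta_rc": 3.0, "delta_unmod": -6.4},
    "L6pS12": {"ccs": 372.0, "delta_rc": 10.8, "delta_unmod": 1.4},
    "L6unmod": {"ccs": 357.0, "delta_rc": 9.4, "delta_unmod": None},
    "R6pS4": {"ccs": 351.0, "delta_rc": 2.7, "delta_unmod": -7.6},
    "R6pS12": {"ccs": 364.0, "delta_rc": 6.5, "delta_unmod": -3.8},
    "R6unmod": {"ccs": 360.0, "delta_rc": 10.3, "delta_unmod": None},
}

#: Conformer CCS peaks (Å²) read off the arrival-time profiles,
#: most intense last per the "least compact conformer" convention.
ATD_PEAKS: dict[str, tuple[float, ...]] = {
    "R6pS4": (337.0, 351.0),
    "R6pS12": (340.0, 352.0, 364.0),
    "L6pS4": (336.0, 346.0),
    "L6pS12": (345.0, 372.0),
}

#: Basic-site residue indices in the 15-mer scaffold.
BASIC_RESIDUES = {"R6": 6, "K11": 11, "K15": 15, "NT": 1}

PHOSPHOSITES = {"pS4": 4, "pS12": 12}


def protonation_pattern(peptide: str, phosphate: str) -> ProtonationPattern:
    """The two published hypotheses for a doubly protonated ion.

    ``phosphate`` is "deprotonated" (salt-bridge hypothesis: three
    protonated basic sites, phosphate −1) or "neutral" (ionic-H-bond
    hypothesis: two protonated sites, phosphate 0).  For the R6 peptides
    the N-terminus is never protonated (the N-acetylated controls
    fragment identically); for the L6 peptides the N-terminus replaces
    the missing arginine in the deprotonated pattern.
    """
    if phosphate not in ("deprotonated", "neutral"):
        raise ValueError("phosphate must be 'deprotonated' or 'neutral'")
    has_arg = peptide.startswith("R6")
    psite = 4 if "pS4" in peptide else 12
    charge = -1 if phosphate == "deprotonated" else 0
    if has_arg:
        if phosphate == "deprotonated":
            name = "(R+, K11+, K15+, POx-)"
            sites = (
                BasicSite("R6", 6, "arg_guanidinium", True),
                BasicSite("K11", 11, "lys_ammonium", True),
                BasicSite("K15", 15, "lys_ammonium", True),
            )
        else:
            name = "(R+, K15+, POx0)"
            sites = (
                BasicSite("R6", 6, "arg_guanidinium", True),
                BasicSite("K11", 11, "lys_ammonium", False),
                BasicSite("K15", 15, "lys_ammonium", True),
            )
    else:
        if phosphate == "deprotonated":
            name = "(NT+, K11+, K15+, POx-)"
            sites = (
                BasicSite("NT", 1, "n_terminus", True),
                BasicSite("K11", 11, "lys_ammonium", True),
                BasicSite("K15", 15, "lys_ammonium", True),
            )
        else:
            name = "(K11+, K15+, POx0)"
            sites = (
                BasicSite("K11", 11, "lys_ammonium", True),
                BasicSite("K15", 15, "lys_ammonium", True),
            )
    return ProtonationPattern(name, sites, psite, charge)


#: Published distance-analysis matrices: (peptide, phosphate state,
#: conformer CCS) -> per structure {site: contact?}.  Sites not listed
#: for a peptide were not probed (no arginine in the L6 set; the
#: N-terminus is not a printed column).
TABLE4_CONTACTS: dict[tuple[str, str, float], list[dict[str, bool]]] = {
    ("R6pS4", "deprotonated", 337.0): [
        {"R6": False, "K11": True, "K15": False},
        {"R6": False, "K11": False, "K15": False},
        {"R6": True, "K11": False, "K15": True},
    ],
    ("R6pS4", "neutral", 337.0): [
        {"R6": True, "K11": False, "K15": False},
        {"R6": False, "K11": False, "K15": False},
        {"R6": True, "K11": False, "K15": False},
    ],
    ("R6pS4", "deprotonated", 351.0): [
        {"R6": True, "K11": False, "K15": False},
        {"R6": False, "K11": True, "K15": True},
        {"R6": False, "K11": False, "K15": True},
    ],
    ("R6pS4", "neutral", 351.0): [
        {"R6": False, "K11": True, "K15": False},
        {"R6": True, "K11": False, "K15": False},
        {"R6": False, "K11": False, "K15": False},
    ],
    ("R6pS12", "deprotonated", 340.0): [
        {"R6": True, "K11": True, "K15": False},
        {"R6": False, "K11": True, "K15": True},
        {"R6": True, "K11": True, "K15": False},
    ],
    ("R6pS12", "neutral", 340.0): [
        {"R6": False, "K11": False, "K15": False},
        {"R6": False, "K11": True, "K15": False},
        {"R6": False, "K11": False, "K15": True},
    ],
    ("R6pS12", "deprotonated", 352.0): [
        {"R6": False, "K11": True, "K15": True},
        {"R6": False, "K11": True, "K15": True},
        {"R6": False, "K11": True, "K15": True},
    ],
    ("R6pS12", "neutral", 352.0): [
        {"R6": False, "K11": False, "K15": True},
        {"R6": True, "K11": False, "K15": False},
        {"R6": False, "K11": False, "K15": True},
    ],
    ("R6pS12", "deprotonated", 364.0): [
        {"R6": False, "K11": False, "K15": True},
        {"R6": False, "K11": True, "K15": False},
        {"R6": False, "K11": True, "K15": True},
    ],
    ("R6pS12", "neutral", 364.0): [
        {"R6": True, "K11": False, "K15": True},
        {"R6": True, "K11": False, "K15": False},
        {"R6": True, "K11": False, "K15": False},
    ],
    ("L6pS4", "deprotonated", 336.0): [
        {"K11": True, "K15": True},
        {"K11": False, "K15": True},
        {"K11": False, "K15": False},
    ],
    ("L6pS4", "neutral", 336.0): [
        {"K11": False, "K15": False},
        {"K11": True, "K15": False},
        {"K11": True, "K15": False},
    ],
    ("L6pS4", "deprotonated", 346.0): [
        {"K11": True, "K15": False},
        {"K11": False, "K15": True},
        {"K11": False, "K15": True},
    ],
    ("L6pS4", "neutral", 346.0): [
        {"K11": False, "K15": False},
        {"K11": True, "K15": False},
        {"K11": False, "K15": False},
    ],
    ("L6pS12", "deprotonated", 372.0): [
        {"K11": True, "K15": False},
        {"K11": False, "K15": False},
        {"K11": True, "K15": False},
    ],
    ("L6pS12", "neutral", 372.0): [
        {"K11": False, "K15": False},
        {"K11": True, "K15": False},
        {"K11": False, "K15": False},
    ],
}
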