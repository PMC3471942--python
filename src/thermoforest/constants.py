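"""Residue-level reference tables.

All tables are plain dicts keyed by one-letter amino-acid code so a caller can
swap in an alternative scale (e.g. a different max-ASA normalisation) without
touching any computation code.
"""

from __future__ import annotations

# Column order of a PSI-BLAST ASCII PSSM.
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

AMINO_ACIDS = frozenset(PSSM_AA_ORDER)

#: Theoretical maximum accessible surface area per residue, in A^2
#: (Tien et al. 2013, "theoretical" column). Used to normalise absolute ASA
#: into relative solvent accessibility and for the dASA composition feature.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Isoelectric point of the free amino acid (Lehninger values). Used for the
#: pIa composition-difference feature.
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}

#: Default DSSP 8-state to 3-state secondary-structure reduction.
#: H/G/I -> helix, E/B -> sheet, everything else -> coil. The grouping of the
#: isolated beta bridge (B) with E is configurable because conventions differ.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", " ": "C", "-": "C", "C": "C",
}

#: Background amino-acid frequencies (Robinson & Robinson 1991), used by the
#: synthetic sequence generator. Normalised at import time.
BACKGROUND_FREQUENCIES = {
    "A": 0.0780, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0192,
    "Q": 0.0426, "E": 0.0629, "G": 0.0738, "H": 0.0219, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0224, "F": 0.0385, "P": 0.0520,
    "S": 0.0712, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0644,
}
_total = sum(BACKGROUND_FREQUENCIES.values())
BACKGROUND_FREQUENCIES = {k: v / _total for k, v in BACKGROUND_FREQUENCIES.items()}
del _total

#: Residue sets behind the composition-difference features. SMAL is the
#: two-residue set {T, D} by deliberate choice (see docs/methods.md); override
#: via the ``residue_sets`` argument of the feature functions if desired.
RESIDUE_SETS = {
    "POSI": frozenset("RKH"),
    "CHAR": frozenset("RKHDE"),
    "SMAL": frozenset("TD"),
    "TINY": frozenset("AGPS"),
}
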