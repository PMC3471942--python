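"""Per-residue annotation: 3-state secondary structure and exposure states.

Structure mode derives ss3/rsa from DSSP output; sequence mode reads them
from prediction files. Both feed the same :class:`ResidueState` objects, and
mutants inherit the wild type's annotation (fixed-conformation assumption:
point mutations are taken not to change the backbone conformation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import MAX_ASA, SS8_TO_SS3
from .records import ProteinRecord, ValidationError

#: Binary exposure threshold: a residue with >= 25% relative accessible
#: surface area counts as exposed.
RSA_EXPOSED_THRESHOLD = 0.25
#: Upper bound of the intermediate band of the 3-state exposure.
RSA_INTERMEDIATE_UPPER = 0.50

EXPOSURE3_ORDER = ("buried", "intermediate", "exposed")


@dataclass(frozen=True)
class ResidueState:
    ss3: str          # H / E / C
    exposure2: str    # exposed / buried
    exposure3: str    # buried / intermediate / exposed


def ss8_to_ss3(dssp_code: str, mapping=SS8_TO_SS3) -> str:
    """Collapse a DSSP 8-state code to H/E/C (default: H,G,I->H; E,B->E)."""
    try:
        return mapping[dssp_code]
    except KeyError:
        raise ValidationError(f"unknown DSSP secondary-structure code {dssp_code!r}") from None


def relative_sa(asa_A2: float, residue: str, scale=MAX_ASA) -> float:
    """Absolute ASA (A^2) -> relative solvent accessibility, asa / maxASA."""
    if asa_A2 < 0:
        raise ValidationError(f"negative ASA {asa_A2}")
    try:
        max_asa = scale[residue]
    except KeyError:
        raise ValidationError(f"no max-ASA entry for residue {residue!r}") from None
    return asa_A2 / max_asa


def exposure_states(rsa: float,
                    threshold: float = RSA_EXPOSED_THRESHOLD,
                    intermediate_upper: float = RSA_INTERMEDIATE_UPPER) -> tuple[str, str]:
    """(exposure2, exposure3) for one residue.

    A value exactly at a threshold goes to the higher-exposure class.
    """
    if rsa < 0:
        raise ValidationError(f"negative rsa {rsa}")
    exposure2 = "exposed" if rsa >= threshold else "buried"
    if rsa < threshold:
        exposure3 = "buried"
    elif rsa < intermediate_upper:
        exposure3 = "intermediate"
    else:
        exposure3 = "exposed"
    return exposure2, exposure3


def residue_states(protein: ProteinRecord,
                   threshold: float = RSA_EXPOSED_THRESHOLD,
                   intermediate_upper: float = RSA_INTERMEDIATE_UPPER) -> list[ResidueState]:
    """Per-residue states from a protein's attached ss3/rsa layers."""
    if protein.ss is None or protein.rsa is None:
        raise ValidationError(
            f"protein {protein.id!r}: ss/rsa annotation required but absent"
        )
    out = []
    for ss, rsa in zip(protein.ss, protein.rsa):
        e2, e3 = exposure_states(float(rsa), threshold, intermediate_upper)
        out.append(ResidueState(ss3=ss, exposure2=e2, exposure3=e3))
    return out


def annotate_from_dssp(protein: ProteinRecord, ss8: list[str], asa: np.ndarray,
                       mapping=SS8_TO_SS3, scale=MAX_ASA) -> ProteinRecord:
    """Attach ss3/rsa layers derived from DSSP rows (aligned by order)."""
    if len(ss8) != len(protein):
        raise ValidationError(
            f"protein {protein.id!r}: {len(ss8)} DSSP rows vs sequence length {len(protein)}"
        )
    ss3 = [ss8_to_ss3(c, mapping) for c in ss8]
    rsa = np.array([relative_sa(a, aa, scale) for a, aa in zip(asa, protein.sequence)])
    return protein.attach(ss=ss3, rsa=rsa)
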