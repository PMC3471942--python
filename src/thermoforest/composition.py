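"""Site-state and whole-sequence composition features.

Two groups live here:

* the 5 secondary-structure / solvent-accessibility indicators of the
  mutated site(s) on the wild-type protein (one-hot for single-point events,
  fractions for multi-point events);
* the 6 relative-difference features between mutant and wild-type sequence:
  composition changes of positively charged (RKH), charged (RKHDE), small
  (T, D) and tiny (A, G, P, S) residues, plus the change of the mean
  per-residue maximum ASA (dASA) and mean per-residue isoelectric point (pIa).

Every relative-difference slot is value(mutant) - value(wild type), so all
six negate exactly when the two sequences swap roles.
"""

from __future__ import annotations

from .annotations import ResidueState
from .constants import ISOELECTRIC_POINT, MAX_ASA, RESIDUE_SETS
from .records import Substitution, ValidationError

SSSA_FEATURE_NAMES = ("Helix", "Sheet", "Coil", "Exposed", "Buried")
RELDIFF_FEATURE_NAMES = ("POSI", "CHAR", "SMAL", "TINY", "dASA", "pIa")


def sssa_features(states: list[ResidueState], subs: tuple[Substitution, ...]
                  ) -> dict[str, float]:
    """Fraction of mutated sites in each SS state and exposure class."""
    counts = {name: 0 for name in SSSA_FEATURE_NAMES}
    for s in subs:
        if s.position > len(states):
            raise ValidationError(f"no annotation at position {s.position}")
        st = states[s.position - 1]
        counts[{"H": "Helix", "E": "Sheet", "C": "Coil"}[st.ss3]] += 1
        counts["Exposed" if st.exposure2 == "exposed" else "Buried"] += 1
    n = len(subs)
    return {name: c / n for name, c in counts.items()}


def composition_fraction(sequence: str, residue_set) -> float:
    if not sequence:
        raise ValidationError("empty sequence")
    members = frozenset(residue_set)
    return sum(1 for aa in sequence if aa in members) / len(sequence)


def _mean_property(sequence: str, table: dict[str, float]) -> float:
    return sum(table[aa] for aa in sequence) / len(sequence)


def reldiff_features(wt_seq: str, mut_seq: str,
                     residue_sets=RESIDUE_SETS,
                     max_asa=MAX_ASA,
                     pi_table=ISOELECTRIC_POINT) -> dict[str, float]:
    """The six mutant-minus-wild-type relative-difference features."""
    if len(wt_seq) != len(mut_seq):
        raise ValidationError(
            f"sequence length mismatch: {len(wt_seq)} vs {len(mut_seq)}"
        )
    out = {}
    for name in ("POSI", "CHAR", "SMAL", "TINY"):
        rset = residue_sets[name]
        out[name] = composition_fraction(mut_seq, rset) - composition_fraction(wt_seq, rset)
    out["dASA"] = _mean_property(mut_seq, max_asa) - _mean_property(wt_seq, max_asa)
    out["pIa"] = _mean_property(mut_seq, pi_table) - _mean_property(wt_seq, pi_table)
    return out
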