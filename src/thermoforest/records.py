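"""Core domain types: proteins, profiles, substitutions, mutation datasets.

Positions are 1-based throughout, matching the mutation-string convention
(``V66A`` = Val at position 66 replaced by Ala). The ddG sign convention is
positive = stabilizing; it is asserted in exactly one place (dataset load,
see :func:`thermoforest.io.read_mutation_table`'s ``negate_ddg`` flag).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AMINO_ACIDS, PSSM_AA_ORDER


class ValidationError(ValueError):
    """A record violates a datamodel invariant."""


class ParseError(ValueError):
    """An input file does not follow its declared format."""


@dataclass(frozen=True)
class Pssm:
    """A position-specific scoring matrix.

    Parameters
    ----------
    log_odds : (L, 20) int array — log-odds scores, PSI-BLAST column order.
    weighted : (L, 20) float array — weighted observed percentages in [0, 100].
    """

    log_odds: np.ndarray
    weighted: np.ndarray
    aa_order: str = PSSM_AA_ORDER

    def __post_init__(self):
        lo = np.asarray(self.log_odds, dtype=float)
        wt = np.asarray(self.weighted, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 20 or wt.shape != lo.shape:
            raise ValidationError(
                f"PSSM matrices must both be (L, 20); got {lo.shape} and {wt.shape}"
            )
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "weighted", wt)

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    def column(self, aa: str) -> int:
        try:
            return self.aa_order.index(aa)
        except ValueError:
            raise ValidationError(f"unknown residue {aa!r} in PSSM lookup") from None


@dataclass
class ProteinRecord:
    """One wild-type (or constructed mutant) protein with optional layers.

    Optional layers (Ca coordinates, 3-state secondary structure, relative
    solvent accessibility, PSSM) are length-checked against the sequence at
    attach time.
    """

    id: str
    sequence: str
    ca_coords: np.ndarray | None = None  # (L, 3) in Angstrom; NaN rows = missing
    ss: list[str] | None = None          # per-residue H/E/C
    rsa: np.ndarray | None = None        # per-residue relative accessibility >= 0
    profile: Pssm | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: non-standard residue(s) {sorted(bad)}"
            )
        for name in ("ca_coords", "ss", "rsa", "profile"):
            layer = getattr(self, name)
            if layer is not None:
                setattr(self, name, self._check_layer(name, layer))

    def _check_layer(self, name, layer):
        L = len(self.sequence)
        if name == "ca_coords":
            layer = np.asarray(layer, dtype=float)
            if layer.shape != (L, 3):
                raise ValidationError(
                    f"protein {self.id!r}: ca_coords shape {layer.shape} != ({L}, 3)"
                )
        elif name == "ss":
            layer = list(layer)
            if len(layer) != L or any(s not in ("H", "E", "C") for s in layer):
                raise ValidationError(
                    f"protein {self.id!r}: ss layer must be length {L} over H/E/C"
                )
        elif name == "rsa":
            layer = np.asarray(layer, dtype=float)
            if layer.shape != (L,) or np.any(layer < 0):
                raise ValidationError(
                    f"protein {self.id!r}: rsa must be length {L} and non-negative"
                )
        elif name == "profile":
            if len(layer) != L:
                raise ValidationError(
                    f"protein {self.id!r}: PSSM has {len(layer)} rows, sequence {L}"
                )
        return layer

    def attach(self, **layers) -> "ProteinRecord":
        """Return a copy with the given layers attached (length-checked)."""
        return replace(self, **layers)

    def __len__(self) -> int:
        return len(self.sequence)


_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class Substitution:
    """A single-residue substitution, e.g. V66A."""

    wt_aa: str
    position: int  # 1-based
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise ValidationError(f"non-standard residue in substitution {self}")
        if self.wt_aa == self.mut_aa:
            raise ValidationError(f"substitution {self} does not change the residue")
        if self.position < 1:
            raise ValidationError(f"substitution {self}: positions are 1-based")

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        m = _SUB_RE.match(text.strip())
        if not m:
            raise ParseError(f"unparsable substitution string {text!r}")
        return cls(wt_aa=m.group(1), position=int(m.group(2)), mut_aa=m.group(3))

    def reversed(self) -> "Substitution":
        return Substitution(self.mut_aa, self.position, self.wt_aa)

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class MutationRecord:
    """One (multi-)substitution event with its ddG label.

    ddG is in kcal/mol, positive = stabilizing. ``direction`` distinguishes
    experimental forward records from hypothetical reverse records; a
    forward/reverse pair shares ``pair_id``.
    """

    protein_id: str
    subs: tuple[Substitution, ...]
    ddg: float
    direction: str = "forward"
    pair_id: str = ""

    def __post_init__(self):
        if not self.subs:
            raise ValidationError("MutationRecord needs at least one substitution")
        positions = [s.position for s in self.subs]
        if len(set(positions)) != len(positions):
            raise ValidationError(
                f"duplicate substitution positions in {self.mutation_string()}"
            )
        if self.direction not in ("forward", "reverse"):
            raise ValidationError(f"direction must be forward/reverse, got {self.direction!r}")
        object.__setattr__(self, "subs", tuple(sorted(self.subs, key=lambda s: s.position)))
        if not self.pair_id:
            object.__setattr__(
                self, "pair_id", f"{self.protein_id}:{self.mutation_string()}"
            )

    def mutation_string(self) -> str:
        return ",".join(str(s) for s in self.subs)

    def validate_against(self, protein: ProteinRecord) -> None:
        for s in self.subs:
            if s.position > len(protein):
                raise ValidationError(
                    f"{protein.id}: substitution {s} beyond sequence length {len(protein)}"
                )
            found = protein.sequence[s.position - 1]
            if found != s.wt_aa:
                raise ValidationError(
                    f"{protein.id}: substitution {s} but sequence has {found} "
                    f"at position {s.position}"
                )

    def mutant_sequence(self, protein: ProteinRecord) -> str:
        self.validate_against(protein)
        seq = list(protein.sequence)
        for s in self.subs:
            seq[s.position - 1] = s.mut_aa
        return "".join(seq)


@dataclass
class MutationDataset:
    """Mutation records plus the proteins they refer to."""

    records: list[MutationRecord] = field(default_factory=list)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)

    def validate(self) -> None:
        seen_pairs: dict[str, set[str]] = {}
        for rec in self.records:
            protein = self.proteins.get(rec.protein_id)
            if protein is None:
                raise ValidationError(f"record references unknown protein {rec.protein_id!r}")
            rec.validate_against(protein)
            seen_pairs.setdefault(rec.pair_id, set())
            if rec.direction in seen_pairs[rec.pair_id]:
                raise ValidationError(f"duplicate {rec.direction} record for pair {rec.pair_id!r}")
            seen_pairs[rec.pair_id].add(rec.direction)

    @property
    def has_reverse(self) -> bool:
        return any(r.direction == "reverse" for r in self.records)

    def protein_of(self, rec: MutationRecord) -> ProteinRecord:
        return self.proteins[rec.protein_id]

    def __len__(self) -> int:
        return len(self.records)
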