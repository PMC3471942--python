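"""Tetra-peptide fragment potentials and the 13 sequential fragment features.

A potential table maps a length-4 fragment key to a log-ratio score contrasting
two reference corpora (canonically a thermostable set A against a mesostable
set B). Two kinds are supported:

* ``occurrence`` — value(f) = ln((cA(f)+k)/(NA+kK)) - ln((cB(f)+k)/(NB+kK)),
  an additive-pseudocount log frequency ratio between the corpora, optionally
  restricted to fragments in one secondary-structure or exposure state;
* ``propensity`` — value(f) = [ln P(f|state) - ln P(f)] in corpus A minus the
  same quantity in corpus B, i.e. the between-corpus difference of a
  state-conditional enrichment.

Here c are fragment counts, N total fragment counts, k the pseudocount and
K the size of the key space. Unseen fragments score the closed-form value at
zero counts, so a table is defined on its whole key domain.

A mutation event is scored as score(mutant) - score(wild type), where
score(s) sums table values over every contiguous tetra-peptide of s (state
tables: only windows whose majority state matches). Only the <= 4 windows
overlapping each substituted site can differ between the two sequences, and
the feature computation exploits that locality.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .annotations import EXPOSURE3_ORDER, ResidueState
from .records import ValidationError

FRAGMENT_LENGTH = 4
SS_STATES = ("H", "E", "C")
EXPOSURE_STATES = EXPOSURE3_ORDER  # buried / intermediate / exposed

#: Feature name -> (table kind, table state) for the 13 sequential features.
SEQ_FRAG_FEATURES = {
    "FBocc": ("occurrence", None),
    "FBhel": ("occurrence", "H"),
    "FBshe": ("occurrence", "E"),
    "FBcoi": ("occurrence", "C"),
    "FBexp": ("occurrence", "exposed"),
    "FBbur": ("occurrence", "buried"),
    "FBint": ("occurrence", "intermediate"),
    "FDhel": ("propensity", "H"),
    "FDshe": ("propensity", "E"),
    "FDcoi": ("propensity", "C"),
    "FDexp": ("propensity", "exposed"),
    "FDbur": ("propensity", "buried"),
    "FDint": ("propensity", "intermediate"),
}


@dataclass
class PotentialTable:
    """Fragment key -> potential value, with explicit default for unseen keys."""

    kind: str                       # occurrence | propensity
    state: str | None               # None, H/E/C, buried/intermediate/exposed, D43/D2/D1
    values: dict[str, float]
    default: float
    pseudocount: float
    n_keys: int                     # size K of the key domain
    corpus_meta: dict[str, str] = field(default_factory=dict)

    def value(self, fragment: str) -> float:
        return self.values.get(fragment, self.default)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n")
            fh.write(f"# state={self.state if self.state is not None else '-'}\n")
            fh.write(f"# pseudocount={self.pseudocount!r}\n")
            fh.write(f"# n_keys={self.n_keys}\n")
            fh.write(f"# default={self.default!r}\n")
            for key, val in sorted(self.corpus_meta.items()):
                fh.write(f"# meta:{key}={val}\n")
            fh.write("fragment\tvalue\n")
            for frag in sorted(self.values):
                fh.write(f"{frag}\t{self.values[frag]!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "PotentialTable":
        meta, values = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, _, val = line[2:].partition("=")
                    meta[key] = val
                elif line and line != "fragment\tvalue":
                    frag, _, val = line.partition("\t")
                    values[frag] = float(val)
        try:
            state = meta["state"]
            return cls(
                kind=meta["kind"],
                state=None if state == "-" else state,
                values=values,
                default=float(meta["default"]),
                pseudocount=float(meta["pseudocount"]),
                n_keys=int(meta["n_keys"]),
                corpus_meta={k[5:]: v for k, v in meta.items() if k.startswith("meta:")},
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: missing table metadata {exc}") from None


def fragment_state(labels, order) -> str:
    """Assign one state to a 4-residue fragment: majority vote over the four
    labels; a 2-2 tie takes the third residue's label; any residual tie takes
    the earliest state in ``order``."""
    if len(labels) != FRAGMENT_LENGTH:
        raise ValidationError(f"fragment needs {FRAGMENT_LENGTH} labels, got {len(labels)}")
    counts = Counter(labels)
    best = max(counts.values())
    tied = [s for s in order if counts.get(s, 0) == best]
    if len(tied) == 1:
        return tied[0]
    if labels[2] in tied:
        return labels[2]
    return tied[0]


def _state_axis(state: str):
    """(order tuple, ResidueState attribute) for the axis a state lives on."""
    if state in SS_STATES:
        return SS_STATES, "ss3"
    if state in EXPOSURE_STATES:
        return EXPOSURE_STATES, "exposure3"
    raise ValidationError(f"unknown fragment state {state!r}")


def _window_labels(states: list[ResidueState], start: int, attr: str):
    return [getattr(states[start + j], attr) for j in range(FRAGMENT_LENGTH)]


def _window_matches(table: PotentialTable, states, start: int) -> bool:
    if table.state is None:
        return True
    order, attr = _state_axis(table.state)
    return fragment_state(_window_labels(states, start, attr), order) == table.state


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def _count_fragments(sequences, states_list=None, state=None) -> tuple[Counter, int]:
    counts: Counter = Counter()
    if state is not None:
        order, attr = _state_axis(state)
    for idx, seq in enumerate(sequences):
        states = states_list[idx] if states_list is not None else None
        for start in range(len(seq) - FRAGMENT_LENGTH + 1):
            if state is not None:
                if len(states) != len(seq):
                    raise ValidationError("annotation length mismatch in corpus")
                if fragment_state(_window_labels(states, start, attr), order) != state:
                    continue
            counts[seq[start : start + FRAGMENT_LENGTH]] += 1
    return counts, sum(counts.values())


def _log_freq(count: int, total: int, pseudocount: float, n_keys: int) -> float:
    return math.log((count + pseudocount) / (total + pseudocount * n_keys))


def _occurrence_values(counts_a, total_a, counts_b, total_b, pseudocount, n_keys):
    values = {}
    for frag in set(counts_a) | set(counts_b):
        values[frag] = (
            _log_freq(counts_a.get(frag, 0), total_a, pseudocount, n_keys)
            - _log_freq(counts_b.get(frag, 0), total_b, pseudocount, n_keys)
        )
    default = (
        _log_freq(0, total_a, pseudocount, n_keys)
        - _log_freq(0, total_b, pseudocount, n_keys)
    )
    return values, default


def build_occurrence_table(corpus_a, corpus_b, pseudocount: float = 1.0,
                           n_keys: int = 20 ** FRAGMENT_LENGTH,
                           state: str | None = None,
                           states_a=None, states_b=None,
                           meta=None) -> PotentialTable:
    """Unconditioned (or state-restricted) occurrence table contrasting A vs B."""
    if not corpus_a or not corpus_b:
        raise ValidationError("both corpora must be nonempty")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    ca, na = _count_fragments(corpus_a, states_a, state)
    cb, nb = _count_fragments(corpus_b, states_b, state)
    if state is not None and (na == 0 or nb == 0):
        warnings.warn(f"state {state!r} has zero fragments in a corpus; "
                      "table is pseudocount-flat", stacklevel=2)
    values, default = _occurrence_values(ca, na, cb, nb, pseudocount, n_keys)
    return PotentialTable("occurrence", state, values, default, pseudocount,
                          n_keys, dict(meta or {}))


def _propensity_corpus_values(sequences, states_list, state, pseudocount, n_keys):
    c_all, n_all = _count_fragments(sequences)
    c_s, n_s = _count_fragments(sequences, states_list, state)
    values = {}
    for frag in set(c_all) | set(c_s):
        values[frag] = (
            _log_freq(c_s.get(frag, 0), n_s, pseudocount, n_keys)
            - _log_freq(c_all.get(frag, 0), n_all, pseudocount, n_keys)
        )
    default = (
        _log_freq(0, n_s, pseudocount, n_keys)
        - _log_freq(0, n_all, pseudocount, n_keys)
    )
    return values, default, n_s


def build_propensity_table(corpus_a, corpus_b, states_a, states_b, state: str,
                           pseudocount: float = 1.0,
                           n_keys: int = 20 ** FRAGMENT_LENGTH,
                           meta=None) -> PotentialTable:
    """State-conditional enrichment, differenced A - B."""
    if not corpus_a or not corpus_b:
        raise ValidationError("both corpora must be nonempty")
    va, da, na_s = _propensity_corpus_values(corpus_a, states_a, state, pseudocount, n_keys)
    vb, db, nb_s = _propensity_corpus_values(corpus_b, states_b, state, pseudocount, n_keys)
    if na_s == 0 or nb_s == 0:
        warnings.warn(f"state {state!r} has zero fragments in a corpus; "
                      "table is pseudocount-flat", stacklevel=2)
    values = {}
    for frag in set(va) | set(vb):
        values[frag] = va.get(frag, da) - vb.get(frag, db)
    return PotentialTable("propensity", state, values, da - db, pseudocount,
                          n_keys, dict(meta or {}))


def build_state_tables(corpus_a, corpus_b, states_a, states_b,
                       pseudocount: float = 1.0, meta=None
                       ) -> dict[tuple[str, str | None], PotentialTable]:
    """Occurrence + propensity tables for all six states (12 tables)."""
    tables = {}
    for state in SS_STATES + tuple(EXPOSURE_STATES):
        tables[("occurrence", state)] = build_occurrence_table(
            corpus_a, corpus_b, pseudocount, state=state,
            states_a=states_a, states_b=states_b, meta=meta)
        tables[("propensity", state)] = build_propensity_table(
            corpus_a, corpus_b, states_a, states_b, state, pseudocount, meta=meta)
    return tables


def build_sequence_tables(corpus_a, corpus_b, states_a, states_b,
                          pseudocount: float = 1.0, meta=None
                          ) -> dict[tuple[str, str | None], PotentialTable]:
    """The full 13-table set behind the sequential fragment features."""
    tables = {("occurrence", None): build_occurrence_table(
        corpus_a, corpus_b, pseudocount, meta=meta)}
    tables.update(build_state_tables(corpus_a, corpus_b, states_a, states_b,
                                     pseudocount, meta=meta))
    return tables


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_sequence(seq: str, table: PotentialTable,
                   states: list[ResidueState] | None = None) -> float:
    """Sum of table values over all (state-matching) tetra-peptide windows."""
    if table.state is not None and states is None:
        raise ValidationError(f"state table {table.state!r} needs residue states")
    total = 0.0
    for start in range(len(seq) - FRAGMENT_LENGTH + 1):
        if table.state is None or _window_matches(table, states, start):
            total += table.value(seq[start : start + FRAGMENT_LENGTH])
    return total


def _local_window_starts(length: int, positions) -> list[int]:
    starts = set()
    for pos in positions:  # 1-based
        i = pos - 1
        for start in range(max(0, i - FRAGMENT_LENGTH + 1),
                           min(length - FRAGMENT_LENGTH, i) + 1):
            starts.add(start)
    return sorted(starts)


def seq_frag_features(wt_seq: str, mut_seq: str, states: list[ResidueState],
                      tables: dict[tuple[str, str | None], PotentialTable],
                      local: bool = True) -> dict[str, float]:
    """The 13 sequential fragment features, score(mutant) - score(wild type).

    ``local=True`` (default) rescored only the windows overlapping a changed
    site; ``local=False`` rescores both whole sequences (used as a
    cross-check, identical up to float summation order).
    """
    if len(wt_seq) != len(mut_seq):
        raise ValidationError("wild-type and mutant sequences differ in length")
    if len(states) != len(wt_seq):
        raise ValidationError("annotation length mismatch")
    out = {}
    if not local:
        for name, key in SEQ_FRAG_FEATURES.items():
            table = _require_table(tables, key)
            out[name] = score_sequence(mut_seq, table, states) - score_sequence(
                wt_seq, table, states)
        return out

    changed = [i + 1 for i, (a, b) in enumerate(zip(wt_seq, mut_seq)) if a != b]
    starts = _local_window_starts(len(wt_seq), changed)
    for name, key in SEQ_FRAG_FEATURES.items():
        table = _require_table(tables, key)
        delta = 0.0
        for start in starts:
            if table.state is None or _window_matches(table, states, start):
                delta += (table.value(mut_seq[start : start + FRAGMENT_LENGTH])
                          - table.value(wt_seq[start : start + FRAGMENT_LENGTH]))
        out[name] = delta
    return out


def _require_table(tables, key) -> PotentialTable:
    try:
        return tables[key]
    except KeyError:
        raise ValidationError(f"missing potential table {key}") from None
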