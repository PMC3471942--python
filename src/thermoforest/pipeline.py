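"""Assembly of the full per-mutation feature vector.

Structure mode produces 41 named features, sequence mode the 34 that need no
coordinates. Names and order follow the four feature groups:
site secondary structure / solvent accessibility (5), sequence relative
differences (6), evolutionary profile scores (10), sequential fragment
potentials (13) and — structure mode only — Delaunay spatial fragment
potentials (7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    RSA_EXPOSED_THRESHOLD,
    RSA_INTERMEDIATE_UPPER,
    residue_states,
)
from .composition import (
    RELDIFF_FEATURE_NAMES,
    SSSA_FEATURE_NAMES,
    reldiff_features,
    sssa_features,
)
from .delaunay import DEFAULT_EDGE_CUTOFF, DT_FRAG_FEATURES, dt_features, tessellate
from .evo import EVO_FEATURE_NAMES, evo_features
from .fragments import SEQ_FRAG_FEATURES, seq_frag_features
from .records import MutationDataset, MutationRecord, ValidationError

FEATURE_NAMES_SEQUENCE = (
    SSSA_FEATURE_NAMES + RELDIFF_FEATURE_NAMES + EVO_FEATURE_NAMES
    + tuple(SEQ_FRAG_FEATURES)
)
FEATURE_NAMES_STRUCTURE = FEATURE_NAMES_SEQUENCE + tuple(DT_FRAG_FEATURES)

#: The feature slots that are exact differences between mutant and wild type
#: (and therefore negate under forward/reverse swap).
DIFFERENCE_FEATURES = (
    RELDIFF_FEATURE_NAMES + tuple(SEQ_FRAG_FEATURES) + tuple(DT_FRAG_FEATURES)
)


def feature_names(mode: str) -> tuple[str, ...]:
    if mode == "structure":
        return FEATURE_NAMES_STRUCTURE
    if mode == "sequence":
        return FEATURE_NAMES_SEQUENCE
    raise ValidationError(f"mode must be 'structure' or 'sequence', got {mode!r}")


@dataclass
class FeaturePipeline:
    """Turns mutation records into named feature vectors.

    Parameters
    ----------
    tables : the 13 sequential potential tables keyed (kind, state).
    dt_tables : the 7 spatial tables (structure mode only).
    mode : "sequence" (34 features) or "structure" (41 features).
    """

    tables: dict
    dt_tables: dict | None = None
    mode: str = "sequence"
    rsa_threshold: float = RSA_EXPOSED_THRESHOLD
    rsa_intermediate_upper: float = RSA_INTERMEDIATE_UPPER
    window_aggregation: str = "sum"
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF
    _tet_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        feature_names(self.mode)  # validates mode
        if self.mode == "structure" and self.dt_tables is None:
            raise ValidationError("structure mode needs Delaunay potential tables")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return feature_names(self.mode)

    def _tessellation(self, protein):
        if protein.ca_coords is None:
            raise ValidationError(
                f"protein {protein.id!r}: structure mode needs Ca coordinates"
            )
        key = (protein.id, protein.ca_coords.tobytes())
        if key not in self._tet_cache:
            self._tet_cache[key] = tessellate(protein.ca_coords, self.edge_cutoff)
        return self._tet_cache[key]

    def featurize_record(self, dataset: MutationDataset, rec: MutationRecord
                         ) -> dict[str, float]:
        protein = dataset.protein_of(rec)
        if protein.profile is None:
            raise ValidationError(f"protein {protein.id!r}: no sequence profile attached")
        mut_seq = rec.mutant_sequence(protein)
        states = residue_states(protein, self.rsa_threshold, self.rsa_intermediate_upper)

        out: dict[str, float] = {}
        out.update(sssa_features(states, rec.subs))
        out.update(reldiff_features(protein.sequence, mut_seq))
        out.update(evo_features(protein.profile, rec.subs, protein.sequence,
                                self.window_aggregation))
        out.update(seq_frag_features(protein.sequence, mut_seq, states, self.tables))
        if self.mode == "structure":
            tets = self._tessellation(protein)
            out.update(dt_features(protein.sequence, mut_seq, tets, self.dt_tables))
        return out

    def featurize(self, dataset: MutationDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(X, meta) for every record; X columns in canonical feature order."""
        names = self.feature_names
        rows, meta = [], []
        for rec in dataset.records:
            values = self.featurize_record(dataset, rec)
            rows.append([values[n] for n in names])
            meta.append({
                "protein_id": rec.protein_id,
                "mutations": rec.mutation_string(),
                "ddg": rec.ddg,
                "direction": rec.direction,
                "pair_id": rec.pair_id,
            })
        X = pd.DataFrame(np.asarray(rows, dtype=float), columns=list(names))
        if not np.isfinite(X.to_numpy()).all():
            raise ValidationError("non-finite feature values produced")
        return X, pd.DataFrame(meta)
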