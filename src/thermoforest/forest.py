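"""The random-forest stability model and its evaluation protocol.

The modelling surface follows the fitted-model idiom: :class:`StabilityForest`
is built from a :class:`~thermoforest.records.MutationDataset` and a
:class:`~thermoforest.pipeline.FeaturePipeline`; ``fit()`` returns a
:class:`StabilityForestResults` carrying the trained ensemble, importances
and a ``summary()``; ``cross_validate()`` runs the full protocol — reverse
augmentation, identity-clustered fold assignment, per-fold regression
training, pooled out-of-fold evaluation per mutation direction — and returns
a :class:`CVResults` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .folds import FoldAssignment, cluster_and_fold
from .metrics import accuracy, auc_midrank, ks_feature_analysis, pearson_r
from .pipeline import FeaturePipeline
from .records import (
    MutationDataset,
    MutationRecord,
    ProteinRecord,
    ValidationError,
)

N_TREES_DEFAULT = 2000
N_FOLDS_DEFAULT = 5

MUTANT_ID_SEP = "|"


def mutant_protein_id(protein_id: str, mutation_string: str) -> str:
    return f"{protein_id}{MUTANT_ID_SEP}{mutation_string}"


def make_mutant_protein(protein: ProteinRecord, rec: MutationRecord) -> ProteinRecord:
    """The mutant as a protein record.

    The mutant inherits the wild type's coordinates, ss3/rsa annotation and
    sequence profile (fixed-conformation assumption + profile reuse), which
    makes every difference-type feature of the reverse event the exact
    negation of the forward one.
    """
    return replace(
        protein,
        id=mutant_protein_id(protein.id, rec.mutation_string()),
        sequence=rec.mutant_sequence(protein),
    )


def augment_with_reverse(dataset: MutationDataset) -> MutationDataset:
    """Add the hypothetical reverse mutation of every forward record.

    The reverse event swaps wild type and mutant and negates ddG (free energy
    is a state function); afterwards the dataset is perfectly balanced
    whenever no record sits exactly at ddG = 0.
    """
    if dataset.has_reverse:
        raise ValidationError("dataset already contains reverse records")
    dataset.validate()
    proteins = dict(dataset.proteins)
    records = list(dataset.records)
    for rec in dataset.records:
        mutant = make_mutant_protein(dataset.protein_of(rec), rec)
        if mutant.id in proteins:
            raise ValidationError(f"duplicate forward record for pair {rec.pair_id!r}")
        proteins[mutant.id] = mutant
        records.append(MutationRecord(
            protein_id=mutant.id,
            subs=tuple(s.reversed() for s in rec.subs),
            ddg=-rec.ddg,
            direction="reverse",
            pair_id=rec.pair_id,
        ))
    out = MutationDataset(records=records, proteins=proteins)
    out.validate()
    return out


def base_protein_map(dataset: MutationDataset) -> dict[str, str]:
    """Map each reverse record's mutant-protein id to its base wild type."""
    forward_protein = {r.pair_id: r.protein_id for r in dataset.records
                       if r.direction == "forward"}
    out = {}
    for rec in dataset.records:
        if rec.direction == "reverse":
            base = forward_protein.get(rec.pair_id)
            if base is None:
                raise ValidationError(f"reverse record {rec.pair_id!r} has no forward partner")
            out[rec.protein_id] = base
    return out


def train_rf(X, y, n_trees: int = N_TREES_DEFAULT, seed: int = 0
             ) -> RandomForestRegressor:
    """Fit the regression forest (prediction = mean over trees)."""
    if n_trees < 1:
        raise ValidationError(f"n_trees must be >= 1, got {n_trees}")
    model = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


def feature_importance(models, names) -> pd.DataFrame:
    """Impurity-decrease importances, averaged across models.

    Columns: mean, se (standard error across models; NaN for a single model),
    sorted descending by mean.
    """
    if not models:
        raise ValidationError("need at least one trained model")
    mat = np.vstack([m.feature_importances_ for m in models])
    mean = mat.mean(axis=0)
    se = (mat.std(axis=0, ddof=1) / np.sqrt(len(models))
          if len(models) > 1 else np.full(mat.shape[1], np.nan))
    df = pd.DataFrame({"mean": mean, "se": se}, index=list(names))
    df.index.name = "feature"
    return df.sort_values("mean", ascending=False)


def evaluate(meta: pd.DataFrame, y_pred) -> pd.DataFrame:
    """Per-direction AUC / ACC / Pearson R.

    Classification metrics use the zero threshold and exclude experimental
    ddG == 0 records; R is computed on all records of the direction. A
    single-class direction reports AUC as NaN.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    rows = {}
    for direction in ("forward", "reverse"):
        mask = (meta["direction"] == direction).to_numpy()
        if not mask.any():
            continue
        y_true = meta.loc[mask, "ddg"].to_numpy(dtype=float)
        pred = y_pred[mask]
        nz = y_true != 0
        rows[direction] = {
            "AUC": auc_midrank(y_true[nz] > 0, pred[nz]) if nz.any() else np.nan,
            "ACC": accuracy(y_true, pred) if nz.any() else np.nan,
            "R": pearson_r(y_true, pred),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "direction"
    return df


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


@dataclass
class StabilityForest:
    """Random-forest ddG model over an augmented mutation dataset.

    Parameters
    ----------
    dataset : forward-only or already-augmented mutation dataset.
    pipeline : feature pipeline (carries the potential tables and mode).
    n_trees : ensemble size (default 2000).
    n_folds : folds for :meth:`cross_validate` (default 5).
    identity_threshold : clustering threshold for fold assignment.
    """

    dataset: MutationDataset
    pipeline: FeaturePipeline
    n_trees: int = N_TREES_DEFAULT
    n_folds: int = N_FOLDS_DEFAULT
    identity_threshold: float = 0.30
    _featurized: tuple | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.dataset.has_reverse:
            self.dataset = augment_with_reverse(self.dataset)
        self.dataset.validate()

    @classmethod
    def from_files(cls, fasta, mutation_table, tables, dt_tables=None,
                   mode="sequence", **kwargs) -> "StabilityForest":
        from . import io as tio
        proteins = {p.id: p for p in tio.read_fasta(fasta)}
        dataset = tio.read_mutation_table(mutation_table, proteins)
        pipeline = FeaturePipeline(tables=tables, dt_tables=dt_tables, mode=mode)
        return cls(dataset=dataset, pipeline=pipeline, **kwargs)

    def featurized(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        if self._featurized is None:
            self._featurized = self.pipeline.featurize(self.dataset)
        return self._featurized

    def fit(self, seed: int = 0) -> "StabilityForestResults":
        X, meta = self.featurized()
        model = train_rf(X, meta["ddg"], self.n_trees, seed)
        return StabilityForestResults(model=model, pipeline=self.pipeline,
                                      seed=seed, n_train=len(X))

    def cross_validate(self, seed: int = 0) -> "CVResults":
        X, meta = self.featurized()
        base_of = base_protein_map(self.dataset)
        base_proteins = {pid: p for pid, p in self.dataset.proteins.items()
                         if pid not in base_of}
        assignment = cluster_and_fold(base_proteins, self.dataset,
                                      k=self.n_folds,
                                      threshold=self.identity_threshold,
                                      seed=seed)
        assignment.base_of.update(base_of)
        folds = np.array([assignment.fold_of_record(r) for r in self.dataset.records])

        y_pred = np.full(len(X), np.nan)
        models, per_fold_rows = [], []
        for fold in range(1, self.n_folds + 1):
            test = folds == fold
            if not test.any():
                continue
            model = train_rf(X[~test], meta.loc[~test, "ddg"], self.n_trees, seed)
            models.append(model)
            y_pred[test] = model.predict(X[test].to_numpy())
            fold_eval = evaluate(meta.loc[test].reset_index(drop=True), y_pred[test])
            for direction, row in fold_eval.iterrows():
                per_fold_rows.append({"fold": fold, "direction": direction, **row})

        predictions = meta.copy()
        predictions["fold"] = folds
        predictions["y_pred"] = y_pred
        return CVResults(
            metrics=evaluate(meta, y_pred),
            per_fold=pd.DataFrame(per_fold_rows),
            importance=feature_importance(models, self.pipeline.feature_names),
            predictions=predictions,
            fold_assignment=assignment,
            config={"n_trees": self.n_trees, "n_folds": self.n_folds,
                    "identity_threshold": self.identity_threshold,
                    "mode": self.pipeline.mode, "seed": seed},
        )


@dataclass
class StabilityForestResults:
    """A trained forest plus its provenance; supports prediction on new data."""

    model: RandomForestRegressor
    pipeline: FeaturePipeline
    seed: int
    n_train: int

    @property
    def feature_importances(self) -> pd.DataFrame:
        return feature_importance([self.model], self.pipeline.feature_names)

    def predict_dataset(self, dataset: MutationDataset) -> pd.DataFrame:
        X, meta = self.pipeline.featurize(dataset)
        meta["y_pred"] = self.model.predict(X.to_numpy())
        meta["call"] = np.where(meta["y_pred"] > 0, "stabilizing", "destabilizing")
        return meta

    def save(self, path) -> None:
        joblib.dump({"format_version": 1,
                     "model": self.model,
                     "mode": self.pipeline.mode,
                     "feature_names": list(self.pipeline.feature_names),
                     "seed": self.seed,
                     "n_train": self.n_train}, path)

    @classmethod
    def load(cls, path, pipeline: FeaturePipeline) -> "StabilityForestResults":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValidationError(f"{path}: unsupported model file")
        if list(pipeline.feature_names) != payload["feature_names"]:
            raise ValidationError(f"{path}: model was trained with different features")
        return cls(model=payload["model"], pipeline=pipeline,
                   seed=payload["seed"], n_train=payload["n_train"])

    def summary(self) -> str:
        top = self.feature_importances.head(10)
        lines = [
            "Stability random-forest regression",
            f"  mode: {self.pipeline.mode} "
            f"({len(self.pipeline.feature_names)} features)",
            f"  trees: {self.model.n_estimators}   "
            f"training records: {self.n_train}   seed: {self.seed}",
            "  top features by impurity importance:",
        ]
        for name, row in top.iterrows():
            lines.append(f"    {name:<10s} {row['mean']:.4f}")
        return "\n".join(lines)


@dataclass
class CVResults:
    """Pooled clustered cross-validation report."""

    metrics: pd.DataFrame        # direction x {AUC, ACC, R}
    per_fold: pd.DataFrame       # fold, direction, AUC, ACC, R
    importance: pd.DataFrame     # feature -> mean, se
    predictions: pd.DataFrame    # per-record out-of-fold predictions
    fold_assignment: FoldAssignment
    config: dict

    def ks_table(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """KS feature screen (stabilizing vs destabilizing forward records)."""
        if X is None:
            raise ValidationError("pass the feature matrix used for training")
        fwd = (self.predictions["direction"] == "forward").to_numpy()
        return ks_feature_analysis(X.loc[fwd], self.predictions.loc[fwd, "ddg"])

    def summary(self) -> str:
        lines = [
            "Clustered cross-validation report",
            "  config: " + ", ".join(f"{k}={v}" for k, v in sorted(self.config.items())),
            f"  folds: {self.config['n_folds']}   "
            f"records: {len(self.predictions)}",
            "",
            "  direction   AUC     ACC     R",
        ]
        for direction, row in self.metrics.iterrows():
            lines.append(f"  {direction:<10s} {row['AUC']:.3f}   "
                         f"{row['ACC']:.3f}   {row['R']:.3f}")
        lines.append("")
        lines.append("  top features by impurity importance (mean +/- se over folds):")
        for name, row in self.importance.head(10).iterrows():
            se = f"{row['se']:.4f}" if np.isfinite(row["se"]) else "-"
            lines.append(f"    {name:<10s} {row['mean']:.4f} +/- {se}")
        return "\n".join(lines)

    def to_files(self, out_dir) -> None:
        """Write report.tsv / per_fold.tsv / importance.tsv / predictions.tsv
        / report.txt, byte-reproducibly for a fixed config + inputs."""
        from .io import ensure_dir
        out = ensure_dir(out_dir)
        fmt = dict(sep="\t", float_format="%.10g")
        self.metrics.to_csv(out / "report.tsv", **fmt)
        self.per_fold.to_csv(out / "per_fold.tsv", index=False, **fmt)
        self.importance.to_csv(out / "importance.tsv", **fmt)
        self.predictions.to_csv(out / "predictions.tsv", index=False, **fmt)
        (out / "report.txt").write_text(self.summary() + "\n")
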